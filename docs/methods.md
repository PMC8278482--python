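# Methods

## The screening procedure

The package implements a stepped screen for protein biomarkers separating
two pooled sample groups (normal vs high ultimate pH meat), designed for
the common situation where raw identification evidence is abundant but
replicate-level statistics are not: one pooled LC-MS run per group, so all
inference is built on presence/absence logic, coarse protein-score ratios,
and a targeted re-quantification of one proteotypic peptide per candidate.

Assumptions worth stating explicitly:

- **Protein score as a coarse abundance proxy.** Triage treats the
  search-engine protein score as a semiquantitative indicator only: it
  gates which proteins are worth quantifying (ratio ≥ 2 for shared
  proteins), it is never reported as a quantity. Shared proteins with
  ratios ≤ 1.5 are treated as irrelevant; the 1.5–2 gap is deliberately
  conservative and configurable (`score_ratio_threshold`).
- **One peptide represents one protein.** The proteotypic peptide is the
  identified match with the maximum ion score (ties broken by lexicographic
  sequence order so runs are reproducible). No protein inference or
  grouping beyond accession identity is attempted.
- **MS1-only quantification.** Mixed MS1/dd-MS² files are demultiplexed in
  memory; only MS level 1 contributes to XICs.
- **No significance testing.** With one run per group the screen certifies
  descriptors by fold change alone; it does not claim statistical
  significance.

## Pipeline parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `min_ion_score` | 19 | — | peptide acceptance boundary (inclusive); proxy for a 1% decoy FDR derived upstream |
| `score_ratio_threshold` | 2.0 | fold | shared-protein triage boundary (inclusive) |
| `ppm_tol` | 5 | ppm | XIC mass half-window (inclusive) |
| `rt_tol` | 0.5 | min | library-interrogation RT window (inclusive) |
| `align_tol` | 1.0 | min | cross-run apex alignment tolerance (inclusive) |
| `min_scans` | 8 | scans | scans-across-peak for a QUANTIFIED call |
| `pseudo_value` | 100 | fold | pseudo fold change for QUANTIFIED-vs-BLQ/absent pairs |
| `fc_threshold` | 2.0 | fold | certification boundary on normalized area ratio (inclusive) |
| `noise_floor` | percentile rule | counts | see below |

All stated boundaries are inclusive: the settings name accepted values
("minimum of", "tolerance of"), so a value exactly at the boundary passes.

**Noise floor.** The peak detector needs an intensity floor to place peak
bounds. By default it is estimated per XIC as the 10th percentile of the
nonzero trace intensities — robust for targeted assays where most nonzero
points belong to the peak itself — and can be overridden with a fixed
value (`noise_floor`), which is also what the boundary probes do when the
true floor is known. Peak bounds extend from the apex while the trace stays
strictly above the floor; scans-across-peak counts the scans between the
bounds; the area is the trapezoidal integral over the bounds, computed on
raw intensities, with IS normalization applied once per run afterwards
(factor = median area of the QUANTIFIED internal standards).

**Multiple peaks in the window.** The apex is the maximum-intensity
above-floor scan within `rt_tol`; intensity ties resolve to the scan
nearest the expected RT — targeted-assay semantics, where the library RT is
trusted over peak height. If two runs detect peaks more than `align_tol`
apart, the apex farther from the library RT is demoted to ABSENT for
pairing.

**Pseudo fold change.** The pseudo value is applied to QUANTIFIED-vs-BLQ
*and* QUANTIFIED-vs-ABSENT pairs: both express "confidently present in one
group, not quantifiable in the other", and keeping them in one ratio
framework lets exclusive proteins appear in the same certified table. Pairs
with no QUANTIFIED side are unquantifiable and emit nothing (logged).

## The synthetic-data generator

`generate_run` simulates centroid MS1 spectra on a uniform scan grid
(default 0.05 min cycle over 30 min): each peptide is a Gaussian elution
profile `I(t) = A·exp(−(t−t₀)²/2σ²)` with σ = FWHM/2.355, recorded at
`m/z·(1 + ppm·10⁻⁶)`, multiplied by a per-centroid log-normal jitter
(σ_log = 0.05) and dropped entirely below the run's noise floor (default
1000 counts) — the dropout is what makes scans-across-peak behave
realistically. mzML is written as a minimal, standard-conformant 1.1
document (centroid MS1 spectra, uncompressed base64 float64 arrays) by the
package's own writer, and read back by an lxml-based reader that also
handles 32-bit float and zlib-compressed arrays from other producers.

`build_study_fixture` pins the study-like conditions: 66 identified
proteins (60 high / 42 normal), 24 + 6 group-exclusive primaries,
6 secondary candidates with score ratios ≥ 2 (one exactly at 2.0),
30 shared non-candidates with ratios spanning 1.0–1.5, 5 IS peptides of
identical true abundance in both runs, per-run global intensity scales of
1.0/1.25 (normalization is therefore load-bearing), ≤ 2 ppm mass-error
jitter per observation (so identification vs run differences stay ≤ 4 ppm,
inside the 5 ppm window), and RT jitter of ± 0.05 min. True fold changes of
measured candidates span 1.15–45×; BLQ-side peptides use a narrow
(0.08 min) peak with apex ≈ 3.9× the floor, which lands 1–3 scans above
noise at any grid phase; apex intensities sit ≥ 2.4·10⁶ counts so weak-side
truncation at the floor biases areas by well under 1%. Exactly 26 of the 36
candidates carry truth ≥ 2-fold (2 absent-in-normal, 4 BLQ-pseudo,
20 measured), the other 10 stay ≤ 1.8-fold. The seed moves jitter and the
noise stream only — tier structure and certification truth are
seed-invariant, which the tests assert across seeds.

What the generator does **not** emulate: chromatographic tailing, isotope
envelopes, chimeric/interfering signals near a target m/z, MS² content
(dummy fragment spectra exist only to exercise demultiplexing), variable
duty cycles, and retention-time drift beyond small jitter. Passing tests
therefore demonstrate the pipeline's logic and numerics, not robustness to
matrix effects or alignment drift on real chromatography.

## Numerical choices and degenerate inputs

- Trapezoidal integration on the scan grid reproduces the analytic Gaussian
  area within 5% whenever the scan interval ≤ FWHM/8 (property-tested; the
  fixture operates at FWHM/interval = 6 for main peaks, where residual
  truncation and grid error stay ≈ 1–2%).
- Fold-change recovery on the fixture is within 15% of truth for measured
  candidates (dominated by IS-median jitter of a few percent plus
  per-area noise); certified/uncertified truth is separated (≥ 2.2 vs
  ≤ 1.8) so the 26-count is stable across seeds.
- Empty XICs, all-zero traces, peptides with zero apex, empty manifests,
  empty candidate lists and header-only tables all flow through as empty
  results, not errors; a run with no quantifiable internal standard raises,
  since normalization is impossible.
- Identification parsing collects malformed rows with line numbers and
  fails only above 10% bad rows (or on a missing column).

## Known limitations

- Single run per group: no variance estimates, no significance levels.
- One proteotypic peptide per protein: a poorly ionizing or interfered
  peptide silently degrades that protein's quantification; the library
  writer exists so users can curate targets.
- The percentile noise floor assumes the XIC is mostly peak; for very noisy
  untargeted traces a fixed floor should be supplied.
- Cross-run matching is a single RT-tolerance rule; there is no warping or
  match-between-runs beyond it.
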