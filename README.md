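# phuscreen

Stepped, gel-free biomarker screening for two-group bottom-up proteomics,
built around the problem of authenticating defective **DFD ("dark, firm,
dry") meat**: beef from pre-slaughter-stressed cattle whose muscle keeps an
abnormally high ultimate pH (pHu ≥ 6.0, measured ~24 h postmortem). The
sarcoplasmic proteome of normal- and high-pHu pooled samples is compared in
four steps:

1. **Qualitative filter** — per-group identification tables (protein
   accession, Mascot-style protein score, peptide-spectrum matches) are
   accepted when each peptide has an individual **ion score ≥ 19**; proteins
   with no accepted peptide are dropped.
2. **Tiered triage on protein scores** — proteins identified in exactly one
   group are **primary candidates**; shared proteins become **secondary
   candidates** when their protein-score ratio
   `max(s_N/s_H, s_H/s_N) ≥ 2` (the score being a coarse abundance
   indicator). Each candidate contributes its **proteotypic peptide** (the
   match with the maximum ion score) to a targeted library.
3. **Targeted label-free MS1 quantification** — for each library peptide an
   extracted ion chromatogram (XIC) is built from raw centroid MS1 spectra
   (mzML; interleaved dd-MS² spectra are discarded) at **±5 ppm**, a peak is
   sought within **±0.5 min** of the expected retention time, and integrated
   trapezoidally. A peak is reliably **QUANTIFIED** only with
   **≥ 8 scans-across-peak**; 1–7 scans is **BLQ** (below limit of
   quantification), none is **ABSENT**. Areas are normalized per run by the
   median area of spiked internal-standard (IS) peptides, and runs are
   matched at **±1 min**.
4. **Certification** — a candidate is a biomarker when its normalized area
   ratio is **≥ 2**. A peptide quantified in one group but BLQ/absent in the
   other receives a flagged **pseudo fold change of 100**. Function classes
   (metabolic, chaperone/stress, structural-contractile, transport, other)
   are attached from a static annotation table.

A seeded synthetic-data generator (`phuscreen.synthetic_data`) emulates the
whole study — Gaussian elution peaks on a uniform MS1 scan grid, centroid
dropout below a noise floor, log-normal intensity jitter, ≤5 ppm mass
error, spiked IS peptides — so the complete pipeline is testable end to end
with known ground truth and no downloads. Its `build_study_fixture` mirrors
the screening study's structure: 24 high-exclusive + 6 normal-exclusive +
6 secondary = 36 candidates, of which 26 certify (including 2 proteins with
signal in only one run and 4 BLQ pseudo-ratio entries).

## Worked example

```bash
phuscreen simulate --study-fixture --seed 1 --out-dir fx
phuscreen run --ident-normal fx/ident_normal.tsv --ident-high fx/ident_high.tsv \
    --mzml-normal fx/normal.mzML --mzml-high fx/high.mzML \
    --annotation fx/annotation.tsv --out-dir fx/report
```

prints

```
36 candidates, 26 certified biomarkers
report in fx/report
```

and `fx/report/biomarkers.tsv` begins

```
accession  tier       direction  fold_change  pseudo  function_class
ACAA2      PRIMARY    high       100.0        True    metabolic
DBI        PRIMARY    high       100.0        True    transport
HSPA8      SECONDARY  high       100.0        True    chaperone/stress
MYOZ1      PRIMARY    high       100.0        True    structural-contractile
PRDX6      PRIMARY    high       100.0        True    other
```

Reading: triage kept 36 of 66 identified proteins as candidates; targeted
MS1 quantification certified 26 of them at the 2-fold threshold. The rows
shown carry the pseudo fold change 100 — ACAA2 and DBI had no detectable
MS1 trace in the normal run at all, while HSPA8, MYOZ1 and PRDX6 were
detected there at only 1–3 scans (BLQ). Directions say which group is
overabundant. All intermediate tables (filtered identifications,
candidates, library, per-run quantification, fold changes) and a JSON run
log with every threshold are written next to the final table. The same
pipeline runs on real exports: any TSV with the declared columns plus
centroid mzML files.

Stages are also exposed individually (`phuscreen filter|triage|quant|certify`)
and as library functions (`phuscreen.run_pipeline`, `phuscreen.detect_peak`, …).

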