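"""Seeded synthetic LC-MS data for two-group biomarker-screening runs.

Generates per-group identification tables (Mascot-export-like TSV) and raw
MS1 centroid runs in mzML with known ground truth, so the whole screening
pipeline — qualitative filtering, protein-score triage, targeted XIC
quantification, fold-change certification — is testable end to end without
any external download.

Peptides elute as Gaussian peaks: a peptide with apex intensity ``A``,
retention-time apex ``t0`` and full width at half maximum ``w`` contributes

    I(t) = A * exp(-(t - t0)^2 / (2 sigma^2)),   sigma = w / 2.355

to the MS1 scan at time ``t``, recorded at m/z = mz * (1 + ppm * 1e-6).
Each centroid gets multiplicative log-normal jitter; centroids below the
run's noise floor are dropped (centroid dropout), which is what makes the
scans-across-peak statistic behave like it does on a real instrument.
"""

from __future__ import annotations

import base64
import json
import struct
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "PeptideSpec",
    "RunSpec",
    "FixtureProtein",
    "FixtureManifest",
    "ValidationError",
    "generate_run",
    "write_mzml",
    "generate_ident_tables",
    "annotation_table",
    "build_study_fixture",
    "expected_scan_count",
    "apex_for_scan_count",
    "gaussian_peak_area",
    "IDENT_COLUMNS",
    "IS_PREFIX",
]

IDENT_COLUMNS = ["accession", "protein_score", "peptide", "charge", "mz", "rt_min", "ion_score"]

#: accession prefix marking spiked internal-standard (plant) proteins
IS_PREFIX = "IS_"

GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


class Group(str, Enum):
    """Pooled sample group: normal-pHu or high-pHu meat."""

    NORMAL = "normal"
    HIGH = "high"

    def other(self) -> "Group":
        return Group.HIGH if self is Group.NORMAL else Group.NORMAL


class ValidationError(ValueError):
    """A run or peptide specification violates an invariant; names the field."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass
class PeptideSpec:
    """One peptide signal in one synthetic run."""

    sequence: str
    charge: int
    mz_theoretical: float  # Th
    rt_apex: float         # min
    peak_fwhm: float       # min
    apex_intensity: float  # counts
    n_scans_above_noise: int = 0  # target scan support (informational)
    ppm_offset: float = 0.0       # x 1e-6 mass error
    ion_score: float = 50.0

    def validate(self, max_abs_ppm: float = 5.0, duration: float | None = None) -> None:
        if self.charge < 1:
            raise ValidationError(f"charge must be >= 1, got {self.charge} ({self.sequence})")
        if self.mz_theoretical <= 0:
            raise ValidationError(f"mz_theoretical must be > 0 ({self.sequence})")
        if self.peak_fwhm <= 0:
            raise ValidationError(f"peak_fwhm must be > 0 ({self.sequence})")
        if self.apex_intensity < 0:
            raise ValidationError(f"apex_intensity must be >= 0 ({self.sequence})")
        if abs(self.ppm_offset) > max_abs_ppm:
            raise ValidationError(
                f"ppm_offset |{self.ppm_offset}| exceeds bound {max_abs_ppm} ({self.sequence})"
            )
        if self.ion_score < 0:
            raise ValidationError(f"ion_score must be >= 0 ({self.sequence})")
        if duration is not None and not (0.0 <= self.rt_apex <= duration):
            raise ValidationError(
                f"rt_apex {self.rt_apex} outside run duration {duration} ({self.sequence})"
            )

    @property
    def sigma(self) -> float:
        return self.peak_fwhm * GAUSS_FWHM_TO_SIGMA

    @property
    def mz_observed(self) -> float:
        return self.mz_theoretical * (1.0 + self.ppm_offset * 1e-6)

    def intensity_at(self, t: float | np.ndarray) -> float | np.ndarray:
        """Noiseless Gaussian elution profile evaluated at scan time ``t``."""
        return self.apex_intensity * np.exp(-((t - self.rt_apex) ** 2) / (2.0 * self.sigma**2))


@dataclass
class RunSpec:
    """Parameters of one synthetic LC-MS run (uniform MS1 scan grid)."""

    run_id: str
    group: Group
    duration: float        # min
    scan_interval: float   # min (MS1 cycle time)
    noise_floor: float     # counts; centroids below this are dropped
    seed: int
    peptides: list[PeptideSpec] = field(default_factory=list)
    is_peptides: list[PeptideSpec] = field(default_factory=list)
    global_intensity_scale: float = 1.0
    noise_sigma: float = 0.05  # sigma of log-normal multiplicative jitter

    def validate(self) -> None:
        if self.scan_interval <= 0:
            raise ValidationError("scan_interval must be > 0")
        if self.duration / self.scan_interval < 10:
            raise ValidationError("duration/scan_interval must allow >= 10 scans")
        if self.noise_floor < 0:
            raise ValidationError("noise_floor must be >= 0")
        if self.global_intensity_scale <= 0:
            raise ValidationError("global_intensity_scale must be > 0")
        if len(self.is_peptides) < 3:
            raise ValidationError("is_peptides must contain >= 3 internal-standard peptides")
        for pep in list(self.peptides) + list(self.is_peptides):
            pep.validate(duration=self.duration)

    def scan_times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.scan_interval)) + 1
        return np.arange(n) * self.scan_interval


def expected_scan_count(
    apex_intensity: float,
    peak_fwhm: float,
    rt_apex: float,
    scan_interval: float,
    duration: float,
    noise_floor: float,
) -> int:
    """Closed-form count of scan-grid times where the noiseless Gaussian
    profile reaches ``noise_floor`` — the ground-truth scans-across-peak."""
    if apex_intensity < noise_floor or apex_intensity <= 0:
        return 0
    sigma = peak_fwhm * GAUSS_FWHM_TO_SIGMA
    t = np.arange(int(np.floor(duration / scan_interval)) + 1) * scan_interval
    profile = apex_intensity * np.exp(-((t - rt_apex) ** 2) / (2.0 * sigma**2))
    return int(np.sum(profile >= noise_floor))


def gaussian_peak_area(apex_intensity: float, peak_fwhm: float) -> float:
    """Analytic area of a Gaussian elution peak: A * sigma * sqrt(2 pi)."""
    return apex_intensity * peak_fwhm * GAUSS_FWHM_TO_SIGMA * np.sqrt(2.0 * np.pi)


def apex_for_scan_count(
    k: int,
    peak_fwhm: float,
    rt_apex: float,
    scan_interval: float,
    duration: float,
    noise_floor: float,
) -> float:
    """Apex intensity placing exactly ``k`` scan-grid points of a noiseless
    Gaussian peak above the noise floor.

    Solved in closed form: with grid distances from the apex sorted
    ascending, the apex is set so the k-th closest scan sits above the floor
    and the (k+1)-th below it, with the log-domain midpoint giving maximal
    margin on both sides. Raises when the requested count is infeasible for
    the given width/grid combination (tied distances straddling the cut).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    sigma = peak_fwhm * GAUSS_FWHM_TO_SIGMA
    t = np.arange(int(np.floor(duration / scan_interval)) + 1) * scan_interval
    d = np.sort(np.abs(t - rt_apex))
    if k >= d.size:
        raise ValidationError(f"grid has only {d.size} scans, cannot fit k={k}")
    if np.isclose(d[k - 1], d[k]):
        raise ValidationError(
            f"k={k} infeasible: scans {k} and {k + 1} are equidistant from the apex; "
            "shift rt_apex off the grid symmetry point"
        )
    apex = noise_floor * np.exp((d[k - 1] ** 2 + d[k] ** 2) / (4.0 * sigma**2))
    return float(apex)


# ---------------------------------------------------------------------------
# Run generation (mzML)
# ---------------------------------------------------------------------------

def generate_run(spec: RunSpec, include_ms2: bool = False) -> list[dict]:
    """Simulate the MS1 centroid spectra of one run.

    Returns a list of spectrum dicts ``{"time": min, "ms_level": int,
    "mz": ndarray, "intensity": ndarray}`` sorted by time; deterministic for
    a fixed ``spec.seed``. With ``include_ms2`` a dummy fragment spectrum is
    interleaved after each non-empty MS1 scan, so that MS-level
    demultiplexing downstream can be exercised.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    times = spec.scan_times()
    all_peps = list(spec.peptides) + list(spec.is_peptides)

    spectra: list[dict] = []
    for i, t in enumerate(times):
        mzs: list[float] = []
        intens: list[float] = []
        for pep in all_peps:
            if pep.apex_intensity <= 0:
                continue
            base = float(pep.intensity_at(t)) * spec.global_intensity_scale
            # draw jitter unconditionally so the stream is stable across peptides
            jitter = np.exp(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma > 0 else 1.0
            value = base * jitter
            if value < spec.noise_floor:
                continue  # centroid dropout
            mzs.append(pep.mz_observed)
            intens.append(value)
        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs, dtype=np.float64)[order]
        int_arr = np.asarray(intens, dtype=np.float64)[order]
        spectra.append({"time": float(t), "ms_level": 1, "mz": mz_arr, "intensity": int_arr})
        if include_ms2 and mz_arr.size:
            # crude dd-MS2 stand-in: fragment spectrum on the base peak
            frag_mz = np.sort(mz_arr[: min(3, mz_arr.size)] * 0.5)
            spectra.append(
                {
                    "time": float(t) + spec.scan_interval * 0.5,
                    "ms_level": 2,
                    "mz": frag_mz,
                    "intensity": np.full(frag_mz.size, 1e4),
                }
            )
    return spectra


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.tolist())).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="phuscreen" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="phuscreen synthetic run generator"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="phuscreen">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_SPECTRUM_TEMPLATE = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="{type_acc}" name="{type_name}" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(spectra: list[dict], path: str | Path, run_id: str = "run") -> Path:
    """Serialize simulated spectra as a minimal, pyteomics-readable mzML 1.1
    document (centroid mode, uncompressed 64-bit float arrays)."""
    path = Path(path)
    parts = [_MZML_HEADER.format(run_id=escape(run_id, {'"': "&quot;"}), count=len(spectra))]
    for i, sp in enumerate(spectra):
        mz_b64 = _b64(np.asarray(sp["mz"], dtype=np.float64))
        int_b64 = _b64(np.asarray(sp["intensity"], dtype=np.float64))
        level = int(sp.get("ms_level", 1))
        type_acc = "MS:1000579" if level == 1 else "MS:1000580"
        type_name = "MS1 spectrum" if level == 1 else "MSn spectrum"
        parts.append(
            _SPECTRUM_TEMPLATE.format(
                index=i,
                scan=i + 1,
                n=len(sp["mz"]),
                ms_level=level,
                type_acc=type_acc,
                type_name=type_name,
                time=sp["time"],
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                int_len=len(int_b64),
                int_b64=int_b64,
            )
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
    return path


# ---------------------------------------------------------------------------
# Fixture manifest and identification tables
# ---------------------------------------------------------------------------

QUANT_PATTERNS = ("both", "blq_normal", "blq_high", "absent_normal", "ident_only", "is")


@dataclass
class FixtureProtein:
    """Ground truth for one protein of the study-like fixture."""

    accession: str
    presence: str                 # normal-only | high-only | both
    score_normal: float | None
    score_high: float | None
    direction: Group              # group of true overabundance
    true_fold_change: float       # direction-group over the other; 100 for pseudo truth
    quant_pattern: str            # see QUANT_PATTERNS
    function_class: str
    sequence: str = ""
    charge: int = 2
    mz_theoretical: float = 0.0
    rt_base: float = 0.0          # nominal apex, min
    apex_base: float = 0.0        # apex intensity in the overabundant group
    # seeded per-group observations, filled by build_study_fixture
    rt_by_group: dict = field(default_factory=dict)
    ppm_ident_by_group: dict = field(default_factory=dict)
    ppm_run_by_group: dict = field(default_factory=dict)
    extra_peptides: list = field(default_factory=list)  # (seq, charge, mz, rt, ion_score)
    ion_score: float = 60.0

    @property
    def tier(self) -> str | None:
        """Expected triage outcome: PRIMARY, SECONDARY or None."""
        if self.accession.startswith(IS_PREFIX):
            return None
        if self.presence in ("normal-only", "high-only"):
            return "PRIMARY"
        ratio = max(self.score_normal / self.score_high, self.score_high / self.score_normal)
        return "SECONDARY" if ratio >= 2.0 else None

    @property
    def certified_truth(self) -> bool:
        if self.tier is None:
            return False
        return self.true_fold_change >= 2.0


@dataclass
class FixtureManifest:
    """Complete ground truth of a synthetic two-group comparison."""

    proteins: list[FixtureProtein]
    seed: int
    duration: float = 30.0
    scan_interval: float = 0.05
    noise_floor: float = 1000.0
    noise_sigma: float = 0.05
    max_abs_ppm: float = 5.0
    scale_by_group: dict = field(
        default_factory=lambda: {Group.NORMAL.value: 1.0, Group.HIGH.value: 1.25}
    )

    def validate(self) -> None:
        seen: set[str] = set()
        for p in self.proteins:
            if p.accession in seen:
                raise ValidationError(f"duplicate accession {p.accession}")
            seen.add(p.accession)
            if p.presence not in ("normal-only", "high-only", "both"):
                raise ValidationError(f"presence {p.presence!r} invalid ({p.accession})")
            if p.quant_pattern not in QUANT_PATTERNS:
                raise ValidationError(f"quant_pattern {p.quant_pattern!r} invalid ({p.accession})")

    def candidates(self) -> list[FixtureProtein]:
        return [p for p in self.proteins if p.tier is not None]

    def expected_counts(self) -> dict:
        cands = self.candidates()
        return {
            "primary": sum(1 for p in cands if p.tier == "PRIMARY"),
            "primary_high": sum(
                1 for p in cands if p.tier == "PRIMARY" and p.direction is Group.HIGH
            ),
            "primary_normal": sum(
                1 for p in cands if p.tier == "PRIMARY" and p.direction is Group.NORMAL
            ),
            "secondary": sum(1 for p in cands if p.tier == "SECONDARY"),
            "candidates": len(cands),
            "certified": sum(1 for p in cands if p.certified_truth),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = asdict(self)
        for p in payload["proteins"]:
            p["direction"] = p["direction"].value if isinstance(p["direction"], Group) else p["direction"]
        path.write_text(json.dumps(payload, indent=1, default=str))
        return path


def generate_ident_tables(manifest: FixtureManifest) -> dict[Group, pd.DataFrame]:
    """Build the two per-group identification tables (Mascot-export-like).

    A protein present in a group contributes its proteotypic peptide row plus
    any extra peptide rows; group-exclusive proteins appear only in their
    group's table. Raises on duplicate accessions (manifest validation).
    """
    manifest.validate()
    rows: dict[Group, list[dict]] = {Group.NORMAL: [], Group.HIGH: []}
    for p in manifest.proteins:
        groups = {
            "normal-only": [Group.NORMAL],
            "high-only": [Group.HIGH],
            "both": [Group.NORMAL, Group.HIGH],
        }[p.presence]
        for g in groups:
            score = p.score_normal if g is Group.NORMAL else p.score_high
            ppm_ident = p.ppm_ident_by_group.get(g.value, 0.0)
            rt = p.rt_by_group.get(g.value, p.rt_base)
            rows[g].append(
                {
                    "accession": p.accession,
                    "protein_score": score,
                    "peptide": p.sequence,
                    "charge": p.charge,
                    "mz": p.mz_theoretical * (1.0 + ppm_ident * 1e-6),
                    "rt_min": rt,
                    "ion_score": p.ion_score,
                }
            )
            for (seq, charge, mz, prt, iscore) in p.extra_peptides:
                rows[g].append(
                    {
                        "accession": p.accession,
                        "protein_score": score,
                        "peptide": seq,
                        "charge": charge,
                        "mz": mz,
                        "rt_min": prt,
                        "ion_score": iscore,
                    }
                )
    return {g: pd.DataFrame(rows[g], columns=IDENT_COLUMNS) for g in (Group.NORMAL, Group.HIGH)}


def annotation_table(manifest: FixtureManifest) -> pd.DataFrame:
    """Protein -> function-class lookup for the fixture (static annotation)."""
    recs = [
        {"accession": p.accession, "function_class": p.function_class}
        for p in manifest.proteins
        if not p.accession.startswith(IS_PREFIX)
    ]
    return pd.DataFrame(recs, columns=["accession", "function_class"])


# ---------------------------------------------------------------------------
# Study-like fixture
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQSTVWY"


def _tryptic(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_AA), size=length - 1))
    return body + rng.choice(["K", "R"])


# (accession, fold change, quant pattern, function class) for each candidate.
# Certified truth: fold change >= 2 (pseudo patterns carry 100).
_HIGH_PRIMARY = [
    ("DBI", 150.0, "absent_normal", "transport"),
    ("ACAA2", 120.0, "absent_normal", "metabolic"),
    ("PRDX6", 100.0, "blq_normal", "other"),
    ("MYOZ1", 100.0, "blq_normal", "structural-contractile"),
    ("CRYAB", 45.0, "both", "chaperone/stress"),
    ("HSPA1B", 30.0, "both", "chaperone/stress"),
    ("HSPB6", 22.0, "both", "chaperone/stress"),
    ("HSPB8", 17.0, "both", "chaperone/stress"),
    ("DNAJA1", 13.0, "both", "chaperone/stress"),
    ("BAG3", 10.0, "both", "chaperone/stress"),
    ("PARK7", 8.0, "both", "other"),
    ("PEBP1", 6.5, "both", "other"),
    ("GSTP1", 5.0, "both", "metabolic"),
    ("MDH1", 4.2, "both", "metabolic"),
    ("CA3", 3.5, "both", "metabolic"),
    ("ALDH2", 3.0, "both", "metabolic"),
    ("FHL1", 2.6, "both", "structural-contractile"),
    ("TNNT1", 2.2, "both", "structural-contractile"),
    ("BIN1", 1.8, "both", "structural-contractile"),
    ("NDUFS1", 1.7, "both", "metabolic"),
    ("SOD1", 1.6, "both", "other"),
    ("PKM", 1.45, "both", "metabolic"),
    ("ENO3", 1.3, "both", "metabolic"),
    ("AK1", 1.15, "both", "metabolic"),
]
_NORMAL_PRIMARY = [
    ("ALDOC", 100.0, "blq_high", "metabolic"),
    ("GAPDHS", 9.0, "both", "metabolic"),
    ("PYGM", 4.0, "both", "metabolic"),
    ("GPD1", 2.5, "both", "metabolic"),
    ("ALB", 1.7, "both", "transport"),
    ("MYLPF", 1.25, "both", "structural-contractile"),
]
# (accession, score_normal, score_high, fold change, pattern, class)
_SECONDARY = [
    ("HSPA8", 150.0, 300.0, 100.0, "blq_normal", "chaperone/stress"),
    ("HSPB1", 90.0, 210.0, 5.5, "both", "chaperone/stress"),
    ("LDHA", 110.0, 260.0, 3.2, "both", "metabolic"),
    ("PGM1", 320.0, 140.0, 2.4, "both", "metabolic"),
    ("TF", 230.0, 105.0, 1.6, "both", "transport"),
    ("AHNAK", 400.0, 190.0, 1.5, "both", "structural-contractile"),
]
_SHARED_NONCAND = [
    "CKM", "ENO1", "GAPDH", "TPI1", "PGK1", "ALDOA", "PGAM2", "GPI", "PFKM", "LDHB",
    "MDH2", "CS", "ACO2", "FH", "GOT1", "GOT2", "MB", "HBB", "HBA1", "ATP5F1A",
    "ATP5F1B", "ACTB", "ACTA1", "TNNC2", "TNNI2", "MYL1", "MYL3", "TTN", "DES", "VIM",
]
_NONCAND_CLASSES = ["metabolic", "metabolic", "metabolic", "metabolic", "metabolic",
                    "metabolic", "metabolic", "metabolic", "metabolic", "metabolic",
                    "metabolic", "metabolic", "metabolic", "metabolic", "metabolic",
                    "metabolic", "transport", "transport", "transport", "metabolic",
                    "metabolic", "structural-contractile", "structural-contractile",
                    "structural-contractile", "structural-contractile",
                    "structural-contractile", "structural-contractile",
                    "structural-contractile", "structural-contractile", "other"]

_N_IS = 5
_BLQ_FWHM = 0.08     # min; narrow so the above-noise window is 2-3 scans wide
_BLQ_APEX = 3900.0   # ~3.9x the noise floor at apex, ~0.34x two scans out
_MAIN_FWHM = 0.30    # min


def build_study_fixture(seed: int) -> tuple[FixtureManifest, RunSpec, RunSpec]:
    """Construct the packaged study-like fixture: manifest plus the two
    pooled-run specifications.

    The fixture mirrors the structure of the screening study it emulates:
    24 high-exclusive and 6 normal-exclusive identifications (primary tier),
    6 shared proteins with protein-score ratio >= 2 (secondary tier), 30
    shared proteins with score ratio <= 1.5 that must not become candidates,
    and 5 spiked internal-standard peptides of equal true abundance in both
    runs. True abundances are set so that 26 of the 36 candidates carry a
    normalized fold change >= 2 — among them 2 proteins with no signal at
    all in the normal run and 4 detected at 1-3 scans (below the limit of
    quantification) in one run — while the other 10 stay below 1.8-fold.
    The seed moves retention-time and mass-error jitter and the centroid
    noise stream only; tier structure and certification truth are fixed.
    """
    rng = np.random.default_rng(seed)
    proteins: list[FixtureProtein] = []

    def jitters() -> tuple[dict, dict, dict]:
        rt_j = {g.value: float(rng.uniform(-0.05, 0.05)) for g in Group}
        ppm_i = {g.value: float(rng.uniform(-2.0, 2.0)) for g in Group}
        ppm_r = {g.value: float(rng.uniform(-2.0, 2.0)) for g in Group}
        return rt_j, ppm_i, ppm_r

    def extras(rt: float, n: int) -> list:
        out = []
        for k in range(n):
            # one deliberately sub-threshold ion score per protein with 2 extras
            iscore = float(rng.uniform(10.0, 18.5)) if k == 0 and n > 1 else float(rng.uniform(20.0, 45.0))
            out.append(
                (
                    _tryptic(rng, int(rng.integers(8, 14))),
                    int(rng.integers(2, 4)),
                    float(rng.uniform(400.0, 1200.0)),
                    max(0.5, rt + float(rng.uniform(-3.0, 3.0))),
                    iscore,
                )
            )
        return out

    n_targets = len(_HIGH_PRIMARY) + len(_NORMAL_PRIMARY) + len(_SECONDARY) + _N_IS
    mz_slots = 420.0 + 17.0 * np.arange(n_targets)  # unique, >> 5 ppm apart
    rt_slots = 2.0 + 26.0 / (n_targets - 1) * np.arange(n_targets)
    slot = 0

    def make(acc, presence, s_norm, s_high, direction, fc, pattern, fclass, apex):
        nonlocal slot
        rt_j, ppm_i, ppm_r = jitters()
        rt_base = float(rt_slots[slot])
        p = FixtureProtein(
            accession=acc,
            presence=presence,
            score_normal=s_norm,
            score_high=s_high,
            direction=direction,
            true_fold_change=fc,
            quant_pattern=pattern,
            function_class=fclass,
            sequence=_tryptic(rng, int(rng.integers(9, 15))),
            charge=int(rng.integers(2, 4)),
            mz_theoretical=float(mz_slots[slot]),
            rt_base=rt_base,
            apex_base=apex,
            rt_by_group={g: rt_base + rt_j[g] for g in rt_j},
            ppm_ident_by_group=ppm_i,
            ppm_run_by_group=ppm_r,
            extra_peptides=extras(rt_base, int(rng.integers(0, 3))),
            ion_score=float(rng.uniform(46.0, 95.0)),
        )
        proteins.append(p)
        slot += 1
        return p

    for i, (acc, fc, pattern, fclass) in enumerate(_HIGH_PRIMARY):
        make(acc, "high-only", None, float(22.0 + 3.8 * i), Group.HIGH, fc, pattern,
             fclass, apex=2.4e6 + 1.0e5 * i)
    for i, (acc, fc, pattern, fclass) in enumerate(_NORMAL_PRIMARY):
        make(acc, "normal-only", float(25.0 + 14.0 * i), None, Group.NORMAL, fc, pattern,
             fclass, apex=2.8e6 + 1.6e5 * i)
    for i, (acc, s_n, s_h, fc, pattern, fclass) in enumerate(_SECONDARY):
        direction = Group.HIGH if s_h > s_n else Group.NORMAL
        make(acc, "both", s_n, s_h, direction, fc, pattern, fclass, apex=3.2e6 + 1.2e5 * i)
    for i in range(_N_IS):
        make(f"{IS_PREFIX}PRUAV{i + 1}", "both", 180.0, 180.0, Group.NORMAL, 1.0, "is",
             "other", apex=2.6e6 + 4.4e5 * i)

    # shared proteins with near-unity score ratios: identification-only
    ratios = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
    for i, acc in enumerate(_SHARED_NONCAND):
        rt_j, ppm_i, ppm_r = jitters()
        base = 80.0 + 9.0 * i
        r = ratios[i % len(ratios)]
        s_n, s_h = (base * r, base) if i % 2 == 0 else (base, base * r)
        rt_base = float(rng.uniform(2.0, 28.0))
        proteins.append(
            FixtureProtein(
                accession=acc,
                presence="both",
                score_normal=s_n,
                score_high=s_h,
                direction=Group.NORMAL if s_n >= s_h else Group.HIGH,
                true_fold_change=1.0,
                quant_pattern="ident_only",
                function_class=_NONCAND_CLASSES[i],
                sequence=_tryptic(rng, int(rng.integers(9, 15))),
                charge=int(rng.integers(2, 4)),
                mz_theoretical=float(rng.uniform(400.0, 1200.0)),
                rt_base=rt_base,
                rt_by_group={g.value: rt_base + rt_j[g.value] for g in Group},
                ppm_ident_by_group=ppm_i,
                ppm_run_by_group=ppm_r,
                extra_peptides=extras(rt_base, int(rng.integers(1, 3))),
                ion_score=float(rng.uniform(40.0, 520.0)),
            )
        )

    manifest = FixtureManifest(proteins=proteins, seed=seed)
    manifest.validate()

    run_specs = {}
    for g in Group:
        peptides: list[PeptideSpec] = []
        is_peps: list[PeptideSpec] = []
        for p in proteins:
            if p.quant_pattern == "ident_only":
                continue
            apex, fwhm = _signal_in_group(p, g, manifest.noise_floor)
            spec = PeptideSpec(
                sequence=p.sequence,
                charge=p.charge,
                mz_theoretical=p.mz_theoretical,
                rt_apex=p.rt_by_group[g.value],
                peak_fwhm=fwhm,
                apex_intensity=apex,
                n_scans_above_noise=expected_scan_count(
                    apex, fwhm, p.rt_by_group[g.value], manifest.scan_interval,
                    manifest.duration, manifest.noise_floor,
                ),
                ppm_offset=p.ppm_run_by_group[g.value],
                ion_score=p.ion_score,
            )
            (is_peps if p.quant_pattern == "is" else peptides).append(spec)
        run_specs[g] = RunSpec(
            run_id=f"{g.value}_pHu_pool",
            group=g,
            duration=manifest.duration,
            scan_interval=manifest.scan_interval,
            noise_floor=manifest.noise_floor,
            seed=int((seed * 2 + (0 if g is Group.NORMAL else 1)) % (2**31 - 1)),
            peptides=peptides,
            is_peptides=is_peps,
            global_intensity_scale=manifest.scale_by_group[g.value],
            noise_sigma=manifest.noise_sigma,
        )
    return manifest, run_specs[Group.NORMAL], run_specs[Group.HIGH]


def _signal_in_group(p: FixtureProtein, g: Group, noise_floor: float) -> tuple[float, float]:
    """True apex intensity and peak width of protein ``p`` in run group ``g``."""
    if p.quant_pattern == "is":
        return p.apex_base, _MAIN_FWHM
    overabundant = g is p.direction
    if p.quant_pattern == "both":
        apex = p.apex_base if overabundant else p.apex_base / p.true_fold_change
        return apex, _MAIN_FWHM
    if p.quant_pattern == "absent_normal":
        return (p.apex_base, _MAIN_FWHM) if g is Group.HIGH else (0.0, _MAIN_FWHM)
    # BLQ patterns: narrow low peak barely over the noise floor on the weak side
    weak = Group.NORMAL if p.quant_pattern == "blq_normal" else Group.HIGH
    if g is weak:
        return _BLQ_APEX * (noise_floor / 1000.0), _BLQ_FWHM
    return p.apex_base, _MAIN_FWHM
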