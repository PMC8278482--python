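"""Targeted label-free MS1 quantification from raw centroid spectra.

For every library peptide an extracted ion chromatogram (XIC) is built from
the MS1 scans at a narrow mass tolerance (default +-5 ppm, inclusive), a
chromatographic peak is sought within the expected retention-time window
(default +-0.5 min), and the peak is integrated trapezoidally between the
points where the trace falls to the noise floor. Reliability is gated on
scans-across-peak: at least ``min_scans`` (default 8) MS1 scans must sample
the peak for a QUANTIFIED call; a detected peak with fewer scans is below
the limit of quantification (BLQ), and no detectable trace at all is
ABSENT. Peak areas are normalized per run by the median area of the spiked
internal-standard peptides, runs are matched at a retention-time alignment
tolerance (default 1 min), and group ratios are formed on normalized areas.
A peptide reliably quantified in one group but BLQ or absent in the other
gets a pseudo-quantitative fold change (default 100), flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import base64
import struct
import zlib

import numpy as np
import pandas as pd
from lxml import etree

from .synthetic_data import Group
from .triage import LibraryEntry

__all__ = [
    "XIC",
    "PeakQuant",
    "FoldChange",
    "read_ms1",
    "extract_xic",
    "detect_peak",
    "normalization_factor",
    "quantify_run",
    "match_across_runs",
    "fold_change",
    "compute_fold_changes",
    "write_quant_table",
    "write_fold_changes",
    "STATUS_QUANTIFIED",
    "STATUS_BLQ",
    "STATUS_ABSENT",
    "DEFAULT_PPM_TOL",
    "DEFAULT_RT_TOL",
    "DEFAULT_ALIGN_TOL",
    "DEFAULT_MIN_SCANS",
    "DEFAULT_PSEUDO_VALUE",
    "NormalizationError",
]

logger = logging.getLogger(__name__)

DEFAULT_PPM_TOL = 5.0       # ppm, inclusive
DEFAULT_RT_TOL = 0.5        # min, library interrogation window
DEFAULT_ALIGN_TOL = 1.0     # min, cross-run chromatogram alignment
DEFAULT_MIN_SCANS = 8       # scans-across-peak for reliable quantification
DEFAULT_PSEUDO_VALUE = 100.0

STATUS_QUANTIFIED = "QUANTIFIED"
STATUS_BLQ = "BLQ"
STATUS_ABSENT = "ABSENT"


class NormalizationError(RuntimeError):
    """No quantifiable internal-standard peak: normalization impossible."""


@dataclass
class XIC:
    """Extracted ion chromatogram of one library entry in one run."""

    run_id: str
    entry: LibraryEntry
    times: np.ndarray       # min, strictly increasing
    intensities: np.ndarray  # counts, zeros where no matching centroid

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must align")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class PeakQuant:
    """Quantification outcome of one library entry in one run."""

    run_id: str
    accession: str
    status: str
    rt_apex: float | None = None
    area: float | None = None            # counts*min, QUANTIFIED only
    scans_across_peak: int = 0
    normalized_area: float | None = None
    rt_expected: float | None = None
    is_standard: bool = False


@dataclass(frozen=True)
class FoldChange:
    """Cross-run abundance ratio for one accession, always >= 1."""

    accession: str
    ratio: float
    direction: Group        # group with the larger normalized signal
    pseudo: bool            # ratio is the assigned pseudo value
    status_normal: str
    status_high: str


# ---------------------------------------------------------------------------
# mzML ingestion
# ---------------------------------------------------------------------------

_NS = "{http://psi.hupo.org/ms/mzml}"

# controlled-vocabulary accessions used when decoding spectra
_CV_MS_LEVEL = "MS:1000511"
_CV_SCAN_START = "MS:1000016"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def _decode_binary_array(bda: etree._Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    kind = None
    dtype = "<d"
    compressed = False
    for cv in bda.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _CV_MZ_ARRAY:
            kind = "mz"
        elif acc == _CV_INT_ARRAY:
            kind = "intensity"
        elif acc == _CV_F32:
            dtype = "<f"
        elif acc == _CV_ZLIB:
            compressed = True
    node = bda.find(f"{_NS}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    values = np.frombuffer(raw, dtype=np.dtype(dtype)).astype(float) if len(raw) >= width else np.empty(0)
    return kind, values


def read_ms1(path: str | Path) -> list[dict]:
    """Load the MS1 subset of an mzML file, sorted by scan start time.

    Mixed MS1/dd-MS2 files are demultiplexed in-memory: spectra whose ms
    level is not 1 are discarded (and counted in the log). Handles centroid
    spectra with uncompressed or zlib-compressed 32/64-bit float arrays.
    Raises if the file yields no MS1 spectrum at all.
    """
    path = Path(path)
    scans: list[dict] = []
    n_dropped = 0
    for _, spec in etree.iterparse(str(path), tag=f"{_NS}spectrum"):
        level = None
        t = None
        mz = np.empty(0)
        intensity = np.empty(0)
        for cv in spec.iterfind(f"{_NS}cvParam"):
            if cv.get("accession") == _CV_MS_LEVEL:
                level = int(cv.get("value"))
        for cv in spec.iter(f"{_NS}cvParam"):
            if cv.get("accession") == _CV_SCAN_START:
                t = float(cv.get("value"))
                if cv.get("unitName") == "second":
                    t /= 60.0
        if level == 1:
            for bda in spec.iter(f"{_NS}binaryDataArray"):
                kind, values = _decode_binary_array(bda)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensity = values
            if t is None:
                raise ValueError(f"{path}: spectrum {spec.get('id')} lacks a scan start time")
            scans.append({"time": t, "mz": mz, "intensity": intensity})
        else:
            n_dropped += 1
        spec.clear(keep_tail=True)
    if n_dropped:
        logger.info("%s: discarded %d non-MS1 spectra", path.name, n_dropped)
    if not scans:
        raise ValueError(f"{path}: no MS1 spectra found")
    scans.sort(key=lambda s: s["time"])
    return scans


def extract_xic(
    scans: list[dict],
    entry: LibraryEntry,
    ppm_tol: float = DEFAULT_PPM_TOL,
    run_id: str = "",
) -> XIC:
    """Sum, per scan, all centroids within ``ppm_tol`` (inclusive) of the
    entry's target m/z; scans with no matching centroid contribute zero."""
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be > 0")
    half = entry.mz_target * ppm_tol * 1e-6
    lo, hi = entry.mz_target - half, entry.mz_target + half
    times = np.empty(len(scans))
    intens = np.zeros(len(scans))
    for i, sc in enumerate(scans):
        times[i] = sc["time"]
        mz = sc["mz"]
        if mz.size:
            a, b = np.searchsorted(mz, lo, "left"), np.searchsorted(mz, hi, "right")
            if b > a:
                intens[i] = sc["intensity"][a:b].sum()
    return XIC(run_id=run_id, entry=entry, times=times, intensities=intens)


# ---------------------------------------------------------------------------
# Peak detection and integration
# ---------------------------------------------------------------------------

def _resolve_noise_floor(xic: XIC, noise_floor: float | None) -> float:
    """Default noise floor: 10th percentile of the XIC's nonzero intensities."""
    if noise_floor is not None:
        return float(noise_floor)
    nz = xic.intensities[xic.intensities > 0]
    if nz.size == 0:
        return 0.0
    return float(np.percentile(nz, 10.0))


def detect_peak(
    xic: XIC,
    rt_expected: float | None = None,
    rt_tol: float = DEFAULT_RT_TOL,
    noise_floor: float | None = None,
    min_scans: int = DEFAULT_MIN_SCANS,
) -> PeakQuant:
    """Find and integrate the chromatographic peak nearest the library RT.

    The apex is the maximum-intensity scan above the noise floor within
    ``rt_tol`` (inclusive) of ``rt_expected`` — ties go to the scan closest
    to the expected RT. Peak bounds extend from the apex in both directions
    while the trace stays above the noise floor; scans-across-peak is the
    number of scans between the bounds and the area their trapezoidal
    integral. ABSENT (no above-floor scan in the window) is an outcome, not
    an error.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be > 0")
    t, y = xic.times, xic.intensities
    entry = xic.entry
    if rt_expected is None:
        rt_expected = entry.rt_expected
    floor = _resolve_noise_floor(xic, noise_floor)

    base = PeakQuant(
        run_id=xic.run_id,
        accession=entry.accession,
        status=STATUS_ABSENT,
        rt_expected=rt_expected,
        is_standard=entry.is_standard,
    )
    if t.size == 0:
        return base
    in_window = np.abs(t - rt_expected) <= rt_tol
    candidates = np.flatnonzero(in_window & (y > floor))
    if candidates.size == 0:
        return base

    peak_y = y[candidates]
    best = peak_y.max()
    # ties: nearest to the expected retention time
    tied = candidates[peak_y == best]
    apex = int(tied[np.argmin(np.abs(t[tied] - rt_expected))])

    left = apex
    while left - 1 >= 0 and y[left - 1] > floor:
        left -= 1
    right = apex
    while right + 1 < y.size and y[right + 1] > floor:
        right += 1

    scans = right - left + 1
    area = float(np.trapezoid(y[left : right + 1], t[left : right + 1])) if scans > 1 else 0.0
    quantified = scans >= min_scans
    return PeakQuant(
        run_id=xic.run_id,
        accession=entry.accession,
        status=STATUS_QUANTIFIED if quantified else STATUS_BLQ,
        rt_apex=float(t[apex]),
        area=area if quantified else None,
        scans_across_peak=int(scans),
        rt_expected=rt_expected,
        is_standard=entry.is_standard,
    )


def normalization_factor(quants: list[PeakQuant]) -> float:
    """Per-run normalization factor: the median area of the QUANTIFIED
    internal-standard peaks. Raises if the run has none (the run cannot be
    normalized and must be re-acquired or regenerated)."""
    areas = [q.area for q in quants if q.is_standard and q.status == STATUS_QUANTIFIED]
    if not areas:
        raise NormalizationError(
            "no quantifiable internal-standard peak in run; re-acquire or regenerate the run"
        )
    return float(np.median(areas))


def quantify_run(
    scans: list[dict],
    library: list[LibraryEntry],
    run_id: str = "",
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_tol: float = DEFAULT_RT_TOL,
    noise_floor: float | None = None,
    min_scans: int = DEFAULT_MIN_SCANS,
) -> dict[str, PeakQuant]:
    """Quantify every library entry in one run and IS-normalize the areas.

    Returns accession -> PeakQuant (internal standards included, flagged).
    Areas are integrated on raw intensities first; the single per-run
    normalization factor is applied afterwards.
    """
    quants: dict[str, PeakQuant] = {}
    for entry in library:
        xic = extract_xic(scans, entry, ppm_tol=ppm_tol, run_id=run_id)
        quants[entry.accession] = detect_peak(
            xic, rt_tol=rt_tol, noise_floor=noise_floor, min_scans=min_scans
        )
    factor = normalization_factor(list(quants.values()))
    for q in quants.values():
        if q.area is not None:
            q.normalized_area = q.area / factor
    return quants


# ---------------------------------------------------------------------------
# Cross-run matching and fold changes
# ---------------------------------------------------------------------------

def match_across_runs(
    quant_normal: dict[str, PeakQuant],
    quant_high: dict[str, PeakQuant],
    align_tol: float = DEFAULT_ALIGN_TOL,
) -> dict[str, tuple[PeakQuant, PeakQuant]]:
    """Pair the two runs' quantifications per accession.

    Two detected peaks (QUANTIFIED or BLQ) are matched when their apexes
    agree within ``align_tol`` (inclusive). When they disagree, the peak
    whose apex sits farther from the library's expected RT is considered a
    different feature and demoted to ABSENT for the pairing.
    """
    pairs: dict[str, tuple[PeakQuant, PeakQuant]] = {}
    for acc in sorted(set(quant_normal) | set(quant_high)):
        qn = quant_normal.get(acc) or PeakQuant("", acc, STATUS_ABSENT)
        qh = quant_high.get(acc) or PeakQuant("", acc, STATUS_ABSENT)
        if (
            qn.status != STATUS_ABSENT
            and qh.status != STATUS_ABSENT
            and abs(qn.rt_apex - qh.rt_apex) > align_tol
        ):
            ref = qn.rt_expected if qn.rt_expected is not None else qh.rt_expected
            dn = abs(qn.rt_apex - ref) if ref is not None else 0.0
            dh = abs(qh.rt_apex - ref) if ref is not None else 0.0
            demoted = PeakQuant(
                run_id=(qn if dn >= dh else qh).run_id,
                accession=acc,
                status=STATUS_ABSENT,
                rt_expected=ref,
                is_standard=qn.is_standard,
            )
            if dn >= dh:
                qn = demoted
            else:
                qh = demoted
        pairs[acc] = (qn, qh)
    return pairs


def fold_change(
    pair: tuple[PeakQuant, PeakQuant],
    pseudo_value: float = DEFAULT_PSEUDO_VALUE,
) -> FoldChange | None:
    """Fold change of one matched pair on normalized areas.

    Both sides QUANTIFIED: ratio is the larger of the two orientations and
    the direction the group with more signal (ties resolve to NORMAL).
    One side QUANTIFIED, the other BLQ or ABSENT: the pseudo fold change is
    granted, flagged, directed at the quantified group. Neither side
    QUANTIFIED: unquantifiable, nothing is emitted.
    """
    qn, qh = pair
    if qn.status == STATUS_QUANTIFIED and qh.status == STATUS_QUANTIFIED:
        a_n, a_h = qn.normalized_area, qh.normalized_area
        ratio = max(a_n / a_h, a_h / a_n)
        direction = Group.NORMAL if a_n >= a_h else Group.HIGH
        return FoldChange(qn.accession, float(ratio), direction, False, qn.status, qh.status)
    if qn.status == STATUS_QUANTIFIED or qh.status == STATUS_QUANTIFIED:
        direction = Group.NORMAL if qn.status == STATUS_QUANTIFIED else Group.HIGH
        return FoldChange(qn.accession or qh.accession, float(pseudo_value), direction, True,
                          qn.status, qh.status)
    logger.info("%s: unquantifiable in both runs (%s/%s)", qn.accession or qh.accession,
                qn.status, qh.status)
    return None


def compute_fold_changes(
    quant_normal: dict[str, PeakQuant],
    quant_high: dict[str, PeakQuant],
    align_tol: float = DEFAULT_ALIGN_TOL,
    pseudo_value: float = DEFAULT_PSEUDO_VALUE,
) -> list[FoldChange]:
    """Match the two runs and emit fold changes for every non-IS target that
    is reliably quantified in at least one group."""
    pairs = match_across_runs(quant_normal, quant_high, align_tol=align_tol)
    out: list[FoldChange] = []
    for acc, pair in pairs.items():
        if pair[0].is_standard or pair[1].is_standard:
            continue
        fc = fold_change(pair, pseudo_value=pseudo_value)
        if fc is not None:
            out.append(fc)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_quant_table(quants: dict[str, PeakQuant], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "accession": q.accession,
                "status": q.status,
                "rt_apex": "" if q.rt_apex is None else f"{q.rt_apex:.3f}",
                "scans": q.scans_across_peak,
                "area": "" if q.area is None else f"{q.area:.6g}",
                "normalized_area": "" if q.normalized_area is None else f"{q.normalized_area:.6g}",
                "is_standard": q.is_standard,
            }
            for q in quants.values()
        ],
        columns=["accession", "status", "rt_apex", "scans", "area", "normalized_area", "is_standard"],
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_fold_changes(fold_changes: list[FoldChange], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "accession": fc.accession,
                "ratio": f"{fc.ratio:.4g}",
                "direction": fc.direction.value,
                "pseudo": fc.pseudo,
                "status_normal": fc.status_normal,
                "status_high": fc.status_high,
            }
            for fc in fold_changes
        ],
        columns=["accession", "ratio", "direction", "pseudo", "status_normal", "status_high"],
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
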