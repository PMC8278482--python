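"""Biomarker certification, functional annotation, and pipeline orchestration.

A candidate is certified as a biomarker when its normalized fold change
reaches the certification threshold (default 2, inclusive — "a minimum of
2-fold change"); pseudo-quantified entries (fold change 100) always clear
it. Function classes are attached by lookup in a user-supplied annotation
table — no live protein-network or ontology queries, so results are
reproducible offline. ``run_pipeline`` chains the whole screen:
identification filter -> score triage -> targeted library -> MS1
quantification -> fold changes -> certification -> annotation, writing
every intermediate table and a log of every configured threshold.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ident_io, quantify, triage
from .quantify import FoldChange
from .synthetic_data import Group

__all__ = [
    "BiomarkerCall",
    "PipelineConfig",
    "ReportBundle",
    "certify",
    "annotate",
    "read_annotation_table",
    "run_pipeline",
    "AnnotationError",
    "FUNCTION_CLASSES",
    "UNANNOTATED",
]

logger = logging.getLogger(__name__)

FUNCTION_CLASSES = ("metabolic", "chaperone/stress", "structural-contractile", "transport", "other")
UNANNOTATED = "unannotated"


class AnnotationError(ValueError):
    """Annotation table malformed or ambiguous."""


@dataclass
class BiomarkerCall:
    """A certified biomarker: direction of overabundance, fold change, class."""

    accession: str
    tier: str
    direction: Group
    fold_change: float
    pseudo: bool
    function_class: str = UNANNOTATED


@dataclass
class PipelineConfig:
    """Every tunable of the screen, with the study-validated defaults."""

    min_ion_score: float = 19.0        # qualitative acceptance boundary
    score_ratio_threshold: float = 2.0  # secondary-tier protein-score ratio
    ppm_tol: float = 5.0               # XIC mass tolerance, ppm
    rt_tol: float = 0.5                # library interrogation RT window, min
    align_tol: float = 1.0             # cross-run alignment tolerance, min
    min_scans: int = 8                 # scans-across-peak for reliability
    pseudo_value: float = 100.0        # BLQ/absent pseudo fold change
    fc_threshold: float = 2.0          # certification boundary
    noise_floor: float | None = None   # None -> 10th pct of nonzero XIC points
    seed: int = 0

    def __post_init__(self):
        for name in ("min_ion_score", "score_ratio_threshold", "ppm_tol", "rt_tol",
                     "align_tol", "min_scans", "pseudo_value", "fc_threshold"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """Everything run_pipeline produced, plus where it was written."""

    config: PipelineConfig
    filtered_normal: list
    filtered_high: list
    candidates: list
    library: list
    quant_normal: dict
    quant_high: dict
    fold_changes: list
    calls: list
    class_counts: dict = field(default_factory=dict)
    out_dir: Path | None = None


def certify(
    fold_changes: list[FoldChange],
    fc_threshold: float = 2.0,
    tiers: dict[str, str] | None = None,
) -> list[BiomarkerCall]:
    """Keep fold changes at or above the certification threshold.

    Pseudo entries carry the pseudo fold change and therefore pass any
    threshold up to it. Output sorted by (direction, descending ratio).
    """
    calls = [
        BiomarkerCall(
            accession=fc.accession,
            tier=(tiers or {}).get(fc.accession, ""),
            direction=fc.direction,
            fold_change=fc.ratio,
            pseudo=fc.pseudo,
        )
        for fc in fold_changes
        if fc.ratio >= fc_threshold
    ]
    calls.sort(key=lambda c: (c.direction.value, -c.fold_change, c.accession))
    return calls


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Read an accession -> function-class TSV; an accession mapped to two
    different classes is an error (ambiguous annotation)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"accession", "function_class"} <= set(df.columns):
        raise AnnotationError(f"{path}: need columns accession, function_class")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        acc, cls = str(row["accession"]), str(row["function_class"])
        if acc in mapping and mapping[acc] != cls:
            raise AnnotationError(f"{path}: {acc} mapped to both {mapping[acc]!r} and {cls!r}")
        mapping[acc] = cls
    return mapping


def annotate(
    calls: list[BiomarkerCall], annotation: dict[str, str]
) -> tuple[list[BiomarkerCall], dict[str, int]]:
    """Attach function classes by lookup; unknown accessions stay
    ``unannotated``. Returns the calls and per-class summary counts."""
    counts: dict[str, int] = {}
    for call in calls:
        call.function_class = annotation.get(call.accession, UNANNOTATED)
        counts[call.function_class] = counts.get(call.function_class, 0) + 1
    return calls, counts


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig,
    ident_normal: str | Path,
    ident_high: str | Path,
    mzml_normal: str | Path,
    mzml_high: str | Path,
    annotation: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Execute the full stepped screen on one two-group comparison.

    Stages: read + ion-score filter the identification tables, strip
    internal standards, triage candidates on protein scores, build the
    targeted library, quantify both mzML runs, form normalized fold
    changes, certify, annotate. Writes all intermediate TSVs, the final
    biomarker table and a JSON run log into ``out_dir`` when given. Any
    stage failure aborts with the stage name and cause.
    """
    stage = "setup"
    try:
        stage = "identification filter"
        prot_n = ident_io.filter_identifications(
            ident_io.read_ident_table(ident_normal, Group.NORMAL), config.min_ion_score
        )
        prot_h = ident_io.filter_identifications(
            ident_io.read_ident_table(ident_high, Group.HIGH), config.min_ion_score
        )
        sample_n, is_n = ident_io.split_internal_standards(prot_n)
        sample_h, is_h = ident_io.split_internal_standards(prot_h)

        stage = "triage"
        candidates = triage.triage_candidates(
            sample_n, sample_h, ratio_threshold=config.score_ratio_threshold
        )
        library = triage.build_library(candidates, is_proteins=is_n + is_h)

        stage = "quantification"
        quant_kwargs = dict(
            ppm_tol=config.ppm_tol,
            rt_tol=config.rt_tol,
            noise_floor=config.noise_floor,
            min_scans=config.min_scans,
        )
        quant_n = quantify.quantify_run(
            quantify.read_ms1(mzml_normal), library, run_id="normal", **quant_kwargs
        )
        quant_h = quantify.quantify_run(
            quantify.read_ms1(mzml_high), library, run_id="high", **quant_kwargs
        )

        stage = "fold change"
        fcs = quantify.compute_fold_changes(
            quant_n, quant_h, align_tol=config.align_tol, pseudo_value=config.pseudo_value
        )

        stage = "certification"
        tiers = {c.accession: c.tier for c in candidates}
        calls = certify(fcs, fc_threshold=config.fc_threshold, tiers=tiers)

        stage = "annotation"
        class_counts: dict[str, int] = {}
        if annotation is not None:
            calls, class_counts = annotate(calls, read_annotation_table(annotation))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = ReportBundle(
        config=config,
        filtered_normal=prot_n,
        filtered_high=prot_h,
        candidates=candidates,
        library=library,
        quant_normal=quant_n,
        quant_high=quant_h,
        fold_changes=fcs,
        calls=calls,
        class_counts=class_counts,
    )
    if out_dir is not None:
        bundle.out_dir = _write_bundle(bundle, Path(out_dir))
    return bundle


def biomarker_table(bundle: ReportBundle) -> pd.DataFrame:
    """Final biomarker table: accession, tier, direction of overabundance,
    fold change, pseudo flag, function class."""
    return pd.DataFrame(
        [
            {
                "accession": c.accession,
                "tier": c.tier,
                "direction": c.direction.value,
                "fold_change": round(c.fold_change, 3),
                "pseudo": c.pseudo,
                "function_class": c.function_class,
            }
            for c in bundle.calls
        ],
        columns=["accession", "tier", "direction", "fold_change", "pseudo", "function_class"],
    )


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    ident_io.write_ident_table(bundle.filtered_normal, out_dir / "filtered_normal.tsv")
    ident_io.write_ident_table(bundle.filtered_high, out_dir / "filtered_high.tsv")
    triage.write_candidates(bundle.candidates, out_dir / "candidates.tsv")
    triage.write_library(bundle.library, out_dir / "library.tsv")
    quantify.write_quant_table(bundle.quant_normal, out_dir / "quant_normal.tsv")
    quantify.write_quant_table(bundle.quant_high, out_dir / "quant_high.tsv")
    quantify.write_fold_changes(bundle.fold_changes, out_dir / "fold_changes.tsv")
    biomarker_table(bundle).to_csv(out_dir / "biomarkers.tsv", sep="\t", index=False)
    log = {
        "config": bundle.config.to_dict(),
        "n_filtered_normal": len(bundle.filtered_normal),
        "n_filtered_high": len(bundle.filtered_high),
        "n_candidates": len(bundle.candidates),
        "n_library": len(bundle.library),
        "n_fold_changes": len(bundle.fold_changes),
        "n_certified": len(bundle.calls),
        "class_counts": bundle.class_counts,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    logger.info("report written to %s (%d certified biomarkers)", out_dir, len(bundle.calls))
    return out_dir
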