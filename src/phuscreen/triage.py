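"""Tiered candidate triage on protein scores, and the targeted library.

Proteins identified exclusively in one group are primary biomarker
candidates. Proteins shared by both groups become secondary candidates when
the ratio of their protein scores, taken in whichever orientation exceeds
one, reaches a minimum fold change (default 2) — the protein score being a
coarse abundance indicator, not a quantity. Everything else is a shared
non-candidate. Each candidate contributes its proteotypic peptide to the
in-house targeted library that drives MS1 quantification, alongside the
spiked internal-standard peptides.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ident_io import IdentifiedProtein, select_proteotypic
from .synthetic_data import Group

__all__ = [
    "Candidate",
    "LibraryEntry",
    "triage_candidates",
    "build_library",
    "write_candidates",
    "write_library",
    "DEFAULT_SCORE_RATIO_THRESHOLD",
]

logger = logging.getLogger(__name__)

DEFAULT_SCORE_RATIO_THRESHOLD = 2.0

TIER_PRIMARY = "PRIMARY"
TIER_SECONDARY = "SECONDARY"


@dataclass(frozen=True)
class LibraryEntry:
    """A targeted proteotypic peptide: what the XIC extractor looks for."""

    accession: str
    sequence: str
    charge: int
    mz_target: float      # observed m/z from the identification evidence, Th
    rt_expected: float    # min
    tier: str             # PRIMARY | SECONDARY | IS
    is_standard: bool = False


@dataclass
class Candidate:
    """A triaged biomarker candidate with its identification evidence."""

    accession: str
    tier: str                      # PRIMARY | SECONDARY
    direction_hint: Group          # group of exclusive presence / higher score
    score_ratio: float | None      # >= 1 for SECONDARY, None for PRIMARY
    evidence: dict                 # Group -> IdentifiedProtein


def triage_candidates(
    normal: list[IdentifiedProtein],
    high: list[IdentifiedProtein],
    ratio_threshold: float = DEFAULT_SCORE_RATIO_THRESHOLD,
) -> list[Candidate]:
    """Partition filtered identifications into the two candidate tiers.

    Inputs must already be ion-score filtered and stripped of
    internal-standard proteins. Shared proteins with a non-positive protein
    score cannot be rationed and are excluded with a warning. The returned
    list is sorted by (tier, accession).
    """
    by_acc_n = {p.accession: p for p in normal}
    by_acc_h = {p.accession: p for p in high}
    candidates: list[Candidate] = []

    for acc in sorted(set(by_acc_n) - set(by_acc_h)):
        candidates.append(
            Candidate(acc, TIER_PRIMARY, Group.NORMAL, None, {Group.NORMAL: by_acc_n[acc]})
        )
    for acc in sorted(set(by_acc_h) - set(by_acc_n)):
        candidates.append(
            Candidate(acc, TIER_PRIMARY, Group.HIGH, None, {Group.HIGH: by_acc_h[acc]})
        )
    for acc in sorted(set(by_acc_n) & set(by_acc_h)):
        s_n, s_h = by_acc_n[acc].protein_score, by_acc_h[acc].protein_score
        if s_n <= 0 or s_h <= 0:
            warnings.warn(
                f"{acc}: non-positive protein score ({s_n}, {s_h}); score ratio undefined, "
                "pair excluded from triage",
                stacklevel=2,
            )
            continue
        ratio = max(s_n / s_h, s_h / s_n)
        if ratio >= ratio_threshold:
            hint = Group.NORMAL if s_n >= s_h else Group.HIGH
            candidates.append(
                Candidate(
                    acc, TIER_SECONDARY, hint, ratio,
                    {Group.NORMAL: by_acc_n[acc], Group.HIGH: by_acc_h[acc]},
                )
            )
    candidates.sort(key=lambda c: (c.tier != TIER_PRIMARY, c.accession))
    return candidates


def build_library(
    candidates: list[Candidate],
    is_proteins: list[IdentifiedProtein] = (),
) -> list[LibraryEntry]:
    """Assemble the targeted library: one proteotypic peptide per candidate
    plus every internal-standard peptide (flagged).

    For a primary candidate the peptide evidence comes from the group where
    the protein was identified. For a secondary candidate the proteotypic
    peptide is the highest-ion-score match across both groups' evidence and
    the expected retention time is the mean of the two groups' observations,
    centring the library search window between runs.
    """
    entries: list[LibraryEntry] = []
    for cand in candidates:
        prots = list(cand.evidence.values())
        best = min(
            (select_proteotypic(p) for p in prots),
            key=lambda m: (-m.ion_score, m.sequence),
        )
        rts = []
        for p in prots:
            same = [m.rt for m in p.peptides if m.sequence == best.sequence and m.charge == best.charge]
            rts.extend(same if same else [select_proteotypic(p).rt])
        entries.append(
            LibraryEntry(
                accession=cand.accession,
                sequence=best.sequence,
                charge=best.charge,
                mz_target=best.mz_observed,
                rt_expected=float(np.mean(rts)),
                tier=cand.tier,
            )
        )
    # internal standards: same proteotypic rule, RT averaged across evidence
    by_acc: dict[str, list[IdentifiedProtein]] = {}
    for p in is_proteins:
        by_acc.setdefault(p.accession, []).append(p)
    for acc in sorted(by_acc):
        prots = by_acc[acc]
        best = min(
            (select_proteotypic(p) for p in prots),
            key=lambda m: (-m.ion_score, m.sequence),
        )
        rts = [
            m.rt
            for p in prots
            for m in p.peptides
            if m.sequence == best.sequence and m.charge == best.charge
        ]
        entries.append(
            LibraryEntry(
                accession=acc,
                sequence=best.sequence,
                charge=best.charge,
                mz_target=best.mz_observed,
                rt_expected=float(np.mean(rts)),
                tier="IS",
                is_standard=True,
            )
        )
    logger.info("library: %d targets, %d internal standards",
                sum(not e.is_standard for e in entries),
                sum(e.is_standard for e in entries))
    return entries


def write_candidates(candidates: list[Candidate], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "accession": c.accession,
                "tier": c.tier,
                "direction_hint": c.direction_hint.value,
                "score_ratio": "" if c.score_ratio is None else f"{c.score_ratio:.3f}",
            }
            for c in candidates
        ],
        columns=["accession", "tier", "direction_hint", "score_ratio"],
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_library(entries: list[LibraryEntry], path: str | Path) -> Path:
    df = pd.DataFrame(
        [
            {
                "accession": e.accession,
                "sequence": e.sequence,
                "charge": e.charge,
                "mz_target": f"{e.mz_target:.5f}",
                "rt_expected": f"{e.rt_expected:.3f}",
                "tier": e.tier,
                "is_standard": e.is_standard,
            }
            for e in entries
        ],
        columns=["accession", "sequence", "charge", "mz_target", "rt_expected", "tier", "is_standard"],
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
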