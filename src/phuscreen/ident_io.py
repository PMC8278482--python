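"""Reading, filtering and summarising per-group protein identifications.

Input is a delimited export of a database-search result: one row per
peptide-spectrum match with its parent protein accession and protein score
(the information content of a Mascot export). The qualitative acceptance
filter keeps peptide matches at or above a minimum individual ion score
(default 19, the identity/extensive-homology boundary reported for a 1%
decoy FDR in the study this pipeline reproduces); proteins left without any
accepted peptide are dropped. Decoy searching itself is a search-engine
function and is not re-implemented here — the threshold is the configurable
proxy for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .synthetic_data import Group, IDENT_COLUMNS, IS_PREFIX

__all__ = [
    "PeptideMatch",
    "IdentifiedProtein",
    "IdentFormatError",
    "read_ident_table",
    "filter_identifications",
    "select_proteotypic",
    "write_ident_table",
    "split_internal_standards",
    "DEFAULT_MIN_ION_SCORE",
]

DEFAULT_MIN_ION_SCORE = 19.0


class IdentFormatError(ValueError):
    """Identification table malformed (missing column or too many bad rows)."""


@dataclass(frozen=True)
class PeptideMatch:
    """One peptide-spectrum match supporting a protein identification."""

    sequence: str
    charge: int
    mz_observed: float  # Th
    rt: float           # min
    ion_score: float

    def __post_init__(self):
        if not (1 <= self.charge <= 4):
            raise ValueError(f"charge {self.charge} outside search range 1-4 ({self.sequence})")
        if self.mz_observed <= 0:
            raise ValueError(f"mz_observed must be > 0 ({self.sequence})")


@dataclass
class IdentifiedProtein:
    """One protein's identification evidence in one sample group."""

    accession: str
    group: Group
    protein_score: float
    peptides: list[PeptideMatch] = field(default_factory=list)

    @property
    def is_standard(self) -> bool:
        """Spiked internal-standard protein, by accession prefix convention."""
        return self.accession.startswith(IS_PREFIX)

    @property
    def proteotypic(self) -> PeptideMatch:
        return select_proteotypic(self)


def select_proteotypic(protein: IdentifiedProtein) -> PeptideMatch:
    """The peptide chosen to represent the protein in targeted quantification:
    maximal ion score, ties broken by lexicographic sequence order."""
    if not protein.peptides:
        raise ValueError(f"{protein.accession}: no peptides to select a proteotypic from")
    return min(protein.peptides, key=lambda p: (-p.ion_score, p.sequence))


def read_ident_table(path: str | Path, group: Group) -> list[IdentifiedProtein]:
    """Parse a per-group identification TSV into proteins with attached PSMs.

    Rows sharing an accession are merged under one protein (the protein score
    is taken from the first row; a conflicting score raises). Malformed rows
    are collected and reported with line numbers; more than 10% bad rows, or
    a missing column, is fatal.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in IDENT_COLUMNS if c not in df.columns]
    if missing:
        raise IdentFormatError(f"{path}: missing column(s) {missing}")

    proteins: dict[str, IdentifiedProtein] = {}
    bad: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after header
        try:
            acc = str(row["accession"])
            score = float(row["protein_score"])
            match = PeptideMatch(
                sequence=str(row["peptide"]),
                charge=int(row["charge"]),
                mz_observed=float(row["mz"]),
                rt=float(row["rt_min"]),
                ion_score=float(row["ion_score"]),
            )
        except (TypeError, ValueError) as exc:
            bad.append(f"line {line_no}: {exc}")
            continue
        if acc in proteins:
            if proteins[acc].protein_score != score:
                bad.append(f"line {line_no}: conflicting protein_score for {acc}")
                continue
            proteins[acc].peptides.append(match)
        else:
            proteins[acc] = IdentifiedProtein(acc, group, score, [match])
    if bad and len(bad) > 0.10 * max(len(df), 1):
        raise IdentFormatError(f"{path}: {len(bad)} malformed rows: " + "; ".join(bad[:5]))
    return list(proteins.values())


def filter_identifications(
    proteins: list[IdentifiedProtein], min_ion_score: float = DEFAULT_MIN_ION_SCORE
) -> list[IdentifiedProtein]:
    """Qualitative acceptance filter: drop PSMs below ``min_ion_score``
    (inclusive threshold — a score equal to the minimum passes), then drop
    proteins left with no accepted peptide. Idempotent."""
    if min_ion_score < 0:
        raise ValueError("min_ion_score must be >= 0")
    out: list[IdentifiedProtein] = []
    for prot in proteins:
        kept = [p for p in prot.peptides if p.ion_score >= min_ion_score]
        if kept:
            out.append(replace(prot, peptides=kept))
    return out


def split_internal_standards(
    proteins: list[IdentifiedProtein],
) -> tuple[list[IdentifiedProtein], list[IdentifiedProtein]]:
    """Separate spiked internal-standard proteins (``IS_`` accessions) from
    sample proteins; the former never enter triage."""
    sample = [p for p in proteins if not p.is_standard]
    standards = [p for p in proteins if p.is_standard]
    return sample, standards


def write_ident_table(proteins: list[IdentifiedProtein], path: str | Path) -> Path:
    """Write accepted identifications back to TSV, adding a ``proteotypic``
    boolean column marking each protein's representative peptide."""
    rows = []
    for prot in proteins:
        proteo = select_proteotypic(prot) if prot.peptides else None
        for pep in prot.peptides:
            rows.append(
                {
                    "accession": prot.accession,
                    "protein_score": prot.protein_score,
                    "peptide": pep.sequence,
                    "charge": pep.charge,
                    "mz": pep.mz_observed,
                    "rt_min": pep.rt,
                    "ion_score": pep.ion_score,
                    "proteotypic": pep == proteo,
                }
            )
    df = pd.DataFrame(rows, columns=IDENT_COLUMNS + ["proteotypic"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path
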