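"""Best-hit ortholog-group assignment and the genome x group presence matrix.

Each protein is attributed to the ortholog group of its single best catalog
hit, provided the hit's e-value clears the assignment threshold (strictly
below ``evalue_max``, default 1e-5). Ties on e-value fall back to the higher
bit score, then to the lexicographically smallest subject id, so assignment
is a function of the hit multiset and never of file order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._round import round_half_up
from .io_formats import AlignmentHit, GenomeRecord

__all__ = [
    "AnnotationSummary",
    "OrthologAssignment",
    "PresenceMatrix",
    "annotation_fraction",
    "assign_best_hits",
    "build_presence_matrix",
]

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class OrthologAssignment:
    """Best-hit mapping of one protein to one ortholog group."""

    genome_id: str
    protein_id: str
    nog_id: str
    evalue: float


@dataclass(frozen=True)
class AnnotationSummary:
    """Per-genome count and percentage of proteins assigned to groups."""

    genome_id: str
    n_assigned: int
    fraction_assigned: float  # percentage, half-up rounded to one decimal


@dataclass
class PresenceMatrix:
    """Binary genome x feature incidence structure.

    Wraps a pandas DataFrame (rows = genomes in input order, columns =
    feature ids sorted lexicographically, values 0/1). Columns are only ever
    created for features observed in at least one genome.
    """

    frame: pd.DataFrame

    @property
    def genome_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def column_counts(self) -> pd.Series:
        """Number of genomes carrying each feature."""
        return self.frame.sum(axis=0)

    def write(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def read(cls, path: str | Path) -> "PresenceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="genome_id").astype("int8")
        if not frame.isin([0, 1]).all().all():
            raise ValueError(f"{path}: presence matrix cells must be 0/1")
        return cls(frame)

    @classmethod
    def from_dict(cls, rows: dict[str, Iterable[str]], genome_order: Sequence[str] | None = None) -> "PresenceMatrix":
        """Build from ``{genome_id: iterable of feature ids present}``."""
        genomes = list(genome_order) if genome_order is not None else list(rows)
        features = sorted({f for feats in rows.values() for f in feats})
        frame = pd.DataFrame(0, index=genomes, columns=features, dtype="int8")
        for g, feats in rows.items():
            for f in feats:
                frame.loc[g, f] = 1
        return cls(frame)


def assign_best_hits(
    hits: Iterable[AlignmentHit],
    genome_id: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[OrthologAssignment]:
    """Retain, per query protein, the best hit with e-value < ``evalue_max``.

    Best = lowest e-value, then highest bit score, then smallest subject id.
    Queries without a passing hit yield no assignment. Output is sorted by
    protein id (deterministic regardless of input order).
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be positive, got {evalue_max}")
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        if not hit.evalue < evalue_max:
            continue
        incumbent = best.get(hit.query_id)
        if incumbent is None or _hit_rank(hit) < _hit_rank(incumbent):
            best[hit.query_id] = hit
    return [
        OrthologAssignment(genome_id=genome_id, protein_id=q, nog_id=h.subject_id, evalue=h.evalue)
        for q, h in sorted(best.items())
    ]


def _hit_rank(hit: AlignmentHit) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bit_score, hit.subject_id)


def build_presence_matrix(
    assignments: Iterable[OrthologAssignment],
    genomes: Sequence[GenomeRecord],
) -> PresenceMatrix:
    """Collapse protein-level assignments to a binary genome x group matrix.

    cell(g, n) = 1 iff genome g has at least one protein assigned to group n.
    Row order follows ``genomes``; columns are sorted group ids. Assignments
    naming a genome absent from ``genomes`` are an error.
    """
    known = {g.genome_id for g in genomes}
    rows: dict[str, set[str]] = {g.genome_id: set() for g in genomes}
    for a in assignments:
        if a.genome_id not in known:
            raise ValueError(f"assignment references unknown genome {a.genome_id!r}")
        rows[a.genome_id].add(a.nog_id)
    return PresenceMatrix.from_dict(rows, genome_order=[g.genome_id for g in genomes])


def annotation_fraction(
    assignments: Sequence[OrthologAssignment],
    genome: GenomeRecord,
) -> AnnotationSummary:
    """Fraction of a genome's proteins assigned to any group, as a percentage.

    Counts distinct proteins (one assignment per protein is the invariant but
    the count is defensive); rounds half-up to one decimal for display parity
    with published per-genome annotation tables.
    """
    proteins = {a.protein_id for a in assignments if a.genome_id == genome.genome_id}
    n_assigned = len(proteins)
    if n_assigned > genome.total_proteins:
        raise ValueError(
            f"{genome.genome_id}: {n_assigned} assigned proteins exceed proteome size {genome.total_proteins}"
        )
    pct = round_half_up(100.0 * n_assigned / genome.total_proteins, 1)
    return AnnotationSummary(genome_id=genome.genome_id, n_assigned=n_assigned, fraction_assigned=pct)
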