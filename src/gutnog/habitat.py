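"""Habitat classification from gut gene-catalog matches.

A genome's genes are searched against a reference catalog of human gut
microbial genes; a gene counts as present in the catalog when some hit
reaches >= 95% identity over >= 90% of the longest of the two sequence
lengths. A species is then called a gut species when at least 5% of its
genes are present in the catalog, a non-gut species when fewer than 0.5%
are, and ambiguous in between (ambiguous genomes are excluded from cohort
analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._round import round_half_up
from .io_formats import AlignmentHit, Habitat

__all__ = [
    "CatalogFilterParams",
    "CatalogMatchResult",
    "classify_habitat",
    "passes_catalog_filter",
]


@dataclass(frozen=True)
class CatalogFilterParams:
    """Thresholds for catalog matching and habitat calls.

    min_identity: percent identity floor (inclusive).
    min_coverage: fraction of max(query length, subject length) the alignment
        must span (inclusive).
    gut_min_fraction / nongut_max_fraction: percentage-of-genes thresholds for
        the gut (>= 5%) and non-gut (< 0.5%) calls.
    """

    min_identity: float = 95.0
    min_coverage: float = 0.90
    gut_min_fraction: float = 5.0
    nongut_max_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.min_coverage <= 1.0:
            raise ValueError(f"min_coverage must be in (0, 1], got {self.min_coverage}")
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError(f"min_identity must be in [0, 100], got {self.min_identity}")
        if self.nongut_max_fraction >= self.gut_min_fraction:
            raise ValueError(
                f"nongut_max_fraction ({self.nongut_max_fraction}) must be below "
                f"gut_min_fraction ({self.gut_min_fraction})"
            )


@dataclass(frozen=True)
class CatalogMatchResult:
    genome_id: str
    n_genes: int
    n_matched: int
    fraction_matched: float  # percentage, full precision
    label: Habitat

    @property
    def fraction_matched_display(self) -> float:
        return round_half_up(self.fraction_matched, 1)


def passes_catalog_filter(hit: AlignmentHit, params: CatalogFilterParams | None = None) -> bool:
    """True iff a hit meets the identity and longest-length coverage floors.

    Coverage denominator is the longer of the two sequences in the pair; both
    comparisons are inclusive. Hits without both lengths cannot be evaluated.
    """
    params = params or CatalogFilterParams()
    if hit.query_length is None or hit.subject_length is None:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id}: sequence lengths required for the coverage filter"
        )
    longest = max(hit.query_length, hit.subject_length)
    if longest == 0:
        raise ValueError(f"hit {hit.query_id}->{hit.subject_id}: zero sequence length")
    coverage = hit.alignment_length / longest
    return hit.percent_identity >= params.min_identity and coverage >= params.min_coverage


def classify_habitat(
    hits: Iterable[AlignmentHit],
    genome_id: str,
    n_genes: int,
    params: CatalogFilterParams | None = None,
) -> CatalogMatchResult:
    """Label one genome from its catalog hits.

    A gene is matched if any of its hits passes the filter; the label depends
    only on the matched fraction: gut at >= gut_min_fraction %, non_gut below
    nongut_max_fraction %, ambiguous between.
    """
    params = params or CatalogFilterParams()
    if n_genes < 1:
        raise ValueError(f"{genome_id}: n_genes must be >= 1")
    matched = {h.query_id for h in hits if passes_catalog_filter(h, params)}
    if len(matched) > n_genes:
        raise ValueError(
            f"{genome_id}: {len(matched)} distinct matched genes exceed declared gene count {n_genes}"
        )
    fraction = 100.0 * len(matched) / n_genes
    if fraction >= params.gut_min_fraction:
        label = Habitat.GUT
    elif fraction < params.nongut_max_fraction:
        label = Habitat.NON_GUT
    else:
        label = Habitat.AMBIGUOUS
    return CatalogMatchResult(
        genome_id=genome_id,
        n_genes=n_genes,
        n_matched=len(matched),
        fraction_matched=fraction,
        label=label,
    )
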