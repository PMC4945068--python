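"""The representation screen: which features set gut genomes apart.

For every feature (an ortholog group, or a description-level group of
ortholog groups) the screen counts the gut and non-gut genomes that carry it.
A feature is *overrepresented* in the gut cohort when its gut genome count
exceeds its non-gut genome count by at least ``delta_min`` (12 for the
23 + 23 study design), *underrepresented* when the non-gut count exceeds the
gut count by at least ``delta_min``, and *neither* otherwise. The rule is an
absolute genome-count difference, not a proportion; with other cohort sizes
``delta_min`` has no canonical value and must be chosen by the caller.

Also here: description-level grouping (ortholog groups sharing an identical
functional description are one feature; undescribed groups are dropped, so
that information is lost at the group level), the shared core, the 2-D
gut x non-gut distribution grid, and the per-status functional-category
composition.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .annotation import PresenceMatrix
from .io_formats import GenomeRecord, Habitat, OrthologGroupAnnotation

__all__ = [
    "DistributionGrid",
    "FunctionGroup",
    "RepresentationRecord",
    "RepresentationStatus",
    "ScreenParams",
    "category_composition",
    "classify_representation",
    "count_representation",
    "distribution_grid",
    "group_by_description",
    "group_presence",
    "screen_matrix",
    "shared_core",
]

DEFAULT_DELTA_MIN = 12

#: Description strings treated as "no description" (after normalization).
_MISSING_DESCRIPTIONS = {"", "na"}


class RepresentationStatus(enum.Enum):
    OVERREPRESENTED = "overrepresented"
    UNDERREPRESENTED = "underrepresented"
    NEITHER = "neither"


@dataclass(frozen=True)
class ScreenParams:
    """Cohort sizes and the genome-count-difference threshold."""

    n_gut: int
    n_nongut: int
    delta_min: int = DEFAULT_DELTA_MIN

    def __post_init__(self) -> None:
        if self.delta_min < 1:
            raise ValueError(f"delta_min must be positive, got {self.delta_min}")
        if self.delta_min > max(self.n_gut, self.n_nongut):
            raise ValueError(
                f"delta_min {self.delta_min} exceeds both cohort sizes "
                f"({self.n_gut}, {self.n_nongut}); no feature could ever qualify"
            )


@dataclass(frozen=True)
class RepresentationRecord:
    """Per-feature cohort counts, difference, status and abundances."""

    feature_id: str
    gut_count: int
    nongut_count: int
    delta: int
    status: RepresentationStatus
    gut_abundance_pct: float
    nongut_abundance_pct: float


@dataclass(frozen=True)
class FunctionGroup:
    """Ortholog groups unified by an identical functional description."""

    group_key: str
    member_nogs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_nogs:
            raise ValueError(f"function group {self.group_key!r} has no members")


@dataclass(frozen=True)
class DistributionGrid:
    """(n_gut+1) x (n_nongut+1) grid of feature counts by cohort incidence.

    ``counts[i, j]`` = number of features present in exactly i gut and j
    non-gut genomes; gut is the first axis.
    """

    counts: np.ndarray

    def total(self) -> int:
        return int(self.counts.sum())

    def log10_display(self) -> np.ndarray:
        """log10 of nonzero cells, NaN elsewhere — the heat-map transform."""
        out = np.full(self.counts.shape, np.nan)
        nz = self.counts > 0
        out[nz] = np.log10(self.counts[nz])
        return out


def _cohort_ids(genomes: Sequence[GenomeRecord]) -> tuple[list[str], list[str]]:
    gut, nongut = [], []
    for g in genomes:
        if g.habitat is Habitat.GUT:
            gut.append(g.genome_id)
        elif g.habitat is Habitat.NON_GUT:
            nongut.append(g.genome_id)
        else:
            raise ValueError(
                f"genome {g.genome_id!r} is labeled {g.habitat.value}; the screen "
                "requires every genome to be gut or non_gut"
            )
    return gut, nongut


def count_representation(
    matrix: PresenceMatrix,
    genomes: Sequence[GenomeRecord],
) -> list[tuple[str, int, int]]:
    """Per-feature (gut genome count, non-gut genome count) tuples.

    Every matrix genome must carry a gut or non_gut label; ambiguous or
    unlabeled genomes must be removed upstream.
    """
    by_id = {g.genome_id: g for g in genomes}
    missing = [gid for gid in matrix.genome_ids if gid not in by_id]
    if missing:
        raise ValueError(f"matrix genomes without metadata: {missing}")
    gut_ids, nongut_ids = _cohort_ids([by_id[gid] for gid in matrix.genome_ids])
    gut_sums = matrix.frame.loc[gut_ids].sum(axis=0)
    nongut_sums = matrix.frame.loc[nongut_ids].sum(axis=0)
    return [
        (feature, int(gut_sums[feature]), int(nongut_sums[feature]))
        for feature in matrix.feature_ids
    ]


def classify_representation(
    feature_id: str,
    gut_count: int,
    nongut_count: int,
    params: ScreenParams,
) -> RepresentationRecord:
    """Apply the genome-count-difference rule to one feature."""
    if not 0 <= gut_count <= params.n_gut:
        raise ValueError(f"{feature_id}: gut_count {gut_count} outside [0, {params.n_gut}]")
    if not 0 <= nongut_count <= params.n_nongut:
        raise ValueError(f"{feature_id}: nongut_count {nongut_count} outside [0, {params.n_nongut}]")
    delta = gut_count - nongut_count
    if delta >= params.delta_min:
        status = RepresentationStatus.OVERREPRESENTED
    elif -delta >= params.delta_min:
        status = RepresentationStatus.UNDERREPRESENTED
    else:
        status = RepresentationStatus.NEITHER
    return RepresentationRecord(
        feature_id=feature_id,
        gut_count=gut_count,
        nongut_count=nongut_count,
        delta=delta,
        status=status,
        gut_abundance_pct=round_half_up(100.0 * gut_count / params.n_gut, 1),
        nongut_abundance_pct=round_half_up(100.0 * nongut_count / params.n_nongut, 1),
    )


def screen_matrix(
    matrix: PresenceMatrix,
    genomes: Sequence[GenomeRecord],
    delta_min: int = DEFAULT_DELTA_MIN,
) -> list[RepresentationRecord]:
    """Count and classify every feature of a presence matrix in one pass."""
    by_id = {g.genome_id: g for g in genomes}
    gut_ids, nongut_ids = _cohort_ids([by_id[gid] for gid in matrix.genome_ids])
    params = ScreenParams(n_gut=len(gut_ids), n_nongut=len(nongut_ids), delta_min=delta_min)
    return [
        classify_representation(feature, g, n, params)
        for feature, g, n in count_representation(matrix, genomes)
    ]


# ---------------------------------------------------------------------------
# description-level grouping


def normalize_description(description: str) -> str:
    """Trim, collapse internal whitespace runs, casefold."""
    return re.sub(r"\s+", " ", description.strip()).casefold()


def group_by_description(
    annotations: Iterable[OrthologGroupAnnotation],
    strict: bool = False,
) -> list[FunctionGroup]:
    """One feature per distinct functional description.

    By default descriptions are compared after whitespace/case normalization
    (published group descriptions are inconsistently capitalized); pass
    ``strict=True`` for byte-identical comparison. Groups with an empty or
    "NA" description are excluded — at the description level that information
    is lost. Output is sorted by group key.
    """
    members: dict[str, set[str]] = {}
    for ann in annotations:
        if normalize_description(ann.description) in _MISSING_DESCRIPTIONS:
            continue
        key = ann.description if strict else normalize_description(ann.description)
        members.setdefault(key, set()).add(ann.nog_id)
    return [
        FunctionGroup(group_key=key, member_nogs=frozenset(nogs))
        for key, nogs in sorted(members.items())
    ]


def group_presence(
    matrix: PresenceMatrix,
    groups: Sequence[FunctionGroup],
) -> PresenceMatrix:
    """Collapse a group-of-ortholog-groups to one OR-combined matrix column.

    A genome carries a group iff it carries any member. Members missing from
    the matrix are ignored with a warning; groups with no member present
    anywhere are excluded with a warning (no all-zero columns).
    """
    columns = set(matrix.feature_ids)
    data: dict[str, pd.Series] = {}
    for group in sorted(groups, key=lambda g: g.group_key):
        present_members = sorted(group.member_nogs & columns)
        absent = sorted(group.member_nogs - columns)
        if absent:
            warnings.warn(
                f"group {group.group_key!r}: members absent from matrix ignored: {absent}",
                stacklevel=2,
            )
        if not present_members:
            warnings.warn(
                f"group {group.group_key!r} has no member present in any genome; excluded",
                stacklevel=2,
            )
            continue
        data[group.group_key] = matrix.frame[present_members].max(axis=1)
    frame = pd.DataFrame(data, index=matrix.genome_ids, dtype="int8")
    frame = frame[sorted(frame.columns)]
    return PresenceMatrix(frame)


def shared_core(matrix: PresenceMatrix) -> set[str]:
    """Features present in every genome (the all-ones columns)."""
    if matrix.frame.shape[0] == 0:
        raise ValueError("shared_core of an empty matrix is undefined")
    counts = matrix.column_counts()
    return set(counts.index[counts == matrix.frame.shape[0]])


# ---------------------------------------------------------------------------
# distribution grid and category composition


def distribution_grid(
    counts: Iterable[tuple[str, int, int]],
    n_gut: int,
    n_nongut: int,
    exclude_singletons: bool = True,
) -> DistributionGrid:
    """Tally features on the (gut count) x (non-gut count) plane.

    ``exclude_singletons`` omits features carried by exactly one genome
    overall, matching the published display convention for this grid.
    """
    grid = np.zeros((n_gut + 1, n_nongut + 1), dtype=int)
    for _feature, g, n in counts:
        if exclude_singletons and g + n == 1:
            continue
        grid[g, n] += 1
    return DistributionGrid(counts=grid)


def category_composition(
    records: Sequence[RepresentationRecord],
    annotations: Mapping[str, OrthologGroupAnnotation] | Iterable[OrthologGroupAnnotation],
    multi_category: str = "per_letter",
) -> pd.DataFrame:
    """Functional-category make-up of each screen status, as percentages.

    Rows: the three statuses. Columns: category letters plus ``unknown``
    (features lacking any category letter). With ``multi_category=
    "per_letter"`` (default) a feature carrying several letters contributes
    one count per letter and the denominator is the total number of
    letter assignments in the status; with ``"first_letter"`` only the
    alphabetically first letter counts. Percentages per status sum to 100
    up to rounding. Empty statuses yield an all-zero row with a warning.
    """
    if multi_category not in ("per_letter", "first_letter"):
        raise ValueError(f"unknown multi_category mode {multi_category!r}")
    if not isinstance(annotations, Mapping):
        annotations = {a.nog_id: a for a in annotations}

    tallies: dict[RepresentationStatus, dict[str, int]] = {s: {} for s in RepresentationStatus}
    for record in records:
        ann = annotations.get(record.feature_id)
        letters = sorted(ann.categories) if ann is not None else []
        if not letters:
            letters = ["unknown"]
        elif multi_category == "first_letter":
            letters = letters[:1]
        tally = tallies[record.status]
        for letter in letters:
            tally[letter] = tally.get(letter, 0) + 1

    all_letters = sorted({letter for tally in tallies.values() for letter in tally} - {"unknown"})
    columns = all_letters + ["unknown"]
    rows = {}
    for status, tally in tallies.items():
        denominator = sum(tally.values())
        if denominator == 0:
            warnings.warn(f"no features with status {status.value}; composition row is all zero", stacklevel=2)
            rows[status.value] = [0.0] * len(columns)
        else:
            rows[status.value] = [
                round_half_up(100.0 * tally.get(letter, 0) / denominator, 1) for letter in columns
            ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
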