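"""Cohort statistics on predicted protein localization.

Per-genome counts of potentially surface exposed (pse), secreted (sec),
cytoplasmic (cyto) and membrane (mem) proteins are summarized per habitat
cohort (mean and standard error of the mean, SEM = s / sqrt(n) with the n-1
sample standard deviation) and each compartment's count is rank-correlated
against proteome size within each cohort (Spearman's rho with mid-rank ties;
two-sided p from the t approximation, or exact permutation enumeration for
small n). The diagnostic contrast of interest: secreted-protein counts track
proteome size in non-gut genomes but not in gut genomes, while membrane and
surface-exposed counts track it in both cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._round import round_half_up
from .io_formats import GenomeRecord, Habitat, LocalizationProfile

__all__ = [
    "CohortSummary",
    "CorrelationResult",
    "cohort_summary",
    "correlation_panel",
    "localization_fractions",
    "spearman_rank_correlation",
]

COMPARTMENTS = ("pse", "sec", "cyto", "mem")
#: compartments whose scaling with proteome size is examined
PANEL_COMPARTMENTS = ("pse", "sec", "mem")

EXACT_N_MAX = 10


@dataclass(frozen=True)
class CohortSummary:
    cohort: str
    variable: str
    n: int
    mean: float
    sem: float

    def display(self, decimals: int = 0) -> tuple[float, float]:
        """(mean, sem) rounded half-up — 0 decimals for counts, 1 for percentages."""
        return round_half_up(self.mean, decimals), round_half_up(self.sem, decimals)


@dataclass(frozen=True)
class CorrelationResult:
    cohort: str
    variable: str
    rho: float
    p_value: float
    n: int


def localization_fractions(profile: LocalizationProfile) -> dict[str, float]:
    """Each compartment count as a percentage of the printed proteome total.

    Full precision is retained; round for display only. When the compartments
    partition the proteome the four percentages sum to 100.
    """
    return {name: 100.0 * getattr(profile, name) / profile.total for name in COMPARTMENTS}


def cohort_summary(values: Sequence[float], cohort: str, variable: str) -> CohortSummary:
    """Mean and SEM of one variable over one cohort (n >= 2)."""
    if len(values) < 2:
        raise ValueError(f"cohort summary needs n >= 2, got n = {len(values)}")
    arr = np.asarray(values, dtype=float)
    return CohortSummary(
        cohort=cohort,
        variable=variable,
        n=len(arr),
        mean=float(arr.mean()),
        sem=float(arr.std(ddof=1) / math.sqrt(len(arr))),
    )


def spearman_rank_correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t_approximation",
) -> CorrelationResult:
    """Spearman's rho with a two-sided p-value.

    ``t_approximation`` (the mainstream default, used here at cohort size 23)
    tests t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom;
    ``exact`` enumerates all n! rank permutations (n <= 10) and reports the
    fraction with |rho| at least as large as observed. |rho| = 1 gives p = 0
    under the t approximation. Constant input vectors leave rho undefined and
    raise.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x_arr)
    if n < 4:
        raise ValueError(f"need n >= 4 observations, got {n}")
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        raise ValueError("rank correlation is undefined for a constant vector")

    rx = stats.rankdata(x_arr)  # mid-ranks for ties
    ry = stats.rankdata(y_arr)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    # rank correlations are rational with spacing >> 1e-12; snap float noise
    if abs(rho) > 1.0 - 1e-12:
        rho = math.copysign(1.0, rho)

    if method == "t_approximation":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    elif method == "exact":
        if n > EXACT_N_MAX:
            raise ValueError(f"exact enumeration is limited to n <= {EXACT_N_MAX}, got {n}")
        observed = abs(rho)
        at_least = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            # tolerance guards against float noise at the boundary
            if abs(r) >= observed - 1e-12:
                at_least += 1
            total += 1
        p = at_least / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(cohort="", variable="", rho=rho, p_value=p, n=n)


def correlation_panel(
    profiles: Sequence[LocalizationProfile],
    genomes: Sequence[GenomeRecord],
    method: str = "t_approximation",
) -> pd.DataFrame:
    """Rank correlation of each compartment count vs proteome size, per cohort.

    Six rows: {gut, non_gut} x {pse, sec, mem}, each correlating the
    compartment count vector against the total-protein vector within the
    cohort. Cohorts need at least 4 genomes. Returns a DataFrame with columns
    cohort, variable, rho, p_value, n.
    """
    habitat_of = {g.genome_id: g.habitat for g in genomes}
    unknown = [p.genome_id for p in profiles if p.genome_id not in habitat_of]
    if unknown:
        raise ValueError(f"profiles without genome metadata: {unknown}")
    bad = [
        p.genome_id
        for p in profiles
        if habitat_of[p.genome_id] not in (Habitat.GUT, Habitat.NON_GUT)
    ]
    if bad:
        raise ValueError(f"profiles for genomes that are neither gut nor non_gut: {bad}")

    rows = []
    for cohort in (Habitat.GUT, Habitat.NON_GUT):
        members = [p for p in profiles if habitat_of[p.genome_id] is cohort]
        if len(members) < 4:
            raise ValueError(f"cohort {cohort.value} has {len(members)} genomes; need >= 4")
        totals = [p.total for p in members]
        for compartment in PANEL_COMPARTMENTS:
            result = spearman_rank_correlation(
                [getattr(p, compartment) for p in members], totals, method=method
            )
            rows.append(
                {
                    "cohort": cohort.value,
                    "variable": compartment,
                    "rho": result.rho,
                    "p_value": result.p_value,
                    "n": result.n,
                }
            )
    return pd.DataFrame(rows)
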