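"""Supporting cohort statistics: descriptives, Wilcoxon rank-sum group
comparisons, residual-movement counting, and the willingness regression.

The Wilcoxon rank-sum test is implemented directly because the report
surface required here — the raw rank sum of the designated first group,
a tie-corrected z from the normal approximation, and an exact two-sided
p by subset enumeration at small combined n — is not what the scipy
wrappers return. scipy only supplies midranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ContractError, DegenerateFitError
from .items import STRATEGIES
from .model import MOVEMENT_CATEGORIES, RATING_DIMENSIONS, Cohort, Respondent

__all__ = [
    "WilcoxonResult",
    "RegressionResult",
    "count_residual_movements",
    "wilcoxon_rank_sum",
    "fit_willingness_regression",
    "summarize_cohort",
    "response_rate",
    "round_half_up",
]

#: Largest combined sample size for which the exact enumeration runs.
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    """Unpaired two-sample Wilcoxon (rank-sum) test result.

    ``rank_sum`` is the sum of (mid)ranks of the designated first group;
    ``z`` its standardized deviation from the null mean, tie-corrected.
    """

    rank_sum: float
    z: float
    p_two_sided: float
    method: str  # "normal_approx" or "exact"


@dataclass(frozen=True)
class RegressionResult:
    """OLS of willingness (1-5) on residual-movement count (0-5)."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float


def round_half_up(x: float) -> int:
    """Round half away from zero, the convention used for reported
    percentages (72.5% -> 73%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def count_residual_movements(respondent: Respondent) -> int:
    """Number of movement categories (0-5) with any preserved movement."""
    return sum(bool(respondent.residual_movement[c]) for c in MOVEMENT_CATEGORIES)


def _rank_sum_null_moments(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    """Mean and tie-corrected variance of the first group's rank sum
    under random assignment of the pooled (mid)ranks."""
    n = len(ranks)
    n_b = n - n_a
    mean = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return mean, var


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    continuity_correction: bool = False,
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
) -> WilcoxonResult:
    """Unpaired two-sample Wilcoxon test on ``group_a`` vs ``group_b``.

    Midranks are used for ties. When the combined sample size is at most
    ``exact_max_n`` the two-sided p-value is exact, by enumerating every
    assignment of the pooled ranks to the first group; otherwise the
    tie-corrected normal approximation is used (continuity correction
    off by default).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    n_a = a.size
    n = pooled.size
    w_obs = float(ranks[:n_a].sum())
    mean, var = _rank_sum_null_moments(ranks, n_a)
    if var == 0.0:  # all observations tied
        z = 0.0
    else:
        delta = w_obs - mean
        if continuity_correction and delta != 0.0:
            delta -= math.copysign(0.5, delta)
        z = delta / math.sqrt(var)
    if n <= exact_max_n:
        # enumerate all C(n, n_a) assignments of pooled ranks to group a
        threshold = abs(w_obs - mean) - 1e-9
        hits = total = 0
        for idx in combinations(range(n), n_a):
            total += 1
            if abs(ranks[list(idx)].sum() - mean) >= threshold:
                hits += 1
        return WilcoxonResult(w_obs, z, hits / total, "exact")
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_obs, z, min(1.0, p), "normal_approx")


def fit_willingness_regression(cohort: Cohort, group: str) -> RegressionResult:
    """OLS of willingness on residual-movement count within one group.

    Respondents with missing willingness are dropped. Raises
    :class:`DegenerateFitError` for n < 2 or a constant predictor.
    """
    pairs = [
        (count_residual_movements(r), r.willingness)
        for r in cohort
        if r.group == group and r.willingness is not None
    ]
    if len(pairs) < 2:
        raise DegenerateFitError(
            f"group {group!r}: need >= 2 respondents with willingness, "
            f"got {len(pairs)}"
        )
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError(
            f"group {group!r}: residual-movement count is constant"
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        group=group,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
        slope_se=float(fit.stderr),
    )


def response_rate(invited: int, enrolled: int) -> int:
    """Enrolment percentage, rounded half-up to an integer."""
    if invited <= 0:
        raise ContractError("invited must be positive")
    if not 0 <= enrolled <= invited:
        raise ContractError("enrolled must be in [0, invited]")
    return round_half_up(100.0 * enrolled / invited)


# ---------------------------------------------------------------------------
# Descriptive summary table
# ---------------------------------------------------------------------------


def _median_range_rows(stratum, variable, values):
    values = [v for v in values if v is not None]
    if not values:
        return []
    arr = np.asarray(values, dtype=float)
    return [
        (stratum, variable, "", "median", float(np.median(arr))),
        (stratum, variable, "", "min", float(arr.min())),
        (stratum, variable, "", "max", float(arr.max())),
    ]


def _percent_rows(stratum, variable, counts: dict, total: int):
    rows = []
    for level, cnt in counts.items():
        rows.append((stratum, variable, level, "count", float(cnt)))
        pct = round_half_up(100.0 * cnt / total) if total else 0
        rows.append((stratum, variable, level, "percent", float(pct)))
    return rows


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Tidy descriptive summary per group and overall.

    Returns a DataFrame with columns ``stratum, variable, level,
    statistic, value`` covering group sizes, sex split, age split at 50,
    ALSFRS-r and disease-duration median/range, residual-movement
    percentages per category, willingness median, and per-strategy
    Likert medians on clarity/difficulty/enjoyability. Percentages are
    integers (rounded half-up) relative to the stratum size; fields that
    are entirely missing are simply absent from the table.
    """
    rows: list[tuple] = []
    total_n = len(cohort)
    strata = [("overall", list(cohort))] + [
        (g, [r for r in cohort if r.group == g]) for g in ("NMD", "SO")
    ]
    for stratum, members in strata:
        n = len(members)
        rows.append((stratum, "respondents", "", "count", float(n)))
        if n == 0:
            continue
        if stratum != "overall" and total_n:
            rows.append(
                (
                    stratum,
                    "respondents",
                    "",
                    "percent_of_total",
                    float(round_half_up(100.0 * n / total_n)),
                )
            )
        sex_counts = {s: sum(r.sex == s for r in members) for s in ("F", "M")}
        rows += _percent_rows(stratum, "sex", sex_counts, n)
        age_counts = {
            "<=50": sum(r.age_years <= 50 for r in members),
            ">50": sum(r.age_years > 50 for r in members),
        }
        rows += _percent_rows(stratum, "age_group", age_counts, n)
        rows += _median_range_rows(
            stratum, "alsfrs_r", [r.alsfrs_r for r in members]
        )
        rows += _median_range_rows(
            stratum,
            "years_since_diagnosis",
            [r.years_since_diagnosis for r in members],
        )
        for cat in MOVEMENT_CATEGORIES:
            cnt = sum(bool(r.residual_movement[cat]) for r in members)
            rows += _percent_rows(stratum, f"movement_{cat}", {"present": cnt}, n)
        rows += _median_range_rows(
            stratum, "willingness", [r.willingness for r in members]
        )
        for strat in STRATEGIES.items:
            for d, dim in enumerate(RATING_DIMENSIONS):
                vals = [
                    r.strategy_ratings.get(strat, (None,) * 3)[d] for r in members
                ]
                vals = [v for v in vals if v is not None]
                if vals:
                    rows.append(
                        (
                            stratum,
                            f"rating_{strat}",
                            dim,
                            "median",
                            float(np.median(vals)),
                        )
                    )
    return pd.DataFrame(
        rows, columns=["stratum", "variable", "level", "statistic", "value"]
    )
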