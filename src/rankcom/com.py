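"""Center-of-mass (COM) rank aggregation and its Monte Carlo null.

The COM score of an item is the mean ranking weight it receives across
respondents:

    COM_i = sum_{k=1..K} k * #{s : Weight_s(i) = k} / T

where the top-ranked item gets weight K (6 for applications, 4 for
strategies), the j-th ranked item K - j + 1, unranked items 0, and T is
the number of respondents who answered the question. COM lies in
[0, K]; with no skipped answers the scores of all items sum to
K(K+1)/2 exactly (21 for applications, 10 for strategies), because each
respondent distributes the same total weight.

Because there is only one COM value per item, no standard test applies;
instead a Monte Carlo randomization null calibrates how much two COM
values can differ by chance: each simulated respondent's weight
multiset (K..1 plus zeros) is permuted uniformly across the items, COM
is recomputed per item, and the *chance SD* is the standard deviation
of the pooled replicate-by-item COM values (items are exchangeable
under this null). A difference between two COM values is flagged as
meaningful iff it is strictly larger than the chance SD.

The chance SD has the closed form sqrt(Var(weight multiset)/T), which
the Monte Carlo estimate converges to; the analytic value is exposed as
:func:`analytic_chance_sd` and used as a cross-check, never as the
calibration itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

from .errors import ContractError, EmptyCohortError, ParameterError
from .items import ItemSet
from .model import Cohort

__all__ = [
    "WeightAssignment",
    "ComResult",
    "NullCalibration",
    "assign_rank_weights",
    "compute_com",
    "calibrate_null",
    "analytic_chance_sd",
    "meaningful_differences",
]


@dataclass(frozen=True)
class WeightAssignment:
    """Per-respondent ranking weights for one item set.

    Respondents who skipped the question are absent from ``weights`` and
    excluded from ``T``.
    """

    item_set: ItemSet
    weights: Mapping[str, Mapping[str, int]]  # respondent id -> item -> weight
    groups: Mapping[str, str]  # respondent id -> group label
    T: int


@dataclass(frozen=True)
class ComResult:
    """COM scores for one item set over a cohort (optionally one group)."""

    item_set: ItemSet
    com: Mapping[str, float]
    T: int
    stratum: Optional[str] = None


@dataclass(frozen=True)
class NullCalibration:
    """Summary of the Monte Carlo randomization null."""

    item_set: ItemSet
    T: int
    n_replicates: int
    seed: int
    chance_sd: float
    replicate_coms: Optional[np.ndarray] = None  # (n_replicates, n_items)


def assign_rank_weights(cohort: Cohort, item_set: ItemSet) -> WeightAssignment:
    """Encode each respondent's ranking as item weights K..1 (unranked 0).

    Skipped rankings are excluded; T counts contributing respondents.
    """
    weights: dict[str, dict[str, int]] = {}
    groups: dict[str, str] = {}
    for r in cohort:
        ranking = cohort.ranking_for(r, item_set)
        if ranking.skipped:
            continue
        weights[r.id] = ranking.weights()
        groups[r.id] = r.group
    return WeightAssignment(
        item_set=item_set, weights=weights, groups=groups, T=len(weights)
    )


def compute_com(
    assignment: WeightAssignment, stratum: Optional[str] = None
) -> ComResult:
    """COM score per item via the count-based formula.

    ``stratum`` restricts to one group's respondents. Raises
    :class:`EmptyCohortError` when no respondent contributes (never a
    silent NaN).
    """
    item_set = assignment.item_set
    ids = [
        rid
        for rid in assignment.weights
        if stratum is None or assignment.groups[rid] == stratum
    ]
    T = len(ids)
    if T == 0:
        raise EmptyCohortError(
            f"no contributing respondents for {item_set.name}"
            + (f" in stratum {stratum!r}" if stratum else "")
        )
    K = item_set.rank_depth
    com: dict[str, float] = {}
    for item in item_set.items:
        # count respondents per weight value k = 1..K, then sum k * count / T
        counts = [0] * (K + 1)
        for rid in ids:
            counts[assignment.weights[rid][item]] += 1
        com[item] = sum(k * counts[k] for k in range(1, K + 1)) / T
    return ComResult(item_set=item_set, com=com, T=T, stratum=stratum)


def analytic_chance_sd(item_set: ItemSet, T: int) -> float:
    """Closed-form limit of the Monte Carlo chance SD: the weight
    multiset's population SD shrunk by sqrt(T)."""
    if T < 1:
        raise ContractError("T must be >= 1")
    ms = np.array(item_set.weight_multiset(), dtype=float)
    return math.sqrt(ms.var() / T)


def calibrate_null(
    item_set: ItemSet,
    T: int,
    n_replicates: int = 1000,
    seed: int = 0,
    keep_replicates: bool = False,
) -> NullCalibration:
    """Monte Carlo randomization null for the COM score.

    Each replicate simulates T respondents whose weight multiset
    (K..1 plus zeros up to the number of items) is permuted uniformly
    across the items; COM is computed per item, and the chance SD is the
    SD of all pooled replicate-by-item COM values.
    """
    if T < 1:
        raise ContractError("T must be >= 1")
    if n_replicates < 1:
        raise ContractError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    multiset = np.array(item_set.weight_multiset(), dtype=float)
    tiled = np.tile(multiset, (n_replicates * T, 1))
    permuted = rng.permuted(tiled, axis=1)
    coms = permuted.reshape(n_replicates, T, item_set.n_items).mean(axis=1)
    chance_sd = float(np.std(coms, ddof=1))
    return NullCalibration(
        item_set=item_set,
        T=T,
        n_replicates=n_replicates,
        seed=seed,
        chance_sd=chance_sd,
        replicate_coms=coms if keep_replicates else None,
    )


def meaningful_differences(
    com_a: ComResult,
    com_b: Optional[ComResult],
    calibration: NullCalibration,
) -> Union[set[tuple[str, str]], set[str]]:
    """Flag COM differences strictly larger than the chance SD.

    With ``com_b=None``, compares items within ``com_a`` and returns the
    set of unordered item pairs ``(i, j)`` (canonical item-set order,
    i before j) whose scores differ by more than the chance SD. With a
    second result (e.g. the other group), compares the two scores of
    each item and returns the set of flagged item names.

    A difference exactly equal to the chance SD is *not* flagged: the
    rule is a strict inequality.
    """
    if calibration.item_set.name != com_a.item_set.name:
        raise ContractError("calibration item set does not match COM result")
    sd = calibration.chance_sd
    items = com_a.item_set.items
    if com_b is None:
        flagged: set[tuple[str, str]] = set()
        for idx, i in enumerate(items):
            for j in items[idx + 1 :]:
                if abs(com_a.com[i] - com_a.com[j]) > sd:
                    flagged.add((i, j))
        return flagged
    if com_b.item_set.name != com_a.item_set.name:
        raise ContractError(
            f"mismatched item sets: {com_a.item_set.name} vs {com_b.item_set.name}"
        )
    return {i for i in items if abs(com_a.com[i] - com_b.com[i]) > sd}
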