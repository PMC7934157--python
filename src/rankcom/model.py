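"""Respondent records, validation, and CSV (de)serialization.

One row per respondent. Rankings are serialized as a single pipe-joined
field of item identifiers, best first (``"attempted_speech|attempted_hand
|..."``); an empty ranking field means the question was skipped. Missing
Likert answers are empty fields, never sentinel numbers, so they can
never leak into a statistic.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import CohortValidationError
from .items import APPLICATIONS, STRATEGIES, ItemSet

__all__ = [
    "GROUPS",
    "SEXES",
    "MOVEMENT_CATEGORIES",
    "RATING_DIMENSIONS",
    "RankingResponse",
    "Respondent",
    "Cohort",
    "read_cohort",
    "write_cohort",
]

#: Aetiology groups: progressive neuromuscular disease vs sudden onset.
GROUPS = ("NMD", "SO")
SEXES = ("F", "M")
#: The five residual-movement categories scored 0/1 per respondent.
MOVEMENT_CATEGORIES = (
    "eyes",
    "mouth_head",
    "hand_arm",
    "leg_feet_toes",
    "residual_speech",
)
RATING_DIMENSIONS = ("clarity", "difficulty", "enjoyability")

RANK_SEP = "|"


@dataclass(frozen=True)
class RankingResponse:
    """A strict partial (top-K) ranking of one item set, best first."""

    item_set: ItemSet
    ordered_items: tuple[str, ...]
    skipped: bool = False

    def __post_init__(self) -> None:
        if self.skipped and self.ordered_items:
            raise CohortValidationError(
                "skipped ranking must have no ordered items"
            )
        if len(set(self.ordered_items)) != len(self.ordered_items):
            raise CohortValidationError(
                f"{self.item_set.name}: duplicate item in ranking"
            )
        unknown = [i for i in self.ordered_items if i not in self.item_set.items]
        if unknown:
            raise CohortValidationError(
                f"{self.item_set.name}: unknown item(s) {unknown}"
            )
        if len(self.ordered_items) > self.item_set.rank_depth:
            raise CohortValidationError(
                f"{self.item_set.name}: {len(self.ordered_items)} items ranked, "
                f"at most {self.item_set.rank_depth} allowed"
            )

    def weights(self) -> dict[str, int]:
        """Rank-to-weight encoding: best item gets K, j-th gets K - j + 1,
        unranked items 0."""
        w = {item: 0 for item in self.item_set.items}
        for pos, item in enumerate(self.ordered_items):
            w[item] = self.item_set.weight_for_position(pos)
        return w


def _check_likert(value: Optional[int], what: str) -> None:
    if value is not None and not (1 <= value <= 5):
        raise CohortValidationError(f"{what}: Likert value {value} outside [1, 5]")


@dataclass(frozen=True)
class Respondent:
    """One participant's full questionnaire record."""

    id: str
    group: str
    age_years: float
    sex: str
    alsfrs_r: int
    residual_movement: Mapping[str, bool]
    application_ranking: RankingResponse
    strategy_ranking: RankingResponse
    strategy_ratings: Mapping[str, tuple[Optional[int], Optional[int], Optional[int]]]
    willingness: Optional[int]
    years_since_diagnosis: Optional[float] = None

    def __post_init__(self) -> None:
        rid = self.id
        if not rid:
            raise CohortValidationError("respondent id must be nonempty")
        if self.group not in GROUPS:
            raise CohortValidationError(f"{rid}: unknown group {self.group!r}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"{rid}: unknown sex {self.sex!r}")
        if not self.age_years > 0:
            raise CohortValidationError(f"{rid}: age_years must be positive")
        if not (0 <= self.alsfrs_r <= 48):
            raise CohortValidationError(
                f"{rid}: alsfrs_r {self.alsfrs_r} outside [0, 48]"
            )
        missing = set(MOVEMENT_CATEGORIES) - set(self.residual_movement)
        if missing:
            raise CohortValidationError(
                f"{rid}: missing residual_movement categories {sorted(missing)}"
            )
        for strat, triple in self.strategy_ratings.items():
            if strat not in STRATEGIES.items:
                raise CohortValidationError(f"{rid}: unknown strategy {strat!r}")
            for dim, val in zip(RATING_DIMENSIONS, triple):
                _check_likert(val, f"{rid}: {strat} {dim}")
        _check_likert(self.willingness, f"{rid}: willingness")
        if (
            self.years_since_diagnosis is not None
            and self.years_since_diagnosis < 0
        ):
            raise CohortValidationError(f"{rid}: negative years_since_diagnosis")


@dataclass(frozen=True)
class Cohort:
    """A validated sequence of respondents plus provenance."""

    respondents: tuple[Respondent, ...]
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.respondents]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate respondent ids: {dupes}")

    def __len__(self) -> int:
        return len(self.respondents)

    def __iter__(self):
        return iter(self.respondents)

    def subset(self, group: str) -> "Cohort":
        return Cohort(
            tuple(r for r in self.respondents if r.group == group),
            provenance=f"{self.provenance}[{group}]",
        )

    def ranking_for(self, respondent: Respondent, item_set: ItemSet) -> RankingResponse:
        if item_set.name == APPLICATIONS.name:
            return respondent.application_ranking
        if item_set.name == STRATEGIES.name:
            return respondent.strategy_ranking
        raise CohortValidationError(f"unknown item set {item_set.name!r}")


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------

_BASE_COLUMNS = [
    "id",
    "group",
    "age_years",
    "sex",
    "alsfrs_r",
    "years_since_diagnosis",
    "willingness",
]
_MOVE_COLUMNS = [f"movement_{c}" for c in MOVEMENT_CATEGORIES]
_RANK_COLUMNS = ["application_ranking", "strategy_ranking"]
_RATING_COLUMNS = [
    f"{strat}__{dim}" for strat in STRATEGIES.items for dim in RATING_DIMENSIONS
]

#: Deterministic on-disk column order.
COLUMNS = _BASE_COLUMNS + _MOVE_COLUMNS + _RANK_COLUMNS + _RATING_COLUMNS


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest round-trip representation
    return str(value)


def _respondent_row(r: Respondent) -> list[str]:
    row = [
        r.id,
        r.group,
        _fmt(r.age_years),
        r.sex,
        _fmt(r.alsfrs_r),
        _fmt(r.years_since_diagnosis),
        _fmt(r.willingness),
    ]
    row += [_fmt(bool(r.residual_movement[c])) for c in MOVEMENT_CATEGORIES]
    row += [
        RANK_SEP.join(r.application_ranking.ordered_items),
        RANK_SEP.join(r.strategy_ranking.ordered_items),
    ]
    for strat in STRATEGIES.items:
        triple = r.strategy_ratings.get(strat, (None, None, None))
        row += [_fmt(v) for v in triple]
    return row


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as UTF-8 CSV with a fixed column order.

    Output is byte-identical across calls for identical input.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(COLUMNS)
    for r in cohort:
        writer.writerow(_respondent_row(r))
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _parse_opt_int(text: str, what: str) -> Optional[int]:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise CohortValidationError(f"{what}: not an integer: {text!r}") from exc


def _parse_opt_float(text: str, what: str) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise CohortValidationError(f"{what}: not a number: {text!r}") from exc


def _parse_ranking(text: str, item_set: ItemSet) -> RankingResponse:
    if text == "":
        return RankingResponse(item_set, (), skipped=True)
    return RankingResponse(item_set, tuple(text.split(RANK_SEP)))


def _parse_row(record: Mapping[str, str], row_no: int) -> Respondent:
    rid = record.get("id", "").strip()
    where = f"row {row_no} (id={rid!r})"
    try:
        move = {}
        for cat in MOVEMENT_CATEGORIES:
            raw = record[f"movement_{cat}"]
            if raw not in ("0", "1"):
                raise CohortValidationError(
                    f"movement_{cat}: expected 0/1, got {raw!r}"
                )
            move[cat] = raw == "1"
        ratings = {}
        for strat in STRATEGIES.items:
            triple = tuple(
                _parse_opt_int(record[f"{strat}__{dim}"], f"{strat}__{dim}")
                for dim in RATING_DIMENSIONS
            )
            ratings[strat] = triple
        age = _parse_opt_float(record["age_years"], "age_years")
        alsfrs = _parse_opt_int(record["alsfrs_r"], "alsfrs_r")
        if age is None or alsfrs is None:
            raise CohortValidationError("age_years and alsfrs_r are required")
        return Respondent(
            id=rid,
            group=record["group"],
            age_years=age,
            sex=record["sex"],
            alsfrs_r=alsfrs,
            residual_movement=move,
            application_ranking=_parse_ranking(
                record["application_ranking"], APPLICATIONS
            ),
            strategy_ranking=_parse_ranking(record["strategy_ranking"], STRATEGIES),
            strategy_ratings=ratings,
            willingness=_parse_opt_int(record["willingness"], "willingness"),
            years_since_diagnosis=_parse_opt_float(
                record["years_since_diagnosis"], "years_since_diagnosis"
            ),
        )
    except CohortValidationError as exc:
        raise CohortValidationError(f"{where}: {exc}") from exc
    except KeyError as exc:
        raise CohortValidationError(f"{where}: missing column {exc}") from exc


def read_cohort(path: str | Path, schema_config: Optional[Mapping] = None) -> Cohort:
    """Read and validate a questionnaire CSV.

    Rows violating any invariant are rejected with a message naming the
    row number, respondent id, and offending field. ``schema_config`` is
    reserved for registry overrides and currently accepts only the key
    ``"provenance"``.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError(f"{path}: empty file, no header")
        missing = set(COLUMNS) - set(reader.fieldnames)
        if missing:
            raise CohortValidationError(
                f"{path}: missing columns {sorted(missing)}"
            )
        respondents = tuple(
            _parse_row(rec, row_no) for row_no, rec in enumerate(reader, start=2)
        )
    provenance = str(path)
    if schema_config and "provenance" in schema_config:
        provenance = str(schema_config["provenance"])
    return Cohort(respondents, provenance=provenance)
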