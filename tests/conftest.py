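import pytest

from rankcom.items import APPLICATIONS, STRATEGIES
from rankcom.model import (
    MOVEMENT_CATEGORIES,
    Cohort,
    RankingResponse,
    Respondent,
)
from rankcom.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture
def make_respondent():
    """Factory for hand-built respondents with sensible defaults."""

    def _make(
        rid="R01",
        group="NMD",
        app_order=APPLICATIONS.items,
        strat_order=STRATEGIES.items[:4],
        movements=("eyes",),
        willingness=3,
        alsfrs_r=10,
        age=55.0,
        sex="F",
        app_skipped=False,
        strat_skipped=False,
        ratings=None,
        duration=12.0,
    ):
        move = {c: c in movements for c in MOVEMENT_CATEGORIES}
        if ratings is None:
            ratings = {s: (3, 3, 3) for s in STRATEGIES.items}
        return Respondent(
            id=rid,
            group=group,
            age_years=age,
            sex=sex,
            alsfrs_r=alsfrs_r,
            residual_movement=move,
            application_ranking=RankingResponse(
                APPLICATIONS, () if app_skipped else tuple(app_order),
                skipped=app_skipped,
            ),
            strategy_ranking=RankingResponse(
                STRATEGIES, () if strat_skipped else tuple(strat_order),
                skipped=strat_skipped,
            ),
            strategy_ratings=ratings,
            willingness=willingness,
            years_since_diagnosis=duration,
        )

    return _make


@pytest.fixture
def tiny_cohort(make_respondent):
    return Cohort(
        (
            make_respondent("R01", "NMD"),
            make_respondent(
                "R02",
                "SO",
                app_order=tuple(reversed(APPLICATIONS.items)),
                strat_order=STRATEGIES.items[4:],
                movements=("eyes", "mouth_head", "residual_speech"),
                willingness=5,
            ),
        ),
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 13 NMD + 15 SO respondents."""
    return generate_cohort(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def noskip_cohort():
    return generate_cohort(GeneratorConfig(skip_prob=0.0, seed=7))
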