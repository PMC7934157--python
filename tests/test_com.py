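"""COM rank aggregation, the Monte Carlo null, and the difference rule."""

import numpy as np
import pytest

import rankcom as rc
from rankcom.com import WeightAssignment
from rankcom.errors import ContractError, EmptyCohortError
from rankcom.items import APPLICATIONS, STRATEGIES, ItemSet
from rankcom.model import Cohort
from rankcom.synthetic import GeneratorConfig, generate_cohort


class TestAssignRankWeights:
    def test_full_application_ranking(self, make_respondent):
        order = (
            "direct_communication",
            "private_writing",
            "computer_use",
            "environmental_control",
            "emotions_expression",
            "artistic_expression",
        )
        cohort = Cohort((make_respondent(app_order=order),))
        wa = rc.assign_rank_weights(cohort, APPLICATIONS)
        weights = wa.weights["R01"]
        assert [weights[i] for i in order] == [6, 5, 4, 3, 2, 1]
        assert wa.T == 1

    def test_strategy_top4_weights_and_zeros(self, make_respondent):
        order = STRATEGIES.items[:4]
        cohort = Cohort((make_respondent(strat_order=order),))
        weights = rc.assign_rank_weights(cohort, STRATEGIES).weights["R01"]
        assert [weights[i] for i in order] == [4, 3, 2, 1]
        assert all(weights[i] == 0 for i in STRATEGIES.items[4:])

    def test_all_skipped_gives_empty_assignment(self, make_respondent):
        cohort = Cohort(
            (
                make_respondent("A", strat_skipped=True),
                make_respondent("B", strat_skipped=True),
            )
        )
        wa = rc.assign_rank_weights(cohort, STRATEGIES)
        assert wa.T == 0 and wa.weights == {}

    def test_skips_shrink_T_for_that_question_only(self, make_respondent):
        cohort = Cohort(
            (make_respondent("A", strat_skipped=True), make_respondent("B"))
        )
        assert rc.assign_rank_weights(cohort, STRATEGIES).T == 1
        assert rc.assign_rank_weights(cohort, APPLICATIONS).T == 2


def _assignment(item_set, per_respondent_weights):
    return WeightAssignment(
        item_set=item_set,
        weights={f"r{k}": w for k, w in enumerate(per_respondent_weights)},
        groups={f"r{k}": "NMD" for k in range(len(per_respondent_weights))},
        T=len(per_respondent_weights),
    )


class TestComputeCom:
    def test_unanimous_first_rank_attains_maximum(self, make_respondent):
        order = APPLICATIONS.items
        cohort = Cohort(
            tuple(make_respondent(f"R{k:02d}", app_order=order) for k in range(28))
        )
        res = rc.compute_com(rc.assign_rank_weights(cohort, APPLICATIONS))
        assert res.com[order[0]] == 6.0

    def test_com_is_mean_weight(self):
        items = ItemSet("pair", ("x", "y"), 2)
        wa = _assignment(
            items, [{"x": 1, "y": 2}, {"x": 2, "y": 1}, {"x": 1, "y": 2}]
        )
        # y gets weights (2, 1, 2) -> hand mean 5/3; x gets 4/3
        res = rc.compute_com(wa)
        assert res.com["y"] == pytest.approx(5 / 3)
        assert res.com["x"] == pytest.approx(4 / 3)

    def test_empty_cohort_raises_not_nan(self):
        wa = _assignment(STRATEGIES, [])
        with pytest.raises(EmptyCohortError):
            rc.compute_com(wa)

    def test_matches_direct_mean_oracle_on_random_cohort(self, noskip_cohort):
        for item_set in (APPLICATIONS, STRATEGIES):
            wa = rc.assign_rank_weights(noskip_cohort, item_set)
            res = rc.compute_com(wa)
            for item in item_set.items:
                direct = np.mean([w[item] for w in wa.weights.values()])
                assert res.com[item] == pytest.approx(direct, abs=0)

    def test_invariant_to_respondent_order(self, noskip_cohort):
        shuffled = Cohort(tuple(reversed(noskip_cohort.respondents)))
        for item_set in (APPLICATIONS, STRATEGIES):
            a = rc.compute_com(rc.assign_rank_weights(noskip_cohort, item_set))
            b = rc.compute_com(rc.assign_rank_weights(shuffled, item_set))
            assert a.com == b.com

    def test_stratified_com_uses_group_T(self, default_cohort):
        wa = rc.assign_rank_weights(default_cohort, STRATEGIES)
        nmd = rc.compute_com(wa, stratum="NMD")
        so = rc.compute_com(wa, stratum="SO")
        assert nmd.T + so.T == rc.compute_com(wa).T
        assert nmd.stratum == "NMD"

    def test_conservation_with_no_skips(self):
        # With full participation the COM scores always sum to K(K+1)/2:
        # 21 for applications, 10 for strategies.
        for seed in range(20):
            cohort = generate_cohort(GeneratorConfig(skip_prob=0.0, seed=seed))
            for item_set, expected in ((APPLICATIONS, 21.0), (STRATEGIES, 10.0)):
                res = rc.compute_com(rc.assign_rank_weights(cohort, item_set))
                assert sum(res.com.values()) == pytest.approx(expected, abs=1e-9)


class TestCalibrateNull:
    def test_matches_closed_form_at_1000_replicates(self):
        cal = rc.calibrate_null(STRATEGIES, T=28, n_replicates=1000, seed=0)
        analytic = rc.analytic_chance_sd(STRATEGIES, 28)
        assert analytic == pytest.approx(np.sqrt(2.1875 / 28))
        assert abs(cal.chance_sd - analytic) / analytic < 0.05

    def test_converges_within_one_percent_at_50k_replicates(self):
        cal = rc.calibrate_null(APPLICATIONS, T=28, n_replicates=50_000, seed=1)
        analytic = rc.analytic_chance_sd(APPLICATIONS, 28)
        assert abs(cal.chance_sd - analytic) / analytic < 0.01

    def test_chance_sd_decreases_with_T(self):
        sds = [
            rc.calibrate_null(STRATEGIES, T=t, n_replicates=2000, seed=5).chance_sd
            for t in (5, 28, 100)
        ]
        assert sds[0] > sds[1] > sds[2]

    def test_reproducible_under_seed(self):
        a = rc.calibrate_null(STRATEGIES, 28, 500, seed=9)
        b = rc.calibrate_null(STRATEGIES, 28, 500, seed=9)
        assert a.chance_sd == b.chance_sd

    def test_degenerate_all_equal_weights(self):
        # single-item set: every respondent hands out the same weight
        single = ItemSet("one", ("only",), 1)
        cal = rc.calibrate_null(single, T=10, n_replicates=100, seed=0)
        assert cal.chance_sd == 0.0


class TestMeaningfulDifferences:
    def _com(self, values, stratum=None):
        items = ItemSet("pair", ("x", "y"), 2)
        return rc.ComResult(
            item_set=items, com=dict(zip(("x", "y"), values)), T=3, stratum=stratum
        )

    def _cal(self, sd):
        items = ItemSet("pair", ("x", "y"), 2)
        return rc.NullCalibration(
            item_set=items, T=3, n_replicates=1, seed=0, chance_sd=sd
        )

    def test_equal_scores_never_flagged(self):
        assert rc.meaningful_differences(self._com((2.0, 2.0)), None, self._cal(0.5)) == set()

    def test_boundary_equal_to_sd_not_flagged(self):
        # the rule is strictly "larger than" the chance SD
        flagged = rc.meaningful_differences(self._com((2.5, 2.0)), None, self._cal(0.5))
        assert flagged == set()

    def test_difference_above_sd_flagged(self):
        flagged = rc.meaningful_differences(self._com((3.0, 2.0)), None, self._cal(0.5))
        assert flagged == {("x", "y")}

    def test_group_vs_group_mode(self):
        a = self._com((3.0, 2.0), stratum="NMD")
        b = self._com((2.4, 1.9), stratum="SO")
        assert rc.meaningful_differences(a, b, self._cal(0.5)) == {"x"}

    def test_mismatched_item_sets_rejected(self):
        other = rc.ComResult(
            item_set=STRATEGIES,
            com={i: 1.0 for i in STRATEGIES.items},
            T=3,
        )
        with pytest.raises(ContractError):
            rc.meaningful_differences(self._com((1.0, 2.0)), other, self._cal(0.5))
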