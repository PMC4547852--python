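import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from epint.differential import (
    StratumTable,
    contingency,
    corrected_odds_ratio,
    differential_interaction_test,
    differential_screen,
    screen_summary,
    tarone_statistic,
)
from epint.interaction import detect_interactions
from epint.permutation import PermutationPlan
from epint.scenarios import differential_spec
from epint.synthetic import generate_matrix

from .conftest import make_matrix


def reference_tarone(tables):
    """Independently coded Breslow-Day-Tarone reference.

    Solves for the fitted both-altered counts numerically (root finding on
    the odds-ratio identity rather than the closed-form quadratic) and
    accumulates the statistic term by term.
    """
    a = np.array([t.co for t in tables], float)
    b = np.array([t.a_only for t in tables], float)
    c = np.array([t.b_only for t in tables], float)
    d = np.array([t.neither for t in tables], float)
    n = a + b + c + d
    psi = np.sum(a * d / n) / np.sum(b * c / n)
    chi = 0.0
    resid_sum = 0.0
    var_sum = 0.0
    for k in range(len(tables)):
        p, q = a[k] + b[k], a[k] + c[k]
        lo = max(0.0, p + q - n[k]) + 1e-12
        hi = min(p, q) - 1e-12

        def f(x):
            return x * (n[k] - p - q + x) - psi * (p - x) * (q - x)

        fitted = optimize.brentq(f, lo, hi, xtol=1e-13)
        var = 1.0 / (
            1.0 / fitted
            + 1.0 / (p - fitted)
            + 1.0 / (q - fitted)
            + 1.0 / (n[k] - p - q + fitted)
        )
        chi += (a[k] - fitted) ** 2 / var
        resid_sum += a[k] - fitted
        var_sum += var
    return chi - resid_sum**2 / var_sum


class TestContingency:
    def test_empty_cohort_gives_zero_table(self):
        inc = np.zeros((4, 2), dtype=np.uint8)
        inc[:, :] = [[1, 1], [1, 0], [0, 1], [0, 0]]
        m = make_matrix(inc, cancer_types=["X"] * 4)
        with pytest.raises(KeyError):
            contingency(m, ("a0", "a1"), "Y")

    def test_hand_computed_counts(self):
        inc = np.zeros((100, 2), dtype=np.uint8)
        inc[:15, 0] = 1
        inc[8:18, 1] = 1  # overlap samples 8..14 -> 7
        m = make_matrix(inc)
        t = contingency(m, ("a0", "a1"), "T")
        assert (t.co, t.a_only, t.b_only, t.neither) == (7, 8, 3, 82)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_counts_partition_the_cohort(self, seed):
        rng = np.random.default_rng(seed)
        inc = rng.integers(0, 2, size=(30, 2)).astype(np.uint8)
        m = make_matrix(inc)
        t = contingency(m, ("a0", "a1"), "T")
        assert t.total == 30


class TestCorrectedOddsRatio:
    def test_hand_computed_example(self):
        assert corrected_odds_ratio(StratumTable(10, 5, 5, 80)) == pytest.approx(
            845.25 / 30.25
        )

    def test_empty_table_gives_one(self):
        assert corrected_odds_ratio(StratumTable(0, 0, 0, 0)) == pytest.approx(1.0)

    def test_symmetric_in_the_two_alterations(self):
        t = StratumTable(3, 7, 2, 18)
        swapped = StratumTable(3, 2, 7, 18)
        assert corrected_odds_ratio(t) == pytest.approx(
            corrected_odds_ratio(swapped)
        )


class TestTaroneStatistic:
    def test_identical_strata_give_zero(self):
        t = StratumTable(10, 5, 5, 80)
        assert tarone_statistic([t, t])[0] == pytest.approx(0.0, abs=1e-10)

    def test_single_stratum_gives_zero_df_zero(self):
        assert tarone_statistic([StratumTable(4, 3, 2, 1)]) == (0.0, 0)

    def test_matches_independent_reference_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            tables = [
                StratumTable(*rng.integers(1, 80, size=4).tolist())
                for _ in range(2)
            ]
            t, df = tarone_statistic(tables, continuity="never")
            assert df == 1
            assert t == pytest.approx(reference_tarone(tables), abs=1e-6)

    def test_matches_statsmodels_breslow_day_tarone(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for _ in range(25):
            tables = [
                StratumTable(*rng.integers(1, 60, size=4).tolist())
                for _ in range(2)
            ]
            t, _ = tarone_statistic(tables, continuity="never")
            arr = np.array(
                [[[x.co, x.a_only], [x.b_only, x.neither]] for x in tables],
                dtype=float,
            ).transpose(1, 2, 0)
            ref = sm.stats.StratifiedTable(arr).test_equal_odds(adjust=True)
            assert t == pytest.approx(ref.statistic, abs=1e-6)

    def test_invariant_to_stratum_order_and_role_swap(self):
        tables = [StratumTable(10, 5, 5, 80), StratumTable(2, 20, 20, 8)]
        t0, _ = tarone_statistic(tables)
        t1, _ = tarone_statistic(tables[::-1])
        swapped = [
            StratumTable(x.co, x.b_only, x.a_only, x.neither) for x in tables
        ]
        t2, _ = tarone_statistic(swapped)
        assert t0 == pytest.approx(t1) == pytest.approx(t2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_statistic_is_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        tables = [
            StratumTable(*rng.integers(0, 40, size=4).tolist()) for _ in range(2)
        ]
        assert tarone_statistic(tables)[0] >= 0

    def test_zero_cells_handled_by_continuity_rule(self):
        tables = [StratumTable(0, 5, 5, 80), StratumTable(8, 2, 3, 40)]
        t, _ = tarone_statistic(tables)  # auto mode corrects all cells
        assert np.isfinite(t) and t >= 0


class TestDifferentialTest:
    def test_ineligible_pair_skipped(self):
        inc = np.zeros((100, 2), dtype=np.uint8)
        inc[:20, :] = 1  # only altered in type X
        m = make_matrix(inc, cancer_types=["X"] * 50 + ["Y"] * 50)
        plan = PermutationPlan(n_permutations=10, seed=0)
        assert (
            differential_interaction_test(("a0", "a1"), "X", "Y", m, plan)
            is None
        )

    def test_identical_strata_give_p_near_one(self):
        # background columns are required: with only the pair's two columns
        # in a block, row margins pin the overlap and the null is degenerate
        rng = np.random.default_rng(0)
        inc = np.zeros((200, 8), dtype=np.uint8)
        for off in (0, 100):
            inc[off : off + 20, 0] = 1
            inc[off + 10 : off + 30, 1] = 1
        inc[:, 2:] = (rng.random((200, 6)) < 0.2).astype(np.uint8)
        m = make_matrix(inc, cancer_types=["X"] * 100 + ["Y"] * 100)
        plan = PermutationPlan(n_permutations=100, seed=1)
        res = differential_interaction_test(("a0", "a1"), "X", "Y", m, plan)
        assert res.T_obs == pytest.approx(0.0, abs=1e-9)
        # strict > counting sends every permutation with T_random = 0 (the
        # discrete analogue of a tie) to the null side; with continuous T
        # the P-value would be ~1, here it is merely far from significant
        assert res.p_empirical > 0.5
        assert res.call == "not_differential"

    def test_planted_differential_pair_recovered(self):
        m, man = generate_matrix(differential_spec(0))
        plan = PermutationPlan(n_permutations=400, seed=7)
        pair = tuple(man.differential_pairs[0])
        res = differential_interaction_test(pair, "TypeA", "TypeB", m, plan)
        assert res.delta_log_or > 0
        assert res.p_empirical <= 0.05


class TestDifferentialScreen:
    def test_empty_detection_gives_empty_screen(self):
        m, _ = generate_matrix(differential_spec(1))
        plan = PermutationPlan(n_permutations=10, seed=0)
        assert differential_screen({}, m, plan) == []

    def test_one_pair_three_other_types_gives_three_comparisons(self):
        rng = np.random.default_rng(0)
        inc = (rng.random((400, 2)) < 0.2).astype(np.uint8)
        types = ["A"] * 100 + ["B"] * 100 + ["C"] * 100 + ["D"] * 100
        m = make_matrix(inc, cancer_types=types)
        plan = PermutationPlan(n_permutations=20, seed=0)
        from epint.interaction import InteractionResult, fdr_and_classify

        r = InteractionResult(
            pair=("a0", "a1"), scope="A", co_observed=5, P_co=0.001, P_me=1.0,
            p_min=0.001, direction="co_occurrence", odds_ratio=4.0,
            log_odds_ratio=np.log(4), p_two_sided=0.002,
        )
        detected = {"A": fdr_and_classify([r])}
        results = differential_screen(detected, m, plan)
        assert len(results) == 3
        assert {x.compared_type for x in results} == {"B", "C", "D"}
        summary = screen_summary(results)
        assert summary["n_comparisons"] == 3
        assert summary["n_pairs_tested"] == 1

    def test_screen_recovers_planted_differential_pairs(self):
        m, man = generate_matrix(differential_spec(2))
        plan = PermutationPlan(n_permutations=500, seed=9)
        nets = {
            t: detect_interactions(m, plan, scope=t)
            for t in m.cancer_type_labels()
        }
        results = differential_screen(nets, m, plan)
        by_pair = {}
        for r in results:
            by_pair.setdefault(r.pair, []).append(r)
        hits = sum(
            any(r.call == "higher_OR" for r in by_pair.get(tuple(p), []))
            for p in man.differential_pairs
        )
        assert hits >= 4  # at least 4 of the 5 planted differential pairs
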