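import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rkit.scoring import (
    EF1_CROSSED_COEFFS,
    EF1_SS_COEFFS,
    estimate_ef1,
    eterna_score_classic,
    f1_crossed_pair,
    f1_structure,
    fit_scaling_law,
    mae_clipped,
    mcrmse,
    mean_by_cluster,
    openknot_score,
)
from rkit.structure import PairScoreMatrix, SecondaryStructure, parse_dotbracket


def struct(db: str) -> SecondaryStructure:
    return parse_dotbracket(db)


class TestClassicScore:
    def test_perfect_agreement(self):
        s = struct("((....))")
        r = np.array([0.1, 0.1, 0.5, 0.5, 0.5, 0.5, 0.1, 0.1])
        assert eterna_score_classic(r, s) == 100.0

    def test_total_disagreement(self):
        s = struct("((....))")
        r = np.array([0.9, 0.9, 0.0, 0.0, 0.0, 0.0, 0.9, 0.9])
        assert eterna_score_classic(r, s) == 0.0

    def test_partial(self):
        s = struct("((..))")
        # paired at 0,1,4,5; unpaired at 2,3
        r = np.array([0.1, 0.9, 0.5, 0.0, 0.1, 0.9])
        assert eterna_score_classic(r, s) == pytest.approx(100 * 3 / 6)

    def test_boundary_values_fail(self):
        s = struct("(....)")
        r = np.array([0.5, 0.125, 0.2, 0.2, 0.2, 0.4])
        # position 0 (paired, = 0.5) and 1 (unpaired, = 0.125) both fail
        assert eterna_score_classic(r, s) == pytest.approx(100 * 4 / 6)

    def test_missing_positions_excluded(self):
        s = struct("((..))")
        r = np.array([0.1, np.nan, 0.5, 0.5, np.nan, 0.1])
        assert eterna_score_classic(r, s) == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            eterna_score_classic(np.zeros(5), struct("((..))"))


class TestOpenKnot:
    def test_crossing_free_candidate_scores_half(self):
        s = struct("((....))")
        r = np.array([0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.1, 0.1])  # classic 100
        res = openknot_score(r, [s])
        assert res.classic_scores[0] == 100.0
        assert res.pk_subscores[0] == 0.0
        assert res.score == 50.0

    def test_pseudoknotted_perfect_fit_scores_100(self):
        s = struct("((..[[..))..]]")
        r = np.full(14, 0.1)
        r[[2, 3, 6, 7, 10, 11]] = 0.9  # unpaired positions reactive
        res = openknot_score(r, [s])
        assert res.score == 100.0

    def test_window_excludes_distant_candidates(self):
        paired = struct("((....))")
        r = np.array([0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.1, 0.4])
        # candidate 2: everything unpaired -> lower classic score
        unpaired = SecondaryStructure(length=8)
        res = openknot_score(r, [paired, unpaired])
        c = res.classic_scores
        assert c[0] - c[1] > 5
        assert res.best_fit == [0]

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            openknot_score(np.zeros(5), [])

    def test_score_in_range_on_random_inputs(self, rng):
        from rkit.simulate import SimConfig, simulate_reactivity, simulate_structure

        cfg = SimConfig()
        for _ in range(200):
            L = int(rng.integers(20, 60))
            cands = [simulate_structure(L, 0.5, rng) for _ in range(3)]
            r = simulate_reactivity(cands[0], cfg, rng)
            res = openknot_score(r, cands)
            assert 0.0 <= res.score <= 100.0
            assert all(0 <= c <= 100 for c in res.classic_scores)

    def test_true_pseudoknot_beats_its_nested_deletion(self, rng):
        """Averaged over replicates, offering the true pseudoknotted structure
        yields a higher OpenKnot score than offering only its crossing-free
        deletion."""
        from rkit.simulate import SimConfig, simulate_reactivity, simulate_structure
        from rkit.structure import crossed_pairs

        cfg = SimConfig()
        with_pk, without_pk = [], []
        n = 0
        while n < 100:
            s = simulate_structure(50, 1.0, rng)
            cp = crossed_pairs(s)
            nested = SecondaryStructure(length=50, pairs=frozenset(set(s.pairs) - set(cp)))
            r = simulate_reactivity(s, cfg, rng)
            with_pk.append(openknot_score(r, [s, nested]).score)
            without_pk.append(openknot_score(r, [nested]).score)
            n += 1
        assert np.mean(with_pk) > np.mean(without_pk)


class TestF1:
    def test_identical(self):
        s = struct("((..[[..))..]]")
        res = f1_structure(s, s)
        assert res.precision == res.recall == res.f1 == 1.0

    def test_disjoint(self):
        a = struct("((....))......")
        b = struct("......((....))")
        assert f1_structure(a, b).f1 == 0.0

    def test_half_overlap(self):
        ref = SecondaryStructure(length=10, pairs=frozenset({(0, 9), (1, 8)}))
        pred = SecondaryStructure(length=10, pairs=frozenset({(0, 9), (2, 7)}))
        res = f1_structure(ref, pred)
        assert res.precision == 0.5
        assert res.recall == 0.5
        assert res.f1 == 0.5

    def test_empty_prediction_scores_zero(self):
        ref = struct("((....))")
        pred = SecondaryStructure(length=8)
        assert f1_structure(ref, pred).f1 == 0.0

    def test_both_empty_scores_one(self):
        e = SecondaryStructure(length=8)
        assert f1_structure(e, e).f1 == 1.0

    def test_f1_symmetric_under_swap(self, rng):
        from rkit.simulate import simulate_structure

        for _ in range(30):
            a = simulate_structure(40, 0.5, rng)
            b = simulate_structure(40, 0.5, rng)
            ra, rb = f1_structure(a, b), f1_structure(b, a)
            assert ra.f1 == pytest.approx(rb.f1)
            assert ra.precision == pytest.approx(rb.recall)


class TestF1Crossed:
    def test_both_crossing_free_is_undefined(self):
        a, b = struct("((....))"), struct("(......)")
        assert f1_crossed_pair(a, b) is None

    def test_overpredicted_crossing_scores_zero(self):
        ref = struct("((....))......")
        pred = SecondaryStructure(length=14, pairs=frozenset({(0, 9), (4, 13)}))
        assert f1_crossed_pair(ref, pred) == 0.0

    def test_identical_pseudoknots_score_one(self):
        s = struct("((..[[..))..]]")
        assert f1_crossed_pair(s, s) == 1.0


class TestMae:
    def test_clipping_hides_out_of_range_error(self):
        assert mae_clipped(np.full(5, 5.0), np.full(5, 2.0)) == 0.0

    def test_maximal_error_is_hi_bound(self):
        assert mae_clipped(np.zeros(5), np.ones(5)) == 1.0

    def test_identity(self, rng):
        x = rng.uniform(0, 1, 20)
        assert mae_clipped(x, x) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=10), r.normal(size=10)
        assert mae_clipped(a, b) == pytest.approx(mae_clipped(b, a))

    def test_no_valid_positions_raises(self):
        with pytest.raises(ValueError):
            mae_clipped(np.full(3, np.nan), np.ones(3))


class TestMcrmse:
    def test_mean_of_channel_rmses(self):
        pred = np.zeros((4, 2))
        data = np.column_stack([np.full(4, 0.1), np.full(4, 0.3)])
        assert mcrmse(pred, data) == pytest.approx(0.2)

    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        assert mcrmse(x, x) == 0.0

    def test_single_channel_equals_rmse(self, rng):
        p, d = rng.normal(size=(10, 1)), rng.normal(size=(10, 1))
        assert mcrmse(p, d) == pytest.approx(np.sqrt(np.mean((p - d) ** 2)))


class TestEf1:
    def test_perfect_pair_scores(self):
        s = struct("((....))")
        m = PairScoreMatrix(np.ones((8, 8)))
        est = estimate_ef1(m, s)
        assert est.ef1 == pytest.approx(2.25 * 1.0 - 1.29)

    def test_zero_of_the_relation(self):
        s = struct("((....))")
        root = -EF1_SS_COEFFS[1] / EF1_SS_COEFFS[0]
        m = PairScoreMatrix(np.full((8, 8), root))
        assert estimate_ef1(m, s).ef1 == pytest.approx(0.0, abs=1e-12)

    def test_no_crossed_pairs_undefined(self):
        s = struct("((....))")
        est = estimate_ef1(PairScoreMatrix(np.ones((8, 8))), s)
        assert est.ef1_crossed is None

    def test_crossed_relation(self):
        s = struct("((..[[..))..]]")
        est = estimate_ef1(PairScoreMatrix(np.ones((14, 14))), s)
        assert est.ef1_crossed == pytest.approx(2.0 - 1.19, abs=1e-12)

    def test_monotone_in_mean_pair_score(self):
        s = struct("((....))")
        values = [
            estimate_ef1(PairScoreMatrix(np.full((8, 8), v)), s).ef1
            for v in np.linspace(0, 1, 11)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_empty_structure_raises(self):
        with pytest.raises(ValueError):
            estimate_ef1(PairScoreMatrix(np.ones((4, 4))), SecondaryStructure(length=4))


class TestScalingLaw:
    def test_noiseless_recovery(self):
        n = np.array([100, 300, 1000, 3000, 10000, 30000])
        y = 0.1 + 2.0 * n ** -0.5
        fit = fit_scaling_law(n, y)
        assert fit.success
        assert fit.a == pytest.approx(0.1, abs=1e-4)
        assert fit.b == pytest.approx(2.0, abs=1e-3)
        assert fit.c == pytest.approx(0.5, abs=1e-4)

    def test_constant_data(self):
        fit = fit_scaling_law([10, 100, 1000, 10000], [0.2, 0.2, 0.2, 0.2])
        assert fit.success
        assert fit.a == pytest.approx(0.2)

    def test_fitted_curve_monotone_on_decreasing_data(self, rng):
        n = np.array([100, 300, 1000, 3000, 10000])
        y = 0.05 + 1.5 * n ** -0.4 + rng.normal(0, 0.002, size=5)
        fit = fit_scaling_law(n, y)
        grid = fit.a + fit.b * np.linspace(100, 10000, 50) ** -fit.c
        assert all(b <= a + 1e-12 for a, b in zip(grid, grid[1:]))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_scaling_law([1, 2, 3], [1, 2, 3])


def test_mean_by_cluster():
    values = [1.0, 3.0, 10.0, None]
    clusters = ["a", "a", "b", "b"]
    assert mean_by_cluster(values, clusters) == pytest.approx((2.0 + 10.0) / 2)
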