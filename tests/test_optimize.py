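"""NSGA-II components, ASF decision making and control-composition selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecmopt as e
from ecmopt.errors import ConfigError, EmptySelectionError, SpecError
from ecmopt.optimize import (
    ParetoResult,
    asf_values,
    crowding_distance,
    fast_nondominated_sort,
    polynomial_mutation,
    sbx_crossover,
)


def _const_model(gene, beta):
    coef = np.zeros(10)
    coef[: len(beta)] = beta
    return e.GeneResponseModel(gene, e.TERMS, coef, 0.9, 0.0, 23, 0.1)


def _linear_spec(bounds, direction="up"):
    """One objective: predicted expression = coded C."""
    model = _const_model("g", [0.0, 1.0])
    return e.ObjectiveSpec(["g"], [direction], np.array([1.0]), [model], bounds)


class TestObjectiveVector:
    def test_signs_and_order(self, bounds):
        up = _const_model("up", [5.0])
        down = _const_model("down", [2.0])
        spec = e.ObjectiveSpec(
            ["up", "down"], ["up", "down"], np.array([1.0, 1.0]), [up, down], bounds
        )
        vec = e.objective_vector(e.Composition(1.0, 0.2, 0.2), spec)
        assert vec.shape == (2,)
        assert vec[0] == pytest.approx(-5.0)  # maximized gene is negated
        assert vec[1] == pytest.approx(2.0)

    def test_bad_spec_rejected(self, bounds):
        m = _const_model("g", [1.0])
        with pytest.raises(SpecError):
            e.ObjectiveSpec(["g"], ["sideways"], np.array([1.0]), [m], bounds)
        with pytest.raises(SpecError):
            e.ObjectiveSpec(["g"], ["up"], np.array([-1.0]), [m], bounds)


class TestNondominatedSort:
    def test_trivial_fronts(self):
        assert [f.tolist() for f in fast_nondominated_sort([[1.0, 2.0]])] == [[0]]
        fronts = fast_nondominated_sort([[0.0, 0.0], [1.0, 1.0]])
        assert [f.tolist() for f in fronts] == [[0], [1]]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        F = rng.normal(size=(200, 3))
        fronts = fast_nondominated_sort(F)
        # brute-force peeling oracle
        remaining = set(range(200))
        oracle = []
        while remaining:
            level = []
            for i in remaining:
                dominated = False
                for j in remaining:
                    if j != i and all(F[j] <= F[i]) and any(F[j] < F[i]):
                        dominated = True
                        break
                if not dominated:
                    level.append(i)
            oracle.append(sorted(level))
            remaining -= set(level)
        assert [sorted(f.tolist()) for f in fronts] == oracle


class TestCrowding:
    def test_two_point_front_infinite(self):
        assert np.all(np.isinf(crowding_distance([[0.0, 1.0], [1.0, 0.0]])))

    def test_three_point_example(self):
        d = crowding_distance([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx(2.0)  # 1 + 1 after range normalization

    def test_matches_independent_reimplementation(self):
        rng = np.random.default_rng(6)
        F = rng.uniform(size=(15, 3))
        d = crowding_distance(F)
        oracle = np.zeros(15)
        for j in range(3):
            order = np.argsort(F[:, j], kind="stable")
            oracle[order[0]] = oracle[order[-1]] = np.inf
            rng_j = F[order[-1], j] - F[order[0], j]
            for k in range(1, 14):
                oracle[order[k]] += (F[order[k + 1], j] - F[order[k - 1], j]) / rng_j
        assert np.allclose(d, oracle)


class TestVariationOperators:
    def test_sbx_prob_zero_and_identical_parents(self):
        rng = np.random.default_rng(0)
        p1, p2 = np.array([1.0, 0.2, 0.3]), np.array([1.4, 0.3, 0.2])
        c1, c2 = sbx_crossover(p1, p2, prob=0.0, rng=rng)
        assert np.array_equal(c1, p1) and np.array_equal(c2, p2)
        c1, c2 = sbx_crossover(p1, p1, prob=1.0, rng=rng)
        assert np.allclose(c1, p1) and np.allclose(c2, p1)

    def test_sbx_conserves_parent_sum_before_clipping(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p1 = rng.uniform(0, 1, 3)
            p2 = rng.uniform(0, 1, 3)
            c1, c2 = sbx_crossover(p1, p2, prob=1.0, var_prob=1.0, rng=rng)
            assert np.allclose(c1 + c2, p1 + p2, atol=1e-10)

    def test_mutation_prob_zero_identity_and_bounds(self):
        rng = np.random.default_rng(2)
        xl, xu = np.zeros(3), np.ones(3)
        x = np.array([0.5, 0.1, 0.9])
        assert np.array_equal(polynomial_mutation(x, prob=0.0, bounds=(xl, xu), rng=rng), x)
        for _ in range(500):
            y = polynomial_mutation(x, prob=1.0, bounds=(xl, xu), rng=rng)
            assert np.all(y >= xl) and np.all(y <= xu)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_mutation_stays_in_bounds_property(self, seed):
        rng = np.random.default_rng(seed)
        xl = np.array([0.75, 0.15, 0.15])
        xu = np.array([1.5, 0.375, 0.375])
        x = rng.uniform(xl, xu)
        y = polynomial_mutation(x, prob=1.0, bounds=(xl, xu), rng=rng)
        assert np.all(y >= xl) and np.all(y <= xu)


class TestNsga2:
    def test_single_objective_reaches_box_optimum(self, bounds):
        spec = _linear_spec(bounds, "up")  # maximize coded C -> C at upper bound
        res = e.optimize_composition(spec, pop_size=52, n_gen=50, seed=3)
        assert res.asf_solution.c >= bounds[0].high - 0.01 * (bounds[0].high - bounds[0].low)

    def test_conflicting_objectives_span_range(self, bounds):
        up = _const_model("a", [0.0, 1.0])
        down = _const_model("b", [0.0, 1.0])
        spec = e.ObjectiveSpec(
            ["a", "b"], ["up", "down"], np.array([1.0, 1.0]), [up, down], bounds
        )
        res = e.optimize_composition(spec, pop_size=100, n_gen=60, seed=4)
        c_span = res.X[:, 0].max() - res.X[:, 0].min()
        assert c_span > 0.9 * (bounds[0].high - bounds[0].low)
        # mutual non-dominance of the returned set
        F = res.F
        for i in range(len(F)):
            for j in range(len(F)):
                if i != j:
                    assert not (np.all(F[j] <= F[i]) and np.any(F[j] < F[i]))

    def test_seeded_determinism(self, bounds):
        spec = _linear_spec(bounds)
        a = e.optimize_composition(spec, pop_size=20, n_gen=10, seed=9)
        b = e.optimize_composition(spec, pop_size=20, n_gen=10, seed=9)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.F, b.F)
        assert a.asf_index == b.asf_index

    def test_bad_population_size(self, bounds):
        spec = _linear_spec(bounds)
        with pytest.raises(ConfigError):
            e.nsga2(spec.evaluate, [0.75, 0.15, 0.15], [1.5, 0.375, 0.375], pop_size=7)


class TestIdealNadir:
    def test_min_max_and_degenerate_guard(self):
        ideal, nadir = e.estimate_ideal_nadir([[0.0, 1.0], [1.0, 0.0]])
        assert np.allclose(ideal, [0, 0]) and np.allclose(nadir, [1, 1])
        with pytest.warns(RuntimeWarning):
            ideal, nadir = e.estimate_ideal_nadir([[0.5, 0.5]])
        assert np.all(nadir > ideal)

    def test_random_matches_min_max(self):
        rng = np.random.default_rng(10)
        F = rng.normal(size=(30, 4))
        ideal, nadir = e.estimate_ideal_nadir(F)
        assert np.allclose(ideal, F.min(axis=0))
        assert np.allclose(nadir, F.max(axis=0))


class TestAsf:
    def test_single_objective_returns_front_minimum(self):
        F = np.array([[3.0], [1.0], [2.0]])
        ideal, nadir = e.estimate_ideal_nadir(F)
        assert e.asf_select(F, ideal, nadir, np.array([1.0])) == 1

    def test_symmetric_front_picks_knee(self):
        F = np.array([[0.0, 1.0], [0.5, 0.5], [1.0, 0.0]])
        idx = e.asf_select(F, np.zeros(2), np.ones(2), np.array([1.0, 1.0]))
        assert idx == 1

    def test_matches_brute_force_scalarization(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            F = rng.uniform(size=(25, 3))
            w = rng.uniform(0.1, 1.0, 3)
            ideal, nadir = e.estimate_ideal_nadir(F)
            idx = e.asf_select(F, ideal, nadir, w)
            wt = w / w.sum()
            vals = []
            for f in F:
                d = (f - ideal) / (nadir - ideal)
                vals.append(max(wt * d) + 1e-6 * d.sum())
            assert idx == int(np.argmin(vals))
            # the selected value is minimal over the front
            assert vals[idx] <= min(vals) + 1e-15

    def test_weight_mismatch_rejected(self):
        with pytest.raises(SpecError):
            asf_values(np.ones((3, 2)), np.zeros(2), np.ones(2), np.array([1.0]))


class TestChebyshev:
    def test_zero_and_unit_distances(self):
        ideal, nadir = np.zeros(2), np.ones(2)
        assert e.chebyshev_distance([0.3, 0.4], [0.3, 0.4], ideal, nadir) == 0.0
        assert e.chebyshev_distance(nadir, ideal, ideal, nadir) == 1.0

    def test_matches_max_abs_oracle(self):
        rng = np.random.default_rng(12)
        ideal = rng.normal(size=4)
        nadir = ideal + rng.uniform(0.5, 2.0, 4)
        f, g = rng.normal(size=4), rng.normal(size=4)
        expected = max(abs((f - g) / (nadir - ideal)))
        assert e.chebyshev_distance(f, g, ideal, nadir) == pytest.approx(expected)


class TestSelectControl:
    def _result_from_front(self, X, F, weights):
        ideal, nadir = e.estimate_ideal_nadir(F)
        idx = e.asf_select(F, ideal, nadir, weights)
        return ParetoResult(
            X=X, F=F, ideal=ideal, nadir=nadir, asf_index=idx,
            asf_weights=weights, seed=0, n_gen=1, pop_size=4,
        )

    def test_only_asf_solution_in_pool_raises(self, bounds):
        spec = _linear_spec(bounds)
        res = e.optimize_composition(spec, pop_size=20, n_gen=20, seed=13)
        sol = res.X[res.asf_index][None, :]
        with pytest.raises(EmptySelectionError):
            e.select_control(res, spec, cheb_range=(0.2, 0.6), candidates=sol)

    def test_matches_filter_then_argmax_oracle(self, fitted_small_spec):
        spec, _ = fitted_small_spec
        res = e.optimize_composition(spec, pop_size=60, n_gen=60, seed=14)
        rng = np.random.default_rng(15)
        cands = np.column_stack(
            [rng.uniform(fb.low, fb.high, 300) for fb in spec.bounds]
        )
        control, info = e.select_control(
            res, spec, front_gap_max=0.25, cheb_range=(0.05, 0.9), candidates=cands
        )
        Fc = spec.evaluate(cands)
        gaps = asf_values(Fc, res.ideal, res.nadir, res.asf_weights) - asf_values(
            res.F, res.ideal, res.nadir, res.asf_weights
        ).min()
        cheb = np.array(
            [e.chebyshev_distance(f, res.F[res.asf_index], res.ideal, res.nadir) for f in Fc]
        )
        ok = (gaps <= 0.25) & (cheb >= 0.05) & (cheb <= 0.9)
        assert ok.any()
        best = np.flatnonzero(ok)[np.argmax(cheb[ok])]
        assert np.allclose(control.as_array(), cands[best])
        assert info["chebyshev"] == pytest.approx(cheb[best])

    def test_paper_configuration_constraints_verified(self, fitted_small_spec):
        """Gap <= 12%, Chebyshev in [20%, 60%]: the study's control recipe."""
        spec, _ = fitted_small_spec
        res = e.optimize_composition(spec, pop_size=100, n_gen=100, seed=16)
        control, info = e.select_control(
            res, spec, front_gap_max=0.12, cheb_range=(0.2, 0.6), seed=17
        )
        f = spec.evaluate(control.as_array()[None, :])
        gap = (
            asf_values(f, res.ideal, res.nadir, res.asf_weights)[0]
            - asf_values(res.F, res.ideal, res.nadir, res.asf_weights).min()
        )
        assert gap <= 0.12 + 1e-9
        cheb = e.chebyshev_distance(f[0], res.F[res.asf_index], res.ideal, res.nadir)
        assert 0.2 - 1e-9 <= cheb <= 0.6 + 1e-9
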