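"""Multi-rate Brownian likelihood, model set, AICc machinery."""

import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from conftest import cherry_tree, random_yule_map, single_state_map
from habitatrates import rate_models as rm
from habitatrates import synthetic_data as sd
from habitatrates.tree_model import HABITAT_STATES, StochasticMap


class TestModelSet:
    def test_ten_models(self):
        assert len(rm.build_model_set()) == 10

    def test_parameter_counts(self):
        models = {m.name: m for m in rm.build_model_set()}
        assert models["1-rate no effect"].k == 2
        assert models["4-rate full"].k == 5
        assert models["3-rate shared incline effect"].k == 4
        assert models["2-rate incline-ground"].k == 3

    def test_partitions_total_and_surjective(self):
        for m in rm.build_model_set():
            assert set(m.states) == set(HABITAT_STATES)
            classes = {m.class_of(s) for s in HABITAT_STATES}
            assert classes == set(range(m.n_classes))

    def test_named_partitions(self):
        models = {m.name: m.mapping for m in rm.build_model_set()}
        ig = models["2-rate incline-ground"]
        assert ig["rock"] == ig["arboreal"]
        assert ig["terrestrial"] == ig["semiarboreal"]
        assert ig["rock"] != ig["terrestrial"]
        tree_eff = models["3-rate shared tree effect"]
        assert tree_eff["semiarboreal"] == tree_eff["arboreal"]


class TestExpectedVcv:
    def test_single_rate_reduces_to_tree_covariance(self):
        tree, smap, _ = random_yule_map(12, seed=60)
        one = rm.build_model_set()[-1]
        V = rm.expected_vcv(smap, one, [2.5])
        assert V == pytest.approx(2.5 * tree.vcv(), abs=1e-9)

    def test_two_tip_star_diagonal(self):
        t = cherry_tree()
        segs = [[("rock", 1.0)], [("arboreal", 1.0)], []]
        smap = StochasticMap(t, segs)
        model = rm.RateModelSpec.from_mapping(
            "ab", {"rock": 0, "arboreal": 1, "terrestrial": 0, "semiarboreal": 1}
        )
        V = rm.expected_vcv(smap, model, [3.0, 7.0], sampling_vars=[0.5, 0.25])
        assert V == pytest.approx(np.diag([3.5, 7.25]))

    def test_simulated_trait_covariance_matches(self):
        """50,000 Brownian replicates on a fixed 10-tip map vs V entrywise."""
        _, smap, _ = random_yule_map(10, seed=61)
        model = rm.build_model_set()[0]
        rates = [1.0, 5.0, 25.0, 125.0]
        sims = sd.simulate_multirate_bm(smap, model, rates, root=0.0, seed=62, n_reps=50_000)
        X = sims.to_numpy().T  # reps × tips
        V = rm.expected_vcv(smap, model, rates)
        emp = (X.T @ X) / len(X)  # known zero mean
        # MC standard error of a covariance entry ~ sqrt((Vii*Vjj + Vij^2)/n);
        # the bound is simultaneous over 55 unique entries, so use 4 SE
        # (Bonferroni-level for ~55 comparisons) rather than a marginal 3 SE
        se = np.sqrt((np.outer(np.diag(V), np.diag(V)) + V**2) / len(X))
        assert np.all(np.abs(emp - V) <= 4 * se)


class TestBmLoglik:
    def test_two_tip_closed_form(self):
        smap = single_state_map(cherry_tree())
        one = rm.build_model_set()[-1]
        ll = rm.bm_loglik(smap, one, [1.0], root=1.0, traits={"A": 0.0, "B": 2.0})
        assert ll == pytest.approx(-0.5 * (2.0 + 0.0 + 2.0 * math.log(2 * math.pi)), abs=1e-6)
        # GLS-profiled root equals the midpoint here
        ll_prof, mu = None, None
        from habitatrates.rate_models import BMLikelihood

        lik = BMLikelihood(smap, {"A": 0.0, "B": 2.0})
        ll_prof, mu = lik.profile_loglik(one, [1.0])
        assert mu == pytest.approx(1.0, abs=1e-6)
        assert ll_prof == pytest.approx(ll, abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 16))
        _, smap, _ = random_yule_map(n, seed=200 + seed)
        model = rng.choice(rm.build_model_set())
        rates = rng.uniform(0.1, 10.0, size=model.n_classes)
        sv = rng.uniform(0.0, 0.5, size=n)
        x = rng.normal(size=n)
        root = float(rng.normal())
        ll = rm.bm_loglik(smap, model, rates, root, x, sv)
        V = rm.expected_vcv(smap, model, rates, sv)
        ref = multivariate_normal(mean=np.full(n, root), cov=V).logpdf(x)
        assert ll == pytest.approx(ref, abs=1e-6)

    def test_equal_rates_collapse_to_one_rate(self):
        _, smap, _ = random_yule_map(9, seed=63)
        x = np.arange(9, dtype=float)
        full = rm.build_model_set()[0]
        one = rm.build_model_set()[-1]
        ll4 = rm.bm_loglik(smap, full, [3.0] * 4, None, x)
        ll1 = rm.bm_loglik(smap, one, [3.0], None, x)
        assert ll4 == pytest.approx(ll1, abs=1e-9)


class TestFitModel:
    def test_nesting_monotonicity(self):
        _, smap, _ = random_yule_map(20, seed=64)
        one = rm.build_model_set()[-1]
        x = sd.simulate_multirate_bm(smap, one, [4.0], seed=65)["rep0"]
        fits = {
            m.name: rm.fit_model(smap, m, x) for m in rm.build_model_set()
        }
        ll1 = fits["1-rate no effect"].loglik
        for name, f in fits.items():
            assert f.loglik >= ll1 - 1e-6, name

    def test_matches_grid_search_two_classes(self):
        _, smap, _ = random_yule_map(8, seed=66)
        model = rm.build_model_set()[8]  # 2-rate incline-ground
        x = sd.simulate_multirate_bm(smap, model, [0.5, 8.0], seed=67)["rep0"]
        fit = rm.fit_model(smap, model, x)
        from habitatrates.rate_models import BMLikelihood

        lik = BMLikelihood(smap, x)
        grid = np.logspace(-4, 3, 200)
        best = -np.inf
        for a in grid:
            for b in grid:
                ll, _ = lik.profile_loglik(model, [a, b])
                best = max(best, ll)
        assert fit.loglik >= best - 0.01

    def test_large_measurement_error_degrades_likelihood(self):
        """Once the variance floor dominates the data scale, inflating it
        further monotonically degrades the fitted likelihood.  (A *small*
        floor can improve the fit when the realized data look overdispersed
        relative to the tree covariance, so no claim is made near zero.)"""
        _, smap, _ = random_yule_map(15, seed=68)
        one = rm.build_model_set()[-1]
        x = sd.simulate_multirate_bm(smap, one, [2.0], seed=69)["rep0"]
        lls = []
        for floor in [0.5, 2.0, 10.0, 50.0, 200.0]:
            f = rm.fit_model(smap, one, x, sampling_vars=np.full(15, floor))
            lls.append(f.loglik)
        assert all(a >= b - 1e-8 for a, b in zip(lls, lls[1:]))
        f0 = rm.fit_model(smap, one, x)
        assert f0.loglik > lls[-1]


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "lnl,k,expected",
        [(-203.45, 5, 417.61), (-74.73, 3, 155.74), (-55.32, 2, 114.78)],
    )
    def test_aicc_arithmetic(self, lnl, k, expected):
        assert rm.aicc(lnl, k, 90) == pytest.approx(expected, abs=0.01)

    def test_aicc_needs_enough_observations(self):
        with pytest.raises(ValueError):
            rm.aicc(-10.0, 5, 6)

    def test_correction_vanishes_for_large_n(self):
        assert rm.aicc(-10.0, 5, 10**5) - (2 * 5 + 20.0) < 1e-3

    def test_equal_aicc_gives_uniform_weights(self):
        w = rm.akaike_weights([100.0] * 10)
        assert w == pytest.approx(np.full(10, 0.1))

    def test_single_model_weight_is_one(self):
        assert rm.akaike_weights([42.0]) == pytest.approx([1.0])

    def test_weights_shift_invariant(self):
        a = np.array([10.0, 12.0, 15.0])
        assert rm.akaike_weights(a) == pytest.approx(rm.akaike_weights(a + 100.0))


class TestModelAveraging:
    def _fits(self, smap, x):
        models = rm.build_model_set()
        return [rm.fit_model(smap, m, x) for m in models]

    def test_degenerate_weight_selects_first_model(self):
        _, smap, _ = random_yule_map(8, seed=70)
        x = np.arange(8, dtype=float)
        fits = self._fits(smap, x)
        w = np.zeros(len(fits))
        w[0] = 1.0
        avg = rm.model_average_rates(fits, w)
        for s in HABITAT_STATES:
            assert avg[s] == pytest.approx(fits[0].rate_for(s))

    def test_constant_rates_average_to_constant(self):
        _, smap, _ = random_yule_map(8, seed=70)
        fits = self._fits(smap, np.arange(8, dtype=float))
        for f in fits:
            f.rates = np.full_like(f.rates, 3.0)
        w = np.full(len(fits), 1.0 / len(fits))
        avg = rm.model_average_rates(fits, w)
        assert avg.to_numpy() == pytest.approx(np.full(4, 3.0))

    def test_hand_arithmetic_two_models(self):
        _, smap, _ = random_yule_map(8, seed=70)
        fits = self._fits(smap, np.arange(8, dtype=float))[:2]
        full, three = fits
        for f, terr_rate in ((full, 4.0), (three, 8.0)):
            r = np.ones(f.model.n_classes)
            r[f.model.class_of("terrestrial")] = terr_rate
            f.rates = r
        avg = rm.model_average_rates(fits, [0.25, 0.75])
        assert avg["terrestrial"] == pytest.approx(0.25 * 4.0 + 0.75 * 8.0)

    def test_mismatched_lengths_error(self):
        _, smap, _ = random_yule_map(8, seed=70)
        fits = self._fits(smap, np.arange(8, dtype=float))
        with pytest.raises(ValueError, match="weights"):
            rm.model_average_rates(fits, [0.5, 0.5])
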