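"""Model fitting: parameter recovery, optimality, constraints, and
profile-likelihood confidence intervals."""

import numpy as np
import pytest
from scipy.stats import chi2

import twinlag as tl


class TestUnivariateFit:
    def test_null_heritability_recovery(self):
        """Pure-E data yields near-zero a² and c² and e² near one."""
        p = tl.AceParams(0.0, 0.0, 1.0)
        data = tl.simulate_univariate(
            p, tl.SimDesign(n_mz=5000, n_dz=5000, seed=11), var_name="x")
        res = tl.UnivariateACE(data, "x").fit(seed=1)
        s = res.standardized()
        assert s["share_a"] == pytest.approx(0.0, abs=0.03)
        assert s["share_c"] == pytest.approx(0.0, abs=0.03)
        assert s["share_e"] == pytest.approx(1.0, abs=0.03)

    def test_depression_component_recovery(self, dep_ace):
        data = tl.simulate_univariate(
            dep_ace, tl.SimDesign(n_mz=5000, n_dz=5000, seed=13))
        res = tl.UnivariateACE(data, "depression").fit(seed=1)
        s = res.standardized()
        assert s["share_a"] == pytest.approx(0.26, abs=0.04)
        assert s["share_c"] == pytest.approx(0.14, abs=0.04)
        assert s["share_e"] == pytest.approx(0.60, abs=0.04)

    def test_optimum_beats_generating_truth(self, univariate_fit):
        """-2lnL at the generating values is never below the optimum."""
        data, model, res = univariate_fit
        truth = {"a": np.sqrt(0.26), "c": np.sqrt(0.14), "e": np.sqrt(0.60),
                 "mu": 0.0}
        assert model.minus2ll(truth) >= res.minus2ll - 1e-6

    def test_unbiased_over_replicates(self, dep_ace):
        """Mean estimates across replicate simulations sit within
        Monte-Carlo error of the generating shares."""
        estimates = []
        for rep in range(30):
            data = tl.simulate_univariate(
                dep_ace, tl.SimDesign(n_mz=1000, n_dz=1000, seed=500 + rep))
            s = tl.UnivariateACE(data, "depression").fit(
                seed=1, n_restarts=1).standardized()
            estimates.append([s["share_a"], s["share_c"], s["share_e"]])
        est = np.array(estimates)
        mean = est.mean(axis=0)
        sem = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        truth = np.array([0.26, 0.14, 0.60])
        assert np.all(np.abs(mean - truth) <= 3.5 * sem + 0.005)


@pytest.fixture(scope="module")
def fitted(paranoia_bivariate):
    p1, p2, lat = paranoia_bivariate
    data = tl.simulate_bivariate(
        p1, p2, lat, tl.SimDesign(n_mz=4000, n_dz=4000, seed=17))
    model = tl.BivariateACE(data, ("depression", "paranoia"))
    return model, model.fit(seed=1, n_restarts=3)


class TestBivariateFit:
    def test_latent_correlation_recovery(self, fitted):
        _, res = fitted
        s = res.standardized()
        assert s["rA"] == pytest.approx(0.78, abs=0.08)
        assert s["rE"] == pytest.approx(0.40, abs=0.08)
        assert s["r_ph"] == pytest.approx(0.53, abs=0.03)

    def test_decomposition_matches_implied_matrix(self, fitted):
        """Two independent code paths: closed-form decomposition versus the
        cross-trait entry of the implied covariance matrix."""
        model, res = fitted
        dec = model.decomposition(res.params)
        mu, sigma, _ = model.implied(model.full_vector(res.params))
        r_implied = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert dec.r_ph == pytest.approx(r_implied, abs=1e-8)

    def test_fixing_parameter_constraint(self, fitted):
        model, res = fitted
        fixed = model.clone(extra_constraints={"rC": 0.45})
        r2 = fixed.fit(seed=1, n_restarts=1)
        assert r2.params["rC"] == pytest.approx(0.45, abs=1e-9)
        assert r2.n_params == res.n_params - 1
        assert r2.minus2ll >= res.minus2ll - 1e-6


class TestCrossLagFit:
    def test_path_recovery_with_attrition(self, cogdis_crosslag):
        data = tl.simulate_twin_pairs(
            cogdis_crosslag,
            tl.SimDesign(n_mz=3300, n_dz=4700, t2_retention=0.31, seed=19),
            var_names=("depression", "cognitive_disorganization"))
        model = tl.CrossLagACE(data,
                               ("depression", "cognitive_disorganization"))
        res = model.fit(seed=1, n_restarts=3)
        s = res.standardized()
        assert s["b11"] == pytest.approx(0.48, abs=0.04)
        assert s["b22"] == pytest.approx(0.63, abs=0.04)
        assert s["b12"] == pytest.approx(0.11, abs=0.04)
        assert s["b21"] == pytest.approx(0.20, abs=0.04)
        assert s["rA_t1"] == pytest.approx(0.78, abs=0.10)

    def test_equality_constraint_binds(self, small_crosslag_data):
        model = tl.CrossLagACE(small_crosslag_data,
                               ("depression", "paranoia"),
                               constraints={"b21": "b12"})
        res = model.fit(seed=1, n_restarts=1)
        assert res.params["b21"] == pytest.approx(res.params["b12"], abs=1e-12)


class TestProfileCI:
    def test_defining_property_and_containment(self, univariate_fit):
        """-2lnL at each CI endpoint equals the minimum + 3.84, and the
        interval contains the point estimate."""
        data, model, res = univariate_fit
        ci = res.profile_ci("a", level=0.95)
        assert ci.lower <= res.params["a"] <= ci.upper
        crit = chi2.ppf(0.95, 1)
        for endpoint in (ci.lower, ci.upper):
            sub = model.clone(extra_constraints={"a": endpoint})
            start = sub.free_from_params({**res.params, "a": endpoint})
            prof = sub.fit(start=start, n_restarts=1).minus2ll
            assert prof - res.minus2ll == pytest.approx(crit, abs=1e-4)

    def test_quadratic_limit_matches_wald(self, univariate_fit):
        """With the covariance fixed, the likelihood in mu is exactly
        quadratic, so profile and Wald intervals coincide."""
        data, model, res = univariate_fit
        sub = model.clone(extra_constraints={k: res.params[k]
                                             for k in ("a", "c", "e")})
        r2 = sub.fit(start=sub.free_from_params(res.params), n_restarts=1)
        ci = r2.profile_ci("mu")
        lo, hi = r2.wald_ci("mu")
        assert ci.lower == pytest.approx(lo, abs=1e-3)
        assert ci.upper == pytest.approx(hi, abs=1e-3)

    def test_correlation_ci_respects_bounds(self, paranoia_bivariate):
        p1, p2, lat = paranoia_bivariate
        data = tl.simulate_bivariate(
            p1, p2, lat, tl.SimDesign(n_mz=600, n_dz=600, seed=23))
        res = tl.BivariateACE(data, ("depression", "paranoia")).fit(
            seed=1, n_restarts=1)
        ci = res.profile_ci("rA")
        assert -1.0 <= ci.lower <= ci.upper <= 1.0


class TestDiagnostics:
    def test_results_bookkeeping(self, univariate_fit):
        data, model, res = univariate_fit
        assert res.n_pairs == 4000
        assert res.n_observations == 8000
        assert res.n_params == 4
        assert res.converged
        assert np.isfinite(res.minus2ll)
        assert "share_a" in res.summary()

    def test_summary_includes_ci_after_profiling(self, univariate_fit):
        _, _, res = univariate_fit
        res.profile_ci("c")
        assert "[" in res.summary()
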