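"""Implied-moment construction: analytic examples, twin-sharing rules,
and Monte-Carlo agreement with the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinlag as tl
from twinlag.moments import NonPsdError, implied_moments_crosslag
from twinlag.params import AceParams, CrossLagParams, LatentCorrelations


class TestUnivariate:
    @pytest.mark.parametrize(
        "a2,c2,e2,zyg,expected_cross",
        [
            (0.0, 0.0, 1.0, "MZ", 0.0),      # no familial resemblance
            (0.0, 0.0, 1.0, "DZ", 0.0),
            (1.0, 0.0, 0.0, "MZ", 1.0),      # pure additive genetics
            (1.0, 0.0, 0.0, "DZ", 0.5),
            (0.26, 0.14, 0.60, "MZ", 0.40),  # a2+c2
            (0.26, 0.14, 0.60, "DZ", 0.27),  # a2/2+c2
        ],
    )
    def test_cross_twin_covariance(self, a2, c2, e2, zyg, expected_cross):
        p = AceParams(np.sqrt(a2), np.sqrt(c2), np.sqrt(e2))
        mu, sigma = tl.implied_moments_univariate(p, zyg)
        assert sigma[0, 0] == pytest.approx(a2 + c2 + e2)
        assert sigma[0, 1] == pytest.approx(expected_cross, abs=1e-12)
        assert np.allclose(sigma, sigma.T)

    def test_identity_when_e_only(self):
        p = AceParams(0.0, 0.0, 1.0)
        _, sigma = tl.implied_moments_univariate(p, "MZ")
        assert np.allclose(sigma, np.eye(2))

    def test_rejects_nonfinite_parameters(self):
        with pytest.raises(ValueError):
            AceParams(np.nan, 0.5, 0.5)
        with pytest.raises(ValueError):
            tl.implied_moments_univariate(AceParams(0.5, 0.5, 0.5), "XX")


def _paths(shares):
    return AceParams.from_shares(*shares)


class TestPathTracingIdentity:
    @given(
        s1=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        s2=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        ra=st.floats(-0.95, 0.95), rc=st.floats(-0.95, 0.95),
        re=st.floats(-0.95, 0.95),
    )
    def test_within_person_cross_trait_correlation(self, s1, s2, ra, rc, re):
        """Matrix construction equals rA·a1·a2 + rC·c1·c2 + rE·e1·e2."""
        p1, p2 = _paths(s1), _paths(s2)
        lat = LatentCorrelations(ra, rc, re)
        _, sigma = tl.implied_moments_bivariate(p1, p2, lat, "MZ")
        closed = ra * p1.a * p2.a + rc * p1.c * p2.c + re * p1.e * p2.e
        assert sigma[0, 1] == pytest.approx(closed, abs=1e-12)
        # unit variances under the standardized parameterization
        assert sigma[0, 0] == pytest.approx(1.0)

    @given(
        s1=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        s2=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        ra=st.floats(-0.9, 0.9), rc=st.floats(-0.9, 0.9),
        re=st.floats(-0.9, 0.9),
    )
    def test_mz_dz_difference_is_half_the_genetic_part(self, s1, s2, ra, rc, re):
        """Switching MZ→DZ halves exactly the A-derived cross-twin entries."""
        p1, p2 = _paths(s1), _paths(s2)
        lat = LatentCorrelations(ra, rc, re)
        _, smz = tl.implied_moments_bivariate(p1, p2, lat, "MZ")
        _, sdz = tl.implied_moments_bivariate(p1, p2, lat, "DZ")
        # A-only model isolates the genetic portion
        a1 = AceParams(p1.a, 0.0, 0.0)
        a2 = AceParams(p2.a, 0.0, 0.0)
        _, amz = tl.implied_moments_bivariate(a1, a2, lat, "MZ")
        _, adz = tl.implied_moments_bivariate(a1, a2, lat, "DZ")
        diff = smz - sdz
        assert np.allclose(diff[:2, :2], 0.0, atol=1e-12)  # within-twin equal
        assert np.allclose(diff, amz - adz, atol=1e-12)
        # DZ genetic cross-twin block is exactly half the MZ one
        assert np.allclose(adz[:2, 2:], 0.5 * amz[:2, 2:], atol=1e-12)


class TestCrossLag:
    def test_decoupled_waves(self):
        """All b's zero + residual params equal to time-1 params → the
        time-2 block replicates time 1 and cross-wave blocks vanish."""
        p1 = AceParams.from_shares(0.3, 0.2, 0.5)
        p2 = AceParams.from_shares(0.5, 0.1, 0.4)
        lat = LatentCorrelations(0.7, 0.4, 0.3)
        p = CrossLagParams(p1, p2, lat, 0, 0, 0, 0, p1, p2, lat)
        for zyg in ("MZ", "DZ"):
            _, sigma = implied_moments_crosslag(p, zyg)
            _, biv = tl.implied_moments_bivariate(p1, p2, lat, zyg)
            t1_idx = [0, 1, 4, 5]
            t2_idx = [2, 3, 6, 7]
            assert np.allclose(sigma[np.ix_(t1_idx, t1_idx)], biv)
            assert np.allclose(sigma[np.ix_(t2_idx, t2_idx)], biv)
            assert np.allclose(sigma[np.ix_(t1_idx, t2_idx)], 0.0)

    def test_identity_transmission(self):
        """b11=1 with zero var1 residual duplicates var1 across waves."""
        p1 = AceParams.from_shares(0.3, 0.2, 0.5)
        p2 = AceParams.from_shares(0.5, 0.1, 0.4)
        lat = LatentCorrelations(0.5, 0.5, 0.2)
        res1 = AceParams(0.0, 0.0, 0.0)
        res2 = AceParams.from_shares(0.4, 0.2, 0.4)
        zero = LatentCorrelations(0.0, 0.0, 0.0)
        p = CrossLagParams(p1, p2, lat, b11=1.0, b12=0.0, b21=0.0, b22=0.0,
                           var1_res_t2=res1, var2_res_t2=res2,
                           latcorr_res_t2=zero)
        _, sigma = implied_moments_crosslag(p, "MZ")
        # var1_t2 (index 2) is an exact copy of var1_t1 (index 0)
        assert sigma[0, 2] == pytest.approx(1.0)
        assert sigma[2, 2] == pytest.approx(1.0)

    def test_symmetry_and_psd(self, paranoia_crosslag):
        for zyg in ("MZ", "DZ"):
            _, sigma = implied_moments_crosslag(paranoia_crosslag, zyg)
            assert np.allclose(sigma, sigma.T)
            assert np.linalg.eigvalsh(sigma).min() > -1e-10

    def test_non_psd_rejected_with_eigenvalue(self):
        # a latent correlation outside [-1, 1] breaks PSD-ness; smuggle one
        # past the container validation to exercise the matrix-level check
        lat = object.__new__(LatentCorrelations)
        for k, v in {"ra": 1.8, "rc": 0.0, "re": 0.0}.items():
            object.__setattr__(lat, k, v)
        p1 = AceParams.from_shares(0.6, 0.2, 0.2)
        zero = LatentCorrelations(0.0, 0.0, 0.0)
        bad = CrossLagParams(p1, p1, lat, 0, 0, 0, 0, p1, p1, zero)
        with pytest.raises(NonPsdError) as exc:
            implied_moments_crosslag(bad, "MZ")
        assert exc.value.min_eigenvalue < 0
        assert "eigenvalue" in str(exc.value)


class TestMonteCarloOracle:
    def test_crosslag_moments_match_simulation(self, paranoia_crosslag):
        """Every implied matrix entry sits within 3 Monte-Carlo SEs of the
        sample covariance of a large simulated sample."""
        n = 250_000
        design = tl.SimDesign(n_mz=n, n_dz=n, t2_retention=1.0, seed=123)
        data = tl.simulate_twin_pairs(paranoia_crosslag, design)
        groups = data.split_zygosity(data.variables)
        for zyg, y in groups.items():
            mu, sigma = implied_moments_crosslag(paranoia_crosslag, zyg)
            centered = y - y.mean(axis=0)
            sample = centered.T @ centered / len(y)
            # MC standard error of each covariance entry
            prod = centered[:, :, None] * centered[:, None, :]
            se = prod.std(axis=0) / np.sqrt(len(y))
            assert np.all(np.abs(sample - sigma) <= 3.0 * se + 1e-12), zyg
            assert np.allclose(y.mean(axis=0), mu, atol=4.0 / np.sqrt(n))

    @settings(max_examples=5)
    @given(
        ra=st.floats(-0.8, 0.8), rc=st.floats(-0.8, 0.8),
        re=st.floats(-0.8, 0.8),
        b11=st.floats(-0.4, 0.6), b22=st.floats(-0.4, 0.6),
        b12=st.floats(-0.2, 0.2), b21=st.floats(-0.2, 0.2),
    )
    def test_randomized_parameters_match_simulation(self, ra, rc, re,
                                                    b11, b22, b12, b21):
        lat = LatentCorrelations(ra, rc, re)
        try:
            p = tl.standardized_crosslag((0.3, 0.2, 0.5), (0.5, 0.1, 0.4),
                                         lat, b11=b11, b22=b22, b12=b12,
                                         b21=b21)
        except ValueError:
            return  # paths transmit more than unit variance: invalid design
        n = 40_000
        data = tl.simulate_twin_pairs(
            p, tl.SimDesign(n_mz=n, n_dz=0, t2_retention=1.0, seed=7))
        y = data.split_zygosity(data.variables)["MZ"]
        mu, sigma = implied_moments_crosslag(p, "MZ")
        centered = y - y.mean(axis=0)
        sample = centered.T @ centered / n
        prod = centered[:, :, None] * centered[:, None, :]
        se = prod.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(sample - sigma) <= 4.0 * se + 1e-12)
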