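"""Derived estimands: decomposition of phenotypic correlations, time-2
total-variance shares, continuity variance explained."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import twinlag as tl
from twinlag.estimands import (bivariate_decomposition,
                               continuity_variance_explained,
                               time2_total_decomposition)
from twinlag.params import AceParams, CrossLagParams, LatentCorrelations


class TestBivariateDecomposition:
    def test_independence_flagged_undefined(self):
        p = AceParams.from_shares(0.3, 0.2, 0.5)
        rep = bivariate_decomposition(p, p, LatentCorrelations(0, 0, 0))
        assert rep.r_ph == 0.0
        assert not rep.defined
        assert np.isnan(rep.prop_a)

    def test_perfect_genetic_overlap(self):
        p = AceParams(1.0, 0.0, 0.0)
        rep = bivariate_decomposition(p, p, LatentCorrelations(1.0, 0, 0))
        assert rep.r_ph == pytest.approx(1.0)
        assert rep.prop_a == pytest.approx(1.0)

    def test_depression_paranoia_decomposition(self, paranoia_bivariate):
        """The preset generating values split the .53 correlation into
        source shares of .53 (A), .11 (C) and .36 (E)."""
        p1, p2, lat = paranoia_bivariate
        rep = bivariate_decomposition(p1, p2, lat)
        # source-specific covariance products behind the split
        assert lat.ra * p1.a * p2.a == pytest.approx(0.281, abs=0.001)
        assert lat.rc * p1.c * p2.c == pytest.approx(0.058, abs=0.001)
        assert lat.re * p1.e * p2.e == pytest.approx(0.191, abs=0.001)
        assert rep.r_ph == pytest.approx(0.53, abs=0.005)
        assert rep.prop_a == pytest.approx(0.53, abs=0.005)
        assert rep.prop_c == pytest.approx(0.11, abs=0.005)
        assert rep.prop_e == pytest.approx(0.36, abs=0.005)

    @given(
        s1=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        s2=st.tuples(*[st.floats(0.05, 1.0)] * 3),
        ra=st.floats(-0.9, 0.9), rc=st.floats(-0.9, 0.9),
        re=st.floats(0.05, 0.9),
    )
    def test_proportions_sum_to_one(self, s1, s2, ra, rc, re):
        p1 = AceParams.from_shares(*s1)
        p2 = AceParams.from_shares(*s2)
        rep = bivariate_decomposition(p1, p2, LatentCorrelations(ra, rc, re))
        if rep.defined:
            assert rep.prop_a + rep.prop_c + rep.prop_e == pytest.approx(
                1.0, abs=1e-8)


class TestTime2TotalDecomposition:
    def test_no_transmission_equals_residual_shares(self):
        p1 = AceParams.from_shares(0.3, 0.2, 0.5)
        p2 = AceParams.from_shares(0.5, 0.1, 0.4)
        lat = LatentCorrelations(0.6, 0.4, 0.2)
        res1 = AceParams.from_shares(0.4, 0.25, 0.35)
        res2 = AceParams.from_shares(0.2, 0.3, 0.5)
        p = CrossLagParams(p1, p2, lat, 0, 0, 0, 0, res1, res2, lat)
        rep = time2_total_decomposition(p)
        assert rep.share_a[0] == pytest.approx(0.4, abs=1e-10)
        assert rep.share_c[1] == pytest.approx(0.3, abs=1e-10)
        assert rep.total_corrs.ra == pytest.approx(0.6, abs=1e-10)

    def test_matches_component_simulation(self, paranoia_crosslag):
        """Monte-Carlo oracle with exposed latents: simulate the A/C/E
        streams separately and measure their time-2 variances."""
        p = paranoia_crosslag
        rng = np.random.default_rng(2024)
        n = 400_000
        B = np.array([[p.b11, p.b21], [p.b12, p.b22]])

        def corr_pair(r):
            z1 = rng.standard_normal(n)
            z2 = r * z1 + np.sqrt(1 - r * r) * rng.standard_normal(n)
            return z1, z2

        comps_t2 = {}
        for key, (q1, q2, r, w1, w2, rw) in {
            "A": (p.var1_t1.a, p.var2_t1.a, p.latcorr_t1.ra,
                  p.var1_res_t2.a, p.var2_res_t2.a, p.latcorr_res_t2.ra),
            "C": (p.var1_t1.c, p.var2_t1.c, p.latcorr_t1.rc,
                  p.var1_res_t2.c, p.var2_res_t2.c, p.latcorr_res_t2.rc),
            "E": (p.var1_t1.e, p.var2_t1.e, p.latcorr_t1.re,
                  p.var1_res_t2.e, p.var2_res_t2.e, p.latcorr_res_t2.re),
        }.items():
            l1, l2 = corr_pair(r)
            t1 = np.vstack([q1 * l1, q2 * l2])
            m1, m2 = corr_pair(rw)
            comps_t2[key] = B @ t1 + np.vstack([w1 * m1, w2 * m2])

        total_var = sum(c.var(axis=1) for c in comps_t2.values())
        rep = time2_total_decomposition(p)
        tol = 0.01
        for key, share in (("A", rep.share_a), ("C", rep.share_c),
                           ("E", rep.share_e)):
            mc = comps_t2[key].var(axis=1) / total_var
            assert np.allclose(share, mc, atol=tol), key
        mc_ra = np.corrcoef(comps_t2["A"])[0, 1]
        assert rep.total_corrs.ra == pytest.approx(mc_ra, abs=tol)

    def test_sign_reflection_invariance(self, paranoia_crosslag):
        """Flipping a latent path's sign together with its correlations
        leaves the implied covariance, and hence the report, unchanged."""
        p = paranoia_crosslag
        flipped = CrossLagParams(
            var1_t1=AceParams(-p.var1_t1.a, p.var1_t1.c, p.var1_t1.e),
            var2_t1=p.var2_t1,
            latcorr_t1=LatentCorrelations(-p.latcorr_t1.ra, p.latcorr_t1.rc,
                                          p.latcorr_t1.re),
            b11=p.b11, b12=p.b12, b21=p.b21, b22=p.b22,
            var1_res_t2=p.var1_res_t2, var2_res_t2=p.var2_res_t2,
            latcorr_res_t2=p.latcorr_res_t2, mu_t2=p.mu_t2)
        a = time2_total_decomposition(p)
        b = time2_total_decomposition(flipped)
        assert np.allclose(a.share_a, b.share_a, atol=1e-12)
        assert np.allclose(a.total_variance, b.total_variance, atol=1e-12)

    @given(
        b11=st.floats(-0.5, 0.5), b22=st.floats(-0.5, 0.5),
        b12=st.floats(-0.2, 0.2), b21=st.floats(-0.2, 0.2),
        ra=st.floats(-0.9, 0.9),
    )
    def test_shares_conserve_total_variance(self, b11, b22, b12, b21, ra):
        lat = LatentCorrelations(ra, 0.3, 0.2)
        try:
            p = tl.standardized_crosslag((0.3, 0.2, 0.5), (0.45, 0.15, 0.4),
                                         lat, b11=b11, b22=b22, b12=b12,
                                         b21=b21)
        except ValueError:
            return
        rep = time2_total_decomposition(p)
        for k in (0, 1):
            assert rep.share_a[k] + rep.share_c[k] + rep.share_e[k] == \
                pytest.approx(1.0, abs=1e-8)
        # the preset solves residuals for unit total time-2 variance
        assert np.allclose(rep.total_variance, 1.0, atol=1e-8)


class TestContinuityVariance:
    @pytest.mark.parametrize("b,expected", [(0.48, 0.2304), (0.0, 0.0),
                                            (1.0, 1.0), (-0.5, 0.25)])
    def test_squared_path(self, b, expected):
        assert continuity_variance_explained(b) == pytest.approx(expected,
                                                                 abs=1e-12)
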