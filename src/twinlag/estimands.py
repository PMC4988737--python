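"""Derived estimands of the bivariate and cross-lagged ACE models.

These are the quantities a twin analysis actually reports: how much of a
phenotypic correlation is carried by genetic versus environmental
overlap, how time-2 total variance splits across A/C/E once transmitted
time-1 variance is counted, and how much variance a continuity path
explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AceParams, CrossLagParams, LatentCorrelations

__all__ = [
    "DecompositionReport",
    "Time2VarianceReport",
    "bivariate_decomposition",
    "time2_total_decomposition",
    "continuity_variance_explained",
]


@dataclass(frozen=True)
class DecompositionReport:
    """Split of a phenotypic correlation into A/C/E-mediated shares.

    ``prop_a`` is the bivariate heritability rA·a1·a2 / rPh; ``prop_c``
    and ``prop_e`` analogous.  When ``r_ph`` is zero the proportions are
    undefined and ``defined`` is False (the props are NaN).
    """

    r_ph: float
    prop_a: float
    prop_c: float
    prop_e: float
    defined: bool = True


@dataclass(frozen=True)
class Time2VarianceReport:
    """ACE shares of time-2 *total* (transmitted + residual) variance.

    ``share_a`` etc. are pairs (variable 1, variable 2); ``total_corrs``
    are the latent correlations re-expressed on total rather than
    residual time-2 variances.
    """

    share_a: tuple[float, float]
    share_c: tuple[float, float]
    share_e: tuple[float, float]
    total_corrs: LatentCorrelations
    total_variance: tuple[float, float]


def bivariate_decomposition(p1: AceParams, p2: AceParams,
                            latcorr: LatentCorrelations,
                            eps: float = 1e-12) -> DecompositionReport:
    """Decompose the implied cross-trait correlation by latent source.

    With standardized trait parameters the implied phenotypic
    correlation is the path-tracing sum

        rPh = rA·a1·a2 + rC·c1·c2 + rE·e1·e2

    and each source's proportion is its term divided by rPh.
    """
    cov_a = latcorr.ra * p1.a * p2.a
    cov_c = latcorr.rc * p1.c * p2.c
    cov_e = latcorr.re * p1.e * p2.e
    r_ph = cov_a + cov_c + cov_e
    if abs(r_ph) < eps:
        return DecompositionReport(r_ph=0.0, prop_a=np.nan, prop_c=np.nan,
                                   prop_e=np.nan, defined=False)
    return DecompositionReport(r_ph=float(r_ph), prop_a=float(cov_a / r_ph),
                               prop_c=float(cov_c / r_ph),
                               prop_e=float(cov_e / r_ph))


def _source_total_cov(p: CrossLagParams):
    """Per-source 2×2 covariance of the two time-2 variables (total scale).

    For each source S in {A, C, E}, the transmitted part propagates the
    time-1 S-attributable phenotypic covariance through the lag matrix B
    (crediting the 2·b·b·rS·s1·s2 covariance of the two transmitted
    streams to S), and the residual part adds the time-2 residual S
    covariance.  Cross-source terms vanish because the latent sources
    are mutually orthogonal.
    """
    B = p.b_matrix
    out = {}
    t1 = ((p.var1_t1.a, p.var2_t1.a, p.latcorr_t1.ra),
          (p.var1_t1.c, p.var2_t1.c, p.latcorr_t1.rc),
          (p.var1_t1.e, p.var2_t1.e, p.latcorr_t1.re))
    res = ((p.var1_res_t2.a, p.var2_res_t2.a, p.latcorr_res_t2.ra),
           (p.var1_res_t2.c, p.var2_res_t2.c, p.latcorr_res_t2.rc),
           (p.var1_res_t2.e, p.var2_res_t2.e, p.latcorr_res_t2.re))
    for key, (s1, s2, r) in zip("ACE", t1):
        cov_t1 = np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])
        q1, q2, rr = res["ACE".index(key)]
        cov_res = np.array([[q1 * q1, rr * q1 * q2], [rr * q1 * q2, q2 * q2]])
        out[key] = B @ cov_t1 @ B.T + cov_res
    return out


def time2_total_decomposition(p: CrossLagParams) -> Time2VarianceReport:
    """ACE decomposition of time-2 total variance and total-scale correlations.

    Invariant to the sign reflections of latent paths that leave the
    implied covariance unchanged, and the three shares sum to one for
    each variable.
    """
    src = _source_total_cov(p)
    total = src["A"] + src["C"] + src["E"]
    tv = np.diag(total)
    if np.any(tv <= 0):
        raise ValueError(f"zero total time-2 variance: {tv}")

    def shares(key):
        return tuple(float(x) for x in np.diag(src[key]) / tv)

    def total_corr(key):
        m = src[key]
        denom = np.sqrt(m[0, 0] * m[1, 1])
        return float(m[0, 1] / denom) if denom > 0 else 0.0

    return Time2VarianceReport(
        share_a=shares("A"), share_c=shares("C"), share_e=shares("E"),
        total_corrs=LatentCorrelations(total_corr("A"), total_corr("C"),
                                       total_corr("E")),
        total_variance=(float(tv[0]), float(tv[1])),
    )


def continuity_variance_explained(b: float) -> float:
    """Fraction of time-2 variance explained by the same trait at time 1.

    For a standardized continuity path b this is simply b²; e.g. a
    continuity of 0.48 means 23% of time-2 variance is carried over.
    """
    return float(b) ** 2
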