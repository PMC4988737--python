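"""Path-traced model-implied moments for twin pair data.

Every function returns the mean vector and covariance matrix of the
stacked phenotype vector of a twin pair under the ACE path model.  The
twin-sharing rules are: same-trait cross-twin A correlation 1 for MZ and
0.5 for DZ pairs; cross-trait cross-twin A correlation rA (MZ) or
0.5·rA (DZ); C shared completely by both members (rC across traits);
E shared not at all.
"""

from __future__ import annotations

import numpy as np

from .params import AceParams, CrossLagParams, ImpliedMoments, LatentCorrelations

__all__ = [
    "NonPsdError",
    "genetic_sharing",
    "implied_moments_univariate",
    "implied_moments_bivariate",
    "implied_moments_crosslag",
    "crosslag_moments",
]

#: additive-genetic sharing coefficient per zygosity
_ALPHA = {"MZ": 1.0, "DZ": 0.5}

# permutation from grouped order (t1 twin1, t1 twin2, t2 twin1, t2 twin2)
# to the canonical order (twin1 all four, twin2 all four)
_CANONICAL = np.array([0, 1, 4, 5, 2, 3, 6, 7])


class NonPsdError(ValueError):
    """Raised when implied pair covariance is not positive semi-definite."""

    def __init__(self, min_eigenvalue: float, zygosity: str):
        self.min_eigenvalue = min_eigenvalue
        self.zygosity = zygosity
        super().__init__(
            f"implied {zygosity} pair covariance is not PSD "
            f"(minimum eigenvalue {min_eigenvalue:.3e})"
        )


def genetic_sharing(zygosity: str) -> float:
    """Expected additive-genetic sharing: 1.0 for MZ, 0.5 for DZ."""
    key = str(zygosity).upper()
    try:
        return _ALPHA[key]
    except KeyError:
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}") from None


def _source_cov(p1: AceParams, p2: AceParams, lat: LatentCorrelations):
    """Per-source within-twin 2×2 phenotypic covariance of the two traits."""
    A = np.array([[p1.a**2, lat.ra * p1.a * p2.a],
                  [lat.ra * p1.a * p2.a, p2.a**2]])
    C = np.array([[p1.c**2, lat.rc * p1.c * p2.c],
                  [lat.rc * p1.c * p2.c, p2.c**2]])
    E = np.array([[p1.e**2, lat.re * p1.e * p2.e],
                  [lat.re * p1.e * p2.e, p2.e**2]])
    return A, C, E


def implied_moments_univariate(p: AceParams, zygosity: str):
    """Implied (mean, covariance) of one trait measured on both twins.

    The within-twin variance is a²+c²+e²; the cross-twin covariance is
    a²+c² for MZ pairs and 0.5·a²+c² for DZ pairs.
    """
    alpha = genetic_sharing(zygosity)
    var = p.variance
    cross = alpha * p.a**2 + p.c**2
    mu = np.array([p.mu, p.mu])
    sigma = np.array([[var, cross], [cross, var]])
    return mu, sigma


def implied_moments_bivariate(p1: AceParams, p2: AceParams,
                              lat: LatentCorrelations, zygosity: str):
    """Implied moments of two traits on both twins (one wave).

    Ordering: twin1 (var1, var2), twin2 (var1, var2).
    """
    alpha = genetic_sharing(zygosity)
    A, C, E = _source_cov(p1, p2, lat)
    within = A + C + E
    cross = alpha * A + C  # E is twin-specific
    mu = np.array([p1.mu, p2.mu, p1.mu, p2.mu])
    sigma = np.block([[within, cross], [cross, within]])
    return mu, sigma


def _crosslag_grouped(p: CrossLagParams, zygosity: str):
    """8×8 moments in grouped order (t1 tw1, t1 tw2, t2 tw1, t2 tw2)."""
    mu1, s1 = implied_moments_bivariate(p.var1_t1, p.var2_t1,
                                        p.latcorr_t1, zygosity)
    _, res = implied_moments_bivariate(p.var1_res_t2, p.var2_res_t2,
                                       p.latcorr_res_t2, zygosity)
    B = p.b_matrix
    T = np.kron(np.eye(2), B)  # apply the lag regression within each twin
    cross = s1 @ T.T           # cov(time-1 block, time-2 block)
    s2 = T @ s1 @ T.T + res
    sigma = np.block([[s1, cross], [T @ s1, s2]])
    mu2_twin = B @ mu1[:2] + np.asarray(p.mu_t2, dtype=float)
    mu = np.concatenate([mu1, mu2_twin, mu2_twin])
    return mu, sigma


def implied_moments_crosslag(p: CrossLagParams, zygosity: str,
                             validate: bool = True):
    """Implied 8-variable pair moments of the cross-lagged ACE model.

    Built by path tracing: the time-1 4×4 latent-structured block is
    propagated to time 2 through the within-twin regression matrix B and
    the residual ACE covariance (same twin-sharing rules, independent of
    time-1 latents) is added.  Ordering: twin1 {var1_t1, var2_t1,
    var1_t2, var2_t2}, twin2 same.
    """
    mu, sigma = _crosslag_grouped(p, zygosity)
    idx = _CANONICAL
    mu = mu[idx]
    sigma = sigma[np.ix_(idx, idx)]
    if validate:
        eig = np.linalg.eigvalsh(sigma)
        floor = -1e-8 * max(1.0, float(eig[-1]))
        if eig[0] < floor:
            raise NonPsdError(float(eig[0]), str(zygosity).upper())
    return mu, sigma


def crosslag_moments(p: CrossLagParams, validate: bool = True) -> ImpliedMoments:
    """Implied moments for both zygosity groups."""
    mu, smz = implied_moments_crosslag(p, "MZ", validate=validate)
    _, sdz = implied_moments_crosslag(p, "DZ", validate=validate)
    return ImpliedMoments(mu=mu, sigma_mz=smz, sigma_dz=sdz)
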