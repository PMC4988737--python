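"""Parameter containers for twin ACE and cross-lagged models.

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared-environment (C), and non-shared-environment (E)
sources by contrasting monozygotic (MZ) pairs, who share all segregating
alleles, with dizygotic (DZ) pairs, who share half on average.  The
containers here hold path loadings on those latent sources; the implied
covariance algebra lives in :mod:`twinlag.moments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AceParams",
    "LatentCorrelations",
    "CrossLagParams",
    "ImpliedMoments",
]


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"{name}: non-finite parameter value {v!r}")


@dataclass(frozen=True)
class AceParams:
    """Path loadings of one phenotype on its A, C and E latent factors.

    Parameters are on the path (standard-deviation) scale: the variance
    contributed by each source is the squared loading.  ``e`` absorbs
    measurement error and is never exactly zero in a fitted model.
    """

    a: float
    c: float
    e: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("AceParams", self.a, self.c, self.e, self.mu)

    @property
    def variance(self) -> float:
        """Total implied phenotypic variance a² + c² + e²."""
        return self.a**2 + self.c**2 + self.e**2

    @property
    def shares(self) -> tuple[float, float, float]:
        """(a², c², e²) as proportions of total variance."""
        tot = self.variance
        if tot <= 0:
            raise ValueError("AceParams: zero total variance, shares undefined")
        return (self.a**2 / tot, self.c**2 / tot, self.e**2 / tot)

    def validate_standardized(self, tol: float = 1e-8) -> None:
        """Check the unit-variance (standardized) parameterization."""
        if abs(self.variance - 1.0) > tol:
            raise ValueError(
                f"AceParams not standardized: a²+c²+e² = {self.variance:.10f}"
            )
        if self.e <= 0:
            raise ValueError("AceParams: e must be strictly positive")

    @classmethod
    def from_shares(cls, a2: float, c2: float, e2: float, mu: float = 0.0,
                    total: float = 1.0) -> "AceParams":
        """Build loadings from variance proportions scaled to ``total``."""
        s = a2 + c2 + e2
        if s <= 0 or min(a2, c2, e2) < 0:
            raise ValueError("shares must be non-negative with positive sum")
        scale = total / s
        return cls(a=np.sqrt(a2 * scale), c=np.sqrt(c2 * scale),
                   e=np.sqrt(e2 * scale), mu=mu)


@dataclass(frozen=True)
class LatentCorrelations:
    """Cross-trait correlations between same-source latent factors.

    ``ra`` is the genetic correlation (the correlation between the two
    traits' additive-genetic factors), ``rc`` and ``re`` the analogous
    shared- and non-shared-environment correlations.
    """

    ra: float
    rc: float
    re: float

    def __post_init__(self) -> None:
        _require_finite("LatentCorrelations", self.ra, self.rc, self.re)
        for name, v in (("ra", self.ra), ("rc", self.rc), ("re", self.re)):
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"LatentCorrelations.{name}={v} outside [-1, 1]")


@dataclass(frozen=True)
class CrossLagParams:
    """Full parameter set of the two-trait, two-wave cross-lagged ACE model.

    Variable 1 and variable 2 each load on their own A/C/E factors at
    time 1 (``var1_t1``, ``var2_t1``) with cross-trait latent
    correlations ``latcorr_t1``.  Time-2 scores are partial regressions
    on both time-1 phenotypes —

    * ``b11``: var1(t1) → var1(t2)   (continuity of variable 1)
    * ``b22``: var2(t1) → var2(t2)   (continuity of variable 2)
    * ``b12``: var1(t1) → var2(t2)   (cross-lag)
    * ``b21``: var2(t1) → var1(t2)   (cross-lag)

    — plus ACE-structured residuals (``var1_res_t2`` etc.) that are
    independent of every time-1 latent factor.  ``mu_t2`` are the
    time-2 regression intercepts.
    """

    var1_t1: AceParams
    var2_t1: AceParams
    latcorr_t1: LatentCorrelations
    b11: float
    b12: float
    b21: float
    b22: float
    var1_res_t2: AceParams
    var2_res_t2: AceParams
    latcorr_res_t2: LatentCorrelations
    mu_t2: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        _require_finite("CrossLagParams", self.b11, self.b12, self.b21,
                        self.b22, *self.mu_t2)

    @property
    def b_matrix(self) -> np.ndarray:
        """Within-twin regression matrix mapping (var1, var2) at t1 to t2.

        Row k gives the regression of time-2 variable k+1 on the two
        time-1 phenotypes, i.e. B = [[b11, b21], [b12, b22]].
        """
        return np.array([[self.b11, self.b21], [self.b12, self.b22]])


@dataclass(frozen=True)
class ImpliedMoments:
    """Model-implied mean vector and per-zygosity pair covariance matrices.

    Variable ordering of the 8-vector: twin 1 {var1_t1, var2_t1,
    var1_t2, var2_t2}, then twin 2 in the same order.
    """

    mu: np.ndarray
    sigma_mz: np.ndarray
    sigma_dz: np.ndarray

    def sigma(self, zygosity: str) -> np.ndarray:
        key = str(zygosity).upper()
        if key == "MZ":
            return self.sigma_mz
        if key == "DZ":
            return self.sigma_dz
        raise ValueError(f"unknown zygosity {zygosity!r}")
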