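"""Generating-parameter presets for the bundled simulator.

The defaults correspond to the point estimates reported for adolescent
depressive symptoms and specific psychotic experiences (paranoia,
hallucinations, cognitive disorganization) in large community twin
samples: moderate heritability, small shared-environment effects, high
genetic correlations with depression, and cross-lagged paths of the
order 0.1–0.2 on standardized scales.  All quantities are on the
standardized (unit time-1 variance) scale; residual time-2 variances are
solved so each time-2 phenotype also has unit total variance.
"""

from __future__ import annotations

import numpy as np

from .params import AceParams, CrossLagParams, LatentCorrelations

__all__ = [
    "TRAIT_ACE_SHARES",
    "DEPRESSION_LATCORR",
    "DEPRESSION_CROSS_PATHS",
    "ace_preset",
    "bivariate_preset",
    "standardized_crosslag",
    "crosslag_preset",
    "SCORE_RANGES",
]

#: time-1 variance shares (a², c², e²) per trait
TRAIT_ACE_SHARES: dict[str, tuple[float, float, float]] = {
    "depression": (0.26, 0.14, 0.60),
    "paranoia": (0.50, 0.12, 0.38),
    "hallucinations": (0.45, 0.10, 0.45),
    "cognitive_disorganization": (0.45, 0.12, 0.43),
}

#: time-1 latent correlations (rA, rC, rE) of each experience with depression
DEPRESSION_LATCORR: dict[str, tuple[float, float, float]] = {
    "paranoia": (0.78, 0.45, 0.40),
    "hallucinations": (0.68, 0.50, 0.30),
    "cognitive_disorganization": (0.78, 0.55, 0.38),
}

#: standardized cross-lag paths (b11, b22, b12, b21) with variable 1 =
#: depression and variable 2 = the psychotic experience; b12 is
#: depression(t1) → experience(t2), b21 the reverse.
DEPRESSION_CROSS_PATHS: dict[str, tuple[float, float, float, float]] = {
    "paranoia": (0.48, 0.55, 0.14, 0.15),
    "hallucinations": (0.48, 0.56, 0.09, 0.14),
    "cognitive_disorganization": (0.48, 0.63, 0.11, 0.20),
}

#: questionnaire score ranges, used only by the cosmetic affine transform
SCORE_RANGES: dict[str, tuple[float, float]] = {
    "depression": (0, 26),
    "paranoia": (0, 72),
    "hallucinations": (0, 45),
    "cognitive_disorganization": (0, 11),
}


def ace_preset(trait: str = "depression", mu: float = 0.0) -> AceParams:
    """Standardized ACE loadings for one trait's time-1 variance shares."""
    a2, c2, e2 = TRAIT_ACE_SHARES[trait]
    return AceParams.from_shares(a2, c2, e2, mu=mu)


def bivariate_preset(experience: str = "paranoia"):
    """(depression params, experience params, latent correlations) at time 1."""
    lat = LatentCorrelations(*DEPRESSION_LATCORR[experience])
    return ace_preset("depression"), ace_preset(experience), lat


def standardized_crosslag(
    shares1: tuple[float, float, float],
    shares2: tuple[float, float, float],
    latcorr: LatentCorrelations,
    b11: float, b22: float, b12: float, b21: float,
    res_shares1: tuple[float, float, float] | None = None,
    res_shares2: tuple[float, float, float] | None = None,
    res_latcorr: LatentCorrelations | None = None,
) -> CrossLagParams:
    """Cross-lag parameters with unit total variance at both waves.

    Time-1 loadings come from the given variance shares.  The residual
    time-2 variance of each variable is 1 minus the variance transmitted
    through the lag regressions, and is split across A/C/E according to
    ``res_shares*`` (defaulting to the time-1 shares); residual latent
    correlations default to the time-1 ones.
    """
    p1 = AceParams.from_shares(*shares1)
    p2 = AceParams.from_shares(*shares2)
    r_ph = (latcorr.ra * p1.a * p2.a + latcorr.rc * p1.c * p2.c
            + latcorr.re * p1.e * p2.e)
    P1 = np.array([[1.0, r_ph], [r_ph, 1.0]])
    B = np.array([[b11, b21], [b12, b22]])
    transmitted = B @ P1 @ B.T
    res_var = 1.0 - np.diag(transmitted)
    if np.any(res_var <= 0):
        raise ValueError(
            f"lag paths transmit more than unit variance (residuals {res_var})"
        )
    rs1 = res_shares1 if res_shares1 is not None else shares1
    rs2 = res_shares2 if res_shares2 is not None else shares2
    return CrossLagParams(
        var1_t1=p1,
        var2_t1=p2,
        latcorr_t1=latcorr,
        b11=b11, b12=b12, b21=b21, b22=b22,
        var1_res_t2=AceParams.from_shares(*rs1, total=float(res_var[0])),
        var2_res_t2=AceParams.from_shares(*rs2, total=float(res_var[1])),
        latcorr_res_t2=res_latcorr if res_latcorr is not None else latcorr,
    )


def crosslag_preset(experience: str = "paranoia") -> CrossLagParams:
    """Default cross-lagged generating model for depression + one experience."""
    b11, b22, b12, b21 = DEPRESSION_CROSS_PATHS[experience]
    return standardized_crosslag(
        TRAIT_ACE_SHARES["depression"],
        TRAIT_ACE_SHARES[experience],
        LatentCorrelations(*DEPRESSION_LATCORR[experience]),
        b11=b11, b22=b22, b12=b12, b21=b21,
    )
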