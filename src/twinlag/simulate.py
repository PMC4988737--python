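"""Synthetic twin-pair generator.

Emulates a two-wave twin study: phenotypes are drawn per pair from the
multivariate normal implied by the generating parameters and zygosity,
and a random subset of pairs is re-assessed at time 2 (the rest have
the whole time-2 block missing, missing completely at random, mirroring
a representative follow-up subsample).  Sexes are assigned identically
within MZ pairs and independently within DZ pairs; they feed the
descriptive layer only, never the generating covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import META_COLUMNS, TwinDataset, phenotype_column
from .moments import (implied_moments_bivariate, implied_moments_crosslag,
                      implied_moments_univariate)
from .params import AceParams, CrossLagParams, LatentCorrelations
from .presets import SCORE_RANGES

__all__ = [
    "SimDesign",
    "simulate_twin_pairs",
    "simulate_bivariate",
    "simulate_univariate",
    "to_score_scale",
]


@dataclass(frozen=True)
class SimDesign:
    """Design of a simulated two-wave twin study.

    ``t2_retention`` is the fraction of pairs with time-2 data (the
    study this emulates re-assessed roughly 31% of families nine months
    after the first wave).  ``sex_ratio`` is the probability that an
    individual (or an MZ pair) is male and is used only for
    descriptives.
    """

    n_mz: int
    n_dz: int
    t2_retention: float = 0.31
    seed: int = 0
    sex_ratio: float = 0.45

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if not 0.0 < self.t2_retention <= 1.0:
            raise ValueError(f"t2_retention={self.t2_retention} outside (0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must lie in [0, 1]")


def _draw_group(rng, mu, sigma, n):
    if n == 0:
        return np.empty((0, len(mu)))
    L = np.linalg.cholesky(sigma + 1e-12 * np.eye(len(mu)))
    return mu + rng.standard_normal((n, len(mu))) @ L.T


def _sexes(rng, n, zygosity, sex_ratio):
    if zygosity == "MZ":
        s = np.where(rng.random(n) < sex_ratio, "M", "F")
        return s, s.copy()
    s1 = np.where(rng.random(n) < sex_ratio, "M", "F")
    s2 = np.where(rng.random(n) < sex_ratio, "M", "F")
    return s1, s2


def _assemble(rng, columns, mz_vals, dz_vals, design) -> pd.DataFrame:
    n = len(mz_vals) + len(dz_vals)
    fam = [f"fam{idx:06d}" for idx in range(1, n + 1)]
    zyg = np.array(["MZ"] * len(mz_vals) + ["DZ"] * len(dz_vals))
    s1_mz, s2_mz = _sexes(rng, len(mz_vals), "MZ", design.sex_ratio)
    s1_dz, s2_dz = _sexes(rng, len(dz_vals), "DZ", design.sex_ratio)
    df = pd.DataFrame({
        "famid": fam,
        "zygosity": zyg,
        "sex1": np.concatenate([s1_mz, s1_dz]),
        "sex2": np.concatenate([s2_mz, s2_dz]),
    })
    vals = np.vstack([mz_vals, dz_vals]) if n else np.empty((0, len(columns)))
    for j, col in enumerate(columns):
        df[col] = vals[:, j] if n else pd.Series(dtype=float)
    return df


def simulate_twin_pairs(
    params: CrossLagParams,
    design: SimDesign,
    var_names: Sequence[str] = ("depression", "paranoia"),
    retention_fn: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TwinDataset:
    """Simulate a two-wave twin study from cross-lagged generating values.

    Parameters
    ----------
    retention_fn : callable, optional
        Hook for attrition sensitivity analyses: maps the (n, 4) array of
        time-1 pair phenotypes to per-pair retention probabilities,
        overriding the MCAR ``design.t2_retention``.
    """
    rng = np.random.default_rng(design.seed)
    v1, v2 = var_names
    columns = [phenotype_column(v, w, tw)
               for tw in (1, 2) for v, w in ((v1, 1), (v2, 1), (v1, 2), (v2, 2))]
    mu_mz, sig_mz = implied_moments_crosslag(params, "MZ")
    mu_dz, sig_dz = implied_moments_crosslag(params, "DZ")
    mz = _draw_group(rng, mu_mz, sig_mz, design.n_mz)
    dz = _draw_group(rng, mu_dz, sig_dz, design.n_dz)
    df = _assemble(rng, columns, mz, dz, design)

    n = len(df)
    if n:
        t1_cols = [phenotype_column(v, 1, tw) for tw in (1, 2) for v in (v1, v2)]
        if retention_fn is not None:
            probs = np.asarray(retention_fn(df[t1_cols].to_numpy()), dtype=float)
        else:
            probs = np.full(n, design.t2_retention)
        keep = rng.random(n) < probs
        t2_cols = [phenotype_column(v, 2, tw) for tw in (1, 2) for v in (v1, v2)]
        df.loc[~keep, t2_cols] = np.nan
    return TwinDataset(df, validate=False)


def simulate_bivariate(
    p1: AceParams,
    p2: AceParams,
    latcorr: LatentCorrelations,
    design: SimDesign,
    var_names: Sequence[str] = ("depression", "paranoia"),
    wave: int = 1,
) -> TwinDataset:
    """Simulate a single-wave study of two correlated traits."""
    rng = np.random.default_rng(design.seed)
    v1, v2 = var_names
    columns = [phenotype_column(v, wave, tw) for tw in (1, 2) for v in (v1, v2)]
    mu_mz, sig_mz = implied_moments_bivariate(p1, p2, latcorr, "MZ")
    mu_dz, sig_dz = implied_moments_bivariate(p1, p2, latcorr, "DZ")
    mz = _draw_group(rng, mu_mz, sig_mz, design.n_mz)
    dz = _draw_group(rng, mu_dz, sig_dz, design.n_dz)
    return TwinDataset(_assemble(rng, columns, mz, dz, design), validate=False)


def simulate_univariate(
    p: AceParams,
    design: SimDesign,
    var_name: str = "depression",
    wave: int = 1,
) -> TwinDataset:
    """Simulate a single-wave study of one trait."""
    rng = np.random.default_rng(design.seed)
    columns = [phenotype_column(var_name, wave, tw) for tw in (1, 2)]
    mu_mz, sig_mz = implied_moments_univariate(p, "MZ")
    mu_dz, sig_dz = implied_moments_univariate(p, "DZ")
    mz = _draw_group(rng, mu_mz, sig_mz, design.n_mz)
    dz = _draw_group(rng, mu_dz, sig_dz, design.n_dz)
    return TwinDataset(_assemble(rng, columns, mz, dz, design), validate=False)


def to_score_scale(data: TwinDataset, ranges: dict[str, tuple[float, float]] | None = None,
                   sd_fraction: float = 0.15) -> TwinDataset:
    """Affine map from the standardized scale to questionnaire-like scores.

    Purely cosmetic I/O realism: each variable is rescaled so its mean
    sits a quarter of the way up the score range with SD equal to
    ``sd_fraction`` of the range, then clipped to the range.  The twin
    covariance structure below the clip is unchanged.
    """
    ranges = ranges or SCORE_RANGES
    df = data.df.copy()
    for v, w in data.variables:
        lo, hi = ranges.get(v, (0.0, 1.0))
        span = hi - lo
        cols = [phenotype_column(v, w, tw) for tw in (1, 2)]
        df[cols] = np.clip(lo + 0.25 * span + df[cols] * sd_fraction * span, lo, hi)
    return TwinDataset(df, validate=False)
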