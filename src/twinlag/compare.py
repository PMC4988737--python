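"""Model comparison: likelihood-ratio tests, BIC, path-equating tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .models import ResultsBase, TwinModel, TwinResults

__all__ = ["ComparisonResult", "likelihood_ratio_test", "bic",
           "equate_paths_test", "EquateTestResult", "sex_stratified_comparison"]

_SLACK = 1e-6


@dataclass(frozen=True)
class ComparisonResult:
    """Likelihood-ratio comparison of a nested against a fuller model."""

    chi2: float
    df: int
    p_value: float
    bic_a: float  # nested (restricted) model
    bic_b: float  # full model

    def __str__(self) -> str:
        return (f"chi2({self.df}) = {self.chi2:.4f}, p = {self.p_value:.4g}; "
                f"BIC nested {self.bic_a:.2f} vs full {self.bic_b:.2f}")


def bic(fit: ResultsBase) -> float:
    """-2lnL + k·ln(number of pairs)."""
    return fit.minus2ll + fit.n_params * np.log(fit.n_pairs)


def likelihood_ratio_test(nested: ResultsBase, full: ResultsBase) -> ComparisonResult:
    """Chi-square difference test of a restriction.

    ``nested`` must be a constrained version of ``full`` fitted to the
    same data; the statistic is the -2lnL difference on df equal to the
    difference in free-parameter counts.
    """
    if nested.n_pairs != full.n_pairs:
        raise ValueError("models were fitted to different numbers of pairs")
    stat = nested.minus2ll - full.minus2ll
    if stat < -_SLACK:
        raise ValueError(
            f"nested model fits better than the full model by {-stat:.3g}; "
            "the full model likely hit a local optimum - refit with more "
            "restarts")
    stat = max(stat, 0.0)
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("'nested' has more free parameters than 'full'")
    if df == 0:
        p = 1.0 if stat <= _SLACK else 0.0
    else:
        p = float(chi2_dist.sf(stat, df))
    return ComparisonResult(chi2=float(stat), df=int(df), p_value=p,
                            bic_a=bic(nested), bic_b=bic(full))


@dataclass(frozen=True)
class EquateTestResult:
    comparison: ComparisonResult
    free: TwinResults
    constrained: TwinResults


def equate_paths_test(model: TwinModel, path_a: str, path_b: str,
                      **fit_kw) -> EquateTestResult:
    """Test whether two paths can be equated without loss of fit.

    Fits the model twice - paths free versus constrained equal - and
    runs the likelihood-ratio test (df = 1).  Used for the reciprocal
    cross-lag questions such as b12 = b21.
    """
    if path_a == path_b:
        raise ValueError(f"degenerate restriction: {path_a!r} equated with itself")
    names = {d.name for d in model.param_defs}
    for p in (path_a, path_b):
        if p not in names:
            raise KeyError(f"unknown path {p!r}")
        if p in model.constraints:
            raise ValueError(f"path {p!r} is already constrained in this model")
    free = model.fit(**fit_kw)
    constrained_model = model.clone(extra_constraints={path_b: path_a})
    start = constrained_model.free_from_params(free.params)
    kw = {k: v for k, v in fit_kw.items() if k != "start"}
    constrained = constrained_model.fit(start=start, **kw)
    if constrained.minus2ll < free.minus2ll:
        # the warm-started constrained fit found a slightly deeper optimum;
        # polish the free fit from there so the nesting bound holds
        refit = model.fit(start=model.free_from_params(constrained.params),
                          **kw)
        if refit.minus2ll < free.minus2ll:
            free = refit
    return EquateTestResult(
        comparison=likelihood_ratio_test(constrained, free),
        free=free, constrained=constrained)


def sex_stratified_comparison(data, build_model, **fit_kw) -> dict:
    """Descriptive sex-difference check on same-sex pairs.

    Fits the structured model pooled across same-sex pairs and
    stratified by sex (parameters free to differ between male and female
    pairs), then compares by LRT and BIC.  Opposite-sex DZ pairs are
    excluded here so the pooled model is genuinely nested in the
    stratified one; in the main no-sex-difference models they are pooled
    with genetic sharing 0.5.

    ``build_model`` maps a TwinDataset to an unfitted model.
    """
    same = data.same_sex_pairs()
    pooled = build_model(same).fit(**fit_kw)
    strata = {}
    m2ll = 0.0
    n_params = 0
    for sex in ("M", "F"):
        res = build_model(data.same_sex_pairs(sex)).fit(**fit_kw)
        strata[sex] = res
        m2ll += res.minus2ll
        n_params += res.n_params

    class _Combined(ResultsBase):
        pass

    combined = _Combined()
    combined.minus2ll = m2ll
    combined.n_params = n_params
    combined.n_pairs = pooled.n_pairs
    combined.n_observations = pooled.n_observations
    combined.converged = all(r.converged for r in strata.values())
    comparison = likelihood_ratio_test(pooled, combined)
    return {
        "pooled": pooled,
        "stratified": strata,
        "stratified_minus2ll": m2ll,
        "stratified_n_params": n_params,
        "comparison": comparison,
        "bic_pooled": bic(pooled),
        "bic_stratified": combined.bic,
        "prefer_no_sex_difference": bic(pooled) <= combined.bic,
    }
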