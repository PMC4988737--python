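"""Model classes fitted by full-information maximum likelihood.

The public surface follows the statsmodels convention: a model object is
built from a :class:`~twinlag.data.TwinDataset` and ``fit()`` returns a
results object carrying estimates, likelihood, diagnostics, confidence
intervals and a ``summary()`` table.

Models
------
UnivariateACE
    One trait on both twins; A/C/E path loadings plus a mean.
BivariateACE
    Two traits at one wave with correlated A/C/E factors (rA, rC, rE).
CrossLagACE
    The two-wave cross-lagged model: time-1 bivariate ACE structure,
    within-twin lag regressions b11/b12/b21/b22, and ACE-structured
    time-2 residuals.
Saturated
    Free means and covariances per group; the baseline for nesting
    comparisons.

Optimization happens on an unconstrained scale: path loadings are free
reals (squared into variances) and latent correlations pass through
tanh, so every candidate within-trait covariance block is positive
semi-definite by construction.  Likelihood surfaces of path models have
sign-reflection symmetries, so fits use seeded multi-start and reported
standardized quantities are sign-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from . import estimands
from .data import TwinDataset
from .fiml import SingularSubmatrixError, minus2ll_from_stats, pattern_stats
from .moments import (NonPsdError, implied_moments_bivariate,
                      implied_moments_crosslag, implied_moments_univariate)
from .params import AceParams, CrossLagParams, LatentCorrelations

__all__ = ["UnivariateACE", "BivariateACE", "CrossLagACE", "Saturated",
           "TwinResults", "SaturatedResults", "ProfileCI", "FitError"]

_PENALTY = 1e13
_TANH_CAP = 1.0 - 1e-9


class FitError(RuntimeError):
    """No optimizer restart converged; carries per-restart diagnostics."""


@dataclass(frozen=True)
class ParamDef:
    name: str
    start: float = 0.0
    link: str = "identity"  # "identity" | "tanh"


def _to_free(value: float, link: str) -> float:
    if link == "tanh":
        return float(np.arctanh(np.clip(value, -_TANH_CAP, _TANH_CAP)))
    return float(value)


def _to_natural(value, link: str):
    if link == "tanh":
        return np.tanh(value)
    return value


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProfileCI:
    """Profile-likelihood confidence interval for one parameter."""

    name: str
    estimate: float
    lower: float
    upper: float
    level: float
    lower_bounded: bool = True   # False: search hit the parameter-space edge
    upper_bounded: bool = True

    def __iter__(self):
        return iter((self.lower, self.upper))


class ResultsBase:
    """Fields shared by structured and saturated fits."""

    minus2ll: float
    n_params: int
    n_pairs: int
    n_observations: int
    converged: bool

    @property
    def bic(self) -> float:
        """Bayesian Information Criterion, -2lnL + k ln(n pairs).

        The sample-size term counts twin pairs (the independent sampling
        units), not individuals.
        """
        return self.minus2ll + self.n_params * np.log(self.n_pairs)


class TwinResults(ResultsBase):
    """Estimates and diagnostics of a structured twin-model fit."""

    def __init__(self, model, theta_free, minus2ll, converged, gradient_norm,
                 message, n_restarts):
        self.model = model
        self.theta_free = np.asarray(theta_free, dtype=float)
        self.minus2ll = float(minus2ll)
        self.converged = bool(converged)
        self.gradient_norm = float(gradient_norm)
        self.message = message
        self.n_restarts = n_restarts
        self.n_params = model.k_free
        self.n_pairs = model.n_pairs
        self.n_observations = model.n_observations
        full = model.expand(self.theta_free)
        self.params: dict[str, float] = {
            d.name: float(full[i]) for i, d in enumerate(model.param_defs)
        }
        self.ci: dict[str, ProfileCI] = {}

    # -- conveniences ---------------------------------------------------

    @property
    def estimates(self) -> dict[str, float]:
        return self.params

    def standardized(self) -> dict[str, float]:
        """Standardized, sign-invariant report of the estimates."""
        return self.model.standardize(self.params)

    def implied_moments(self):
        return self.model.implied(self.model.full_vector(self.params))

    # -- uncertainty ----------------------------------------------------

    def wald_se(self, step: float = 1e-4) -> dict[str, float]:
        """Delta-method standard errors from the numerical Hessian of -2lnL."""
        H = _numerical_hessian(self.model.objective, self.theta_free, step)
        cov = 2.0 * np.linalg.pinv(H)  # inverse observed information
        se_free = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        out = {}
        for j, i in enumerate(self.model.free_indices):
            d = self.model.param_defs[i]
            jac = 1.0
            if d.link == "tanh":
                jac = 1.0 - np.tanh(self.theta_free[j]) ** 2
            out[d.name] = float(se_free[j] * jac)
        return out

    def wald_ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        se = self.wald_se()[name]
        z = chi2.ppf(level, 1) ** 0.5
        est = self.params[name]
        return est - z * se, est + z * se

    def profile_ci(self, name: str, level: float = 0.95, **fit_kw) -> ProfileCI:
        """Profile-likelihood CI: bounds where the re-optimized -2lnL rises
        by the chi-square(1) quantile (3.84 at 95%) above its minimum."""
        ci = _profile_ci(self, name, level, fit_kw)
        self.ci[name] = ci
        return ci

    # -- presentation ---------------------------------------------------

    def summary(self, standardized: bool = True) -> str:
        m = self.model
        lines = [
            f"{type(m).__name__} results",
            "=" * 60,
            f"pairs: {self.n_pairs}  (MZ {m.zygosity_counts['MZ']}, "
            f"DZ {m.zygosity_counts['DZ']})   observations: {self.n_observations}",
            f"-2 log-likelihood: {self.minus2ll:.4f}   free parameters: "
            f"{self.n_params}   BIC: {self.bic:.4f}",
            f"converged: {self.converged}   max |gradient|: "
            f"{self.gradient_norm:.2e}",
            "-" * 60,
        ]
        for name, val in self.params.items():
            ci = self.ci.get(name)
            tail = (f"   [{ci.lower:.4f}, {ci.upper:.4f}]" if ci else "")
            lines.append(f"  {name:<14s} {val: .4f}{tail}")
        if standardized:
            lines.append("-" * 60)
            lines.append("standardized:")
            for name, val in self.standardized().items():
                lines.append(f"  {name:<20s} {val: .4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<{type(self.model).__name__}Results -2lnL={self.minus2ll:.2f} "
                f"k={self.n_params} converged={self.converged}>")


def _numerical_hessian(f, x, rel_step):
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def _profile_ci(results: TwinResults, name: str, level: float, fit_kw) -> ProfileCI:
    model = results.model
    if name not in results.params:
        raise KeyError(f"unknown parameter {name!r}")
    if name not in {model.param_defs[i].name for i in model.free_indices}:
        raise ValueError(f"parameter {name!r} is not free in this model")
    crit = chi2.ppf(level, 1)
    target = results.minus2ll + crit
    est = results.params[name]
    link = next(d.link for d in model.param_defs if d.name == name)
    # path loadings enter the covariance squared, so zero is a stationary
    # point along them; the perturbed second restart lets probe refits
    # escape a co-parameter stuck at zero
    kw = dict(n_restarts=2, seed=0)
    kw.update(fit_kw)

    mle = dict(results.params)
    warm = dict(results.params)

    def profile(value: float) -> float:
        try:
            sub = model.clone(extra_constraints={name: value})
        except ValueError:
            # every other parameter already fixed: nothing to re-optimize
            return model.minus2ll({**warm, name: value})
        # two starts guard against the warm chain stranding the optimizer
        # on the wrong side of a bracket jump; tolerate one failing
        best = None
        errors = []
        for sp in ({**mle, name: value}, {**warm, name: value}):
            try:
                res = sub.fit(start=sub.free_from_params(sp), **kw)
            except FitError as exc:
                errors.append(exc)
                continue
            if best is None or res.minus2ll < best.minus2ll:
                best = res
        if best is None:
            raise FitError(
                f"profile probe at {name}={value:.6g} failed: {errors}")
        warm.update(best.params)
        return best.minus2ll

    try:
        se = results.wald_se().get(name) or 0.1
    except Exception:  # Hessian can fail near boundaries; fall back
        se = 0.1
    step0 = max(1.96 * se, 1e-3)

    def bisect(inner, outer, f_outer):
        # inner side is below target, outer at or above; probe fits can be
        # slightly noisy near variance boundaries, so plain bisection with a
        # likelihood tolerance is more robust than a derivative-aware root
        # finder here
        value = outer
        for _ in range(80):
            if abs(f_outer - target) < 1e-5 or abs(outer - inner) < 1e-9:
                return value
            mid = 0.5 * (inner + outer)
            f_mid = profile(mid)
            if f_mid >= target:
                outer, f_outer, value = mid, f_mid, mid
            else:
                inner = mid
        return value

    def search(direction: int):
        hard = None
        if link == "tanh":
            hard = _TANH_CAP if direction > 0 else -_TANH_CAP
        lo_v = est
        step = step0
        for _ in range(60):
            cand = est + direction * step
            if hard is not None and (cand - hard) * direction > 0:
                cand = hard
            f = profile(cand)
            if f >= target:
                return float(bisect(lo_v, cand, f)), True
            lo_v = cand
            if hard is not None and cand == hard:
                return float(hard), False
            step *= 1.8
        return float(lo_v), False

    upper, ub = search(+1)
    lower, lb = search(-1)
    if not (ub and lb):
        warnings.warn(f"profile CI for {name!r} is one-sided "
                      f"(bounded: lower={lb}, upper={ub})")
    return ProfileCI(name=name, estimate=est, lower=lower, upper=upper,
                     level=level, lower_bounded=lb, upper_bounded=ub)


# ---------------------------------------------------------------------------
# structured models
# ---------------------------------------------------------------------------

class TwinModel:
    """Shared machinery: parameter space, constraints, FIML objective."""

    #: subclasses set these before calling _prepare
    param_defs: list[ParamDef]

    def __init__(self, data: TwinDataset, var_waves, standardize: bool = True,
                 constraints: dict | None = None):
        self.data = data
        self.var_waves = list(var_waves)
        self.standardize_data = standardize
        self.constraints = dict(constraints or {})
        work = data.zscored(self.var_waves) if standardize else data
        groups = work.split_zygosity(self.var_waves)
        self._stats = {z: pattern_stats(y) for z, y in groups.items()}
        self.zygosity_counts = {z: int(sum(st.n for st in s))
                                for z, s in self._stats.items()}
        self.n_pairs = sum(self.zygosity_counts.values())
        if self.n_pairs == 0:
            raise ValueError("dataset contains no usable pairs")
        self.n_observations = int(sum(
            st.n * int(st.mask.sum()) for s in self._stats.values() for st in s
        ))
        self._resolve_constraints()

    # -- constraint machinery -------------------------------------------

    def _resolve_constraints(self) -> None:
        names = [d.name for d in self.param_defs]
        index = {n: i for i, n in enumerate(names)}
        unknown = [k for k in self.constraints if k not in index]
        if unknown:
            raise KeyError(f"constraints reference unknown parameters {unknown}")
        fixed: dict[int, float] = {}
        alias: dict[int, int] = {}
        for key, val in self.constraints.items():
            i = index[key]
            if isinstance(val, str):
                if val not in index:
                    raise KeyError(f"constraint alias target {val!r} unknown")
                j = index[val]
                if i == j:
                    raise ValueError(f"degenerate constraint {key!r} = itself")
                alias[i] = j
            else:
                fixed[i] = float(val)
        # resolve alias chains onto free targets
        for i, j in list(alias.items()):
            seen = {i}
            while j in alias:
                j = alias[j]
                if j in seen:
                    raise ValueError("cyclic equality constraints")
                seen.add(j)
            if j in fixed:
                fixed[i] = fixed[j]
                del alias[i]
                continue
            if self.param_defs[i].link != self.param_defs[j].link:
                raise ValueError("cannot equate parameters with different links")
            alias[i] = j
        self._fixed = fixed
        self._alias = alias
        self.free_indices = [i for i in range(len(names))
                             if i not in fixed and i not in alias]
        self.k_free = len(self.free_indices)
        if self.k_free == 0:
            raise ValueError("model has no free parameters")

    def expand(self, theta_free: np.ndarray) -> np.ndarray:
        """Free (link-scale) vector -> full natural parameter vector."""
        n = len(self.param_defs)
        link_vals = np.empty(n)
        for j, i in enumerate(self.free_indices):
            link_vals[i] = theta_free[j]
        for i, v in self._fixed.items():
            link_vals[i] = _to_free(v, self.param_defs[i].link)
        for i, j in self._alias.items():
            link_vals[i] = link_vals[j]
        natural = np.empty(n)
        for i, d in enumerate(self.param_defs):
            natural[i] = _to_natural(link_vals[i], d.link)
        return natural

    def full_vector(self, params: dict[str, float]) -> np.ndarray:
        return np.array([params[d.name] for d in self.param_defs])

    def free_from_params(self, params: dict[str, float]) -> np.ndarray:
        """Link-scale free vector whose expansion matches ``params``."""
        return np.array([
            _to_free(params[self.param_defs[i].name], self.param_defs[i].link)
            for i in self.free_indices
        ])

    def default_start(self) -> np.ndarray:
        return np.array([
            _to_free(self.param_defs[i].start, self.param_defs[i].link)
            for i in self.free_indices
        ])

    def clone(self, extra_constraints: dict | None = None) -> "TwinModel":
        merged = dict(self.constraints)
        merged.update(extra_constraints or {})
        new = object.__new__(type(self))
        new.__dict__.update(self.__dict__)
        new.constraints = merged
        new._resolve_constraints()
        return new

    # -- likelihood -------------------------------------------------------

    def _implied(self, natural: np.ndarray):
        raise NotImplementedError

    def implied(self, natural: np.ndarray):
        """(mu, sigma_mz, sigma_dz) implied by a full natural vector."""
        return self._implied(np.asarray(natural, dtype=float))

    def minus2ll(self, params: dict[str, float]) -> float:
        """-2lnL at explicit natural parameter values."""
        mu, smz, sdz = self.implied(self.full_vector(params))
        total = 0.0
        if self._stats["MZ"]:
            total += minus2ll_from_stats(self._stats["MZ"], mu, smz)
        if self._stats["DZ"]:
            total += minus2ll_from_stats(self._stats["DZ"], mu, sdz)
        return total

    def objective(self, theta_free: np.ndarray) -> float:
        natural = self.expand(theta_free)
        try:
            mu, smz, sdz = self._implied(natural)
            total = 0.0
            if self._stats["MZ"]:
                total += minus2ll_from_stats(self._stats["MZ"], mu, smz)
            if self._stats["DZ"]:
                total += minus2ll_from_stats(self._stats["DZ"], mu, sdz)
        except (SingularSubmatrixError, NonPsdError, np.linalg.LinAlgError):
            return _PENALTY
        if not np.isfinite(total):
            return _PENALTY
        return total

    # -- fitting ----------------------------------------------------------

    def fit(self, start: np.ndarray | None = None, n_restarts: int = 5,
            seed: int = 0, gtol: float = 1e-5, ftol: float = 1e-9,
            maxiter: int = 5000) -> TwinResults:
        """Minimize the FIML -2lnL with seeded multi-start quasi-Newton.

        The first start is ``start`` (or the model default); subsequent
        restarts perturb it with N(0, 0.1²) noise on the link scale.
        """
        rng = np.random.default_rng(seed)
        base = np.asarray(start, dtype=float) if start is not None \
            else self.default_start()
        best = None
        diagnostics = []
        for r in range(max(1, n_restarts)):
            x0 = base if r == 0 else base + rng.normal(0.0, 0.1, size=base.shape)
            res = optimize.minimize(
                self.objective, x0, method="L-BFGS-B",
                options={"maxiter": maxiter, "maxfun": 10 * maxiter,
                         "ftol": ftol, "gtol": gtol},
            )
            ok = bool(res.success) and res.fun < _PENALTY / 2
            diagnostics.append((r, ok, float(res.fun), res.message))
            if ok and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError(f"no restart converged: {diagnostics}")
        grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None \
            else np.nan
        return TwinResults(self, best.x, best.fun, True, grad_norm,
                           str(best.message), len(diagnostics))

    def standardize(self, params: dict[str, float]) -> dict[str, float]:
        raise NotImplementedError


def _share_block(prefix: str, a: float, c: float, e: float) -> dict[str, float]:
    tot = a * a + c * c + e * e
    return {
        f"share_a{prefix}": a * a / tot,
        f"share_c{prefix}": c * c / tot,
        f"share_e{prefix}": e * e / tot,
    }


def _signed(r: float, x: float, y: float) -> float:
    s = np.sign(x) * np.sign(y)
    return float(r * (s if s != 0 else 1.0))


class UnivariateACE(TwinModel):
    """Univariate ACE model for one trait measured on both twins.

    Parameters ``a``, ``c``, ``e`` are free path loadings (their squares
    are the variance components) and ``mu`` the phenotype mean.  With
    the default z-scored data, ``standardized()`` shares estimate the
    familiar a²/c²/e² proportions.
    """

    def __init__(self, data: TwinDataset, trait: str, wave: int = 1,
                 standardize: bool = True, constraints: dict | None = None):
        self.trait = trait
        self.wave = wave
        self.param_defs = [
            ParamDef("a", 0.55), ParamDef("c", 0.40),
            ParamDef("e", 0.70), ParamDef("mu", 0.0),
        ]
        super().__init__(data, [(trait, wave)], standardize, constraints)

    def _implied(self, v):
        a, c, e, mu = v
        p = AceParams(a=a, c=c, e=e, mu=mu)
        mu_mz, s_mz = implied_moments_univariate(p, "MZ")
        _, s_dz = implied_moments_univariate(p, "DZ")
        return mu_mz, s_mz, s_dz

    def standardize(self, params):
        a, c, e = params["a"], params["c"], params["e"]
        tot = a * a + c * c + e * e
        out = _share_block("", a, c, e)
        out.update({"a": abs(a) / tot**0.5, "c": abs(c) / tot**0.5,
                    "e": abs(e) / tot**0.5, "total_variance": tot})
        return out


class BivariateACE(TwinModel):
    """Correlated-factors bivariate ACE model at a single wave.

    Each trait has its own A/C/E loadings; cross-trait covariation is
    carried by the latent correlations ``rA``, ``rC``, ``rE`` (fitted
    through a tanh link so they stay inside (-1, 1)).
    """

    def __init__(self, data: TwinDataset, traits, wave: int = 1,
                 standardize: bool = True, constraints: dict | None = None):
        self.traits = tuple(traits)
        self.wave = wave
        self.param_defs = [
            ParamDef("a_v1", 0.55), ParamDef("c_v1", 0.40), ParamDef("e_v1", 0.70),
            ParamDef("a_v2", 0.55), ParamDef("c_v2", 0.40), ParamDef("e_v2", 0.70),
            ParamDef("rA", 0.5, "tanh"), ParamDef("rC", 0.3, "tanh"),
            ParamDef("rE", 0.3, "tanh"),
            ParamDef("mu_v1", 0.0), ParamDef("mu_v2", 0.0),
        ]
        super().__init__(data, [(t, wave) for t in self.traits],
                         standardize, constraints)

    def _unpack(self, v):
        p1 = AceParams(a=v[0], c=v[1], e=v[2], mu=v[9])
        p2 = AceParams(a=v[3], c=v[4], e=v[5], mu=v[10])
        lat = LatentCorrelations(ra=v[6], rc=v[7], re=v[8])
        return p1, p2, lat

    def _implied(self, v):
        p1, p2, lat = self._unpack(v)
        mu, s_mz = implied_moments_bivariate(p1, p2, lat, "MZ")
        _, s_dz = implied_moments_bivariate(p1, p2, lat, "DZ")
        return mu, s_mz, s_dz

    def standardize(self, params):
        out = _share_block("_v1", params["a_v1"], params["c_v1"], params["e_v1"])
        out.update(_share_block("_v2", params["a_v2"], params["c_v2"],
                                params["e_v2"]))
        out["rA"] = _signed(params["rA"], params["a_v1"], params["a_v2"])
        out["rC"] = _signed(params["rC"], params["c_v1"], params["c_v2"])
        out["rE"] = _signed(params["rE"], params["e_v1"], params["e_v2"])
        dec = self.decomposition(params)
        out["r_ph"] = dec.r_ph
        return out

    def decomposition(self, params) -> "estimands.DecompositionReport":
        """Bivariate decomposition of the implied phenotypic correlation."""
        p1, p2, lat = self._unpack(self.full_vector(params))
        return estimands.bivariate_decomposition(
            _unit(p1), _unit(p2),
            LatentCorrelations(_signed(lat.ra, p1.a, p2.a),
                               _signed(lat.rc, p1.c, p2.c),
                               _signed(lat.re, p1.e, p2.e)))


def _unit(p: AceParams) -> AceParams:
    s = p.variance ** 0.5
    return AceParams(a=abs(p.a) / s, c=abs(p.c) / s, e=abs(p.e) / s, mu=0.0)


_CL_NAMES = [
    ("a_v1_t1", 0.55, "identity"), ("c_v1_t1", 0.40, "identity"),
    ("e_v1_t1", 0.70, "identity"),
    ("a_v2_t1", 0.55, "identity"), ("c_v2_t1", 0.40, "identity"),
    ("e_v2_t1", 0.70, "identity"),
    ("rA_t1", 0.5, "tanh"), ("rC_t1", 0.3, "tanh"), ("rE_t1", 0.3, "tanh"),
    ("b11", 0.4, "identity"), ("b12", 0.1, "identity"),
    ("b21", 0.1, "identity"), ("b22", 0.4, "identity"),
    ("a_v1_res", 0.45, "identity"), ("c_v1_res", 0.30, "identity"),
    ("e_v1_res", 0.60, "identity"),
    ("a_v2_res", 0.45, "identity"), ("c_v2_res", 0.30, "identity"),
    ("e_v2_res", 0.60, "identity"),
    ("rA_res", 0.4, "tanh"), ("rC_res", 0.3, "tanh"), ("rE_res", 0.3, "tanh"),
    ("mu_v1_t1", 0.0, "identity"), ("mu_v2_t1", 0.0, "identity"),
    ("mu_v1_t2", 0.0, "identity"), ("mu_v2_t2", 0.0, "identity"),
]


class CrossLagACE(TwinModel):
    """Two-wave cross-lagged ACE model for two traits.

    ``b11``/``b22`` are within-variable continuity paths, ``b12``
    (variable 1 at t1 → variable 2 at t2) and ``b21`` the cross-lags.
    Time-2 residual latents are orthogonal to all time-1 latents.
    Equality constraints such as ``{"b21": "b12"}`` support the
    path-equating likelihood-ratio tests.
    """

    def __init__(self, data: TwinDataset, traits,
                 standardize: bool = True, constraints: dict | None = None):
        self.traits = tuple(traits)
        self.param_defs = [ParamDef(n, s, l) for n, s, l in _CL_NAMES]
        v1, v2 = self.traits
        super().__init__(data, [(v1, 1), (v2, 1), (v1, 2), (v2, 2)],
                         standardize, constraints)

    def crosslag_params(self, params: dict[str, float]) -> CrossLagParams:
        g = params.__getitem__
        return CrossLagParams(
            var1_t1=AceParams(g("a_v1_t1"), g("c_v1_t1"), g("e_v1_t1"),
                              g("mu_v1_t1")),
            var2_t1=AceParams(g("a_v2_t1"), g("c_v2_t1"), g("e_v2_t1"),
                              g("mu_v2_t1")),
            latcorr_t1=LatentCorrelations(g("rA_t1"), g("rC_t1"), g("rE_t1")),
            b11=g("b11"), b12=g("b12"), b21=g("b21"), b22=g("b22"),
            var1_res_t2=AceParams(g("a_v1_res"), g("c_v1_res"), g("e_v1_res")),
            var2_res_t2=AceParams(g("a_v2_res"), g("c_v2_res"), g("e_v2_res")),
            latcorr_res_t2=LatentCorrelations(g("rA_res"), g("rC_res"),
                                              g("rE_res")),
            mu_t2=(g("mu_v1_t2"), g("mu_v2_t2")),
        )

    def _implied(self, v):
        params = {d.name: v[i] for i, d in enumerate(self.param_defs)}
        p = self.crosslag_params(params)
        mu, s_mz = implied_moments_crosslag(p, "MZ", validate=False)
        _, s_dz = implied_moments_crosslag(p, "DZ", validate=False)
        return mu, s_mz, s_dz

    def standardize(self, params):
        p = self.crosslag_params(params)
        out = _share_block("_v1_t1", p.var1_t1.a, p.var1_t1.c, p.var1_t1.e)
        out.update(_share_block("_v2_t1", p.var2_t1.a, p.var2_t1.c,
                                p.var2_t1.e))
        out["rA_t1"] = _signed(p.latcorr_t1.ra, p.var1_t1.a, p.var2_t1.a)
        out["rC_t1"] = _signed(p.latcorr_t1.rc, p.var1_t1.c, p.var2_t1.c)
        out["rE_t1"] = _signed(p.latcorr_t1.re, p.var1_t1.e, p.var2_t1.e)
        # standardized lag paths: source t1 SD over target t2 total SD
        _, sigma = implied_moments_crosslag(p, "MZ", validate=False)
        sd = np.sqrt(np.diag(sigma)[:4])  # v1t1, v2t1, v1t2, v2t2
        out["b11"] = params["b11"] * sd[0] / sd[2]
        out["b12"] = params["b12"] * sd[0] / sd[3]
        out["b21"] = params["b21"] * sd[1] / sd[2]
        out["b22"] = params["b22"] * sd[1] / sd[3]
        rep = estimands.time2_total_decomposition(p)
        out.update({
            "share_a_v1_t2": rep.share_a[0], "share_c_v1_t2": rep.share_c[0],
            "share_e_v1_t2": rep.share_e[0],
            "share_a_v2_t2": rep.share_a[1], "share_c_v2_t2": rep.share_c[1],
            "share_e_v2_t2": rep.share_e[1],
            "rA_t2_total": rep.total_corrs.ra, "rC_t2_total": rep.total_corrs.rc,
            "rE_t2_total": rep.total_corrs.re,
        })
        return out


# ---------------------------------------------------------------------------
# saturated baseline
# ---------------------------------------------------------------------------

class SaturatedResults(ResultsBase):
    """Combined per-group free-moments fit."""

    def __init__(self, groups: dict, n_pairs: int, n_observations: int):
        self.groups = groups
        self.minus2ll = float(sum(g["minus2ll"] for g in groups.values()))
        self.n_params = int(sum(g["n_params"] for g in groups.values()))
        self.converged = all(g["converged"] for g in groups.values())
        self.n_pairs = n_pairs
        self.n_observations = n_observations

    def group_moments(self, group: str):
        g = self.groups[group]
        return g["mean"], g["cov"]

    def summary(self) -> str:
        lines = [f"Saturated model: {len(self.groups)} groups, "
                 f"{self.n_params} free parameters",
                 f"-2 log-likelihood: {self.minus2ll:.4f}   BIC: {self.bic:.4f}"]
        for name, g in self.groups.items():
            lines.append(f"  {name}: n={g['n_pairs']}  -2lnL={g['minus2ll']:.4f}"
                         f"  k={g['n_params']}  converged={g['converged']}")
        return "\n".join(lines)


class Saturated:
    """Free means and covariances per group, estimated by FIML.

    ``group_by='zygosity'`` gives the standard two-group baseline;
    ``'zygosity_sex'`` splits further into MZ/DZ same-sex-male,
    same-sex-female, and DZ opposite-sex groups.  Each group contributes
    k means and k(k+1)/2 covariance parameters (a triangular-factor
    parameterization keeps the candidate covariance PSD).
    """

    def __init__(self, data: TwinDataset, var_waves=None,
                 group_by: str = "zygosity", standardize: bool = True):
        self.data = data
        self.var_waves = list(var_waves) if var_waves else data.variables
        self.group_by = group_by
        work = data.zscored(self.var_waves) if standardize else data
        self._groups = self._split(work)
        self.n_pairs = sum(len(y) for y in self._groups.values())
        self.n_observations = int(sum((~np.isnan(y)).sum()
                                      for y in self._groups.values()))

    def _split(self, work: TwinDataset) -> dict[str, np.ndarray]:
        df = work.df
        if self.group_by == "zygosity":
            keys = df["zygosity"]
        elif self.group_by == "zygosity_sex":
            ss = np.where(df["sex1"] == df["sex2"],
                          df["sex1"].astype(str) * 2, "OS")
            keys = df["zygosity"].astype(str) + "_" + ss
        else:
            raise ValueError(f"unknown group_by {self.group_by!r}")
        out = {}
        for key in sorted(keys.unique()):
            sub = work.subset((keys == key).to_numpy())
            y = sub.matrix(self.var_waves)
            if len(y):
                out[key] = y
        return out

    def fit(self, gtol: float = 1e-5, ftol: float = 1e-9,
            maxiter: int = 20000) -> SaturatedResults:
        groups = {}
        for name, y in self._groups.items():
            groups[name] = self._fit_group(name, y, gtol, ftol, maxiter)
        return SaturatedResults(groups, self.n_pairs, self.n_observations)

    def _fit_group(self, name, y, gtol, ftol, maxiter):
        k = y.shape[1]
        n_params = k + k * (k + 1) // 2
        if len(y) < k + 2:
            raise ValueError(
                f"saturated model not identified in group {name!r}: "
                f"{len(y)} pairs for {n_params} parameters")
        stats = pattern_stats(y)
        complete = len(stats) == 1 and stats[0].mask.all()
        if complete:
            # closed-form MLE: sample mean and n-denominator covariance
            mean, cov = stats[0].mean, stats[0].scatter
            m2ll = minus2ll_from_stats(stats, mean, cov)
            return {"mean": mean, "cov": cov, "minus2ll": m2ll,
                    "n_params": n_params, "n_pairs": len(y),
                    "converged": True, "closed_form": True}

        mu0, cov0 = _pairwise_moments(y)
        L0 = np.linalg.cholesky(cov0)
        tril = np.tril_indices(k, -1)

        def build(theta):
            mu = theta[:k]
            L = np.zeros((k, k))
            L[np.diag_indices(k)] = np.exp(theta[k:2 * k])
            L[tril] = theta[2 * k:]
            return mu, L @ L.T

        def obj(theta):
            mu, sigma = build(theta)
            try:
                val = minus2ll_from_stats(stats, mu, sigma)
            except np.linalg.LinAlgError:
                return _PENALTY
            return val if np.isfinite(val) else _PENALTY

        x0 = np.concatenate([mu0, np.log(np.diag(L0)), L0[tril]])
        res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                options={"maxiter": maxiter,
                                         "maxfun": 10 * maxiter,
                                         "ftol": ftol, "gtol": gtol})
        mu, sigma = build(res.x)
        return {"mean": mu, "cov": sigma, "minus2ll": float(res.fun),
                "n_params": n_params, "n_pairs": len(y),
                "converged": bool(res.success), "closed_form": False}


def _pairwise_moments(y: np.ndarray):
    """Pairwise-complete start values, ridge-repaired to positive definite."""
    df = pd.DataFrame(y)
    mu = df.mean().to_numpy()
    cov = df.cov(min_periods=2).to_numpy()
    bad = ~np.isfinite(cov)
    if bad.any():
        cov[bad] = 0.0
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    floor = max(1e-3, 1e-6 * float(w.max())) if w.max() > 0 else 1e-3
    cov = (v * np.maximum(w, floor)) @ v.T
    mu[~np.isfinite(mu)] = 0.0
    return mu, cov
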