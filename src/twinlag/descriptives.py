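"""Descriptive layer: per-sex means and t-tests, phenotypic correlations
on one randomly selected twin per pair, and MZ/DZ twin correlations.

Because co-twins are not independent observations, means, SDs and
phenotypic correlations are computed on one randomly selected member of
each pair; the selection seed is an explicit, logged input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TwinDataset, phenotype_column

__all__ = [
    "select_one_per_pair",
    "CorrelationCI",
    "pearson_with_ci",
    "TTestResult",
    "sex_difference_ttest",
    "TwinCorrelations",
    "twin_correlations",
    "descriptives_table",
    "correlation_table",
    "twin_correlation_table",
]


def select_one_per_pair(data: TwinDataset, seed: int) -> pd.DataFrame:
    """One randomly selected twin per family (seeded fair coin).

    Returns a single-individual table with columns ``famid``,
    ``zygosity``, ``sex``, ``twin`` (1 or 2) and one ``<var>_t<wave>``
    column per phenotype.
    """
    rng = np.random.default_rng(seed)
    pick = rng.integers(1, 3, size=data.n_pairs)  # 1 or 2, fair
    df = data.df
    out = pd.DataFrame({
        "famid": df["famid"].to_numpy(),
        "zygosity": df["zygosity"].to_numpy(),
        "twin": pick,
        "sex": np.where(pick == 1, df["sex1"], df["sex2"]),
    })
    for v, w in data.variables:
        c1 = df[phenotype_column(v, w, 1)].to_numpy(dtype=float)
        c2 = df[phenotype_column(v, w, 2)].to_numpy(dtype=float)
        out[f"{v}_t{w}"] = np.where(pick == 1, c1, c2)
    return out


@dataclass(frozen=True)
class CorrelationCI:
    r: float
    lower: float
    upper: float
    n: int
    level: float
    defined: bool = True


def pearson_with_ci(x, y, level: float = 0.95) -> CorrelationCI:
    """Pearson correlation on pairwise-complete cases with a Fisher-z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 complete cases, got {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationCI(np.nan, np.nan, np.nan, n, level, defined=False)
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return CorrelationCI(r, r, r, n, level)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return CorrelationCI(r, float(np.tanh(z - q * se)),
                         float(np.tanh(z + q * se)), n, level)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int
    levels: tuple[str, str]


def sex_difference_ttest(values, sex_labels,
                         levels: tuple[str, str] = ("M", "F")) -> TTestResult:
    """Pooled-variance two-sample t-test between sexes.

    The statistic is (mean of ``levels[1]`` - mean of ``levels[0]``) /
    pooled SE with df = n1 + n2 - 2, so with the default ordering a
    positive t means females score higher.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex_labels, dtype=object)
    ok = ~np.isnan(values)
    values, sex = values[ok], sex[ok]
    g1 = values[sex == levels[0]]
    g2 = values[sex == levels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"each group needs >= 2 observations (n={len(g1)}, {len(g2)})")
    res = stats.ttest_ind(g2, g1, equal_var=True)
    df = len(g1) + len(g2) - 2
    return TTestResult(
        t=float(res.statistic), df=int(df), p_value=float(res.pvalue),
        mean_1=float(g1.mean()), sd_1=float(g1.std(ddof=1)), n_1=len(g1),
        mean_2=float(g2.mean()), sd_2=float(g2.std(ddof=1)), n_2=len(g2),
        levels=levels)


@dataclass(frozen=True)
class TwinCorrelations:
    r_mz: float
    r_dz: float
    n_mz: int
    n_dz: int
    defined: bool = True


def twin_correlations(data: TwinDataset, variable: str,
                      wave: int = 1) -> TwinCorrelations:
    """Cross-twin Pearson correlations per zygosity group (double entry).

    Each complete pair contributes both orderings (twin1-twin2 and
    twin2-twin1) so the estimate is invariant to twin labelling.  If
    either group has fewer than 4 complete pairs the result is flagged
    undefined (NaN correlations).
    """
    out = {}
    ns = {}
    defined = True
    for z in ("MZ", "DZ"):
        sub = data.df[data.df["zygosity"] == z]
        x = sub[phenotype_column(variable, wave, 1)].to_numpy(dtype=float)
        y = sub[phenotype_column(variable, wave, 2)].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        ns[z] = len(x)
        if len(x) < 4:
            out[z] = np.nan
            defined = False
            continue
        xx = np.concatenate([x, y])
        yy = np.concatenate([y, x])
        if np.std(xx) == 0:
            out[z] = np.nan
            defined = False
        else:
            out[z] = float(np.corrcoef(xx, yy)[0, 1])
    return TwinCorrelations(r_mz=out["MZ"], r_dz=out["DZ"],
                            n_mz=ns["MZ"], n_dz=ns["DZ"], defined=defined)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def descriptives_table(data: TwinDataset, seed: int) -> pd.DataFrame:
    """Per-variable descriptive statistics with sex-difference t-tests.

    One row per (variable, wave): N individuals, overall and per-sex
    mean (SD), pooled t, df and two-sided p.  Computed on one randomly
    selected twin per pair.
    """
    single = select_one_per_pair(data, seed)
    rows = []
    for v, w in data.variables:
        col = single[f"{v}_t{w}"]
        ok = ~col.isna()
        vals = col[ok].to_numpy()
        sex = single.loc[ok, "sex"].to_numpy()
        tt = sex_difference_ttest(vals, sex)
        rows.append({
            "variable": v, "wave": w, "n": int(ok.sum()),
            "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)),
            "mean_male": tt.mean_1, "sd_male": tt.sd_1,
            "mean_female": tt.mean_2, "sd_female": tt.sd_2,
            "t": tt.t, "df": tt.df, "p_value": tt.p_value,
        })
    return pd.DataFrame(rows)


def correlation_table(data: TwinDataset, seed: int,
                      level: float = 0.95) -> pd.DataFrame:
    """All pairwise phenotypic correlations on one twin per pair."""
    single = select_one_per_pair(data, seed)
    vws = data.variables
    rows = []
    for i, (v1, w1) in enumerate(vws):
        for v2, w2 in vws[i + 1:]:
            ci = pearson_with_ci(single[f"{v1}_t{w1}"], single[f"{v2}_t{w2}"],
                                 level=level)
            rows.append({"var_a": v1, "wave_a": w1, "var_b": v2, "wave_b": w2,
                         "n": ci.n, "r": ci.r, "ci_lower": ci.lower,
                         "ci_upper": ci.upper})
    return pd.DataFrame(rows)


def twin_correlation_table(data: TwinDataset) -> pd.DataFrame:
    """MZ and DZ cross-twin correlations for every variable and wave."""
    rows = []
    for v, w in data.variables:
        tc = twin_correlations(data, v, wave=w)
        rows.append({"variable": v, "wave": w, "r_mz": tc.r_mz,
                     "r_dz": tc.r_dz, "n_mz": tc.n_mz, "n_dz": tc.n_dz})
    return pd.DataFrame(rows)
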