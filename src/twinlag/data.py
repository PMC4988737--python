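"""The wide per-pair twin dataset container.

One row per twin pair.  Metadata columns: ``famid``, ``zygosity`` (MZ or
DZ), ``sex1``, ``sex2`` (M/F per twin).  Phenotype columns follow the
naming convention ``<variable>_t<wave>_tw<twin>`` with wave in {1, 2}
and twin in {1, 2}; missing values are NaN.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["TwinDataset", "META_COLUMNS", "phenotype_column"]

META_COLUMNS = ["famid", "zygosity", "sex1", "sex2"]

_PHENO_RE = re.compile(r"^(?P<var>.+)_t(?P<wave>[12])_tw(?P<twin>[12])$")

_SEX_TOKENS = {"m": "M", "male": "M", "f": "F", "female": "F", "m ": "M"}


def phenotype_column(var: str, wave: int, twin: int) -> str:
    return f"{var}_t{wave}_tw{twin}"


def _normalize_sex(s):
    if pd.isna(s):
        return np.nan
    return _SEX_TOKENS.get(str(s).strip().lower(), str(s).strip().upper())


class TwinDataset:
    """Per-pair phenotype records with zygosity, sex, and missingness.

    Parameters
    ----------
    df : pandas.DataFrame
        Wide table, one row per pair.  Validated on construction:
        unique ``famid``, zygosity in {MZ, DZ} (case-insensitive), and at
        least one phenotype value per retained row.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        missing_meta = [c for c in META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise ValueError(f"missing metadata columns: {missing_meta}")
        df["zygosity"] = df["zygosity"].astype(str).str.strip().str.upper()
        for col in ("sex1", "sex2"):
            df[col] = df[col].map(_normalize_sex)
        self.df = df.reset_index(drop=True)
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------

    def _validate(self) -> None:
        errors = []
        bad_zyg = ~self.df["zygosity"].isin(["MZ", "DZ"])
        if bad_zyg.any():
            rows = self.df.index[bad_zyg].tolist()[:10]
            toks = self.df.loc[bad_zyg, "zygosity"].unique().tolist()
            errors.append(f"unknown zygosity tokens {toks} at rows {rows}")
        dup = self.df["famid"][self.df["famid"].duplicated()]
        if len(dup):
            errors.append(f"duplicate famid values: {sorted(set(dup))[:10]}")
        pcols = self.phenotype_columns
        if pcols and len(self.df):
            empty = self.df[pcols].isna().all(axis=1)
            if empty.any():
                errors.append(
                    f"{int(empty.sum())} rows have no phenotype values "
                    f"(rows {self.df.index[empty].tolist()[:10]})"
                )
        if errors:
            raise ValueError("invalid twin table: " + "; ".join(errors))

    # -- basic properties ----------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.df)

    @property
    def phenotype_columns(self) -> list[str]:
        return [c for c in self.df.columns if _PHENO_RE.match(c)]

    @property
    def variables(self) -> list[tuple[str, int]]:
        """Ordered unique (variable, wave) combinations present."""
        seen: list[tuple[str, int]] = []
        for c in self.df.columns:
            m = _PHENO_RE.match(c)
            if m:
                key = (m.group("var"), int(m.group("wave")))
                if key not in seen:
                    seen.append(key)
        return seen

    def zygosity_counts(self) -> dict[str, int]:
        vc = self.df["zygosity"].value_counts()
        return {z: int(vc.get(z, 0)) for z in ("MZ", "DZ")}

    # -- numeric extraction --------------------------------------------

    def matrix(self, var_waves: Sequence[tuple[str, int]]) -> np.ndarray:
        """Stacked pair array: twin-1 columns for each (var, wave), then twin-2."""
        cols = [phenotype_column(v, w, tw) for tw in (1, 2) for v, w in var_waves]
        missing = [c for c in cols if c not in self.df.columns]
        if missing:
            raise KeyError(f"phenotype columns not in dataset: {missing}")
        return self.df[cols].to_numpy(dtype=float)

    def split_zygosity(self, var_waves: Sequence[tuple[str, int]]):
        """{'MZ': array, 'DZ': array} of pair matrices (groups may be empty)."""
        out = {}
        for z in ("MZ", "DZ"):
            sub = self.df[self.df["zygosity"] == z]
            cols = [phenotype_column(v, w, tw) for tw in (1, 2) for v, w in var_waves]
            out[z] = sub[cols].to_numpy(dtype=float)
        return out

    # -- transforms ------------------------------------------------------

    def zscored(self, var_waves: Iterable[tuple[str, int]] | None = None) -> "TwinDataset":
        """Z-score each variable per wave, pooling both twins.

        The mean and SD are computed over all non-missing values of the
        two twin columns jointly, so co-twins stay on a common scale.
        """
        df = self.df.copy()
        targets = list(var_waves) if var_waves is not None else self.variables
        for v, w in targets:
            cols = [phenotype_column(v, w, tw) for tw in (1, 2)]
            vals = df[cols].to_numpy(dtype=float)
            m = np.nanmean(vals)
            s = np.nanstd(vals)
            if not np.isfinite(s) or s == 0:
                raise ValueError(f"cannot z-score {v} wave {w}: zero variance")
            df[cols] = (vals - m) / s
        return TwinDataset(df, validate=False)

    def rank_inverse_normal(self, var_waves: Iterable[tuple[str, int]] | None = None,
                            offset: float = 3.0 / 8.0) -> "TwinDataset":
        """Rank-based inverse-normal transform (Blom offset by default).

        Offered for sensitivity analyses with skewed questionnaire
        scores; the default pipeline z-scores only.
        """
        from scipy.stats import norm, rankdata

        df = self.df.copy()
        targets = list(var_waves) if var_waves is not None else self.variables
        for v, w in targets:
            cols = [phenotype_column(v, w, tw) for tw in (1, 2)]
            vals = df[cols].to_numpy(dtype=float)
            flat = vals.ravel()
            obs = ~np.isnan(flat)
            n = obs.sum()
            ranks = rankdata(flat[obs])
            flat[obs] = norm.ppf((ranks - offset) / (n - 2 * offset + 1))
            df[cols] = flat.reshape(vals.shape)
        return TwinDataset(df, validate=False)

    def subset(self, mask) -> "TwinDataset":
        return TwinDataset(self.df[np.asarray(mask)], validate=False)

    def same_sex_pairs(self, sex: str | None = None) -> "TwinDataset":
        """Pairs whose members share a sex (optionally a specific one)."""
        m = self.df["sex1"] == self.df["sex2"]
        if sex is not None:
            m &= self.df["sex1"] == _normalize_sex(sex)
        return self.subset(m.to_numpy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        zc = self.zygosity_counts()
        vws = ", ".join(f"{v}@t{w}" for v, w in self.variables)
        return (f"<TwinDataset n_pairs={self.n_pairs} "
                f"MZ={zc['MZ']} DZ={zc['DZ']} variables=[{vws}]>")
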