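"""Readers, writers, configuration and the analysis pipeline.

The data format is a wide per-pair CSV: one row per family with columns
``famid, zygosity, sex1, sex2`` followed by phenotype columns named
``<var>_t<wave>_tw<twin>``.  Empty cells are missing values.  The config
file is YAML; pipeline results are written as a flat JSON file plus
human-readable tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import bic, equate_paths_test, likelihood_ratio_test
from .data import META_COLUMNS, TwinDataset, phenotype_column
from .descriptives import (correlation_table, descriptives_table,
                           twin_correlation_table)
from .models import BivariateACE, CrossLagACE, Saturated, UnivariateACE

__all__ = ["TwinTableError", "read_twin_table", "write_twin_table",
           "read_config", "write_params_sidecar", "read_params_sidecar",
           "run_pipeline"]


class TwinTableError(ValueError):
    """Itemized validation failure while reading a twin table."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid twin table:\n  " + "\n  ".join(self.problems))


def read_twin_table(path, required_columns=None) -> TwinDataset:
    """Read and validate a wide per-pair CSV.

    Zygosity tokens are case-insensitive {MZ, DZ}; empty cells become
    missing values.  Duplicate famids, unknown zygosity tokens and
    non-numeric phenotype cells raise a :class:`TwinTableError` naming
    the offending rows.  A per-read validation report (dropped or
    flagged rows) is attached as ``dataset.validation``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    problems = []
    missing = [c for c in META_COLUMNS if c not in raw.columns]
    if missing:
        raise TwinTableError([f"missing required columns: {missing}"])
    if required_columns:
        absent = [c for c in required_columns if c not in raw.columns]
        if absent:
            raise TwinTableError([f"missing declared columns: {absent}"])

    zyg = raw["zygosity"].astype(str).str.strip().str.upper()
    bad = ~zyg.isin(["MZ", "DZ"])
    for idx in raw.index[bad]:
        problems.append(f"row {idx + 2}: unknown zygosity token "
                        f"{raw.loc[idx, 'zygosity']!r}")
    dup = raw["famid"][raw["famid"].duplicated(keep=False)]
    if len(dup):
        for famid in sorted(set(dup)):
            rows = (raw.index[raw['famid'] == famid] + 2).tolist()
            problems.append(f"duplicate famid {famid!r} at rows {rows}")

    pheno_cols = [c for c in raw.columns if c not in META_COLUMNS]
    parsed = {}
    for c in pheno_cols:
        num = pd.to_numeric(raw[c], errors="coerce")
        bad_cells = num.isna() & raw[c].notna() & (raw[c].str.strip() != "")
        for idx in raw.index[bad_cells]:
            problems.append(f"row {idx + 2}: non-numeric value "
                            f"{raw.loc[idx, c]!r} in column {c!r}")
        parsed[c] = num
    if problems:
        raise TwinTableError(problems)

    df = raw[META_COLUMNS].copy()
    for c, num in parsed.items():
        df[c] = num
    report = []
    if pheno_cols:
        empty = df[pheno_cols].isna().all(axis=1)
        if empty.any():
            report.append(f"dropped {int(empty.sum())} rows with no "
                          f"phenotype values")
            df = df[~empty]
    data = TwinDataset(df)
    data.validation = report
    return data


def write_twin_table(data: TwinDataset, path) -> None:
    """Write the wide per-pair CSV (empty cells for missing values)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.df.to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_params_sidecar(truth: dict, path) -> None:
    """Store generating parameters next to a simulated dataset."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=False)


def read_params_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_MODEL_KINDS = {"univariate", "bivariate", "crosslag"}


def _build_model(kind: str, data: TwinDataset, spec: dict):
    constraints = spec.get("constraints") or {}
    if kind == "univariate":
        return UnivariateACE(data, trait=spec["trait"],
                             wave=int(spec.get("wave", 1)),
                             constraints=constraints)
    if kind == "bivariate":
        return BivariateACE(data, traits=spec["traits"],
                            wave=int(spec.get("wave", 1)),
                            constraints=constraints)
    if kind == "crosslag":
        return CrossLagACE(data, traits=spec["traits"],
                           constraints=constraints)
    raise ValueError(f"unknown model kind {kind!r} (one of {_MODEL_KINDS})")


def _results_record(res) -> dict:
    rec = {
        "estimates": res.params,
        "standardized": res.standardized(),
        "minus2ll": res.minus2ll,
        "n_params": res.n_params,
        "n_pairs": res.n_pairs,
        "n_observations": res.n_observations,
        "bic": res.bic,
        "converged": res.converged,
        "gradient_norm": res.gradient_norm,
    }
    if res.ci:
        rec["ci"] = {k: [v.lower, v.upper] for k, v in res.ci.items()}
    return rec


def run_pipeline(config: dict | str | Path, data: TwinDataset | None = None) -> dict:
    """Run the full analysis sequence described by a config.

    Stages (each optional): descriptives; saturated baseline per
    zygosity group; structured models with constraints; LRT + BIC
    against the saturated model; path-equating tests; derived estimand
    reports.  Any stage failure is recorded in ``bundle['failures']``
    and the remaining stages still run.  Writes ``results.json`` and
    tables under ``out_dir`` when configured.
    """
    if not isinstance(config, dict):
        config = read_config(config)
    seed = int(config.get("seed", 0))
    bundle: dict = {"config": _plain(config), "seed": seed,
                    "version": __version__, "failures": []}

    if data is None:
        data = read_twin_table(config["data"])
    bundle["n_pairs"] = data.n_pairs
    bundle["zygosity_counts"] = data.zygosity_counts()

    if config.get("descriptives", True):
        try:
            bundle["descriptives"] = {
                "table1": descriptives_table(data, seed).to_dict("records"),
                "correlations": correlation_table(
                    data, seed, level=float(config.get("ci_level", 0.95))
                ).to_dict("records"),
                "twin_correlations":
                    twin_correlation_table(data).to_dict("records"),
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation
            bundle["failures"].append({"stage": "descriptives",
                                       "error": str(exc)})

    fit_kw = dict(config.get("fit", {}))
    fit_kw.setdefault("seed", seed)

    saturated = None
    saturated_vars = None
    if config.get("comparisons", {}).get("saturated", False):
        try:
            var_waves = None
            models_cfg = config.get("models", [])
            cl = next((m for m in models_cfg if m["kind"] == "crosslag"), None)
            if cl:
                v1, v2 = cl["traits"]
                var_waves = [(v1, 1), (v2, 1), (v1, 2), (v2, 2)]
            saturated = Saturated(data, var_waves=var_waves).fit()
            saturated_vars = set(var_waves or data.variables)
            bundle["saturated"] = {
                "minus2ll": saturated.minus2ll,
                "n_params": saturated.n_params,
                "bic": saturated.bic,
                "converged": saturated.converged,
            }
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"stage": "saturated", "error": str(exc)})

    bundle["models"] = {}
    fitted = {}
    for spec in config.get("models", []):
        kind = spec["kind"]
        name = spec.get("name", kind)
        try:
            model = _build_model(kind, data, spec)
            res = model.fit(**fit_kw)
            rec = _results_record(res)
            if kind == "bivariate":
                dec = model.decomposition(res.params)
                rec["decomposition"] = {
                    "r_ph": dec.r_ph, "prop_a": dec.prop_a,
                    "prop_c": dec.prop_c, "prop_e": dec.prop_e,
                }
            # the LRT against the saturated baseline only makes sense for
            # models of the same variable set
            if saturated is not None and set(model.var_waves) == saturated_vars:
                cmp_ = likelihood_ratio_test(res, saturated)
                rec["vs_saturated"] = {"chi2": cmp_.chi2, "df": cmp_.df,
                                       "p_value": cmp_.p_value,
                                       "bic_model": cmp_.bic_a,
                                       "bic_saturated": cmp_.bic_b}
            fitted[name] = (model, res)
            bundle["models"][name] = rec
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"stage": f"model:{name}",
                                       "error": str(exc)})

    for pair in config.get("comparisons", {}).get("equate", []):
        path_a, path_b = pair
        target = next((nm for nm, (m, _) in fitted.items()
                       if {path_a, path_b} <= {d.name for d in m.param_defs}),
                      None)
        key = f"equate_{path_a}_{path_b}"
        if target is None:
            bundle["failures"].append({"stage": key,
                                       "error": "no fitted model has both paths"})
            continue
        try:
            model, _ = fitted[target]
            eq = equate_paths_test(model, path_a, path_b, **fit_kw)
            bundle.setdefault("equate_tests", {})[key] = {
                "model": target, "chi2": eq.comparison.chi2,
                "df": eq.comparison.df, "p_value": eq.comparison.p_value,
            }
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"stage": key, "error": str(exc)})

    truth_path = config.get("truth")
    if truth_path:
        try:
            truth = read_params_sidecar(truth_path)
            recov = {}
            tvals = truth.get("standardized", truth)
            for name, rec in bundle["models"].items():
                deltas = {k: rec["standardized"][k] - float(v)
                          for k, v in tvals.items()
                          if k in rec["standardized"]
                          and isinstance(v, (int, float))}
                if deltas:
                    recov[name] = deltas
            bundle["recovery_deltas"] = recov
        except Exception as exc:  # noqa: BLE001
            bundle["failures"].append({"stage": "recovery", "error": str(exc)})

    out_dir = config.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(_plain(bundle), fh, indent=2, sort_keys=True)
        if "descriptives" in bundle:
            pd.DataFrame(bundle["descriptives"]["table1"]).to_csv(
                out / "descriptives.csv", index=False)
            pd.DataFrame(bundle["descriptives"]["correlations"]).to_csv(
                out / "correlations.csv", index=False)
    return bundle
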