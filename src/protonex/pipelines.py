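"""Analysis pipelines: inventory tables, eigenrate sweeps, fit runs, comparisons.

These functions take and return pandas DataFrames and plain dataclasses; the
command-line interface in :mod:`protonex.cli` is a thin wrapper around them.
All randomness flows through explicit seeds so a full pipeline run is
byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .composition import (
    MixtureSpec,
    SUCROSE,
    proton_inventory,
    sucrose_solution_density,
)
from .exchange import ExchangePair, fast_exchange_approx, longitudinal_eigenrates
from .fitting import DecayCurve, FitConfig, FitResult, fit_curve, replicate_stats
from .synth import SeriesSpec, scenario_mixture

__all__ = [
    "RunConfig",
    "load_run_config",
    "mixture_grid",
    "inventory_table",
    "sweep_table",
    "read_decay_csv",
    "write_decay_csv",
    "fit_run",
    "fit_summary_table",
    "compare_table",
]

INVENTORY_COLUMNS = [
    "wt_percent", "solvent", "A_tot", "B_tot", "C_nonexch",
    "x_A", "x_B", "xp_exch", "xp_non",
]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (parsed from YAML/JSON)."""

    scenarios: List[str] = field(default_factory=lambda: ["H2O", "D2O", "FD-D2O"])
    wt_percent_grid: List[float] = field(default_factory=lambda: list(range(5, 70, 5)))
    k_ex_grid: List[float] = field(default_factory=lambda: list(np.geomspace(1e-5, 1e-1, 17)))
    fit: FitConfig = field(default_factory=FitConfig)
    output_dir: Optional[str] = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not self.scenarios or not self.wt_percent_grid or not self.k_ex_grid:
            raise ValueError("scenario, wt% and k_ex grids must be nonempty")


def load_run_config(path: Union[str, Path]) -> RunConfig:
    """Read a RunConfig from a YAML (or JSON) file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fit_kwargs = raw.pop("fit", {})
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in RunConfig.__dataclass_fields__})
    if fit_kwargs:
        cfg.fit = FitConfig(**fit_kwargs)
    return cfg


def load_mixtures(path: Union[str, Path]) -> List[MixtureSpec]:
    """Read a MixtureSpec collection from a YAML/JSON file.

    The file holds a list of records with keys ``wt_percent`` and ``solvent``
    plus optional ``solvent_protiation``, ``solute_site_protiation``,
    ``density`` and ``temperature``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"{path}: expected a nonempty list of mixture records")
    mixes = []
    for rec in raw:
        rec = dict(rec)
        if "wt_percent" not in rec:
            raise ValueError(f"{path}: mixture record missing wt_percent: {rec}")
        mixes.append(MixtureSpec(
            solute_wt_fraction=float(rec.pop("wt_percent")) / 100.0,
            solvent_kind=rec.pop("solvent", "H2O"),
            **rec,
        ))
    return mixes


def mixture_grid(
    wt_percents: Sequence[float], scenario: str, with_density: bool = True
) -> List[MixtureSpec]:
    """MixtureSpecs over a wt% grid for one solvent scenario."""
    if len(wt_percents) == 0:
        raise ValueError("empty wt% grid")
    mixes = [scenario_mixture(float(w), scenario) for w in wt_percents]
    if not with_density:
        from dataclasses import replace
        mixes = [replace(m, density=None) for m in mixes]
    return mixes


def inventory_table(
    wt_percents: Sequence[float],
    scenarios: Sequence[str] = ("H2O", "D2O", "FD-D2O"),
) -> pd.DataFrame:
    """Proton-inventory table over a concentration grid, one row per mixture."""
    rows = []
    for scenario in scenarios:
        for mix, wt in zip(mixture_grid(wt_percents, scenario), wt_percents):
            inv = proton_inventory(mix, SUCROSE)
            rows.append({
                "wt_percent": float(wt), "solvent": scenario,
                "A_tot": inv.A_tot, "B_tot": inv.B_tot, "C_nonexch": inv.C_nonexch,
                "x_A": inv.x_A, "x_B": inv.x_B,
                "xp_exch": inv.xp_exch, "xp_non": inv.xp_non,
            })
    return pd.DataFrame(rows, columns=INVENTORY_COLUMNS)


def sweep_table(
    k_ex_grid: Sequence[float],
    wt_percents: Sequence[float],
    scenario: str = "H2O",
    R1_A: float = 1.0 / 3.0,
    R1_B: float = 1.0 / 1.2,
) -> pd.DataFrame:
    """Exact vs fast-exchange 1/lambda landscape over (k_ex, composition).

    Columns: ``kex, wt_percent, x_B, inv_lambda1, inv_lambda2,
    inv_lambda1_approx, inv_lambda2_approx``. Times are in seconds.
    """
    if len(k_ex_grid) == 0 or len(wt_percents) == 0:
        raise ValueError("k_ex and wt% grids must be nonempty")
    rows = []
    for wt in wt_percents:
        inv = proton_inventory(scenario_mixture(float(wt), scenario), SUCROSE)
        for kex in k_ex_grid:
            pair = ExchangePair.from_inventory(inv, R1_A=R1_A, R1_B=R1_B, k_ex=float(kex))
            l1, l2 = longitudinal_eigenrates(pair)
            approx = fast_exchange_approx(pair)
            rows.append({
                "kex": float(kex), "wt_percent": float(wt), "x_B": inv.x_B,
                "inv_lambda1": 1.0 / l1 if l1 > 0 else np.inf,
                "inv_lambda2": 1.0 / l2 if l2 > 0 else np.inf,
                "inv_lambda1_approx": 1.0 / approx.lambda1 if approx.lambda1 > 0 else np.inf,
                "inv_lambda2_approx": 1.0 / approx.lambda2 if approx.lambda2 > 0 else np.inf,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# decay-curve IO and fit runs
# ---------------------------------------------------------------------------

def write_decay_csv(curve: DecayCurve, path: Union[str, Path]) -> None:
    """Write a decay curve as CSV with columns time_s, signal, replicate."""
    pd.DataFrame({
        "time_s": curve.times, "signal": curve.signal,
        "replicate": curve.replicate_id,
    }).to_csv(path, index=False)


def read_decay_csv(
    path: Union[str, Path], experiment: str, metadata: Optional[dict] = None
) -> List[DecayCurve]:
    """Read decay curves from a CSV (columns time_s, signal, replicate)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"time_s", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: decay CSV needs columns {sorted(required)} (header required)")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    curves = []
    for rep, grp in df.groupby("replicate"):
        grp = grp.sort_values("time_s")
        curves.append(DecayCurve(
            times=grp["time_s"].to_numpy(), signal=grp["signal"].to_numpy(),
            experiment=experiment, replicate_id=int(rep),
            metadata=dict(metadata or {}),
        ))
    return curves


def fit_run(
    curves: Sequence[DecayCurve],
    config: FitConfig = FitConfig(model_order="bi"),
    verbose: bool = False,
) -> List[FitResult]:
    """Fit every curve; one log line per curve when verbose."""
    if len(curves) == 0:
        raise ValueError("no curves to fit")
    results = []
    for curve in curves:
        res = fit_curve(curve, config)
        if verbose:
            meta = curve.metadata
            print(
                f"[fit] {meta.get('scenario', '?')} {meta.get('wt_percent', '?')} wt% "
                f"rep{curve.replicate_id} {curve.experiment}: order={res.model_order} "
                f"R2={res.r_squared:.5f} converged={res.converged}"
            )
        results.append(res)
    return results


def fit_summary_table(
    curves: Sequence[DecayCurve], results: Sequence[FitResult]
) -> pd.DataFrame:
    """Replicate-aggregated summary, one row per (scenario, wt%, experiment).

    Time constants are reported in ms; coefficients are the normalized
    amplitudes. Replicate spread is the standard deviation across fits.
    """
    if len(curves) != len(results):
        raise ValueError("curves and results must align")
    if len(curves) == 0:
        raise ValueError("empty fit set")
    groups: Dict[tuple, List[int]] = {}
    for i, c in enumerate(curves):
        key = (c.metadata.get("scenario", ""), c.metadata.get("wt_percent", np.nan), c.experiment)
        groups.setdefault(key, []).append(i)
    rows = []
    for (scenario, wt, experiment), idx in groups.items():
        fits = [results[i] for i in idx]
        if len(fits) >= 2:
            stats = replicate_stats(fits)
        else:
            stats = {
                name: (getattr(fits[0], name), 0.0)
                for name in ("a_slow", "a_fast", "T_slow", "T_fast", "y0")
                if getattr(fits[0], name) is not None
            }
        row = {
            "scenario": scenario, "wt_percent": wt, "experiment": experiment,
            "n_replicates": len(fits),
            "R2": float(np.mean([f.r_squared for f in fits])),
            "RMSE": float(np.mean([f.rmse for f in fits])),
        }
        for name, (mean, sd) in stats.items():
            if name.startswith("T"):
                row[f"{name}_ms"] = mean * 1e3
                row[f"{name}_ms_sd"] = sd * 1e3
            else:
                row[name] = mean
                row[f"{name}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["scenario", "experiment", "wt_percent"]).reset_index(drop=True)


def compare_table(
    fit_summary: pd.DataFrame, inventory: pd.DataFrame
) -> pd.DataFrame:
    """Join fitted coefficients with predicted proton fractions.

    Matches rows on (scenario, wt_percent) and reports the deviation of the
    fitted fast coefficient from the predicted nonexchangeable fraction (and
    slow vs exchangeable), plus per-scenario mean absolute deviations in the
    DataFrame attrs (``mad_fast`` / ``mad_slow`` keyed by scenario).
    """
    if fit_summary.empty:
        raise ValueError("empty fit summary")
    inv = inventory.rename(columns={"solvent": "scenario"})
    merged = fit_summary.merge(inv, on=["scenario", "wt_percent"], how="left")
    if merged["xp_non"].isna().any():
        missing = merged.loc[merged["xp_non"].isna(), ["scenario", "wt_percent"]]
        raise KeyError(f"no inventory rows for samples:\n{missing.to_string(index=False)}")
    merged["dev_fast"] = merged["a_fast"] - merged["xp_non"]
    merged["dev_slow"] = merged["a_slow"] - merged["xp_exch"]
    merged.attrs["mad_fast"] = merged.groupby("scenario")["dev_fast"].apply(
        lambda s: float(np.mean(np.abs(s)))).to_dict()
    merged.attrs["mad_slow"] = merged.groupby("scenario")["dev_slow"].apply(
        lambda s: float(np.mean(np.abs(s)))).to_dict()
    return merged


def fit_results_to_json(
    curves: Sequence[DecayCurve], results: Sequence[FitResult], path: Union[str, Path]
) -> None:
    """Dump per-curve fit records (all FitResult fields) as JSON."""
    records = []
    for curve, res in zip(curves, results):
        rec = {
            k: v for k, v in asdict(res).items() if k != "residuals"
        }
        rec["ci"] = {k: list(v) for k, v in res.ci.items()}
        rec["metadata"] = curve.metadata
        rec["replicate_id"] = curve.replicate_id
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=1, default=float))
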