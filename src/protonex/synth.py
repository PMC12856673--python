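"""Model-faithful synthetic relaxation data.

Emulates time-domain NMR measurements on sucrose–water preparations in three
solvent scenarios — H2O, D2O, and freeze-dried (pre-deuterated) sucrose
redissolved in D2O — by composing the two-pool exchange signal with the
additive nonexchangeable-proton component, on the standard acquisition grids
(32 log-spaced saturation-recovery delays from 4 ms to 30 s; CPMG echo trains
of up to 3000 echoes at 300–3000 us inter-pulse spacing), with additive
Gaussian noise and full seed reproducibility.

The per-concentration relaxation rates of the pools are free inputs of the
model; the default profiles here are smooth monotone-decreasing relaxation
times chosen to bracket the ranges typical of aqueous sugar solutions at room
temperature. They are a plausible stand-in, not measured values, and every
quantitative test in this package is designed not to depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .composition import (
    MixtureSpec,
    ProtonInventory,
    SUCROSE,
    freeze_dry_exchange,
    proton_inventory,
    sucrose_solution_density,
)
from .exchange import ExchangePair, observed_signal
from .fitting import DecayCurve

__all__ = [
    "NoiseModel",
    "Acquisition",
    "SeriesSpec",
    "RateSet",
    "default_rate_model",
    "scenario_mixture",
    "simulate_decay",
    "simulate_series",
    "RECOVERY_GRID",
    "cpmg_grid",
    "DEFAULT_K_EX",
]

#: Default second-order exchange rate constant, s^-1 mol^-1 m^3 (upper end of
#: the intermediate regime for water-carbohydrate proton exchange).
DEFAULT_K_EX = 1e-2

#: 32 log-spaced saturation-recovery delays, 4 ms to 30 s.
RECOVERY_GRID = np.geomspace(4e-3, 30.0, 32)


def cpmg_grid(tau: float = 1e-3, n_echoes: int = 3000) -> np.ndarray:
    """CPMG echo times ``2*tau*k`` for ``k = 1..n_echoes`` (tau in s)."""
    if not 300e-6 <= tau <= 3000e-6:
        raise ValueError("inter-pulse spacing tau must lie in [300, 3000] us")
    if n_echoes < 1:
        raise ValueError("need at least one echo")
    return 2.0 * tau * np.arange(1, n_echoes + 1)


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise, sigma as a fraction of the signal maximum."""

    sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class Acquisition:
    """Time-grid descriptor for one experiment kind."""

    experiment: str = "saturation_recovery"
    n_points: int = 32
    t_min: float = 4e-3
    t_max: float = 30.0
    tau: float = 1e-3  # CPMG inter-pulse spacing, s
    n_echoes: int = 1500

    def grid(self) -> np.ndarray:
        if self.experiment == "saturation_recovery":
            return np.geomspace(self.t_min, self.t_max, self.n_points)
        if self.experiment == "cpmg":
            return cpmg_grid(self.tau, self.n_echoes)
        raise ValueError(f"unknown experiment {self.experiment!r}")


@dataclass(frozen=True)
class RateSet:
    """Relaxation rates (s^-1) of the three proton classes at one composition."""

    R1_A: float  # solvent exchangeable pool
    R1_B: float  # solute hydroxyl pool
    R2_A: float
    R2_B: float
    R1_non: float  # carbon-bound solute protons
    R2_non: float


def default_rate_model(wt_percent: float, scenario: str = "H2O") -> RateSet:
    """Smooth monotone-decreasing relaxation-time profiles vs sucrose content.

    Relaxation times shorten with increasing sucrose (rising viscosity); the
    nonexchangeable pool relaxes markedly faster than the exchangeable pools at
    every composition, which is what makes the two contributions resolvable.
    """
    p = wt_percent
    T1_A = 3.0 * np.exp(-0.023 * p)
    T1_B = 1.2 * np.exp(-0.015 * p)
    T2_A = 1.5 * np.exp(-0.030 * p)
    T2_B = 0.5 * np.exp(-0.020 * p)
    T1_non = 0.30 * np.exp(-0.010 * p)
    T2_non = 0.06 * np.exp(-0.008 * p)
    return RateSet(
        R1_A=1.0 / T1_A, R1_B=1.0 / T1_B,
        R2_A=1.0 / T2_A, R2_B=1.0 / T2_B,
        R1_non=1.0 / T1_non, R2_non=1.0 / T2_non,
    )


@dataclass(frozen=True)
class SeriesSpec:
    """A simulated concentration series for one solvent scenario."""

    wt_percent_grid: Sequence[float] = tuple(range(5, 70, 5))
    scenario: str = "H2O"  # "H2O" | "D2O" | "FD-D2O"
    k_ex: float = DEFAULT_K_EX
    rate_model: Callable[[float, str], RateSet] = default_rate_model
    acquisitions: Sequence[Acquisition] = (
        Acquisition("saturation_recovery"),
        Acquisition("cpmg"),
    )
    noise: NoiseModel = NoiseModel()
    replicates: int = 3

    def __post_init__(self) -> None:
        if len(self.wt_percent_grid) == 0:
            raise ValueError("wt_percent_grid must be nonempty")
        if self.scenario not in ("H2O", "D2O", "FD-D2O"):
            raise ValueError("scenario must be 'H2O', 'D2O' or 'FD-D2O'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def scenario_mixture(wt_percent: float, scenario: str) -> MixtureSpec:
    """MixtureSpec for one point of a scenario series.

    FD-D2O solutes carry the labile-site H occupancy equilibrated in a
    20 wt% sucrose / 80 wt% D2O solution prior to freeze-drying.
    """
    density = sucrose_solution_density(wt_percent)
    w = wt_percent / 100.0
    if scenario == "H2O":
        return MixtureSpec(w, "H2O", density=density)
    if scenario == "D2O":
        return MixtureSpec(w, "D2O", density=density)
    stage1 = MixtureSpec(0.20, "D2O")
    occupancy = freeze_dry_exchange(stage1)
    return MixtureSpec(w, "D2O", solute_site_protiation=occupancy, density=density)


def _pair_for(inv: ProtonInventory, rates: RateSet, k_ex: float) -> ExchangePair:
    return ExchangePair.from_inventory(
        inv, R1_A=rates.R1_A, R1_B=rates.R1_B, R2_A=rates.R2_A, R2_B=rates.R2_B,
        k_ex=k_ex,
    )


def simulate_decay(
    pair: ExchangePair,
    experiment: str = "saturation_recovery",
    acquisition: Optional[Acquisition] = None,
    noise: Optional[NoiseModel] = None,
    nonexch_rate: float = 0.0,
    nonexch_fraction: float = 0.0,
    replicate_id: int = 0,
    metadata: Optional[dict] = None,
) -> DecayCurve:
    """Simulate one decay curve from the exchange model.

    The noiseless signal is the (optionally three-component) observed model
    signal; noise is additive Gaussian with standard deviation
    ``noise.sigma * max|signal|``, drawn from ``noise.seed``.
    """
    acq = acquisition or Acquisition(experiment)
    if acq.experiment != experiment:
        acq = replace(acq, experiment=experiment)
    times = acq.grid()
    channel = "T1" if experiment == "saturation_recovery" else "T2"
    clean = observed_signal(pair, nonexch_rate, nonexch_fraction, times, channel)
    signal = clean
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        signal = clean + rng.normal(0.0, noise.sigma * np.max(np.abs(clean)), clean.shape)
    return DecayCurve(
        times=times, signal=signal, experiment=experiment,
        replicate_id=replicate_id, metadata=dict(metadata or {}),
    )


def simulate_series(spec: SeriesSpec) -> List[DecayCurve]:
    """Simulate a full concentration series (all acquisitions, all replicates).

    For each composition the proton inventory fixes the pool sizes and the
    nonexchangeable fraction; the rate model supplies per-pool relaxation
    rates. Each curve's metadata records the scenario, wt%, replicate seed and
    the ground-truth model quantities for truth-based scoring.
    """
    curves: List[DecayCurve] = []
    for i, wt in enumerate(spec.wt_percent_grid):
        mix = scenario_mixture(float(wt), spec.scenario)
        inv = proton_inventory(mix, SUCROSE)
        rates = spec.rate_model(float(wt), spec.scenario)
        pair = _pair_for(inv, rates, spec.k_ex)
        for acq in spec.acquisitions:
            channel = "T1" if acq.experiment == "saturation_recovery" else "T2"
            non_rate = rates.R1_non if channel == "T1" else rates.R2_non
            for rep in range(spec.replicates):
                seed = (spec.noise.seed * 1_000_003 + i * 971 + rep * 31 +
                        (0 if channel == "T1" else 17)) % (2**31)
                meta = {
                    "scenario": spec.scenario,
                    "wt_percent": float(wt),
                    "seed": seed,
                    "k_ex": spec.k_ex,
                    "xp_non": inv.xp_non,
                    "xp_exch": inv.xp_exch,
                    "x_A": inv.x_A,
                    "nonexch_rate": non_rate,
                }
                curves.append(
                    simulate_decay(
                        pair, acq.experiment, acq,
                        NoiseModel(spec.noise.sigma, seed),
                        nonexch_rate=non_rate, nonexch_fraction=inv.xp_non,
                        replicate_id=rep, metadata=meta,
                    )
                )
    return curves
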