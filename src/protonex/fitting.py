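"""Mono- and biexponential fitting of relaxation decay curves.

Saturation-recovery curves are fit to

    Mz(t)/Mz_inf = 1 - a_s exp(-t/T_s) - a_f exp(-t/T_f)  (+ y0)

and CPMG echo decays to

    Mxy(t)/Mxy(0) = a_s exp(-t/T_s) + a_f exp(-t/T_f)  (+ y0)

with the slow/fast ordering convention ``T_slow >= T_fast`` enforced after the
fit. The optional offset ``y0`` absorbs baseline drift and pulse-calibration
residuals. Nonlinear least squares is delegated to :mod:`lmfit`;
initialization, model selection (F-test plus a runs test on the
mono-fit residuals), replicate aggregation and confidence bands are local.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "DecayCurve",
    "FitConfig",
    "FitResult",
    "ModelSelection",
    "fit_recovery",
    "fit_cpmg",
    "fit_curve",
    "select_model",
    "replicate_stats",
    "confidence_band",
]

EXPERIMENTS = ("saturation_recovery", "cpmg")


@dataclass(frozen=True)
class DecayCurve:
    """A measured or simulated relaxation decay."""

    times: np.ndarray  # s, strictly increasing
    signal: np.ndarray  # arbitrary units
    experiment: str  # "saturation_recovery" | "cpmg"
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"experiment must be one of {EXPERIMENTS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class FitConfig:
    """Controls for the decay fits.

    ``ci_level`` defaults to 0.80; ``ci_method="bootstrap"`` uses a seeded
    parametric bootstrap (``n_bootstrap`` resamples), ``"covariance"`` the
    linearized covariance of the least-squares fit.
    """

    model_order: str = "auto"  # "mono" | "bi" | "auto"
    include_offset: bool = True
    t_bounds: Tuple[float, float] = (1e-4, 1e2)  # s
    amp_bounds: Tuple[float, float] = (0.0, 1.5)
    y0_bounds: Tuple[float, float] = (-0.1, 0.1)
    normalize: bool = True
    max_iterations: int = 2000
    tolerance: float = 1e-12
    ci_level: float = 0.80
    ci_method: str = "bootstrap"
    n_bootstrap: int = 200
    seed: int = 0
    f_test_alpha: float = 0.05
    runs_test_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.model_order not in ("mono", "bi", "auto"):
            raise ValueError("model_order must be 'mono', 'bi' or 'auto'")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.t_bounds[0] <= 0 or self.amp_bounds[0] < 0:
            raise ValueError("bounds must be positive (amplitudes non-negative)")
        if self.ci_method not in ("bootstrap", "covariance"):
            raise ValueError("ci_method must be 'bootstrap' or 'covariance'")


@dataclass(frozen=True)
class FitResult:
    """Fitted amplitudes, time constants, offset and diagnostics."""

    a_slow: float
    a_fast: float
    T_slow: float
    T_fast: Optional[float]
    y0: float
    r_squared: float
    rmse: float
    converged: bool
    model_order: str
    experiment: str
    ci: Dict[str, Tuple[float, float]]
    n_iterations: int
    residuals: np.ndarray
    scale: float = 1.0  # normalization divisor applied to the raw signal
    amp_total: float = 1.0  # fitted plateau (recovery) / total amplitude (cpmg)
    offset_fitted: bool = True

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    @property
    def n_parameters(self) -> int:
        n = 2 if self.model_order == "mono" else 4
        return n + (1 if self.offset_fitted else 0)


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the mono-vs-bi comparison."""

    selected: str
    mono: FitResult
    bi: FitResult
    f_pvalue: float
    runs_pvalue: float

    @property
    def selected_result(self) -> FitResult:
        return self.bi if self.selected == "bi" else self.mono


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------
# Recovery curves are fit with a free plateau: S(t) = Minf - A_s e - A_f e;
# the reported coefficients are normalized by the fitted plateau
# (a_i = A_i / Minf) and the offset is the plateau's deviation from the crude
# normalization (y0 = Minf - 1). CPMG decays are fit with raw amplitudes plus
# a baseline: S(t) = A_s e + A_f e + y0, coefficients normalized by the total
# fitted amplitude. Both parameterizations are identifiable (no plateau/offset
# degeneracy) and recover noiseless curves exactly.


def _recovery_model(t, amp_total, a_s, a_f, T_s, T_f, _y0_unused=0.0):
    return amp_total * (1.0 - a_s * np.exp(-t / T_s) - a_f * np.exp(-t / T_f))


def _decay_model(t, amp_total, a_s, a_f, T_s, T_f, y0):
    return amp_total * (a_s * np.exp(-t / T_s) + a_f * np.exp(-t / T_f)) + y0


def _evaluate(result: "FitResult", t: np.ndarray) -> np.ndarray:
    """Fitted model on the normalized signal scale."""
    func = _recovery_model if result.experiment == "saturation_recovery" else _decay_model
    return func(
        t, result.amp_total, result.a_slow, result.a_fast, result.T_slow,
        result.T_fast if result.T_fast is not None else 1.0, result.y0,
    )


def _normalize(curve: DecayCurve, normalize: bool) -> Tuple[np.ndarray, float]:
    """Scale the signal to ~[0, 1]: plateau for recovery, initial amp for CPMG."""
    s = curve.signal
    if not normalize:
        return s, 1.0
    if curve.experiment == "saturation_recovery":
        tail = s[-max(3, len(s) // 8):]
        scale = float(np.mean(tail))
    else:
        scale = float(np.max(s[: max(3, len(s) // 16)]))
    if scale <= 0:
        scale = float(np.max(np.abs(s))) or 1.0
    return s / scale, scale


def _mono_initial_guess(t: np.ndarray, y: np.ndarray, recovery: bool) -> Tuple[float, float]:
    """Amplitude and time-constant guess from signal amplitude and time scale."""
    decay = (1.0 - y) if recovery else y
    decay = np.clip(decay, 1e-12, None)
    amp = float(min(max(decay[0], 0.05), 1.4))
    # time where the decaying part falls below amp/e
    below = np.nonzero(decay < amp / math.e)[0]
    T = float(t[below[0]]) if below.size else float(t[-1] / 3.0)
    return amp, max(T, 2e-4)


def _fit_order(
    curve: DecayCurve, config: FitConfig, order: str
) -> FitResult:
    t = curve.times
    y, scale = _normalize(curve, config.normalize)
    recovery = curve.experiment == "saturation_recovery"

    n_params = (2 if order == "mono" else 4) + (1 if config.include_offset else 0)
    if len(curve) < max(n_params + 1, 4):
        raise ValueError(f"too few points ({len(curve)}) for a {order} fit")
    if order == "bi" and len(curve) < 8:
        raise ValueError("biexponential fits require at least 8 points")

    a0, T0 = _mono_initial_guess(t, y, recovery)
    params = lmfit.Parameters()
    tmin, tmax = config.t_bounds
    amin, amax = config.amp_bounds
    if order == "mono":
        params.add("A_s", value=a0, min=amin, max=amax)
        params.add("T_s", value=np.clip(T0, tmin, tmax), min=tmin, max=tmax)
    else:
        # split the mono time constant geometrically and halve the amplitude
        params.add("A_s", value=a0 * 0.5, min=amin, max=amax)
        params.add("A_f", value=a0 * 0.5, min=amin, max=amax)
        params.add("T_s", value=np.clip(T0 * 3.0, tmin, tmax), min=tmin, max=tmax)
        params.add("T_f", value=np.clip(T0 / 3.0, tmin, tmax), min=tmin, max=tmax)
    if recovery:
        # the fitted plateau doubles as the offset constant; fixed when the
        # data are taken as exactly normalized
        params.add("Minf", value=1.0, min=1.0 + config.y0_bounds[0],
                   max=1.0 + config.y0_bounds[1], vary=config.include_offset)
    elif config.include_offset:
        params.add("y0", value=0.0, min=config.y0_bounds[0], max=config.y0_bounds[1])

    def residual(p):
        a_s = p["A_s"].value
        a_f = p["A_f"].value if order == "bi" else 0.0
        T_s = p["T_s"].value
        T_f = p["T_f"].value if order == "bi" else 1.0
        if recovery:
            return _recovery_model(t, p["Minf"].value, a_s, a_f, T_s, T_f) - y
        y0 = p["y0"].value if config.include_offset else 0.0
        return _decay_model(t, 1.0, a_s, a_f, T_s, T_f, y0) - y

    minim = lmfit.Minimizer(residual, params, max_nfev=config.max_iterations)
    out = minim.minimize(method="least_squares", xtol=config.tolerance,
                         ftol=config.tolerance, gtol=config.tolerance)

    p = out.params
    A_s, T_s = p["A_s"].value, p["T_s"].value
    A_f, T_f = (p["A_f"].value, p["T_f"].value) if order == "bi" else (0.0, None)
    if order == "bi" and T_f is not None and T_f > T_s:
        A_s, A_f, T_s, T_f = A_f, A_s, T_f, T_s
    if recovery:
        # A_s, A_f already sit inside the plateau-scaled model, so they are
        # the plateau-normalized coefficients themselves
        amp_total = p["Minf"].value
        y0 = amp_total - 1.0
        a_s, a_f = A_s, A_f
    else:
        y0 = p["y0"].value if config.include_offset else 0.0
        amp_total = A_s + A_f
        a_s, a_f = (A_s / amp_total, A_f / amp_total) if amp_total > 0 else (1.0, 0.0)

    res = np.asarray(out.residual, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(res**2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    rmse = math.sqrt(rss / len(y))

    ci = _parameter_ci(out, order, recovery, config)
    return FitResult(
        a_slow=a_s, a_fast=a_f, T_slow=T_s, T_fast=T_f, y0=y0,
        r_squared=r2, rmse=rmse,
        converged=bool(out.success), model_order=order,
        experiment=curve.experiment, ci=ci,
        n_iterations=int(out.nfev), residuals=res, scale=scale,
        amp_total=amp_total, offset_fitted=config.include_offset,
    )


def _parameter_ci(out, order, recovery, config) -> Dict[str, Tuple[float, float]]:
    """Per-parameter CI from the linearized covariance (z * stderr).

    Amplitude standard errors are propagated through the normalization by the
    fitted plateau / total amplitude (independent-parameter delta method).
    """
    z = stats.norm.ppf(0.5 + config.ci_level / 2.0)
    swap = order == "bi" and out.params["T_f"].value > out.params["T_s"].value

    def rel_err(name):
        par = out.params.get(name)
        if par is None or par.stderr is None or par.value == 0:
            return None
        return par.stderr / abs(par.value)

    # recovery amplitudes are already plateau-normalized inside the model;
    # cpmg amplitudes are normalized by their fitted sum afterwards
    norm_val = (
        1.0 if recovery
        else sum(out.params[n].value for n in ("A_s", "A_f") if n in out.params)
    )
    norm_rel = None

    ci: Dict[str, Tuple[float, float]] = {}
    for name, par in out.params.items():
        if par.stderr is None:
            continue
        key = name
        if swap and name in ("A_s", "A_f", "T_s", "T_f"):
            key = {"A_s": "A_f", "A_f": "A_s", "T_s": "T_f", "T_f": "T_s"}[name]
        if key in ("A_s", "A_f"):
            value = par.value / norm_val if norm_val > 0 else par.value
            rel = rel_err(name) or 0.0
            total_rel = math.hypot(rel, norm_rel) if norm_rel else rel
            stderr = abs(value) * total_rel
            key = {"A_s": "a_s", "A_f": "a_f"}[key]
        elif name == "Minf":
            key, value, stderr = "y0", par.value - 1.0, par.stderr
        else:
            value, stderr = par.value, par.stderr
        ci[key] = (value - z * stderr, value + z * stderr)
    return ci


def fit_recovery(curve: DecayCurve, config: FitConfig = FitConfig(model_order="bi")) -> FitResult:
    """Fit a saturation-recovery curve (mono/bi per ``config.model_order``)."""
    if curve.experiment != "saturation_recovery":
        raise ValueError("fit_recovery expects a saturation_recovery curve")
    return fit_curve(curve, config)


def fit_cpmg(curve: DecayCurve, config: FitConfig = FitConfig(model_order="bi")) -> FitResult:
    """Fit a CPMG echo decay (mono/bi per ``config.model_order``)."""
    if curve.experiment != "cpmg":
        raise ValueError("fit_cpmg expects a cpmg curve")
    return fit_curve(curve, config)


def fit_curve(curve: DecayCurve, config: FitConfig = FitConfig()) -> FitResult:
    """Fit a decay curve; ``model_order="auto"`` runs model selection."""
    if config.model_order == "auto":
        return select_model(curve, config).selected_result
    return _fit_order(curve, config, config.model_order)


def _runs_test_pvalue(residuals: np.ndarray) -> float:
    """Wald–Wolfowitz runs test on residual signs (normal approximation).

    Structured (serially correlated) residuals — the signature of an
    underfitted decay — give few runs and a small p-value.
    """
    signs = residuals > np.median(residuals)
    n1 = int(np.sum(signs))
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mean = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def select_model(curve: DecayCurve, config: FitConfig = FitConfig()) -> ModelSelection:
    """Choose mono vs biexponential by an F-test on the nested fits combined
    with a runs test on the mono residuals; both must reject for "bi"."""
    mono = _fit_order(curve, config, "mono")
    bi = _fit_order(curve, config, "bi")
    n = len(curve)
    p_mono, p_bi = mono.n_parameters, bi.n_parameters
    rss_m, rss_b = mono.rss, bi.rss
    eps = 1e-30
    if rss_m <= eps * n:  # mono already fits to numerical precision
        f_p = 1.0
    elif rss_b <= eps * n:
        f_p = 0.0
    else:
        fstat = ((rss_m - rss_b) / (p_bi - p_mono)) / (rss_b / (n - p_bi))
        f_p = float(stats.f.sf(max(fstat, 0.0), p_bi - p_mono, n - p_bi))
    runs_p = _runs_test_pvalue(mono.residuals)
    selected = "bi" if (f_p < config.f_test_alpha and runs_p < config.runs_test_alpha) else "mono"
    return ModelSelection(selected=selected, mono=mono, bi=bi, f_pvalue=f_p, runs_pvalue=runs_p)


def replicate_stats(results: Sequence[FitResult]) -> Dict[str, Tuple[float, float]]:
    """Element-wise mean and standard deviation over replicate fits.

    Per-fit covariances are *not* pooled into the replicate spread. All
    replicates must share the model order.
    """
    if len(results) < 2:
        raise ValueError("need at least two replicate fits")
    orders = {r.model_order for r in results}
    if len(orders) > 1:
        raise ValueError(
            f"mixed model orders across replicates {sorted(orders)}: refit with a fixed order"
        )
    names = ["a_slow", "a_fast", "T_slow", "T_fast", "y0"]
    out: Dict[str, Tuple[float, float]] = {}
    for name in names:
        vals = [getattr(r, name) for r in results]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=float)
        out[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out


def confidence_band(
    curve: DecayCurve,
    result: FitResult,
    config: FitConfig = FitConfig(),
    eval_times: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise confidence band of the fitted curve at ``config.ci_level``.

    Returns ``(times, lower, upper)`` on the normalized signal scale. The
    default is a parametric bootstrap (refit of ``n_bootstrap`` synthetic
    curves built from the fitted model plus residual-scale Gaussian noise);
    ``ci_method="covariance"`` propagates the linearized parameter covariance.
    Raises if the result has not converged; a bootstrap failure rate above 10%
    is flagged with a RuntimeError.
    """
    if not result.converged:
        raise ValueError("confidence band requires a converged fit")
    t_eval = curve.times if eval_times is None else np.asarray(eval_times, dtype=float)

    fitted = _evaluate(result, t_eval)
    sigma = result.rmse
    if sigma == 0.0:
        return t_eval, fitted.copy(), fitted.copy()

    if config.ci_method == "covariance":
        lo, hi = _covariance_band(result, config, t_eval)
        return t_eval, lo, hi

    rng = np.random.default_rng(config.seed)
    fit_cfg = FitConfig(
        model_order=result.model_order, include_offset=config.include_offset,
        t_bounds=config.t_bounds, amp_bounds=config.amp_bounds,
        y0_bounds=config.y0_bounds, normalize=False,
        max_iterations=config.max_iterations, tolerance=1e-10,
    )
    model_on_grid = _evaluate(result, curve.times)
    bands, failures = [], 0
    for _ in range(config.n_bootstrap):
        synthetic = model_on_grid + rng.normal(0.0, sigma, size=model_on_grid.shape)
        try:
            boot = _fit_order(
                DecayCurve(curve.times, synthetic, curve.experiment), fit_cfg,
                result.model_order,
            )
            if not boot.converged:
                raise RuntimeError
            bands.append(_evaluate(boot, t_eval))
        except Exception:
            failures += 1
    if failures > 0.1 * config.n_bootstrap:
        raise RuntimeError(
            f"bootstrap failure rate {failures}/{config.n_bootstrap} exceeds 10%"
        )
    band = np.asarray(bands)
    alpha = 1.0 - config.ci_level
    lo = np.quantile(band, alpha / 2.0, axis=0)
    hi = np.quantile(band, 1.0 - alpha / 2.0, axis=0)
    return t_eval, lo, hi


def _covariance_band(result, config, t_eval):
    """Delta-method band from the per-parameter standard errors.

    Uses the independent-parameter (diagonal-covariance) approximation; the
    bootstrap band is the reference method when parameter correlations matter.
    """
    names = ["a_slow", "T_slow", "y0"]
    if result.model_order == "bi":
        names = ["a_slow", "a_fast", "T_slow", "T_fast", "y0"]
    z = stats.norm.ppf(0.5 + config.ci_level / 2.0)
    key_map = {"a_slow": "a_s", "a_fast": "a_f", "T_slow": "T_s", "T_fast": "T_f", "y0": "y0"}
    theta = np.array([
        getattr(result, n) if getattr(result, n) is not None else 1.0 for n in names
    ])
    se = np.array([
        (result.ci[key_map[n]][1] - result.ci[key_map[n]][0]) / (2 * z)
        if key_map[n] in result.ci else 0.0
        for n in names
    ])

    def model(th, t):
        vals = dict(zip(names, th))
        func = _recovery_model if result.experiment == "saturation_recovery" else _decay_model
        amp = 1.0 + vals.get("y0", 0.0) if result.experiment == "saturation_recovery" else result.amp_total
        return func(t, amp, vals.get("a_slow", 0.0), vals.get("a_fast", 0.0),
                    vals.get("T_slow", 1.0), vals.get("T_fast", 1.0), vals.get("y0", 0.0))

    J = np.empty((t_eval.size, theta.size))
    for j in range(theta.size):
        h = max(1e-7 * abs(theta[j]), 1e-10)
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (model(up, t_eval) - model(dn, t_eval)) / (2 * h)
    var = (J**2) @ (se**2)
    half = z * np.sqrt(var)
    fitted = _evaluate(result, t_eval)
    return fitted - half, fitted + half
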