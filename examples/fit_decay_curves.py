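"""Simulate and fit a saturation-recovery curve, with model selection and CIs.

Generates a noisy recovery curve from the three-component observed-signal
model (fast-exchanging pools plus nonexchangeable protons), runs the
mono-vs-bi model selection, and prints the fitted time constants, normalized
coefficients and an 80% bootstrap confidence band summary.
"""

import numpy as np

from protonex import (
    DecayCurve,
    ExchangePair,
    FitConfig,
    NoiseModel,
    confidence_band,
    select_model,
    simulate_decay,
)

pair = ExchangePair(R1_A=1 / 2.5, R1_B=1 / 0.9, k_ex=1e-2, A_tot=9e4, B_tot=6e3)
f_non = 0.20          # 20% of protons are carbon-bound, relaxing with T1 = 0.25 s
curve = simulate_decay(
    pair, "saturation_recovery", noise=NoiseModel(sigma=0.01, seed=42),
    nonexch_rate=1 / 0.25, nonexch_fraction=f_non,
)

sel = select_model(curve, FitConfig())
print(f"model selection: {sel.selected} "
      f"(F-test p = {sel.f_pvalue:.2e}, runs-test p = {sel.runs_pvalue:.2e})")
res = sel.bi
print(f"fitted: a_slow = {res.a_slow:.3f}, a_fast = {res.a_fast:.3f}, "
      f"T_slow = {res.T_slow*1e3:.0f} ms, T_fast = {res.T_fast*1e3:.0f} ms, "
      f"R^2 = {res.r_squared:.5f}")
print(f"truth : a_fast = f_non = {f_non:.3f} (fast-exchange identification)")

cfg = FitConfig(model_order="bi", n_bootstrap=200, seed=1)
t, lo, hi = confidence_band(curve, res, cfg)
print(f"80% bootstrap band: mean width {np.mean(hi - lo):.4f} "
      f"(widest {np.max(hi - lo):.4f} at t = {t[np.argmax(hi - lo)]*1e3:.1f} ms)")
# the fitted fast coefficient tracks the nonexchangeable proton fraction, not
# a bound-water population: that is the model's central reinterpretation
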