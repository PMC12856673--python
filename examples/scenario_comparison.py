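"""Concentration series in three solvent scenarios: fits vs proton fractions.

Simulates triplicate saturation-recovery series for sucrose in H2O, D2O and
freeze-dried-sucrose/D2O, fits every curve biexponentially, aggregates the
replicates, and compares the fitted fast coefficient with the predicted
nonexchangeable proton fraction for each sample.
"""

from protonex import (
    Acquisition,
    FitConfig,
    NoiseModel,
    SeriesSpec,
    compare_table,
    fit_run,
    fit_summary_table,
    inventory_table,
    simulate_series,
)

wts = [10, 25, 40, 55]
print(f"{'scenario':>8} {'wt%':>4} {'a_fast':>7} {'xp_non':>7} {'T_slow(ms)':>10}")
for scenario in ("H2O", "D2O", "FD-D2O"):
    spec = SeriesSpec(
        wt_percent_grid=wts, scenario=scenario, replicates=3,
        acquisitions=(Acquisition("saturation_recovery"),),
        noise=NoiseModel(sigma=0.01, seed=5),
    )
    curves = simulate_series(spec)
    results = fit_run(curves, FitConfig(model_order="bi"))
    summary = fit_summary_table(curves, results)
    merged = compare_table(summary, inventory_table(wts, scenarios=[scenario]))
    for _, row in merged.iterrows():
        print(f"{scenario:>8} {row.wt_percent:4.0f} {row.a_fast:7.3f} "
              f"{row.xp_non:7.3f} {row.T_slow_ms:10.0f}")
    mad = merged.attrs["mad_fast"][scenario]
    print(f"{'':>8} mean |a_fast - xp_non| = {mad:.3f}")
# expected pattern: a_fast climbs with concentration in H2O, is flat near
# 0.63 in D2O, and sits near 0.95 for the freeze-dried samples — ordering
# H2O < D2O < FD-D2O at every concentration, tracking the proton bookkeeping
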