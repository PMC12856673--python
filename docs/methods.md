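# Methods

## The exchange-relaxation model

Two pools of identical nuclei (¹H) exchange protons bimolecularly: a proton
transfer from a water molecule to a sugar hydroxyl is balanced by a transfer
in the opposite direction (a cyclic, charge-neutral mechanism), so both
directions share one second-order rate constant `k_ex` (s⁻¹·mol⁻¹·m³). In an
NMR experiment the *total* proton concentrations of the pools, `A_tot`
(solvent exchangeable sites) and `B_tot` (solute hydroxyl sites), are
constants, which linearizes the kinetics into pseudo-first-order
coefficients `k_A = k_ex·B_tot`, `k_B = k_ex·A_tot`. Adding longitudinal
relaxation gives a 2×2 linear ODE system of Bloch–McConnell form whose
eigen-decomposition is biexponential with rates

    λ1,2 = ½[(rA + rB) ∓ √((rA − rB)² + 4 kA kB)],  rj = kj + R1_j,

ordered `λ1 ≤ λ2` (slow first; the minus root). The printed saturation
amplitudes

    Λ1 = −Mz_A∞ (R1_A − λ2)/(λ2 − λ1),  Λ2 = −Mz_A∞ (λ1 − R1_A)/(λ2 − λ1)

are valid exactly when (i) both pools start saturated (Mz(0) = 0) and (ii)
the equilibrium magnetizations are proportional to pool sizes
(`k_A Mz_A∞ = k_B Mz_B∞`) — the physical situation for pools of identical
nuclei. `longitudinal_solution` uses them in that case and falls back to the
general eigen-decomposition for custom initial conditions,
non-proportional equilibria, or `k_B = 0` (where the pool-B amplitude
formula is singular). The weight of each exponential in the *summed*
normalized recovery is `Λi (k_B + rA − λi) / (k_B (Mz_A∞ + Mz_B∞))`; this
coefficient was re-derived from the pool solutions and validated against
direct integration (the two weights sum to exactly 1 under saturation).

Transverse magnetization obeys the same algebra under `Mz_B∞ → 0` and
`R1_j → R2_j − i ω_j`, giving complex eigenrates (decay + precession) and
amplitudes `Θ1 + Θ2 = Mxy_A(0)`. On resonance (`ω = 0`, the default, since
CPMG refocusing keeps the signal real) everything is real and "magnitude"
and "real" detection coincide. CPMG refocusing is idealized: the
free-evolution solution is applied directly to the echo-top times; diffusion
and exchange-modulated dephasing between pulses are ignored.

Fast-exchange asymptotics (`k_A, k_B ≫ R1`):
`λ1 ≈ x_A R1_A + x_B R1_B` with `x_A = A_tot/(A_tot+B_tot)`,
`λ2 ≈ k_ex(A_tot+B_tot) + x_B R1_A + x_A R1_B`, and the slow/fast
contribution coefficients tend to (1, 0). `fast_exchange_approx` reports
(never enforces) regime validity as `min(k_A, k_B) > 10·max(R1)`.

Carbon-bound solute protons do not exchange; `observed_signal` adds them as
an independent single-exponential component weighted by their fraction
`f_non` of all protons. In the fast-exchange regime a biexponential fit of
this composite recovers `a_fast ≈ f_non` — the model's central
reinterpretation of the "bound water" coefficient.

The magnetization scale constant `mu` (proportionality between population
difference and magnetization) defaults to 1 and cancels in every normalized
output. All internal rates are s⁻¹ and times s; summary tables convert time
constants to ms.

## Proton bookkeeping

Stoichiometry records: sucrose C12H22O11 (M = 342.30 g/mol, 14 carbon-bound
H, 8 hydroxyl sites), H2O (M = 18.015) and D2O (M = 20.027) with 2 labile
sites each. Per kg of mixture with solute mass fraction w: `n_solute =
1000 w / M_s`, `n_solvent = 1000 (1−w) / M_w`. Labile hydrogen — supplied by
the solvent at `solvent_protiation` and the solute hydroxyls at
`solute_site_protiation` — is assumed to scramble *uniformly* over all
labile sites (consistent with fast cyclic exchange); no equilibrium isotope
fractionation factor is applied (a configurable factor field exists; with a
single uniform occupancy it cancels identically). The inventory then reports
pool concentrations (per kg, or mol/m³ when a density is supplied), the
pool fractions `x_A`, `x_B` of the exchangeable pool, and the
exchangeable/nonexchangeable fractions `xp_exch`, `xp_non` of all protons.

Freeze-drying: a solute equilibrated in (heavy) water carries away the
equilibrium labile-site H occupancy `(labile H)/(labile sites)` of the
stage-1 solution; back-exchange with ambient moisture is neglected. The
default freeze-dried preparation is 20 wt% sucrose in D2O (occupancy
≈ 0.055 for ideal D2O).

Parameters that matter:

* `solvent_protiation` — atom fraction H at solvent sites. Defaults: 1.0
  (H2O), 0.003 (D2O; typical 99.7 atom % D). Freeze-dried-sample
  predictions are sensitive to this residual, so it is an explicit field.
* `density` (kg/m³) — needed only for mol/m³ concentrations (hence for
  `k_A`, `k_B` magnitudes); all fractions are density-free. When absent, an
  embedded ~20 °C aqueous-sucrose density table (0–70 wt%, linear
  interpolation) may be used via `sucrose_solution_density`; it is
  approximate (handbook-style values, no temperature correction).

## Decay fitting

Saturation-recovery curves are fit as `Minf·(1 − a_s e^(−t/T_s) −
a_f e^(−t/T_f))` after dividing by a crude plateau estimate (mean of the
last ⌈n/8⌉ points); the free plateau `Minf` plays the role of the offset
constant (`y0 = Minf − 1`) and the reported coefficients are
plateau-normalized. CPMG decays are fit as `A_s e^(−t/T_s) + A_f e^(−t/T_f)
+ y0` after dividing by the initial amplitude, with coefficients normalized
by `A_s + A_f`. Both parameterizations are identifiable (no plateau/offset
degeneracy) and recover noiseless curves to numerical precision. Ordering
`T_slow ≥ T_fast` is enforced by swap after the fit.

Initialization is deterministic: amplitude from the first decaying point,
time constant from the 1/e crossing; the biexponential starts from the mono
guess with the time constant split geometrically (×3, ÷3) and the amplitude
halved. Bounds: `T ∈ [1e−4, 1e2]` s, amplitudes `∈ [0, 1.5]`,
`y0 ∈ [−0.1, 0.1]` (normalized units). Optimization is trust-region least
squares via lmfit (`xtol = ftol = gtol = 1e−12`).

Model selection formalizes the residual-structure argument: biexponential is
chosen only when *both* the nested-model F-test (α = 0.05) and a
Wald–Wolfowitz runs test on the mono-fit residuals (α = 0.05) reject —
structured residuals are the signature of an underfitted decay. Exactly
monoexponential data short-circuit to mono (zero-RSS guard).

Uncertainty: per-parameter CIs (default level 0.80) come from the linearized
covariance, with amplitude errors propagated through the normalization
(independent-parameter delta method). The fitted-curve confidence band uses
a seeded parametric bootstrap by default (200 refits of model + residual-σ
Gaussian noise; failure rate >10% raises), with the covariance (delta
method, diagonal approximation) band as the fast alternative. Replicate
aggregation reports element-wise mean ± sd and deliberately does not pool
per-fit covariances into the replicate spread; mixed model orders across
replicates are an error.

Precision at the standard acquisition (32 log-spaced points, 4 ms–30 s, 1%
Gaussian noise, truth a = 0.7/0.3, T = 2.0/0.3 s): single-curve scatter is
3–8% per parameter (information-limited — verified against an independent
unconstrained least-squares oracle), while the median estimate over 100
seeds is within 0.3% of truth for every parameter; the built-in simulation
study therefore tests robust bias (<2%) and noiseless exactness, not
single-curve scatter.

## Synthetic data

`simulate_decay` evaluates the noiseless model signal (two-pool exchange
plus optional nonexchangeable component) on the standard grids — 32
log-spaced recovery delays 4 ms–30 s; CPMG echo trains `2τk` with
τ ∈ [300, 3000] μs, up to 3000 echoes — and adds i.i.d. Gaussian noise with
σ expressed as a fraction of the signal maximum (TD-NMR magnitude noise at
high SNR; a Rician option is deliberately omitted). Everything is
reproducible from the seed; series derive per-curve seeds deterministically
from the spec seed.

`simulate_series` emulates the three experimental preparations (H2O, D2O at
0.003 residual protiation, freeze-dried sucrose redissolved in D2O) over a
wt% grid with three replicates: the proton inventory fixes pool sizes and
`f_non`; a rate model supplies per-pool `R1`/`R2`. The default rate model
uses smooth monotone-decreasing relaxation-time profiles (e.g. water-pool
T1 = 3.0·e^(−0.023·wt%) s, nonexchangeable T1 = 0.30·e^(−0.010·wt%) s),
chosen once as plausible room-temperature values for aqueous sucrose with a
clear slow/fast separation; they are replaceable by user tables and no
quantitative acceptance quantity depends on them. Default
`k_ex = 1e−2 s⁻¹·mol⁻¹·m³`, the upper end of the intermediate regime for
water–carbohydrate exchange, placing H2O-rich samples safely in fast
exchange.

What the generator does *not* emulate: pulse-sequence imperfections (flip
angle, B1 inhomogeneity), Rician noise floors, temperature drift, radiation
damping, diffusion during CPMG, pH-dependent exchange catalysis. Passing
tests on this data demonstrate internal consistency of model, bookkeeping
and fitting — not instrument-level realism.

## Numerical choices

* ODE oracle: `solve_ivp`/DOP853 at rtol 1e−13, atol 1e−14×(magnetization
  scale); the transverse system is integrated as 4 real ODEs. Closed forms
  agree with it to better than 1e−8 relative across slow-to-fast regimes.
* Degenerate eigenrates (λ1 = λ2, only when `kA·kB = 0` and `rA = rB`)
  return a flagged single-exponential solution instead of dividing by
  λ2 − λ1.
* `k_ex = 0` (and generally `k_B = 0`) avoids the printed pool-B amplitude
  formula (singular denominator) via the decoupled/general branch.
* Contribution coefficients are signed weights normalized to sum to 1 for
  the longitudinal channel; transverse coefficients use real parts on
  resonance and magnitudes off resonance.
* Coverage testing of the band uses the covariance method over 150 seeded
  mono-fit curves (pointwise-averaged coverage checked against the nominal
  80%); the bootstrap band is exercised on single curves. Problem sizes
  throughout the suite (24-set oracle ensembles, 100-seed recovery study,
  4-point scenario series) were chosen as the smallest that make the
  statistical assertions stable.

## Known limitations

* Two exchanging pools only; the nonexchangeable component is additive, not
  a third exchanging site.
* No relaxation-mechanism theory: `R1`/`R2` are inputs, not predictions
  (no spectral densities, no field dependence).
* The density correlation and default rate profiles are conveniences for
  simulation, not measured properties of any particular sample.
* Freeze-dried-sample predictions depend linearly on the residual D2O
  protiation, which must be supplied (default 0.003).
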