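"""Two-pool proton-exchange relaxation with second-order rate coefficients.

Water protons (pool A) and solute labile protons (pool B) exchange through a
bimolecular mechanism, so the pseudo-first-order coefficients entering the
coupled magnetization equations are concentration products::

    k_A = k_ex * B_tot        k_B = k_ex * A_tot

with ``k_ex`` the second-order exchange rate constant (s^-1 mol^-1 m^3).
The coupled longitudinal equations

    dMz_A/dt = R1_A (Mz_A_inf - Mz_A) - k_A Mz_A + k_B Mz_B
    dMz_B/dt = R1_B (Mz_B_inf - Mz_B) - k_B Mz_B + k_A Mz_A

share the structure of the Bloch–McConnell equations and admit a closed-form
biexponential solution; the transverse analogue follows by the substitutions
``Mz_B_inf -> 0`` and ``R1_j -> R2_j - i*omega_j``. This module provides the
closed forms, their fast-exchange asymptotics, model-predicted contribution
coefficients, a three-component observed signal including the nonexchangeable
proton pool, and a tight-tolerance ODE integrator used as a validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .composition import ProtonInventory

__all__ = [
    "ExchangePair",
    "LongitudinalSolution",
    "TransverseSolution",
    "FastExchangeApprox",
    "longitudinal_eigenrates",
    "longitudinal_solution",
    "longitudinal_signal",
    "transverse_solution",
    "transverse_signal",
    "fast_exchange_approx",
    "predicted_coefficients",
    "observed_signal",
    "ode_reference",
]

_DEGENERACY_RTOL = 1e-12


@dataclass(frozen=True)
class ExchangePair:
    """Full parameterization of the two exchanging proton pools.

    Rates are in s^-1, concentrations in mol/m^3 (any consistent concentration
    unit works: only the products ``k_ex * concentration`` and the pool
    *fractions* enter the dynamics). Equilibrium/initial magnetizations default
    to being proportional to pool sizes, which is the physical situation for
    pools of identical nuclei; ``mu`` is the magnetization scale constant and
    cancels in every normalized output.
    """

    R1_A: float
    R1_B: float
    R2_A: float = 0.0
    R2_B: float = 0.0
    omega_A: float = 0.0
    omega_B: float = 0.0
    k_ex: float = 0.0
    A_tot: float = 1.0
    B_tot: float = 0.0
    Mz_inf_A: Optional[float] = None
    Mz_inf_B: Optional[float] = None
    Mxy0_A: Optional[float] = None
    Mxy0_B: Optional[float] = None
    mu: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R1_A", "R1_B", "R2_A", "R2_B", "k_ex", "A_tot", "B_tot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Mz_inf_A is None:
            object.__setattr__(self, "Mz_inf_A", self.mu * self.A_tot)
        if self.Mz_inf_B is None:
            object.__setattr__(self, "Mz_inf_B", self.mu * self.B_tot)
        if self.Mxy0_A is None:
            object.__setattr__(self, "Mxy0_A", self.mu * self.A_tot)
        if self.Mxy0_B is None:
            object.__setattr__(self, "Mxy0_B", self.mu * self.B_tot)

    @classmethod
    def from_inventory(
        cls,
        inventory: ProtonInventory,
        R1_A: float,
        R1_B: float,
        R2_A: float = 0.0,
        R2_B: float = 0.0,
        k_ex: float = 0.0,
        **kwargs,
    ) -> "ExchangePair":
        """Build a pair from a proton inventory (pool sizes set magnetizations)."""
        return cls(
            R1_A=R1_A, R1_B=R1_B, R2_A=R2_A, R2_B=R2_B, k_ex=k_ex,
            A_tot=inventory.A_tot, B_tot=inventory.B_tot, **kwargs,
        )

    # -- derived quantities -------------------------------------------------
    @property
    def k_A(self) -> float:
        return self.k_ex * self.B_tot

    @property
    def k_B(self) -> float:
        return self.k_ex * self.A_tot

    @property
    def r_A(self) -> float:
        return self.k_A + self.R1_A

    @property
    def r_B(self) -> float:
        return self.k_B + self.R1_B

    @property
    def x_A(self) -> float:
        tot = self.A_tot + self.B_tot
        if tot <= 0:
            raise ValueError("A_tot + B_tot must be positive")
        return self.A_tot / tot

    @property
    def x_B(self) -> float:
        return 1.0 - self.x_A

    def swapped(self) -> "ExchangePair":
        """Pair with the A/B labels (and all associated quantities) exchanged."""
        return ExchangePair(
            R1_A=self.R1_B, R1_B=self.R1_A, R2_A=self.R2_B, R2_B=self.R2_A,
            omega_A=self.omega_B, omega_B=self.omega_A, k_ex=self.k_ex,
            A_tot=self.B_tot, B_tot=self.A_tot,
            Mz_inf_A=self.Mz_inf_B, Mz_inf_B=self.Mz_inf_A,
            Mxy0_A=self.Mxy0_B, Mxy0_B=self.Mxy0_A, mu=self.mu,
        )


@dataclass(frozen=True)
class LongitudinalSolution:
    """Closed-form biexponential recovery of the coupled longitudinal system.

    ``Mz_A(t) = Mz_inf_A - Lambda1 e^{-lambda1 t} - Lambda2 e^{-lambda2 t}``
    and similarly for pool B with amplitudes ``Lambda1_B``/``Lambda2_B``.
    ``a1s``/``a1f`` are the normalized weights of the slow/fast exponentials in
    the summed recovery. ``degenerate`` flags an effectively single-exponential
    solution (coincident eigenrates).
    """

    lambda1: float
    lambda2: float
    Lambda1: float
    Lambda2: float
    Lambda1_B: float
    Lambda2_B: float
    Mz_inf_A: float
    Mz_inf_B: float
    a1s: float
    a1f: float
    degenerate: bool = False

    def pools(self, times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Per-pool trajectories ``(Mz_A(t), Mz_B(t))``."""
        t = np.asarray(times, dtype=float)
        e1, e2 = np.exp(-self.lambda1 * t), np.exp(-self.lambda2 * t)
        mz_a = self.Mz_inf_A - self.Lambda1 * e1 - self.Lambda2 * e2
        mz_b = self.Mz_inf_B - self.Lambda1_B * e1 - self.Lambda2_B * e2
        return mz_a, mz_b

    def total_signal(self, times: np.ndarray) -> np.ndarray:
        """Normalized summed recovery ``(Mz_A + Mz_B)/(Mz_inf_A + Mz_inf_B)``."""
        mz_a, mz_b = self.pools(times)
        return (mz_a + mz_b) / (self.Mz_inf_A + self.Mz_inf_B)


@dataclass(frozen=True)
class TransverseSolution:
    """Closed-form decay of the coupled transverse system (complex rotating frame)."""

    theta1: complex
    theta2: complex
    Theta1: complex
    Theta2: complex
    Theta1_B: complex
    Theta2_B: complex
    Mxy0_A: float
    Mxy0_B: float
    a2s: float
    a2f: float
    degenerate: bool = False

    def pools(self, times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        t = np.asarray(times, dtype=float)
        e1, e2 = np.exp(-self.theta1 * t), np.exp(-self.theta2 * t)
        return self.Theta1 * e1 + self.Theta2 * e2, self.Theta1_B * e1 + self.Theta2_B * e2

    def total_signal(self, times: np.ndarray, detection: str = "magnitude") -> np.ndarray:
        mxy = sum(self.pools(times))
        if detection == "magnitude":
            return np.abs(mxy)
        if detection == "real":
            return np.real(mxy)
        raise ValueError(f"detection must be 'magnitude' or 'real', got {detection!r}")


@dataclass(frozen=True)
class FastExchangeApprox:
    """Fast-exchange limits of the eigenrates and contribution coefficients."""

    lambda1: float
    lambda2: float
    a_slow: float = 1.0
    a_fast: float = 0.0
    regime_valid: bool = True


# ---------------------------------------------------------------------------
# eigenrates and closed forms
# ---------------------------------------------------------------------------

def longitudinal_eigenrates(pair: ExchangePair) -> Tuple[float, float]:
    """Slow/fast decay eigenrates of the coupled longitudinal system.

    ``lambda_{1,2} = ((rA + rB) -/+ sqrt((rA - rB)^2 + 4 kA kB)) / 2`` with
    ``rA = kA + R1_A`` and ``rB = kB + R1_B``; ordered ``lambda1 <= lambda2``.
    """
    ra, rb = pair.r_A, pair.r_B
    disc = np.sqrt((ra - rb) ** 2 + 4.0 * pair.k_A * pair.k_B)
    return 0.5 * ((ra + rb) - disc), 0.5 * ((ra + rb) + disc)


def _relax_matrix(pair: ExchangePair, channel: str):
    """Decay matrix K such that d(deviation)/dt = -K * deviation."""
    if channel == "longitudinal":
        return np.array(
            [[pair.r_A, -pair.k_B], [-pair.k_A, pair.r_B]], dtype=float
        )
    r2a = pair.R2_A - 1j * pair.omega_A + pair.k_A
    r2b = pair.R2_B - 1j * pair.omega_B + pair.k_B
    return np.array([[r2a, -pair.k_B], [-pair.k_A, r2b]], dtype=complex)


def longitudinal_solution(
    pair: ExchangePair,
    initial: Union[str, Tuple[float, float]] = "saturation",
) -> LongitudinalSolution:
    """Closed-form solution of the coupled longitudinal equations.

    ``initial="saturation"`` starts both pools at zero magnetization (the
    saturation-recovery preparation); a ``(Mz_A0, Mz_B0)`` tuple gives the
    general solution via the 2x2 eigen-decomposition, which reduces to the
    printed saturation amplitudes when the equilibrium magnetizations are
    proportional to pool sizes.
    """
    l1, l2 = longitudinal_eigenrates(pair)
    mza_inf, mzb_inf = float(pair.Mz_inf_A), float(pair.Mz_inf_B)

    if initial == "saturation":
        m0 = np.array([0.0, 0.0])
    else:
        m0 = np.asarray(initial, dtype=float)
        if m0.shape != (2,):
            raise ValueError("initial must be 'saturation' or a (Mz_A0, Mz_B0) pair")

    proportional = np.isclose(
        pair.k_A * mza_inf, pair.k_B * mzb_inf,
        rtol=1e-9, atol=1e-12 * max(1.0, abs(mza_inf), abs(mzb_inf)),
    )
    degenerate = (l2 - l1) <= _DEGENERACY_RTOL * max(l2, 1e-300)

    use_printed = (
        initial == "saturation" and proportional and not degenerate and pair.k_B > 0
    )
    if use_printed:
        # printed saturation amplitudes for pool A; pool-B amplitudes follow
        # from substituting the pool-A solution back into its rate equation
        lam1 = -mza_inf / (l2 - l1) * (pair.R1_A - l2)
        lam2 = -mza_inf / (l2 - l1) * (l1 - pair.R1_A)
        lam1_b = lam1 * (pair.r_A - l1) / pair.k_B
        lam2_b = lam2 * (pair.r_A - l2) / pair.k_B
    elif degenerate:
        # coincident eigenrates: single effective exponential
        amp = np.array([mza_inf, mzb_inf]) - m0
        lam1, lam1_b = amp
        lam2 = lam2_b = 0.0
    else:
        # general eigen-decomposition; the steady state solves K m = b and
        # equals (Mz_inf_A, Mz_inf_B) only when k_A Mz_inf_A = k_B Mz_inf_B
        K = _relax_matrix(pair, "longitudinal")
        b = np.array([pair.R1_A * mza_inf, pair.R1_B * mzb_inf])
        m_ss = np.linalg.solve(K, b) if np.linalg.det(K) != 0 else np.array([mza_inf, mzb_inf])
        evals, evecs = np.linalg.eig(K)
        order = np.argsort(evals.real)
        evals, evecs = evals[order].real, evecs[:, order].real
        coeffs = np.linalg.solve(evecs, m_ss - m0)
        amps = evecs * coeffs  # column i = amplitude vector of e^{-lambda_i t}
        l1, l2 = evals
        lam1, lam1_b = amps[:, 0]
        lam2, lam2_b = amps[:, 1]
        mza_inf, mzb_inf = m_ss  # trajectories relax toward the true steady state

    c1 = lam1 + lam1_b
    c2 = lam2 + lam2_b
    norm = c1 + c2  # equals Mz_inf_A + Mz_inf_B in the saturation case
    a1s, a1f = (c1 / norm, c2 / norm) if abs(norm) > 0 else (1.0, 0.0)
    return LongitudinalSolution(
        lambda1=l1, lambda2=l2, Lambda1=lam1, Lambda2=lam2,
        Lambda1_B=lam1_b, Lambda2_B=lam2_b,
        Mz_inf_A=mza_inf, Mz_inf_B=mzb_inf,
        a1s=float(a1s), a1f=float(a1f), degenerate=bool(degenerate),
    )


def longitudinal_signal(
    pair: ExchangePair,
    times: np.ndarray,
    initial: Union[str, Tuple[float, float]] = "saturation",
) -> np.ndarray:
    """Normalized summed recovery ``(Mz_A(t) + Mz_B(t)) / (Mz_inf_A + Mz_inf_B)``."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return longitudinal_solution(pair, initial).total_signal(t)


def transverse_solution(pair: ExchangePair) -> TransverseSolution:
    """Closed-form solution of the coupled transverse equations.

    Eigenrates and amplitudes follow from the longitudinal forms under the
    substitutions ``Mz_B_inf -> 0`` and ``R1_j -> R2_j - i omega_j``.
    """
    r2a = pair.R2_A - 1j * pair.omega_A + pair.k_A
    r2b = pair.R2_B - 1j * pair.omega_B + pair.k_B
    disc = np.sqrt((r2a - r2b) ** 2 + 4.0 * pair.k_A * pair.k_B + 0j)
    th1 = 0.5 * ((r2a + r2b) - disc)
    th2 = 0.5 * ((r2a + r2b) + disc)
    if th2.real < th1.real:
        th1, th2 = th2, th1
    m0a, m0b = float(pair.Mxy0_A), float(pair.Mxy0_B)

    degenerate = abs(th2 - th1) <= _DEGENERACY_RTOL * max(abs(th2), 1e-300)
    if degenerate:
        t1, t2 = m0a + 0j, 0j
        t1_b, t2_b = m0b + 0j, 0j
    elif pair.k_B > 0:
        t1 = -(m0a * (th2 - r2a) + pair.k_B * m0b) / (th1 - th2)
        t2 = m0a - t1
        t1_b = t1 * (r2a - th1) / pair.k_B
        t2_b = t2 * (r2a - th2) / pair.k_B
    else:
        # k_B = 0 (empty A pool): the printed pool-B amplitudes are singular;
        # fall back to the generic eigen-decomposition of the complex 2x2 system
        K = _relax_matrix(pair, "transverse")
        evals, evecs = np.linalg.eig(K)
        order = np.argsort(evals.real)
        evals, evecs = evals[order], evecs[:, order]
        coeffs = np.linalg.solve(evecs, np.array([m0a, m0b], dtype=complex))
        amps = evecs * coeffs
        th1, th2 = evals
        t1, t1_b = amps[:, 0]
        t2, t2_b = amps[:, 1]

    on_resonance = pair.omega_A == 0.0 and pair.omega_B == 0.0
    if on_resonance:
        c1, c2 = (t1 + t1_b).real, (t2 + t2_b).real
        norm = c1 + c2
    else:
        c1, c2 = abs(t1 + t1_b), abs(t2 + t2_b)
        norm = c1 + c2
    a2s, a2f = (c1 / norm, c2 / norm) if abs(norm) > 0 else (1.0, 0.0)
    return TransverseSolution(
        theta1=th1, theta2=th2, Theta1=t1, Theta2=t2,
        Theta1_B=t1_b, Theta2_B=t2_b, Mxy0_A=m0a, Mxy0_B=m0b,
        a2s=float(a2s), a2f=float(a2f), degenerate=bool(degenerate),
    )


def transverse_signal(
    pair: ExchangePair, times: np.ndarray, detection: str = "magnitude"
) -> np.ndarray:
    """Observed transverse decay ``Mxy_A(t) + Mxy_B(t)`` under the detection mode."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return transverse_solution(pair).total_signal(t, detection)


# ---------------------------------------------------------------------------
# asymptotics, coefficients, composite signal
# ---------------------------------------------------------------------------

def fast_exchange_approx(pair: ExchangePair, regime_margin: float = 10.0) -> FastExchangeApprox:
    """First-order fast-exchange asymptotics of the longitudinal eigenrates.

    ``lambda1 ~ xA R1_A + xB R1_B`` (the population-weighted mean rate) and
    ``lambda2 ~ k_ex (A_tot + B_tot) + xB R1_A + xA R1_B``; the slow/fast
    contribution coefficients tend to 1 and 0. ``regime_valid`` reports whether
    both exchange coefficients exceed ``regime_margin`` times the larger
    relaxation rate (the regime is reported, never enforced).
    """
    xa, xb = pair.x_A, pair.x_B
    l1 = xa * pair.R1_A + xb * pair.R1_B
    l2 = pair.k_ex * (pair.A_tot + pair.B_tot) + xb * pair.R1_A + xa * pair.R1_B
    rmax = max(pair.R1_A, pair.R1_B)
    valid = min(pair.k_A, pair.k_B) > regime_margin * rmax if rmax > 0 else pair.k_ex > 0
    return FastExchangeApprox(lambda1=l1, lambda2=l2, regime_valid=bool(valid))


def predicted_coefficients(pair: ExchangePair, channel: str = "T1") -> Tuple[float, float]:
    """Model-predicted normalized (slow, fast) contribution coefficients.

    These are what an ideal biexponential fit of the noiseless summed signal
    would return; they tend to (1, 0) as ``k_ex`` grows.
    """
    if channel == "T1":
        sol = longitudinal_solution(pair, "saturation")
        return sol.a1s, sol.a1f
    if channel == "T2":
        sol = transverse_solution(pair)
        return sol.a2s, sol.a2f
    raise ValueError(f"channel must be 'T1' or 'T2', got {channel!r}")


def observed_signal(
    pair: ExchangePair,
    nonexch_rate: float,
    nonexch_fraction: float,
    times: np.ndarray,
    channel: str = "T1",
) -> np.ndarray:
    """Three-component observed signal including the nonexchangeable pool.

    The carbon-bound solute protons do not exchange; they add an independent
    single-exponential component with weight ``nonexch_fraction`` (their
    fraction of all protons) on top of the two-pool exchange signal::

        S(t) = (1 - f_non) S_exchange(t) + f_non S_non(t)
    """
    if not 0.0 <= nonexch_fraction <= 1.0:
        raise ValueError("nonexch_fraction must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    f = nonexch_fraction
    if channel == "T1":
        exch = longitudinal_signal(pair, t) if f < 1.0 else np.zeros_like(t)
        non = 1.0 - np.exp(-nonexch_rate * t)
    elif channel == "T2":
        exch = transverse_signal(pair, t) if f < 1.0 else np.zeros_like(t)
        scale = pair.Mxy0_A + pair.Mxy0_B
        exch = exch / scale if scale > 0 else exch
        non = np.exp(-nonexch_rate * t)
    else:
        raise ValueError(f"channel must be 'T1' or 'T2', got {channel!r}")
    return (1.0 - f) * exch + f * non


# ---------------------------------------------------------------------------
# numerical oracle
# ---------------------------------------------------------------------------

def ode_reference(
    pair: ExchangePair,
    times: np.ndarray,
    channel: str = "longitudinal",
    initial: Union[str, Tuple, None] = None,
    rtol: float = 1e-13,
) -> Tuple[np.ndarray, np.ndarray]:
    """Direct numerical integration of the coupled rate equations.

    Returns the per-pool trajectories ``(M_A(t), M_B(t))`` — real for
    ``channel="longitudinal"``, complex for ``"transverse"`` — computed with a
    high-order adaptive integrator at tight tolerance. Serves as the
    independent validation oracle for the closed-form solutions.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a non-empty strictly increasing grid")
    scale = max(abs(pair.Mz_inf_A), abs(pair.Mz_inf_B), pair.Mxy0_A, pair.Mxy0_B, 1e-30)

    if channel == "longitudinal":
        if initial is None or initial == "saturation":
            y0 = np.array([0.0, 0.0])
        else:
            y0 = np.asarray(initial, dtype=float)

        def rhs(_, m):
            a, b = m
            return [
                pair.R1_A * (pair.Mz_inf_A - a) - pair.k_A * a + pair.k_B * b,
                pair.R1_B * (pair.Mz_inf_B - b) - pair.k_B * b + pair.k_A * a,
            ]
    elif channel == "transverse":
        if initial is None:
            m0 = np.array([pair.Mxy0_A, pair.Mxy0_B], dtype=complex)
        else:
            m0 = np.asarray(initial, dtype=complex)
        y0 = np.array([m0[0].real, m0[0].imag, m0[1].real, m0[1].imag])

        def rhs(_, y):
            a, b = y[0] + 1j * y[1], y[2] + 1j * y[3]
            da = -(pair.R2_A - 1j * pair.omega_A) * a - pair.k_A * a + pair.k_B * b
            db = -(pair.R2_B - 1j * pair.omega_B) * b - pair.k_B * b + pair.k_A * a
            return [da.real, da.imag, db.real, db.imag]
    else:
        raise ValueError(f"channel must be 'longitudinal' or 'transverse', got {channel!r}")

    t0 = min(0.0, t[0])
    sol = solve_ivp(
        rhs, (t0, t[-1]), y0, t_eval=t, method="DOP853",
        rtol=rtol, atol=0.1 * rtol * scale,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    if channel == "longitudinal":
        return sol.y[0], sol.y[1]
    return sol.y[0] + 1j * sol.y[1], sol.y[2] + 1j * sol.y[3]
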