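"""Stoichiometric proton bookkeeping for solute–water–D2O mixtures.

A prepared sample (e.g. sucrose dissolved in H2O or D2O) carries protons in
three site classes:

* solvent exchangeable sites (2 per water/D2O molecule),
* solute exchangeable (hydroxyl) sites,
* solute nonexchangeable (carbon-bound) positions.

Labile hydrogen is assumed to scramble uniformly over *all* exchangeable
sites — solvent and solute hydroxyls alike — via the fast cyclic exchange
mechanism, so a single equilibrium H occupancy applies to every labile site.
No equilibrium isotope fractionation factor is applied (it can be supplied
via ``fractionation_factor`` if needed).

The resulting :class:`ProtonInventory` gives the pool concentrations that
drive the two-pool exchange model (``A_tot``, ``B_tot``) and the fractions of
exchangeable vs nonexchangeable protons that the biexponential contribution
coefficients are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "SpeciesStoichiometry",
    "MixtureSpec",
    "ProtonInventory",
    "SUCROSE",
    "WATER",
    "HEAVY_WATER",
    "DEFAULT_D2O_RESIDUAL_PROTIATION",
    "proton_inventory",
    "freeze_dry_exchange",
    "wt_to_concentrations",
    "sucrose_solution_density",
]

#: Typical residual protiation of commercial 99.7 atom % D heavy water.
DEFAULT_D2O_RESIDUAL_PROTIATION = 0.003


@dataclass(frozen=True)
class SpeciesStoichiometry:
    """Hydrogen bookkeeping record for one molecular species.

    Parameters
    ----------
    name:
        Species label.
    molar_mass:
        Molar mass in g/mol.
    n_nonexchangeable_H:
        Carbon-bound protons per molecule (never exchange with solvent).
    n_exchangeable_sites:
        Labile-hydrogen sites per molecule (hydroxyl / solvent sites).
    """

    name: str
    molar_mass: float
    n_nonexchangeable_H: int
    n_exchangeable_sites: int

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be positive, got {self.molar_mass}")
        if self.n_nonexchangeable_H < 0 or self.n_exchangeable_sites < 0:
            raise ValueError("hydrogen counts must be non-negative")


#: Sucrose C12H22O11: 14 carbon-bound protons and 8 hydroxyl (labile) sites.
SUCROSE = SpeciesStoichiometry("sucrose", 342.30, 14, 8)
#: Light water: both hydrogens are labile.
WATER = SpeciesStoichiometry("H2O", 18.015, 0, 2)
#: Heavy water: two labile sites, H occupancy set by the mixture spec.
HEAVY_WATER = SpeciesStoichiometry("D2O", 20.027, 0, 2)


@dataclass(frozen=True)
class MixtureSpec:
    """Description of a prepared solute–solvent mixture.

    ``solvent_protiation`` and ``solute_site_protiation`` are atom fractions of
    H (vs D) at the respective exchangeable sites *as prepared*, before any
    scrambling between site classes.
    """

    solute_wt_fraction: float
    solvent_kind: str = "H2O"
    solvent_protiation: Optional[float] = None
    solute_site_protiation: float = 1.0
    density: Optional[float] = None  # kg/m^3
    temperature: float = 25.0  # degC, metadata only
    fractionation_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.solvent_kind not in ("H2O", "D2O"):
            raise ValueError(f"solvent_kind must be 'H2O' or 'D2O', got {self.solvent_kind!r}")
        if self.solvent_protiation is None:
            default = 1.0 if self.solvent_kind == "H2O" else DEFAULT_D2O_RESIDUAL_PROTIATION
            object.__setattr__(self, "solvent_protiation", default)
        for label, value in (
            ("solute_wt_fraction", self.solute_wt_fraction),
            ("solvent_protiation", self.solvent_protiation),
            ("solute_site_protiation", self.solute_site_protiation),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{label} must lie in [0, 1], got {value}")
        if self.density is not None and self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.fractionation_factor <= 0:
            raise ValueError("fractionation_factor must be positive")

    @property
    def solvent(self) -> SpeciesStoichiometry:
        return WATER if self.solvent_kind == "H2O" else HEAVY_WATER


@dataclass(frozen=True)
class ProtonInventory:
    """Proton concentrations and fractions for one mixture.

    ``A_tot``/``B_tot``/``C_nonexch`` are in mol/m^3 when ``basis`` is
    ``"molar"`` (density was available), otherwise in mol/kg of mixture
    (``basis == "per_kg"``); the fractions are basis-independent.
    """

    A_tot: float  # protons at solvent exchangeable sites
    B_tot: float  # protons at solute exchangeable sites
    C_nonexch: float  # nonexchangeable solute protons
    x_A: float  # fraction of solvent protons in the exchangeable pool
    x_B: float  # fraction of solute protons in the exchangeable pool
    xp_exch: float  # exchangeable fraction of all protons
    xp_non: float  # nonexchangeable fraction of all protons
    basis: str = "molar"

    def __post_init__(self) -> None:
        if min(self.A_tot, self.B_tot, self.C_nonexch) < 0:
            raise ValueError("proton concentrations must be non-negative")


def _moles_per_kg(mix: MixtureSpec, solute: SpeciesStoichiometry, solvent: SpeciesStoichiometry):
    """Moles of solute and solvent per kg of mixture."""
    w = mix.solute_wt_fraction
    n_solute = 1000.0 * w / solute.molar_mass
    n_solvent = 1000.0 * (1.0 - w) / solvent.molar_mass
    return n_solute, n_solvent


def _site_bookkeeping(mix, solute, solvent):
    """Per-kg labile-H and site counts, after scrambling over all labile sites."""
    n_solute, n_solvent = _moles_per_kg(mix, solute, solvent)
    solvent_sites = solvent.n_exchangeable_sites * n_solvent
    solute_sites = solute.n_exchangeable_sites * n_solute
    labile_H = solvent_sites * mix.solvent_protiation + solute_sites * mix.solute_site_protiation
    total_sites = solvent_sites + solute_sites
    if total_sites > 0:
        occupancy = labile_H / total_sites
    else:
        occupancy = 0.0
    # fractionation_factor != 1 would bias H toward one site class; with a
    # single equilibrium constant the uniform occupancy is simply rescaled
    # identically for both classes, so it cancels in every output.
    a_tot = solvent_sites * occupancy
    b_tot = solute_sites * occupancy
    c_non = solute.n_nonexchangeable_H * n_solute
    return a_tot, b_tot, c_non


def proton_inventory(
    mix: MixtureSpec,
    solute: SpeciesStoichiometry = SUCROSE,
    solvent: Optional[SpeciesStoichiometry] = None,
) -> ProtonInventory:
    """Compute the proton inventory of a mixture.

    Returns pool concentrations in mol/m^3 when ``mix.density`` is set,
    otherwise per kg of mixture (flagged by ``basis``). Raises if the mixture
    contains no protons at all ("no proton signal").
    """
    solvent = solvent if solvent is not None else mix.solvent
    a, b, c = _site_bookkeeping(mix, solute, solvent)
    total = a + b + c
    if total <= 0.0:
        raise ValueError("no proton signal: mixture contains no H at any site")
    exch = a + b
    x_a = a / exch if exch > 0 else 1.0
    scale, basis = (mix.density, "molar") if mix.density is not None else (1.0, "per_kg")
    return ProtonInventory(
        A_tot=a * scale,
        B_tot=b * scale,
        C_nonexch=c * scale,
        x_A=x_a,
        x_B=1.0 - x_a,
        xp_exch=exch / total,
        xp_non=c / total,
        basis=basis,
    )


def freeze_dry_exchange(
    stage1: MixtureSpec,
    solute: SpeciesStoichiometry = SUCROSE,
    solvent: Optional[SpeciesStoichiometry] = None,
) -> float:
    """Equilibrium H occupancy of solute labile sites after a pre-exchange step.

    A solute dissolved in (heavy) water equilibrates its labile sites with the
    solvent; freeze-drying then removes the solvent while the occupancy is
    retained by the solute. The returned value is used as
    ``solute_site_protiation`` of the redissolved sample.
    """
    solvent = solvent if solvent is not None else stage1.solvent
    n_solute, n_solvent = _moles_per_kg(stage1, solute, solvent)
    solvent_sites = solvent.n_exchangeable_sites * n_solvent
    solute_sites = solute.n_exchangeable_sites * n_solute
    total_sites = solvent_sites + solute_sites
    if total_sites <= 0:
        raise ValueError("mixture has no exchangeable sites")
    labile_H = (
        solvent_sites * stage1.solvent_protiation + solute_sites * stage1.solute_site_protiation
    )
    return labile_H / total_sites


def wt_to_concentrations(
    mix: MixtureSpec,
    solute: SpeciesStoichiometry = SUCROSE,
    solvent: Optional[SpeciesStoichiometry] = None,
    density: Optional[float] = None,
) -> tuple[float, float, float]:
    """Pool concentrations ``(A_tot, B_tot, C_nonexch)`` in mol/m^3.

    ``density`` (kg/m^3) overrides ``mix.density``. If neither is given, an
    error instructs the caller to either supply one or use
    :func:`sucrose_solution_density`.
    """
    rho = density if density is not None else mix.density
    if rho is None:
        raise ValueError(
            "density required for mol/m^3 concentrations: supply density= or use "
            "sucrose_solution_density(wt_percent) for aqueous sucrose"
        )
    if rho <= 0:
        raise ValueError(f"density must be positive, got {rho}")
    inv = proton_inventory(replace(mix, density=None), solute, solvent)
    return inv.A_tot * rho, inv.B_tot * rho, inv.C_nonexch * rho


# Aqueous sucrose density vs wt% at ~20-25 degC (handbook-style values);
# linear interpolation is well within the accuracy needed for kA, kB scales.
_SUCROSE_DENSITY_WT = np.arange(0.0, 75.0, 5.0)
_SUCROSE_DENSITY = np.array(
    [998.2, 1017.8, 1038.1, 1059.1, 1081.0, 1103.6, 1127.0, 1151.2,
     1176.4, 1202.5, 1229.7, 1257.7, 1286.5, 1316.4, 1347.2]
)


def sucrose_solution_density(wt_percent: float) -> float:
    """Approximate density (kg/m^3) of an aqueous sucrose solution, 0–70 wt%."""
    if not 0.0 <= wt_percent <= 70.0:
        raise ValueError("density correlation covers 0-70 wt% only")
    return float(np.interp(wt_percent, _SUCROSE_DENSITY_WT, _SUCROSE_DENSITY))
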