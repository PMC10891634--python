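"""Analytic Gibbs-energy model of ion selectivity in nanopores.

The model treats hydration as a competition between the Gibbs energy of bulk
water (``dG_water_water``, per water molecule) and that of the interfacial
water layer created when a solute is inserted.  Interfacial water has lost its
tetrahedral (DDAA, double-donor/double-acceptor) hydrogen bonds, so the
interfacial term is proportional to the DDAA hydrogen-bond Gibbs energy and to
the surface-to-volume ratio of the solute, hence ∝ 1/R for a sphere of radius
R::

    dG_hydration(R) = dG_water_water + 8 · dG_DDAA · r_H2O / R

Both energies are negative (stabilising).  The two terms are equal at the
*critical radius* R_c = 8·dG_DDAA·r_H2O / dG_water_water, which separates the
"initial" solvation regime (R < R_c, interfacial term dominates, solutes
disperse, effective repulsion) from the "hydrophobic" regime (R > R_c, bulk
term dominates, solutes aggregate, effective attraction).

For an ion approaching a membrane pierced by a circular nanopore, the
interfacial energy decomposes into an ion–membrane term minus an ion–circle
term (the circle being the material that would fill the pore).  Each term is
a geometric "interfacial measure" multiplied by a single coefficient ``kappa``
(kJ·Å/mol by default, see :func:`default_kappa`); the ion–circle measure is
1/(R_pore + r_ion + sep), so the barrier met by an ion entering a pore in the
initial regime is::

    dG_barrier ∝ 1/(R_pore + r_ion) − 1/(R_pore_c + r_ion_c)

which vanishes at the critical contact distance d_c = R_pore_c + r_ion_c and
decreases as either the ion or the pore grows — the thermodynamic origin of
size-based selectivity (a narrow pore bars small, strongly hydrated ions
behind a high barrier while larger ions pass over a lower one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "WaterThermoParams",
    "IonPoreGeometry",
    "EnergyDecomposition",
    "CriticalSet",
    "SelectivityResult",
    "default_kappa",
    "hydration_free_energy",
    "critical_radius",
    "classify_regime",
    "pair_critical_distance",
    "membrane_measure",
    "circle_measure",
    "ion_filter_energy",
    "solve_critical_contact_distance",
    "critical_contact",
    "barrier_height",
    "selectivity_map",
    "relative_selectivity",
]


class SingularParameterError(ValueError):
    """A model parameter makes the requested quantity undefined."""


class NoCriticalPointError(RuntimeError):
    """The critical-contact balance has no root in the search bracket."""


@dataclass(frozen=True)
class WaterThermoParams:
    """Ambient-water thermodynamic constants.

    ``dG_DDAA`` is the Gibbs energy of a tetrahedral (DDAA) hydrogen bond and
    ``dG_water_water`` the per-molecule Gibbs energy of bulk water, both
    negative, in kJ/mol.  ``r_H2O`` is the mean molecular radius of water in
    Å.  ``n_HB`` is the hydrogen-bond count per DDAA water (2 by definition
    of a double donor).  The defaults place the single-sphere critical radius
    at 6.5 Å under ambient conditions (293 K, 0.1 MPa); ``r_H2O`` and
    ``dG_water_water`` are calibrated stand-ins, not measured inputs, and may
    be overridden from config.
    """

    dG_DDAA: float = -2.66       # kJ/mol
    r_H2O: float = 1.4           # Å
    dG_water_water: float = -4.58  # kJ/mol per water molecule
    n_HB: float = 2.0
    temperature: float = 293.0   # K
    pressure: float = 0.1        # MPa

    def __post_init__(self) -> None:
        if self.dG_DDAA >= 0:
            raise ValueError("dG_DDAA must be negative (stabilising)")
        if self.dG_water_water > 0:
            raise ValueError("dG_water_water must be <= 0 (stabilising)")
        if self.r_H2O <= 0:
            raise ValueError("r_H2O must be positive")


@dataclass(frozen=True)
class IonPoreGeometry:
    """Geometry of one ion/nanopore configuration, all lengths in Å.

    ``d_axial`` is the centre-of-ion to centre-of-membrane distance along the
    pore axis; ``sep`` is the surface separation between the ion and the pore
    sphere, so the ion–circle centre distance is ``R_pore + r_ion + sep``.
    """

    r_ion: float
    R_pore: float
    w_membrane: float = 20.0
    d_axial: float = 0.0
    sep: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_ion", "R_pore", "w_membrane", "d_axial", "sep"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.d_ion_circle <= 0:
            raise ValueError("R_pore + r_ion + sep must be positive")

    @property
    def d_ion_circle(self) -> float:
        return self.R_pore + self.r_ion + self.sep


@dataclass
class EnergyDecomposition:
    """Gibbs-energy terms (kJ/mol unless noted) for one configuration."""

    dG_total: Optional[float] = None
    dG_solute_solute: float = 0.0
    dG_solute_water: Optional[float] = None
    dG_water_water_term: Optional[float] = None
    dG_hydration: Optional[float] = None
    dG_ion_filter: Optional[float] = None
    dG_ion_membrane: Optional[float] = None
    dG_ion_circle: Optional[float] = None
    dG_barrier: Optional[float] = None
    R_interfacial_ratio: Optional[float] = None


@dataclass(frozen=True)
class CriticalSet:
    """Critical sizes of the model (Å).

    ``R_c``: single-sphere critical radius; ``R_c_pair``: critical
    centre-to-centre distance for two identical spheres; ``d_c``: critical
    ion–pore contact distance R_pore_c + r_ion_c.
    """

    R_c: float
    R_c_pair: float
    d_c: float
    R_pore_c: float
    r_ion_c: float


@dataclass(frozen=True)
class SelectivityResult:
    """Relative binding free energy ΔΔG between two ion species.

    Sign convention: ``ddG < 0`` means the site prefers ion *a* over ion *b*
    (the a→b substitution costs free energy at the site relative to bulk).
    """

    ddG: float
    dG_site_a: float
    dG_site_b: float
    dG_bulk_a: float
    dG_bulk_b: float
    preferred_ion: Literal["a", "b", "none"]


def default_kappa(params: WaterThermoParams) -> float:
    """Interfacial-energy coefficient κ (kJ·Å/mol), single knob of the model.

    Chosen so that κ·(1/R) reproduces the interfacial hydration term
    8·dG_DDAA·r_H2O/R of an isolated sphere; negative (stabilising).
    """
    return 8.0 * params.dG_DDAA * params.r_H2O


def hydration_free_energy(R: float, params: WaterThermoParams) -> float:
    """Hydration free energy (kJ/mol) of a spherical solute of radius R (Å).

    Strictly increasing in R, asymptoting to ``dG_water_water`` as R → ∞.
    """
    if R <= 0:
        raise ValueError("solute radius must be positive")
    return params.dG_water_water + 8.0 * params.dG_DDAA * params.r_H2O / R


def critical_radius(params: WaterThermoParams) -> float:
    """Critical solute radius R_c (Å): interfacial term equals bulk term."""
    if params.dG_water_water == 0:
        raise SingularParameterError("dG_water_water = 0 leaves R_c undefined")
    return 8.0 * params.dG_DDAA * params.r_H2O / params.dG_water_water


def classify_regime(
    R: float, params: WaterThermoParams, rtol: float = 1e-12
) -> Literal["initial", "hydrophobic", "critical"]:
    """Solvation regime of a sphere of radius R: below R_c the interfacial
    term dominates ("initial", dispersive), above it the bulk term dominates
    ("hydrophobic", aggregative)."""
    if R <= 0:
        raise ValueError("solute radius must be positive")
    Rc = critical_radius(params)
    if abs(R - Rc) <= rtol * Rc:
        return "critical"
    return "initial" if R < Rc else "hydrophobic"


def pair_critical_distance(params: WaterThermoParams) -> float:
    """Critical centre distance (Å) for two identical spheres in water.

    The two-sphere interfacial term scales as 1/R_solute_solute, giving half
    the single-sphere critical radius (3.25 Å at ambient defaults).
    """
    return 0.5 * critical_radius(params)


def membrane_measure(d_axial: float, w_membrane: float) -> float:
    """Ion–membrane interfacial measure π·(√(w²+d²) − d), in Å.

    ``d_axial`` is the on-axis distance of the (point) ion from a membrane
    disc of radius ``w_membrane``.  Strictly decreasing in d, value π·w at
    contact, decaying like π·w²/(2d) at large d.
    """
    if d_axial < 0 or w_membrane <= 0:
        raise ValueError("require d_axial >= 0 and w_membrane > 0")
    return np.pi * (np.hypot(w_membrane, d_axial) - d_axial)


def circle_measure(geom: IonPoreGeometry) -> float:
    """Ion–circle interfacial measure 1/(R_pore + r_ion + sep), in Å⁻¹."""
    d = geom.d_ion_circle
    if d <= 0:
        raise SingularParameterError("ion-circle distance must be positive")
    return 1.0 / d


def ion_filter_energy(
    geom: IonPoreGeometry,
    params: WaterThermoParams,
    kappa: Optional[float] = None,
) -> EnergyDecomposition:
    """κ-scaled interfacial decomposition dG_ion_filter = dG_ion_membrane −
    dG_ion_circle for one geometry.

    The membrane term uses the axial distance ``geom.d_axial``; the circle
    term the centre distance R_pore + r_ion + sep.
    """
    k = default_kappa(params) if kappa is None else kappa
    dG_mem = k * membrane_measure(geom.d_axial, geom.w_membrane)
    dG_circ = k * circle_measure(geom)
    return EnergyDecomposition(
        dG_ion_membrane=dG_mem,
        dG_ion_circle=dG_circ,
        dG_ion_filter=dG_mem - dG_circ,
    )


def _contact_balance(d_c: float, w: float, params: WaterThermoParams,
                     kappa: float) -> float:
    # at contact (sep = 0) the on-axis ion sits d_c = R_pore + r_ion from the
    # membrane centre; balance dG_ion_membrane - dG_ion_circle = dG_water_water
    return kappa * (membrane_measure(d_c, w) - 1.0 / d_c) - params.dG_water_water


def solve_critical_contact_distance(
    params: WaterThermoParams,
    w_membrane: float = 20.0,
    kappa: Optional[float] = None,
    d_max: float = 1e6,
) -> float:
    """Root d_c of the contact balance dG_ion_membrane − dG_ion_circle =
    dG_water_water, taken on the decreasing branch (regime flips initial →
    hydrophobic as d grows through it)."""
    k = default_kappa(params) if kappa is None else kappa
    if k == 0 or params.dG_water_water == 0:
        raise SingularParameterError("kappa and dG_water_water must be nonzero")
    f = lambda d: _contact_balance(d, w_membrane, params, k)
    grid = np.geomspace(1e-6, d_max, 4096)
    vals = np.array([f(d) for d in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15))
    if not roots:
        raise NoCriticalPointError(
            "ion-filter balance has no root in (0, %g] Å for these parameters"
            % d_max
        )
    return float(roots[-1])


def critical_contact(
    params: WaterThermoParams,
    r_ion: Optional[float] = None,
    R_pore: Optional[float] = None,
    w_membrane: float = 20.0,
    kappa: Optional[float] = None,
    d_max: float = 1e6,
) -> CriticalSet:
    """Solve the ion–filter balance at contact for the critical pore/ion size.

    Exactly one of ``r_ion``/``R_pore`` is given; the conjugate critical size
    is the root of dG_ion_membrane(d_c) − dG_ion_circle(d_c) = dG_water_water
    with d_c = R_pore + r_ion and sep = 0.  Where the balance has two roots
    the one on the decreasing branch is returned: there the regime flips from
    initial (d < d_c, barrier) to hydrophobic (d > d_c), matching the physical
    reading of the critical distance.
    """
    if (r_ion is None) == (R_pore is None):
        raise ValueError("supply exactly one of r_ion / R_pore")
    given = r_ion if r_ion is not None else R_pore
    if given is None or given < 0:
        raise ValueError("supplied size must be >= 0")
    k = default_kappa(params) if kappa is None else kappa
    d_c = solve_critical_contact_distance(params, w_membrane=w_membrane,
                                          kappa=k, d_max=d_max)
    conjugate = d_c - given
    if conjugate <= 0:
        raise NoCriticalPointError(
            "critical contact distance %.3f Å is smaller than the supplied "
            "size %.3f Å; no positive conjugate critical size" % (d_c, given)
        )
    if r_ion is not None:
        r_c, Rp_c = r_ion, conjugate
    else:
        r_c, Rp_c = conjugate, R_pore  # type: ignore[assignment]
    Rc = critical_radius(params)
    return CriticalSet(R_c=Rc, R_c_pair=0.5 * Rc, d_c=d_c,
                       R_pore_c=float(Rp_c), r_ion_c=float(r_c))


def barrier_height(
    geom: IonPoreGeometry,
    params: WaterThermoParams,
    critical: CriticalSet,
    kappa: Optional[float] = None,
) -> tuple[float, str]:
    """Energy barrier (kJ/mol, positive magnitude) for an ion entering a pore.

    |κ|·[1/(R_pore + r_ion) − 1/d_c] in the initial regime (contact distance
    below critical), exactly zero at the critical combination and clamped to
    zero in the hydrophobic regime.  Returns ``(barrier, regime)``.
    """
    k = default_kappa(params) if kappa is None else kappa
    d = geom.R_pore + geom.r_ion
    if d <= 0:
        raise SingularParameterError("R_pore + r_ion must be positive")
    diff = 1.0 / d - 1.0 / critical.d_c
    if diff > 0:
        return abs(k) * diff, "initial"
    if diff == 0:
        return 0.0, "critical"
    return 0.0, "hydrophobic"


def selectivity_map(
    r_ion_grid: Iterable[float],
    R_pore_grid: Iterable[float],
    params: WaterThermoParams,
    w_membrane: float = 20.0,
    kappa: Optional[float] = None,
) -> pd.DataFrame:
    """Classify every (r_ion, R_pore) cell as free-pass / barrier / forbidden.

    Initial-regime cells (contact distance below critical) carry the barrier
    value; hydrophobic cells pass freely when the ion fits the aperture
    (r_ion ≤ R_pore) and are sterically forbidden otherwise.
    """
    r_ions = np.asarray(list(r_ion_grid), dtype=float)
    R_pores = np.asarray(list(R_pore_grid), dtype=float)
    if (r_ions <= 0).any() or (R_pores <= 0).any():
        raise ValueError("grids must be positive")
    k = default_kappa(params) if kappa is None else kappa
    # d_c depends only on (params, w, kappa): solve once
    Rc = critical_radius(params)
    d_c = solve_critical_contact_distance(params, w_membrane=w_membrane, kappa=k)
    crit = CriticalSet(R_c=Rc, R_c_pair=0.5 * Rc, d_c=d_c,
                       R_pore_c=np.nan, r_ion_c=np.nan)
    rows = []
    for ri in r_ions:
        for Rp in R_pores:
            geom = IonPoreGeometry(r_ion=ri, R_pore=Rp, w_membrane=w_membrane)
            b, regime = barrier_height(geom, params, crit, kappa=k)
            if regime == "initial":
                label = "barrier"
            elif ri <= Rp:
                label, b = "free-pass", 0.0
            else:
                label, b = "forbidden", np.nan
            rows.append((ri, Rp, regime, label, b))
    return pd.DataFrame(
        rows, columns=["r_ion", "R_pore", "regime", "label", "barrier_kJmol"]
    )


def relative_selectivity(
    dG_site_a: float,
    dG_bulk_a: float,
    dG_site_b: float,
    dG_bulk_b: float,
) -> SelectivityResult:
    """ΔΔG_a→b = (ΔG_site,a − ΔG_site,b) − (ΔG_bulk,a − ΔG_bulk,b).

    Negative ΔΔG means the site stabilises ion *a* more than bulk water does,
    relative to ion *b*: the site prefers *a*.
    """
    for v in (dG_site_a, dG_bulk_a, dG_site_b, dG_bulk_b):
        if not np.isfinite(v):
            raise ValueError("energies must be finite")
    ddG = (dG_site_a - dG_site_b) - (dG_bulk_a - dG_bulk_b)
    preferred: Literal["a", "b", "none"]
    preferred = "a" if ddG < 0 else ("b" if ddG > 0 else "none")
    return SelectivityResult(
        ddG=ddG, dG_site_a=dG_site_a, dG_site_b=dG_site_b,
        dG_bulk_a=dG_bulk_a, dG_bulk_b=dG_bulk_b, preferred_ion=preferred,
    )
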