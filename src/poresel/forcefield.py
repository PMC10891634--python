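"""Minimal non-bonded force field: switched Lennard-Jones + reaction-field
Coulomb under periodic minimum image.

Species parameters follow the common rigid 3-site water model (TIP3P-like
geometry and charges) with standard CHARMM-compatible Lennard-Jones values
for the monovalent ions and a neutral aromatic-carbon wall atom; they are
versioned here as the package's parameter table, not fitted.  Lennard-Jones
interactions are switched smoothly (C1) to zero between ``r_on`` and
``r_off``; electrostatics use a Barker–Watts reaction field (relative
permittivity ``eps_rf``) truncated at ``r_off``, or bare truncated Coulomb
when ``coulomb_mode="bare"``.

Pairs within the same molecule and frozen–frozen (wall–wall) pairs are
excluded.  Energies kJ/mol, lengths Å, charges e.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
from numba import njit

from .constants import KCAL, MASSES
from .frames import Frame

__all__ = ["SpeciesParams", "ForceFieldParams", "default_forcefield",
           "compute_forces", "pair_energy_tables"]

_RMIN_TO_SIGMA = 2.0 ** (-1.0 / 6.0)


@dataclass(frozen=True)
class SpeciesParams:
    epsilon: float   # kJ/mol
    sigma: float     # Å
    charge: float    # e
    mass: float      # g/mol


def _from_charmm(eps_kcal: float, rmin_half: float, charge: float,
                 mass: float) -> SpeciesParams:
    return SpeciesParams(epsilon=eps_kcal * KCAL,
                         sigma=2.0 * rmin_half * _RMIN_TO_SIGMA,
                         charge=charge, mass=mass)


@dataclass(frozen=True)
class ForceFieldParams:
    """Non-bonded parameters plus the rigid water geometry."""

    species: Dict[str, SpeciesParams] = field(default_factory=dict)
    r_on: float = 10.0           # Å, LJ switch start
    r_off: float = 12.0          # Å, LJ switch end = Coulomb cutoff
    eps_rf: float = 78.0         # reaction-field dielectric
    coulomb_mode: str = "rf"     # "rf" or "bare" (truncated 1/r)
    r_OH: float = 0.9572         # Å
    theta_HOH: float = 104.52    # degrees

    def __post_init__(self) -> None:
        if not (0 < self.r_on < self.r_off):
            raise ValueError("require 0 < r_on < r_off")
        if self.coulomb_mode not in ("rf", "bare"):
            raise ValueError("coulomb_mode must be 'rf' or 'bare'")

    @property
    def r_HH(self) -> float:
        return 2.0 * self.r_OH * np.sin(np.deg2rad(self.theta_HOH) / 2.0)

    def with_cutoffs(self, r_on: float, r_off: float) -> "ForceFieldParams":
        return replace(self, r_on=r_on, r_off=r_off)

    def lookup(self, label: str) -> SpeciesParams:
        try:
            return self.species[label.upper()]
        except KeyError:
            raise KeyError(f"no force-field parameters for species '{label}'")


def default_forcefield(**overrides) -> ForceFieldParams:
    """TIP3P-like water, CHARMM-compatible ions, neutral carbon wall."""
    species = {
        "OW": SpeciesParams(0.1521 * KCAL, 3.15066, -0.834, MASSES["OW"]),
        "HW": _from_charmm(0.046, 0.2245, +0.417, MASSES["HW"]),
        "NA": _from_charmm(0.0469, 1.41075, +1.0, MASSES["NA"]),
        "K": _from_charmm(0.0870, 1.76375, +1.0, MASSES["K"]),
        "CL": _from_charmm(0.150, 2.27, -1.0, MASSES["CL"]),
        "C": SpeciesParams(0.07 * KCAL, 3.55, 0.0, MASSES["C"]),
    }
    return ForceFieldParams(species=species, **overrides)


@njit(cache=True, fastmath=True)
def _nb_kernel(pos, box, eps, sig, q, mol_id, frozen,
               r_on, r_off, k_rf, c_rf, use_rf):
    """O(N²) pair loop: switched LJ + (reaction-field) Coulomb."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    r_on2 = r_on * r_on
    r_off2 = r_off * r_off
    denom = (r_off2 - r_on2) ** 3
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            if frozen[i] and frozen[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > 0.5 * box[0]:
                dx -= box[0]
            elif dx < -0.5 * box[0]:
                dx += box[0]
            if dy > 0.5 * box[1]:
                dy -= box[1]
            elif dy < -0.5 * box[1]:
                dy += box[1]
            if dz > 0.5 * box[2]:
                dz -= box[2]
            elif dz < -0.5 * box[2]:
                dz += box[2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= r_off2 or r2 < 1e-12:
                continue
            r = np.sqrt(r2)
            f_over_r = 0.0  # -(dV/dr)/r
            # Lennard-Jones with C1 switching
            eij = np.sqrt(eps[i] * eps[j])
            if eij > 0.0:
                sij = 0.5 * (sig[i] + sig[j])
                sr6 = (sij * sij / r2) ** 3
                sr12 = sr6 * sr6
                v_lj = 4.0 * eij * (sr12 - sr6)
                dv_lj = -24.0 * eij * (2.0 * sr12 - sr6) / r
                if r2 <= r_on2:
                    energy += v_lj
                    f_over_r += -dv_lj / r
                else:
                    sw = (r_off2 - r2) ** 2 * (r_off2 + 2.0 * r2 - 3.0 * r_on2) / denom
                    dsw = 12.0 * r * (r_off2 - r2) * (r_on2 - r2) / denom
                    energy += v_lj * sw
                    f_over_r += -(dv_lj * sw + v_lj * dsw) / r
            # Coulomb
            qq = q[i] * q[j]
            if qq != 0.0:
                if use_rf:
                    v_c = 1389.35457644382 * qq * (1.0 / r + k_rf * r2 - c_rf)
                    dv_c = 1389.35457644382 * qq * (-1.0 / r2 + 2.0 * k_rf * r)
                else:
                    v_c = 1389.35457644382 * qq / r
                    dv_c = -1389.35457644382 * qq / r2
                energy += v_c
                f_over_r += -dv_c / r
            fx = f_over_r * dx
            fy = f_over_r * dy
            fz = f_over_r * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return forces, energy


@njit(cache=True, fastmath=True)
def _build_pairs(pos, box, mol_id, frozen, r_list):
    """Verlet pair list: all non-excluded pairs within ``r_list`` (Å)."""
    n = pos.shape[0]
    pairs = np.empty((n * max(n - 1, 1) // 2, 2), dtype=np.int64)
    m = 0
    r2max = r_list * r_list
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol_id[i] == mol_id[j]:
                continue
            if frozen[i] and frozen[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > 0.5 * box[0]:
                dx -= box[0]
            elif dx < -0.5 * box[0]:
                dx += box[0]
            if dy > 0.5 * box[1]:
                dy -= box[1]
            elif dy < -0.5 * box[1]:
                dy += box[1]
            if dz > 0.5 * box[2]:
                dz -= box[2]
            elif dz < -0.5 * box[2]:
                dz += box[2]
            if dx * dx + dy * dy + dz * dz < r2max:
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return pairs[:m].copy()


@njit(cache=True, fastmath=True)
def _pair_kernel(pos, box, pairs, eps_ij, sig_ij, qq_ij,
                 r_on, r_off, k_rf, c_rf, use_rf):
    """Switched LJ + Coulomb over a precomputed pair list."""
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    r_on2 = r_on * r_on
    r_off2 = r_off * r_off
    denom = (r_off2 - r_on2) ** 3
    for p in range(pairs.shape[0]):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if dx > 0.5 * box[0]:
            dx -= box[0]
        elif dx < -0.5 * box[0]:
            dx += box[0]
        if dz > 0.5 * box[2]:
            dz -= box[2]
        elif dz < -0.5 * box[2]:
            dz += box[2]
        if dy > 0.5 * box[1]:
            dy -= box[1]
        elif dy < -0.5 * box[1]:
            dy += box[1]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r_off2 or r2 < 1e-12:
            continue
        r = np.sqrt(r2)
        f_over_r = 0.0
        eij = eps_ij[p]
        if eij > 0.0:
            sij = sig_ij[p]
            sr6 = (sij * sij / r2) ** 3
            sr12 = sr6 * sr6
            v_lj = 4.0 * eij * (sr12 - sr6)
            dv_lj = -24.0 * eij * (2.0 * sr12 - sr6) / r
            if r2 <= r_on2:
                energy += v_lj
                f_over_r += -dv_lj / r
            else:
                sw = (r_off2 - r2) ** 2 * (r_off2 + 2.0 * r2 - 3.0 * r_on2) / denom
                dsw = 12.0 * r * (r_off2 - r2) * (r_on2 - r2) / denom
                energy += v_lj * sw
                f_over_r += -(dv_lj * sw + v_lj * dsw) / r
        qq = qq_ij[p]
        if qq != 0.0:
            if use_rf:
                v_c = 1389.35457644382 * qq * (1.0 / r + k_rf * r2 - c_rf)
                dv_c = 1389.35457644382 * qq * (-1.0 / r2 + 2.0 * k_rf * r)
            else:
                v_c = 1389.35457644382 * qq / r
                dv_c = -1389.35457644382 * qq / r2
            energy += v_c
            f_over_r += -dv_c / r
        fx = f_over_r * dx
        fy = f_over_r * dy
        fz = f_over_r * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return forces, energy


class NeighborList:
    """Verlet list with a skin; rebuilt when any atom moves half the skin."""

    def __init__(self, ff: ForceFieldParams, mol_id, frozen, skin: float = 1.0):
        self.ff = ff
        self.skin = skin
        self.mol_id = np.asarray(mol_id, dtype=np.int64)
        self.frozen = np.asarray(frozen, dtype=np.bool_)
        self.pairs: np.ndarray | None = None
        self._ref_pos: np.ndarray | None = None

    def _needs_rebuild(self, pos: np.ndarray) -> bool:
        if self.pairs is None or self._ref_pos is None:
            return True
        disp = pos - self._ref_pos
        d2max = float(np.max(np.einsum("ij,ij->i", disp, disp)))
        return d2max > (0.5 * self.skin) ** 2

    def forces(self, pos: np.ndarray, box: np.ndarray, eps, sig, q):
        box = np.asarray(box, dtype=np.float64)
        pos = np.ascontiguousarray(pos, dtype=np.float64)
        # displacement check on raw (unwrapped) coordinates; the kernels use
        # a single-image convention, so wrap a copy for them
        rebuild = self._needs_rebuild(pos)
        wrapped = pos - box * np.floor(pos / box)
        if rebuild:
            self.pairs = _build_pairs(wrapped, box, self.mol_id, self.frozen,
                                      self.ff.r_off + self.skin)
            self._ref_pos = pos.copy()
            i, j = self.pairs[:, 0], self.pairs[:, 1]
            eps = np.asarray(eps, float)
            sig = np.asarray(sig, float)
            q = np.asarray(q, float)
            self._eps_ij = np.sqrt(eps[i] * eps[j])
            self._sig_ij = 0.5 * (sig[i] + sig[j])
            self._qq_ij = q[i] * q[j]
        k_rf, c_rf = rf_constants(self.ff)
        return _pair_kernel(wrapped, box, self.pairs,
                            self._eps_ij, self._sig_ij, self._qq_ij,
                            self.ff.r_on, self.ff.r_off, k_rf, c_rf,
                            self.ff.coulomb_mode == "rf")


def rf_constants(ff: ForceFieldParams) -> Tuple[float, float]:
    """Reaction-field k_rf and shift c_rf for the cutoff r_off."""
    rc = ff.r_off
    k_rf = (ff.eps_rf - 1.0) / ((2.0 * ff.eps_rf + 1.0) * rc ** 3)
    c_rf = 1.0 / rc + k_rf * rc ** 2
    return k_rf, c_rf


def nb_forces(pos, box, eps, sig, q, mol_id, frozen, ff: ForceFieldParams):
    """Forces (kJ/mol/Å) and potential energy (kJ/mol) on raw arrays."""
    k_rf, c_rf = rf_constants(ff)
    box = np.asarray(box, dtype=np.float64)
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    pos = pos - box * np.floor(pos / box)
    return _nb_kernel(
        pos,
        box,
        np.asarray(eps, dtype=np.float64), np.asarray(sig, dtype=np.float64),
        np.asarray(q, dtype=np.float64), np.asarray(mol_id, dtype=np.int64),
        np.asarray(frozen, dtype=np.bool_),
        ff.r_on, ff.r_off, k_rf, c_rf, ff.coulomb_mode == "rf",
    )


def pair_energy_tables(frame: Frame, ff: ForceFieldParams):
    """Per-atom parameter arrays (eps, sig, q, mol_id, frozen, mass) in the
    frame's canonical atom order."""
    species = frame.species()
    eps = np.array([ff.lookup(s).epsilon for s in species])
    sig = np.array([ff.lookup(s).sigma for s in species])
    q = np.empty(len(species))
    mass = np.array([ff.lookup(s).mass for s in species])
    mol_id = np.empty(len(species), dtype=np.int64)
    frozen = np.zeros(len(species), dtype=bool)
    nw3 = 3 * frame.n_waters
    ni = len(frame.ion_pos)
    for a, s in enumerate(species):
        q[a] = ff.lookup(s).charge
        if a < nw3:
            mol_id[a] = a // 3
        else:
            mol_id[a] = frame.n_waters + (a - nw3)
    # ion charges may be overridden on the frame
    q[nw3:nw3 + ni] = frame.ion_charges
    frozen[nw3 + ni:] = True
    return eps, sig, q, mol_id, frozen, mass


def compute_forces(frame: Frame, ff: ForceFieldParams):
    """Forces and potential energy for a frame (wall atoms contribute forces
    to mobile atoms but are frozen themselves)."""
    eps, sig, q, mol_id, frozen, _ = pair_energy_tables(frame, ff)
    return nb_forces(frame.positions(), frame.box, eps, sig, q,
                     mol_id, frozen, ff)
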