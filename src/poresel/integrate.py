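"""Langevin dynamics with rigid 3-site waters (BAOAB splitting + SHAKE/RATTLE).

The integrator advances a :class:`System` (mobile waters and ions, frozen
wall atoms) with the BAOAB splitting of Langevin dynamics; with zero friction
it reduces to velocity Verlet.  Water rigidity is enforced by iterative SHAKE
position corrections (with the matching velocity update) after each drift
substep and RATTLE velocity projections after each kick, holding the two O–H
bonds and the H–H distance.  Runs are bit-reproducible for a given seed in
single-threaded mode.

Internal units: Å, ps, kJ/mol; masses are converted to kJ·ps²/(mol·Å²) so
that kinetic energy and k_B·T share the energy unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from numba import njit

from .constants import KB
from .forcefield import ForceFieldParams, NeighborList, pair_energy_tables
from .frames import Frame, Trajectory

__all__ = ["IntegratorConfig", "System", "LangevinIntegrator"]

#: g/mol → kJ·ps²/(mol·Å²)
MASS_UNIT = 0.01


class ConstraintError(RuntimeError):
    """SHAKE/RATTLE failed to converge; carries the offending positions."""

    def __init__(self, msg: str, positions: Optional[np.ndarray] = None):
        super().__init__(msg)
        self.positions = positions


@dataclass(frozen=True)
class IntegratorConfig:
    seed: int
    timestep_fs: float = 2.0
    friction: float = 2.0          # ps⁻¹
    temperature: float = 300.0     # K
    constraint_tol: float = 1e-8   # relative, on squared bond lengths

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0 or self.temperature <= 0:
            raise ValueError("timestep and temperature must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory for every stochastic run")


@dataclass
class System:
    """Mutable simulation state in the canonical atom order."""

    pos: np.ndarray
    vel: np.ndarray
    box: np.ndarray
    eps: np.ndarray
    sig: np.ndarray
    charge: np.ndarray
    mass: np.ndarray               # g/mol
    mol_id: np.ndarray
    frozen: np.ndarray
    n_waters: int
    ion_labels: List[str] = field(default_factory=list)
    pore_center: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    @classmethod
    def from_frame(cls, frame: Frame, ff: ForceFieldParams,
                   pore_center: Optional[np.ndarray] = None) -> "System":
        eps, sig, q, mol_id, frozen, mass = pair_energy_tables(frame, ff)
        if pore_center is None and len(frame.wall_pos):
            pore_center = np.array([0.5 * frame.box[0], 0.5 * frame.box[1],
                                    float(np.mean(frame.wall_pos[:, 2]))])
        return cls(pos=frame.positions().astype(float), box=frame.box.copy(),
                   vel=np.zeros((frame.n_atoms, 3)),
                   eps=eps, sig=sig, charge=q, mass=mass, mol_id=mol_id,
                   frozen=frozen, n_waters=frame.n_waters,
                   ion_labels=[l.upper() for l in frame.ion_labels],
                   pore_center=pore_center)

    @property
    def n_atoms(self) -> int:
        return len(self.pos)

    @property
    def ion_indices(self) -> np.ndarray:
        nw3 = 3 * self.n_waters
        return np.arange(nw3, nw3 + len(self.ion_labels))

    def to_frame(self) -> Frame:
        nw3 = 3 * self.n_waters
        ni = len(self.ion_labels)
        return Frame(box=self.box.copy(),
                     water_O=self.pos[0:nw3:3].copy(),
                     water_H1=self.pos[1:nw3:3].copy(),
                     water_H2=self.pos[2:nw3:3].copy(),
                     ion_labels=list(self.ion_labels),
                     ion_pos=self.pos[nw3:nw3 + ni].copy(),
                     ion_charges=self.charge[nw3:nw3 + ni].copy(),
                     wall_pos=self.pos[nw3 + ni:].copy())

    def n_dof(self) -> int:
        """Degrees of freedom: 3 per mobile atom minus 3 constraints/water."""
        n_mobile = int((~self.frozen).sum())
        return 3 * n_mobile - 3 * self.n_waters

    def kinetic_energy(self) -> float:
        m = self.mass[~self.frozen] * MASS_UNIT
        v = self.vel[~self.frozen]
        return float(0.5 * np.sum(m[:, None] * v * v))

    def kinetic_temperature(self) -> float:
        return 2.0 * self.kinetic_energy() / (self.n_dof() * KB)


@njit(cache=True)
def _shake(pos, ref, vel, inv_mass, n_waters, d_oh2, d_hh2, tol, dt_sub):
    """Iterative SHAKE on rigid waters; also applies the velocity correction
    for the position shift over substep dt_sub.  Returns max iterations used."""
    max_iter = 0
    for w in range(n_waters):
        iO = 3 * w
        iH1 = iO + 1
        iH2 = iO + 2
        it = 0
        for it in range(500):
            done = True
            for c in range(3):
                if c == 0:
                    i, j, d2 = iO, iH1, d_oh2
                elif c == 1:
                    i, j, d2 = iO, iH2, d_oh2
                else:
                    i, j, d2 = iH1, iH2, d_hh2
                rx = pos[i, 0] - pos[j, 0]
                ry = pos[i, 1] - pos[j, 1]
                rz = pos[i, 2] - pos[j, 2]
                r2 = rx * rx + ry * ry + rz * rz
                diff = d2 - r2
                if abs(diff) > tol * d2:
                    done = False
                    # reference (pre-drift) bond vector
                    sx = ref[i, 0] - ref[j, 0]
                    sy = ref[i, 1] - ref[j, 1]
                    sz = ref[i, 2] - ref[j, 2]
                    dot = rx * sx + ry * sy + rz * sz
                    if abs(dot) < 1e-12:
                        dot = 1e-12
                    g = diff / (2.0 * dot * (inv_mass[i] + inv_mass[j]))
                    pos[i, 0] += g * inv_mass[i] * sx
                    pos[i, 1] += g * inv_mass[i] * sy
                    pos[i, 2] += g * inv_mass[i] * sz
                    pos[j, 0] -= g * inv_mass[j] * sx
                    pos[j, 1] -= g * inv_mass[j] * sy
                    pos[j, 2] -= g * inv_mass[j] * sz
                    if dt_sub > 0.0:
                        vel[i, 0] += g * inv_mass[i] * sx / dt_sub
                        vel[i, 1] += g * inv_mass[i] * sy / dt_sub
                        vel[i, 2] += g * inv_mass[i] * sz / dt_sub
                        vel[j, 0] -= g * inv_mass[j] * sx / dt_sub
                        vel[j, 1] -= g * inv_mass[j] * sy / dt_sub
                        vel[j, 2] -= g * inv_mass[j] * sz / dt_sub
            if done:
                break
        if it + 1 > max_iter:
            max_iter = it + 1
        if it >= 499:
            return -1
    return max_iter


@njit(cache=True)
def _rattle(pos, vel, inv_mass, n_waters, tol):
    """Exact velocity projection for rigid triatomics: the constraint
    conditions r_c·(v_i − v_j) = 0 are linear in the three Lagrange
    multipliers, so each water is a closed-form 3×3 solve."""
    for w in range(n_waters):
        iO = 3 * w
        iH1 = iO + 1
        iH2 = iO + 2
        wO = inv_mass[iO]
        wH = inv_mass[iH1]
        r0 = pos[iO] - pos[iH1]
        r1 = pos[iO] - pos[iH2]
        r2v = pos[iH1] - pos[iH2]
        b0 = np.dot(r0, vel[iO] - vel[iH1])
        b1 = np.dot(r1, vel[iO] - vel[iH2])
        b2 = np.dot(r2v, vel[iH1] - vel[iH2])
        a00 = (wO + wH) * np.dot(r0, r0)
        a11 = (wO + wH) * np.dot(r1, r1)
        a22 = 2.0 * wH * np.dot(r2v, r2v)
        r0r1 = np.dot(r0, r1)
        r0r2 = np.dot(r0, r2v)
        r1r2 = np.dot(r1, r2v)
        a01 = wO * r0r1
        a02 = -wH * r0r2
        a12 = wH * r1r2
        a10 = wO * r0r1
        a20 = -wH * r0r2
        a21 = wH * r1r2
        det = (a00 * (a11 * a22 - a12 * a21)
               - a01 * (a10 * a22 - a12 * a20)
               + a02 * (a10 * a21 - a11 * a20))
        if abs(det) < 1e-300:
            return -1
        # Cramer's rule for A λ = -b
        l0 = (-b0 * (a11 * a22 - a12 * a21)
              - a01 * (-b1 * a22 - a12 * -b2)
              + a02 * (-b1 * a21 - a11 * -b2)) / det
        l1 = (a00 * (-b1 * a22 - a12 * -b2)
              - -b0 * (a10 * a22 - a12 * a20)
              + a02 * (a10 * -b2 - -b1 * a20)) / det
        l2 = (a00 * (a11 * -b2 - -b1 * a21)
              - a01 * (a10 * -b2 - -b1 * a20)
              + -b0 * (a10 * a21 - a11 * a20)) / det
        for k in range(3):
            vel[iO, k] += wO * (l0 * r0[k] + l1 * r1[k])
            vel[iH1, k] += wH * (-l0 * r0[k] + l2 * r2v[k])
            vel[iH2, k] += wH * (-l1 * r1[k] - l2 * r2v[k])
    return 0


class LangevinIntegrator:
    """BAOAB Langevin integrator over a :class:`System`.

    ``extra_force(system) -> (n_atoms, 3) array`` lets callers add biasing,
    restraint or field forces on top of the force-field forces; the pure
    force-field forces of the current positions are kept on
    ``self.last_ff_forces`` for collective-variable estimators.
    """

    def __init__(self, system: System, ff: ForceFieldParams,
                 config: IntegratorConfig,
                 extra_force: Optional[Callable[[System], np.ndarray]] = None):
        self.system = system
        self.ff = ff
        self.config = config
        self.extra_force = extra_force
        self.rng = np.random.default_rng(config.seed)
        self.dt = config.timestep_fs * 1e-3  # ps
        m = system.mass * MASS_UNIT
        self.inv_mass = np.where(system.frozen, 0.0, 1.0 / m)
        self._m_int = m
        gamma = config.friction
        self._c1 = np.exp(-gamma * self.dt)
        kT = KB * config.temperature
        self._c2 = np.sqrt((1.0 - self._c1 ** 2) * kT / m)
        self._c2[system.frozen] = 0.0
        self._nlist = NeighborList(ff, system.mol_id, system.frozen)
        self.last_ff_forces, self.last_potential = self._ff_forces()
        self.last_forces = self._total_forces(self.last_ff_forces)
        self._d_oh2 = ff.r_OH ** 2
        self._d_hh2 = ff.r_HH ** 2

    def _ff_forces(self):
        s = self.system
        return self._nlist.forces(s.pos, s.box, s.eps, s.sig, s.charge)

    def _total_forces(self, ff_forces: np.ndarray) -> np.ndarray:
        if self.extra_force is None:
            return ff_forces
        return ff_forces + self.extra_force(self.system)

    def initialize_velocities(self, temperature: Optional[float] = None) -> None:
        """Maxwell–Boltzmann draw, constraint-projected, frozen atoms at rest."""
        s = self.system
        T = self.config.temperature if temperature is None else temperature
        sigma = np.sqrt(KB * T / self._m_int)
        s.vel = self.rng.standard_normal(s.pos.shape) * sigma[:, None]
        s.vel[s.frozen] = 0.0
        self._apply_rattle()

    def _apply_shake(self, ref: np.ndarray, dt_sub: float) -> None:
        s = self.system
        if s.n_waters == 0:
            return
        tol = self.config.constraint_tol
        r = _shake(s.pos, ref, s.vel, self.inv_mass, s.n_waters,
                   self._d_oh2, self._d_hh2, tol, dt_sub)
        if r < 0:
            raise ConstraintError("SHAKE failed to converge", s.pos.copy())

    def _apply_rattle(self) -> None:
        s = self.system
        if s.n_waters == 0:
            return
        r = _rattle(s.pos, s.vel, self.inv_mass, s.n_waters, 1e-10)
        if r < 0:
            raise ConstraintError("RATTLE failed to converge", s.pos.copy())

    def step(self, n_steps: int = 1,
             callback: Optional[Callable[[int, "LangevinIntegrator"], None]] = None
             ) -> None:
        """Advance ``n_steps`` BAOAB steps; ``callback(step, self)`` runs
        after each completed step with fresh forces on ``last_ff_forces``."""
        s = self.system
        dt = self.dt
        half = 0.5 * dt
        mobile = ~s.frozen
        for k in range(n_steps):
            # B half kick
            s.vel[mobile] += half * self.last_forces[mobile] * \
                self.inv_mass[mobile, None]
            self._apply_rattle()
            # A half drift
            ref = s.pos.copy()
            s.pos[mobile] += half * s.vel[mobile]
            self._apply_shake(ref, half)
            # O full (Ornstein-Uhlenbeck)
            noise = self.rng.standard_normal(s.pos.shape)
            s.vel[mobile] = (self._c1 * s.vel[mobile]
                             + self._c2[mobile, None] * noise[mobile])
            self._apply_rattle()
            # A half drift
            ref = s.pos.copy()
            s.pos[mobile] += half * s.vel[mobile]
            self._apply_shake(ref, half)
            # B half kick with fresh forces
            self.last_ff_forces, self.last_potential = self._ff_forces()
            self.last_forces = self._total_forces(self.last_ff_forces)
            s.vel[mobile] += half * self.last_forces[mobile] * \
                self.inv_mass[mobile, None]
            self._apply_rattle()
            if callback is not None:
                callback(k, self)

    def total_energy(self) -> float:
        return self.system.kinetic_energy() + self.last_potential


def integrate(frame: Frame, ff: ForceFieldParams, config: IntegratorConfig,
              n_steps: int, sample_every: int = 0,
              initialize_velocities: bool = True) -> Trajectory:
    """Run plain Langevin dynamics on a frame and return a trajectory.

    ``sample_every = 0`` records only the final frame.  The trajectory
    metadata carries the seed and step count, and reruns with the same seed
    are bit-identical (single-threaded).
    """
    system = System.from_frame(frame, ff)
    integ = LangevinIntegrator(system, ff, config)
    if initialize_velocities:
        integ.initialize_velocities()
    frames: List[Frame] = []

    def cb(step, it):
        if sample_every and (step + 1) % sample_every == 0:
            frames.append(it.system.to_frame())

    integ.step(n_steps, callback=cb if sample_every else None)
    if not sample_every:
        frames.append(system.to_frame())
    return Trajectory(frames, metadata={
        "seed": config.seed, "n_steps": n_steps,
        "timestep_fs": config.timestep_fs, "friction": config.friction,
        "temperature": config.temperature, "sample_every": sample_every,
    })
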