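"""End-to-end study protocols: hydration-shell coordination runs and
ion–nanopore ABF barrier sweeps.

These wrap the generators, simulator and analyses into the two standard
experiments of the package.  Problem sizes are arguments so the same
protocol runs at desk scale (hundreds of waters, tens of picoseconds) or
larger; every run is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

from .abf import ABFConfig, PMFProfile, pmf_barrier, run_abf
from .constants import M_WATER, N_AVOGADRO
from .forcefield import ForceFieldParams, default_forcefield
from .frames import Trajectory
from .integrate import IntegratorConfig, LangevinIntegrator, System
from .rdf import rdf
from .synth import SystemSpec, gen_ion_in_water, gen_pore_system

__all__ = ["CoordinationResult", "coordination_protocol",
           "pore_barrier_protocol", "cubic_edge_for_waters"]


def cubic_edge_for_waters(n_waters: int, density: float = 1.0) -> float:
    """Cubic box edge (Å) holding ``n_waters`` at a mass density (g/cm³)."""
    vol = n_waters * M_WATER / (density * N_AVOGADRO) * 1e24  # Å³
    return vol ** (1.0 / 3.0)


@dataclass
class CoordinationResult:
    ion: str
    first_minimum: float
    coordination_number: float
    n_waters: int
    production_ps: float
    seed: int


def _scaled_ff(edge_or_min_box: float) -> ForceFieldParams:
    """Desk-scale switching range: 7–9 Å where the box allows it, shrunk
    proportionally (keeping the 7:9 ratio) in smaller boxes so the minimum
    image stays unambiguous."""
    r_off = min(9.0, 0.5 * edge_or_min_box - 0.5)
    r_on = r_off * 7.0 / 9.0
    return default_forcefield(r_on=round(r_on, 2), r_off=round(r_off, 2))


def coordination_protocol(
    ion: str,
    seed: int,
    n_waters: int = 300,
    density: float = 1.0,
    equil_ps: float = 10.0,
    production_ps: float = 100.0,
    timestep_fs: float = 2.0,
    sample_every: int = 50,
    ff: Optional[ForceFieldParams] = None,
) -> CoordinationResult:
    """First-hydration-shell coordination number of a single ion in water.

    Generates a periodic box of rigid waters with the ion at the centre,
    equilibrates under strong-friction Langevin dynamics, samples a
    production segment at 300 K, and reports the mean water-oxygen count
    inside the ion–oxygen RDF first minimum.
    """
    edge = cubic_edge_for_waters(n_waters + 1, density)
    if ff is None:
        ff = _scaled_ff(edge)
    spec = SystemSpec(box=(edge, edge, edge), n_waters=n_waters,
                      density=density, seed=seed)
    frame = gen_ion_in_water(spec, ion=ion)
    frame.validate_geometry(max_cutoff=ff.r_off)
    system = System.from_frame(frame, ff)

    equil = LangevinIntegrator(
        system, ff, IntegratorConfig(seed=seed, friction=5.0,
                                     timestep_fs=timestep_fs))
    equil.initialize_velocities()
    equil.step(int(equil_ps * 1000 / timestep_fs))

    frames = []
    prod = LangevinIntegrator(
        system, ff, IntegratorConfig(seed=seed + 1, friction=2.0,
                                     timestep_fs=timestep_fs))

    def cb(k, it):
        if (k + 1) % sample_every == 0:
            frames.append(it.system.to_frame())

    prod.step(int(production_ps * 1000 / timestep_fs), callback=cb)
    traj = Trajectory(frames, metadata={"seed": seed, "ion": ion})
    prof = rdf(traj, ion, "OW", bin_width=0.05)
    if prof.first_minimum is None or prof.coordination_number is None:
        raise RuntimeError("no RDF first minimum found; sampling too short?")
    return CoordinationResult(
        ion=ion.upper(), first_minimum=prof.first_minimum,
        coordination_number=prof.coordination_number,
        n_waters=n_waters, production_ps=production_ps, seed=seed,
    )


def pore_barrier_protocol(
    pore_radius: float,
    ion: str,
    seed: int,
    box: Tuple[float, float, float] = (16.0, 16.0, 24.0),
    total_steps: int = 40_000,
    equil_steps: int = 2_000,
    cv_min: float = 1.2,
    cv_max: float = 7.0,
    bin_width: float = 0.2,
    ramp_threshold: int = 100,
    sample_every: int = 0,
    ff: Optional[ForceFieldParams] = None,
) -> Tuple[float, PMFProfile, Trajectory]:
    """ABF barrier for one ion approaching a graphene-like nanopore.

    Builds the periodic sheet + axial ion + water system, equilibrates, and
    sweeps the axial-distance CV with windowed ABF.  Returns the barrier
    (max PMF relative to the large-distance anchor), the profile, and the
    sampled trajectory (empty unless ``sample_every`` > 0).
    """
    if ff is None:
        ff = _scaled_ff(min(box))
    spec = SystemSpec(box=box, pore_radius=pore_radius, seed=seed)
    frame = gen_pore_system(spec, ion=ion, ion_cv=cv_max - 0.5)
    system = System.from_frame(frame, ff)
    equil = LangevinIntegrator(
        system, ff, IntegratorConfig(seed=seed, friction=10.0))
    equil.initialize_velocities()
    equil.step(equil_steps)
    acfg = ABFConfig(cv_min=cv_min, cv_max=cv_max, bin_width=bin_width,
                     ramp_threshold=ramp_threshold, total_steps=total_steps,
                     window_width=2.6, window_overlap=0.4,
                     k_wall=300.0, k_transverse=100.0)
    profile, traj = run_abf(system, acfg, ff,
                            IntegratorConfig(seed=seed + 1, friction=2.0),
                            sample_every=sample_every)
    return pmf_barrier(profile), profile, traj
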