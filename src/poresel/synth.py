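"""Synthetic study systems: water boxes, graphene-like pore sheets, ionic
solutions, hand-built hydrogen-bond motif fixtures and analytic CV landscapes.

Every generator is a pure function of its SystemSpec and seed (the same seed
reproduces coordinates bitwise), and emulates the simulated conditions the
package targets: a 40 × 40 × 60 Å periodic box of rigid 3-site water, a
graphene-like sheet (C–C 1.42 Å) pierced by a circular pore of nominal
radius 1.8 / 3.7 / 5.6 Å, and single K⁺/Na⁺ ions approaching on the pore
axis.  Waters are placed on a jittered cubic lattice with random rigid
orientations; the lattice spacing at liquid density keeps molecules
overlap-free so a short strong-friction Langevin segment suffices to relax
the structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import M_WATER, N_AVOGADRO
from .frames import Frame

__all__ = [
    "SystemSpec",
    "PackingError",
    "waters_for_density",
    "gen_water_box",
    "gen_graphene_pore",
    "gen_ion_in_water",
    "gen_pore_system",
    "gen_solution",
    "gen_motif_fixture",
    "Landscape",
    "gen_toy_landscape",
]

#: water geometry used for generated molecules (matches the force field)
R_OH = 0.9572
THETA_HOH = 104.52
CC_BOND = 1.42          # graphene C-C, Å
C_LJ_RADIUS = 1.775     # σ_C/2, used for the accessible-radius report


class PackingError(RuntimeError):
    """The requested density/exclusions cannot be packed."""


@dataclass(frozen=True)
class SystemSpec:
    """Composition of a synthetic system.

    Either ``n_waters`` or ``density`` (g/cm³) fixes the water content.  The
    default box is the 40 × 40 × 60 Å study box; default pore radii follow
    the 1.8/3.7/5.6 Å series.  ``ions`` maps species label → count (the
    voltage analogue uses 10 K⁺ + 10 Na⁺ + 20 Cl⁻ for neutrality).
    """

    box: Tuple[float, float, float] = (40.0, 40.0, 60.0)
    n_waters: Optional[int] = None
    density: float = 1.0
    ions: dict = field(default_factory=dict)
    pore_radius: float = 3.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_waters is None and not (0.8 <= self.density <= 1.2):
            raise ValueError("water density outside the liquid range "
                             "0.8-1.2 g/cm³")

    def water_count(self) -> int:
        if self.n_waters is not None:
            return self.n_waters
        return waters_for_density(self.box, self.density)

    def total_ion_charge(self) -> float:
        from .frames import ION_CHARGES
        return sum(ION_CHARGES.get(k.upper(), 0.0) * v
                   for k, v in self.ions.items())


def waters_for_density(box: Sequence[float], density: float = 1.0) -> int:
    """Water count for a box (Å) at a mass density (g/cm³): ρ·V·N_A/M."""
    vol_cm3 = float(np.prod(np.asarray(box, dtype=float))) * 1e-24
    return int(round(density * vol_cm3 * N_AVOGADRO / M_WATER))


def _water_sites(box: np.ndarray, n: int, rng: np.random.Generator,
                 exclusions: List[Tuple[np.ndarray, float]],
                 jitter: float = 0.1) -> np.ndarray:
    """n lattice sites with jitter, avoiding exclusion spheres (min image)."""
    if n == 0:
        return np.zeros((0, 3))
    vol = float(np.prod(box))
    # body-centred candidate lattice, oversampled so exclusion spheres can
    # be carved out without running short of sites; nearest-site distance
    # √3/2·step stays ≥ ~2.6 Å so jittered waters never overlap
    spacing = 2.95
    dims = np.maximum(np.floor(box / spacing).astype(int), 1)
    steps = box / dims
    corners = np.stack(np.meshgrid(*[(np.arange(d) + 0.25) * s
                                     for d, s in zip(dims, steps)],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    grid = np.concatenate([corners, corners + 0.5 * steps], axis=0)
    if exclusions:
        keep = np.ones(len(grid), dtype=bool)
        for center, radius in exclusions:
            d = grid - center
            d -= box * np.round(d / box)
            keep &= np.sqrt((d * d).sum(axis=1)) > radius
        grid = grid[keep]
    if len(grid) < n:
        raise PackingError(
            f"only {len(grid)} lattice sites available for {n} waters")
    idx = rng.choice(len(grid), size=n, replace=False)
    sites = grid[np.sort(idx)]
    sites = sites + rng.uniform(-jitter, jitter, size=sites.shape)
    return sites


def _orient_waters(sites: np.ndarray, rng: np.random.Generator
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigid water geometry at each site with a random rotation."""
    half = math.radians(THETA_HOH) / 2.0
    u1 = np.array([math.sin(half), 0.0, math.cos(half)])
    u2 = np.array([-math.sin(half), 0.0, math.cos(half)])
    n = len(sites)
    if n == 0:
        z = np.zeros((0, 3))
        return z, z, z
    rots = Rotation.random(n, random_state=np.random.RandomState(
        rng.integers(0, 2 ** 31)))
    h1 = sites + R_OH * rots.apply(np.tile(u1, (n, 1)))
    h2 = sites + R_OH * rots.apply(np.tile(u2, (n, 1)))
    return sites, h1, h2


def gen_water_box(spec: SystemSpec) -> Frame:
    """Periodic box of non-overlapping rigid waters at the target density."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    n = spec.water_count()
    sites = _water_sites(box, n, rng, exclusions=[])
    O, H1, H2 = _orient_waters(sites, rng)
    return Frame(box=box, water_O=O, water_H1=H1, water_H2=H2)


def gen_graphene_pore(
    box: Sequence[float],
    pore_radius: float,
    z0: Optional[float] = None,
    cc: float = CC_BOND,
) -> Tuple[np.ndarray, dict]:
    """Graphene-like hexagonal sheet in the plane z = z0 with a circular
    pore about the box axis; returns (positions, info).

    Atoms whose axial distance is below ``pore_radius`` are removed.  The
    info dict reports the nominal radius, the accessible radius
    (axis-to-nearest-carbon minus the carbon LJ radius) and atom counts.
    """
    box = np.asarray(box, dtype=float)
    if pore_radius >= 0.5 * min(box[0], box[1]):
        raise ValueError("pore radius too large for the sheet (degenerate)")
    if z0 is None:
        z0 = 0.5 * box[2]
    # rectangular 4-atom cell: 3·cc × √3·cc
    cell_x, cell_y = 3.0 * cc, math.sqrt(3.0) * cc
    nx = int(round(box[0] / cell_x)) or 1
    ny = int(round(box[1] / cell_y)) or 1
    sx, sy = box[0] / nx, box[1] / ny    # strain to fit the periodic box
    basis = np.array([[0.0, 0.0], [cc, 0.0],
                      [1.5 * cc, 0.5 * math.sqrt(3.0) * cc],
                      [2.5 * cc, 0.5 * math.sqrt(3.0) * cc]])
    basis = basis * np.array([sx / cell_x, sy / cell_y])
    pts = []
    for i in range(nx):
        for j in range(ny):
            origin = np.array([i * sx, j * sy])
            pts.append(basis + origin)
    xy = np.concatenate(pts, axis=0)
    center = 0.5 * box[:2]
    d = xy - center
    d -= box[:2] * np.round(d / box[:2])
    dist = np.hypot(d[:, 0], d[:, 1])
    keep = dist >= pore_radius
    removed = int((~keep).sum())
    xy = xy[keep]
    dist = dist[keep]
    pos = np.column_stack([xy, np.full(len(xy), float(z0))])
    info = {
        "nominal_radius": float(pore_radius),
        "accessible_radius": float(dist.min() - C_LJ_RADIUS) if len(dist)
        else None,
        "n_atoms": len(pos),
        "n_removed": removed,
        "z0": float(z0),
        "strain": (sx / cell_x, sy / cell_y),
    }
    return pos, info


def gen_ion_in_water(
    spec: SystemSpec,
    ion: str = "NA",
    exclusion: float = 2.4,
) -> Frame:
    """One ion at the box centre in a water box (hydration-shell studies)."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    center = 0.5 * box
    n = spec.water_count()
    sites = _water_sites(box, n, rng, exclusions=[(center, exclusion)])
    O, H1, H2 = _orient_waters(sites, rng)
    return Frame(box=box, water_O=O, water_H1=H1, water_H2=H2,
                 ion_labels=[ion.upper()], ion_pos=center[None, :])


def gen_pore_system(
    spec: SystemSpec,
    ion: str = "K",
    ion_cv: float = 7.0,
    wall_exclusion: float = 2.6,
    ion_exclusion: float = 2.4,
) -> Frame:
    """Graphene-pore sheet mid-box, one ion on the pore axis at axial
    distance ``ion_cv`` above it, waters filling the rest of the box."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    wall, info = gen_graphene_pore(box, spec.pore_radius)
    ion_pos = np.array([0.5 * box[0], 0.5 * box[1], info["z0"] + ion_cv])
    exclusions = [(w, wall_exclusion) for w in wall]
    exclusions.append((ion_pos, ion_exclusion))
    n = spec.n_waters
    if n is None:
        # water fills the box volume minus the sheet slab
        slab = box[0] * box[1] * (2.0 * wall_exclusion)
        n = waters_for_density(box, spec.density)
        n = int(round(n * (1.0 - slab / float(np.prod(box)))))
    sites = _water_sites(box, n, rng, exclusions=exclusions)
    O, H1, H2 = _orient_waters(sites, rng)
    frame = Frame(box=box, water_O=O, water_H1=H1, water_H2=H2,
                  ion_labels=[ion.upper()], ion_pos=ion_pos[None, :],
                  wall_pos=wall)
    return frame


def gen_solution(
    spec: SystemSpec,
    with_sheet: bool = True,
) -> Frame:
    """Mixed ionic solution (e.g. 10 K⁺ + 10 Na⁺ + 20 Cl⁻), optionally with
    a pore sheet, for voltage-driven crossing experiments."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    wall = np.zeros((0, 3))
    exclusions: List[Tuple[np.ndarray, float]] = []
    if with_sheet:
        wall, info = gen_graphene_pore(box, spec.pore_radius)
        exclusions = [(w, 2.6) for w in wall]
    labels: List[str] = []
    for lbl, count in sorted(spec.ions.items()):
        labels.extend([lbl.upper()] * int(count))
    n_ions = len(labels)
    n_w = spec.water_count()
    if with_sheet and spec.n_waters is None:
        # the sheet slab displaces its share of the water
        slab = box[0] * box[1] * 5.2
        n_w = int(round(n_w * (1.0 - slab / float(np.prod(box)))))
    sites = _water_sites(box, n_w + n_ions, rng, exclusions=exclusions)
    order = rng.permutation(n_w + n_ions)
    ion_sites = sites[order[:n_ions]]
    water_sites = sites[order[n_ions:]]
    O, H1, H2 = _orient_waters(water_sites, rng)
    return Frame(box=box, water_O=O, water_H1=H1, water_H2=H2,
                 ion_labels=labels, ion_pos=ion_sites, wall_pos=wall)


# ---------------------------------------------------------------------------
# hydrogen-bond motif fixtures
# ---------------------------------------------------------------------------

def _make_water(O: np.ndarray, u1: np.ndarray, u2: np.ndarray
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Water with H's along unit directions u1, u2 (rescaled to the rigid
    HOH angle in the plane they span)."""
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    # symmetrise to the exact HOH angle within the (u1,u2) plane
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    perp = u1 - np.dot(u1, bis) * bis
    perp /= np.linalg.norm(perp)
    half = math.radians(THETA_HOH) / 2.0
    v1 = math.cos(half) * bis + math.sin(half) * perp
    v2 = math.cos(half) * bis - math.sin(half) * perp
    return O, O + R_OH * v1, O + R_OH * v2


def gen_motif_fixture(label: str, box_edge: float = 30.0,
                      r_hb: float = 2.8) -> Frame:
    """Hand-placed waters whose central molecule classifies as the requested
    motif under the default geometric criterion.

    Labels: DDAA, DDA, DAA, DA, dimer, trimer-ring.  Water 0 is the central
    molecule for the motif fixtures.
    """
    box = np.array([box_edge] * 3)
    c = 0.5 * box
    # centre water H directions
    half = math.radians(THETA_HOH) / 2.0
    u1 = np.array([math.sin(half), 0.0, math.cos(half)])
    u2 = np.array([-math.sin(half), 0.0, math.cos(half)])
    # outward directions for donors, tilted out of the (u1,u2) plane
    w = -(u1 + u2)
    w /= np.linalg.norm(w)
    nrm = np.cross(u1, u2)
    nrm /= np.linalg.norm(nrm)
    v3 = math.cos(math.radians(52)) * w + math.sin(math.radians(52)) * nrm
    v4 = math.cos(math.radians(52)) * w - math.sin(math.radians(52)) * nrm

    def acceptor(direction: np.ndarray):
        """Water accepting from the centre: O on ``direction``, H's aimed
        outward so it does not donate back."""
        O = c + r_hb * direction
        out = direction / np.linalg.norm(direction)
        side = np.cross(out, nrm)
        if np.linalg.norm(side) < 1e-8:
            side = np.cross(out, u1)
        side /= np.linalg.norm(side)
        return _make_water(O, out + 0.3 * side, out - 0.3 * side)

    def donor(direction: np.ndarray):
        """Water donating to the centre: one H aimed straight at it."""
        O = c + r_hb * direction
        toward = -direction / np.linalg.norm(direction)
        side = np.cross(toward, nrm)
        if np.linalg.norm(side) < 1e-8:
            side = np.cross(toward, u1)
        side /= np.linalg.norm(side)
        # second H well away from the centre direction
        return _make_water(O, toward, -toward + 1.2 * side)

    waters: List[Tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    lbl = label.lower().replace("_", "-")
    if lbl in ("ddaa", "dda", "daa", "da"):
        if lbl in ("ddaa", "dda"):
            waters.append(_make_water(c, u1, u2))          # donates 2
            waters.append(acceptor(u1))
            waters.append(acceptor(u2))
        else:
            waters.append(_make_water(c, u1, -w + 0.8 * nrm))  # donates 1
            waters.append(acceptor(u1))
        n_acc = {"ddaa": 2, "dda": 1, "daa": 2, "da": 1}[lbl]
        for direction in (v3, v4)[:n_acc]:
            waters.append(donor(direction))
    elif lbl == "dimer":
        waters.append(_make_water(c, u1, u2))
        waters.append(acceptor(u1))
    elif lbl == "trimer-ring":
        # equilateral triangle, each donating to the next
        for i in range(3):
            ang = 2.0 * math.pi * i / 3.0
            waters.append(np.array([math.cos(ang), math.sin(ang), 0.0]))
        ring = [c + (r_hb / math.sqrt(3.0)) * np.array(
            [math.cos(2 * math.pi * i / 3 + math.pi / 6),
             math.sin(2 * math.pi * i / 3 + math.pi / 6), 0.0])
            for i in range(3)]
        waters = []
        for i in range(3):
            toward = ring[(i + 1) % 3] - ring[i]
            waters.append(_make_water(ring[i], toward,
                                      np.array([0.0, 0.0, 1.0])))
    else:
        raise ValueError(f"unknown motif label '{label}'")
    O = np.array([wtr[0] for wtr in waters])
    H1 = np.array([wtr[1] for wtr in waters])
    H2 = np.array([wtr[2] for wtr in waters])
    return Frame(box=box, water_O=O, water_H1=H1, water_H2=H2)


# ---------------------------------------------------------------------------
# analytic CV landscapes
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Analytic 1-D potential with exact gradient and closed-form PMF."""

    form: str
    potential: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    pmf: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)


def gen_toy_landscape(form: str, **params) -> Landscape:
    """Analytic landscapes for validating the ABF estimator.

    flat: U = 0.  harmonic: U = ½k(x−x0)².  double-well:
    U = h·((x² − a²)/a²)², barrier height h between minima at ±a.
    """
    if form == "flat":
        return Landscape("flat",
                         potential=lambda x: np.zeros_like(np.asarray(x, float)),
                         gradient=lambda x: np.zeros_like(np.asarray(x, float)),
                         pmf=lambda x: np.zeros_like(np.asarray(x, float)),
                         params={})
    if form == "harmonic":
        k = params.get("k", 10.0)
        x0 = params.get("x0", 0.0)
        pot = lambda x: 0.5 * k * (np.asarray(x, float) - x0) ** 2
        return Landscape("harmonic", potential=pot,
                         gradient=lambda x: k * (np.asarray(x, float) - x0),
                         pmf=pot, params={"k": k, "x0": x0})
    if form == "double-well":
        a = params.get("a", 1.5)
        h = params.get("h", 5.0)
        pot = lambda x: h * ((np.asarray(x, float) ** 2 - a ** 2) / a ** 2) ** 2
        grad = lambda x: 4.0 * h * np.asarray(x, float) * \
            (np.asarray(x, float) ** 2 - a ** 2) / a ** 4
        return Landscape("double-well", potential=pot, gradient=grad,
                         pmf=pot, params={"a": a, "h": h})
    raise ValueError(f"unknown landscape form '{form}'")
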