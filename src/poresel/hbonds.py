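"""Geometric hydrogen-bond census and interfacial/bulk water partition.

A hydrogen bond between two waters is declared when the oxygen–oxygen
distance is below ``r_OO_max`` (3.5 Å) *and* the angle at the donor oxygen
between the donor→acceptor O–O vector and the donor O–H bond is below
``angle_OOH_max`` (30°), the standard geometric criterion.  Each donor
hydrogen binds at most one acceptor (the nearest eligible one), so a water
donates ≤ 2 bonds and the (donated, accepted) pair classifies its local
motif: (2,2) DDAA — tetrahedral, (2,1) DDA, (1,2) DAA, (1,1) DA, anything
else "other".

Water is partitioned into *interfacial* (oxygen within a shell cutoff of any
solute/wall atom, minimum image) and *bulk* (the rest); the mean hydrogen
bonds per water of each class quantifies the bond truncation at interfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .frames import Frame, Trajectory, min_image_vec

__all__ = [
    "HBondCriteria",
    "MotifCounts",
    "WaterPartition",
    "detect_hbonds",
    "motif_census",
    "partition_water",
    "mean_hbonds",
    "hbond_summary",
]

Bond = Tuple[int, int, int]  # (donor water, H index 0/1, acceptor water)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: O–O distance and donor ∠(O–O, O–H) angle cuts."""

    r_OO_max: float = 3.5        # Å
    angle_OOH_max: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.r_OO_max <= 0 or self.angle_OOH_max <= 0:
            raise ValueError("criteria must be strictly positive")


@dataclass
class MotifCounts:
    counts: Dict[str, int]
    n_HB_mean: float
    n_waters: int

    def __getitem__(self, key: str) -> int:
        return self.counts[key]


@dataclass
class WaterPartition:
    interfacial: np.ndarray      # bool mask over waters
    shell_cutoff: float

    @property
    def interfacial_count(self) -> int:
        return int(self.interfacial.sum())

    @property
    def bulk_count(self) -> int:
        return int((~self.interfacial).sum())


def _wrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(pos, box)


def detect_hbonds(frame: Frame, criteria: HBondCriteria = HBondCriteria()
                  ) -> List[Bond]:
    """All donor→acceptor hydrogen bonds in a frame, neighbor-list based.

    Returns (donor, H index, acceptor) triples sorted lexicographically; each
    donor hydrogen contributes at most one bond (nearest eligible acceptor).
    """
    box = frame.box
    if (box < 2.0 * criteria.r_OO_max).any():
        raise ValueError("box too small for the O-O cutoff (minimum image)")
    n = frame.n_waters
    if n < 2:
        return []
    O = frame.water_O
    tree = cKDTree(_wrap(O, box), boxsize=box)
    pairs = tree.query_pairs(criteria.r_OO_max, output_type="ndarray")
    if len(pairs) == 0:
        return []
    cos_max = np.cos(np.deg2rad(criteria.angle_OOH_max))
    H = (frame.water_H1, frame.water_H2)
    # candidate directed pairs, both orientations
    cand_d = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cand_a = np.concatenate([pairs[:, 1], pairs[:, 0]])
    oo = min_image_vec(O[cand_a] - O[cand_d], box)
    r_oo = np.linalg.norm(oo, axis=1)
    bonds: List[Bond] = []
    best: Dict[Tuple[int, int], Tuple[float, int]] = {}
    for h_idx in (0, 1):
        oh = min_image_vec(H[h_idx][cand_d] - O[cand_d], box)
        cos = np.einsum("ij,ij->i", oo, oh) / (
            r_oo * np.linalg.norm(oh, axis=1))
        ok = cos > cos_max
        for d, a, r in zip(cand_d[ok], cand_a[ok], r_oo[ok]):
            key = (int(d), h_idx)
            prev = best.get(key)
            if prev is None or r < prev[0]:
                best[key] = (float(r), int(a))
    for (d, h_idx), (_, a) in best.items():
        bonds.append((d, h_idx, a))
    bonds.sort()
    return bonds


def motif_census(frame: Frame, criteria: HBondCriteria = HBondCriteria()
                 ) -> MotifCounts:
    """Classify every water by its (donated, accepted) hydrogen-bond counts."""
    bonds = detect_hbonds(frame, criteria)
    n = frame.n_waters
    donated = np.zeros(n, dtype=int)
    accepted = np.zeros(n, dtype=int)
    for d, _, a in bonds:
        donated[d] += 1
        accepted[a] += 1
    labels = {(2, 2): "DDAA", (2, 1): "DDA", (1, 2): "DAA", (1, 1): "DA"}
    counts = {"DDAA": 0, "DDA": 0, "DAA": 0, "DA": 0, "other": 0}
    for da in zip(donated, accepted):
        counts[labels.get(da, "other")] += 1
    n_HB = 2.0 * len(bonds) / n if n else 0.0
    return MotifCounts(counts=counts, n_HB_mean=n_HB, n_waters=n)


def partition_water(frame: Frame, solute_pos: Optional[np.ndarray] = None,
                    shell_cutoff: float = 3.5) -> WaterPartition:
    """Split waters into interfacial (O within ``shell_cutoff`` of any solute
    or wall atom) and bulk.  With no solute atoms every water is bulk."""
    if shell_cutoff <= 0:
        raise ValueError("shell_cutoff must be positive")
    if solute_pos is None:
        solute_pos = frame.solute_positions()
    solute_pos = np.asarray(solute_pos, dtype=float).reshape(-1, 3)
    n = frame.n_waters
    if len(solute_pos) == 0:
        warnings.warn("empty solute selection: all waters classified as bulk")
        return WaterPartition(np.zeros(n, dtype=bool), shell_cutoff)
    box = frame.box
    tree = cKDTree(_wrap(solute_pos, box), boxsize=box)
    d, _ = tree.query(_wrap(frame.water_O, box), k=1)
    return WaterPartition(np.asarray(d) <= shell_cutoff, shell_cutoff)


def _per_water_bond_counts(frame: Frame, criteria: HBondCriteria) -> np.ndarray:
    counts = np.zeros(frame.n_waters, dtype=float)
    for d, _, a in detect_hbonds(frame, criteria):
        counts[d] += 1
        counts[a] += 1
    return counts


def mean_hbonds(
    trajectory: Trajectory,
    subset: Literal["all", "interfacial", "bulk"] = "all",
    criteria: HBondCriteria = HBondCriteria(),
    shell_cutoff: float = 3.5,
) -> float:
    """Mean hydrogen bonds per water (n_HB) over a trajectory.

    Bonds touching each subset water are counted per water; the per-frame
    subset means are averaged over frames that contain subset waters.
    """
    if len(trajectory) == 0:
        raise ValueError("trajectory must contain at least one frame")
    frame_means = []
    for frame in trajectory:
        counts = _per_water_bond_counts(frame, criteria)
        if subset == "all":
            mask = np.ones(frame.n_waters, dtype=bool)
        else:
            part = partition_water(frame, shell_cutoff=shell_cutoff)
            mask = part.interfacial if subset == "interfacial" else ~part.interfacial
        if mask.any():
            frame_means.append(float(counts[mask].mean()))
    if not frame_means:
        raise ValueError(f"subset '{subset}' empty in every frame")
    return float(np.mean(frame_means))


def hbond_summary(
    trajectory: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    shell_cutoff: float = 3.5,
) -> Dict[str, object]:
    """n_HB for all/interfacial/bulk water plus the depletion flag.

    ``interfacial_below_bulk`` is True when interfacial water carries fewer
    hydrogen bonds per molecule than bulk water, the signature of bond
    truncation at interfaces.
    """
    out: Dict[str, object] = {
        "n_HB_all": mean_hbonds(trajectory, "all", criteria, shell_cutoff)}
    try:
        n_int = mean_hbonds(trajectory, "interfacial", criteria, shell_cutoff)
        n_blk = mean_hbonds(trajectory, "bulk", criteria, shell_cutoff)
    except ValueError:
        out["interfacial_below_bulk"] = None
        return out
    out["n_HB_interfacial"] = n_int
    out["n_HB_bulk"] = n_blk
    out["interfacial_below_bulk"] = bool(n_int < n_blk)
    return out
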