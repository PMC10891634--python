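"""Periodic-box snapshots of water, ions and frozen wall atoms.

A :class:`Frame` holds one orthorhombic periodic snapshot with waters stored
as rigid (O, H1, H2) triplets, free ions, and frozen wall (sheet) atoms.  A
:class:`Trajectory` is a list of frames plus metadata (seed, provenance).

Atom ordering convention, used consistently by the simulator and the file
formats: waters first (O,H,H per molecule), then ions, then wall atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, List, Optional, Sequence

import numpy as np

from .constants import MASSES

__all__ = ["Frame", "Trajectory", "min_image_vec", "min_image_dist"]

#: default charges per ion species label, in e
ION_CHARGES = {"NA": 1.0, "K": 1.0, "CL": -1.0}


def min_image_vec(dvec: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vector(s) in an orthorhombic box."""
    return dvec - box * np.round(dvec / box)


def min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance(s) between position arrays ``a`` and ``b``."""
    d = min_image_vec(np.asarray(a) - np.asarray(b), np.asarray(box))
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class Frame:
    box: np.ndarray                       # (3,) Å
    water_O: np.ndarray                   # (n_w, 3) Å
    water_H1: np.ndarray                  # (n_w, 3)
    water_H2: np.ndarray                  # (n_w, 3)
    ion_labels: List[str] = field(default_factory=list)
    ion_pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    ion_charges: Optional[np.ndarray] = None
    wall_pos: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        for name in ("water_O", "water_H1", "water_H2", "ion_pos", "wall_pos"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float
                                           ).reshape(-1, 3))
        if not (self.box > 0).all():
            raise ValueError("box edges must be positive")
        n = len(self.water_O)
        if len(self.water_H1) != n or len(self.water_H2) != n:
            raise ValueError("water O/H1/H2 arrays must have equal length")
        if self.ion_charges is None:
            self.ion_charges = np.array(
                [ION_CHARGES.get(lbl.upper(), 0.0) for lbl in self.ion_labels]
            )
        self.ion_charges = np.asarray(self.ion_charges, dtype=float)
        if len(self.ion_charges) != len(self.ion_pos):
            raise ValueError("ion charge/position length mismatch")
        for arr in (self.water_O, self.water_H1, self.water_H2,
                    self.ion_pos, self.wall_pos):
            if arr.size and not np.isfinite(arr).all():
                raise ValueError("positions must be finite")

    # -- derived views -----------------------------------------------------
    @property
    def n_waters(self) -> int:
        return len(self.water_O)

    @property
    def n_atoms(self) -> int:
        return 3 * self.n_waters + len(self.ion_pos) + len(self.wall_pos)

    def validate_geometry(self, oh_min: float = 0.8, oh_max: float = 1.2,
                          max_cutoff: Optional[float] = None) -> None:
        """Check intramolecular O–H lengths and (optionally) that the box is
        large enough for unambiguous minimum image at ``max_cutoff``."""
        if self.n_waters:
            for H in (self.water_H1, self.water_H2):
                d = min_image_dist(self.water_O, H, self.box)
                if ((d < oh_min) | (d > oh_max)).any():
                    raise ValueError("O-H bond length outside %g-%g Å"
                                     % (oh_min, oh_max))
        if max_cutoff is not None and (self.box < 2.0 * max_cutoff).any():
            raise ValueError(
                "box %s too small for cutoff %g Å (minimum image ambiguous)"
                % (self.box, max_cutoff))

    def species(self) -> List[str]:
        """Per-atom species labels in the canonical atom order."""
        out: List[str] = []
        for _ in range(self.n_waters):
            out.extend(["OW", "HW", "HW"])
        out.extend(lbl.upper() for lbl in self.ion_labels)
        out.extend("C" for _ in range(len(self.wall_pos)))
        return out

    def positions(self) -> np.ndarray:
        """All positions (n_atoms, 3) in the canonical atom order."""
        waters = np.empty((3 * self.n_waters, 3))
        waters[0::3] = self.water_O
        waters[1::3] = self.water_H1
        waters[2::3] = self.water_H2
        return np.concatenate([waters, self.ion_pos, self.wall_pos], axis=0)

    def masses(self) -> np.ndarray:
        return np.array([MASSES[s] for s in self.species()])

    def with_positions(self, pos: np.ndarray) -> "Frame":
        """New frame with the same composition and new canonical positions."""
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (self.n_atoms, 3):
            raise ValueError("position array shape mismatch")
        nw3 = 3 * self.n_waters
        ni = len(self.ion_pos)
        return Frame(
            box=self.box.copy(),
            water_O=pos[0:nw3:3].copy(),
            water_H1=pos[1:nw3:3].copy(),
            water_H2=pos[2:nw3:3].copy(),
            ion_labels=list(self.ion_labels),
            ion_pos=pos[nw3:nw3 + ni].copy(),
            ion_charges=np.asarray(self.ion_charges).copy(),
            wall_pos=pos[nw3 + ni:].copy(),
        )

    def solute_positions(self) -> np.ndarray:
        """Ion + wall positions (the non-water atoms), canonical order."""
        return np.concatenate([self.ion_pos, self.wall_pos], axis=0)

    def total_charge(self) -> float:
        """Net system charge in e (waters are neutral by construction)."""
        return float(np.sum(self.ion_charges))


@dataclass
class Trajectory:
    frames: List[Frame]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.frames[i], dict(self.metadata))
        return self.frames[i]

    @classmethod
    def from_frames(cls, frames: Sequence[Frame], **metadata) -> "Trajectory":
        return cls(list(frames), dict(metadata))
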