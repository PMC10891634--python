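"""File formats: extended XYZ and PDB trajectories, PMF tables, manifests.

XYZ files use the extended convention (``Lattice="..."`` in the comment
line) and are parsed natively so the periodic box travels with every frame;
PDB files (CRYST1 box) go through MDAnalysis.  Atom order inside a frame is
canonical: waters as OW,HW,HW triplets, then ions (K/NA/CL), then wall
carbons (C) — the same convention the simulator uses.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import yaml

from .abf import PMFProfile
from .frames import Frame, Trajectory

__all__ = ["ParseError", "read_trajectory", "write_trajectory",
           "read_xyz", "write_xyz", "read_pdb", "write_pdb",
           "write_pmf", "read_pmf", "RunManifest", "load_config"]

_ION_LABELS = {"K", "NA", "CL"}


class ParseError(ValueError):
    """Malformed trajectory file; message carries the frame/line."""


def _frame_from_atoms(species: List[str], pos: np.ndarray, box: np.ndarray,
                      where: str) -> Frame:
    waters_O, waters_H1, waters_H2 = [], [], []
    ion_labels: List[str] = []
    ion_pos, wall_pos = [], []
    i = 0
    n = len(species)
    while i < n:
        s = species[i].upper()
        if s == "OW":
            if i + 2 >= n or species[i + 1].upper() != "HW" \
                    or species[i + 2].upper() != "HW":
                raise ParseError(f"{where}: water at atom {i} is not an "
                                 "OW,HW,HW triplet")
            waters_O.append(pos[i])
            waters_H1.append(pos[i + 1])
            waters_H2.append(pos[i + 2])
            i += 3
        elif s in _ION_LABELS:
            ion_labels.append(s)
            ion_pos.append(pos[i])
            i += 1
        elif s == "C":
            wall_pos.append(pos[i])
            i += 1
        else:
            raise ParseError(f"{where}: unknown species '{species[i]}' "
                             f"at atom {i}")
    return Frame(box=box,
                 water_O=np.array(waters_O).reshape(-1, 3),
                 water_H1=np.array(waters_H1).reshape(-1, 3),
                 water_H2=np.array(waters_H2).reshape(-1, 3),
                 ion_labels=ion_labels,
                 ion_pos=np.array(ion_pos).reshape(-1, 3),
                 wall_pos=np.array(wall_pos).reshape(-1, 3))


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def write_xyz(trajectory: Union[Trajectory, Frame], path: Union[str, Path]
              ) -> None:
    if isinstance(trajectory, Frame):
        trajectory = Trajectory([trajectory])
    with open(path, "w") as fh:
        for frame in trajectory:
            species = frame.species()
            pos = frame.positions()
            b = frame.box
            fh.write(f"{len(species)}\n")
            fh.write(f'Lattice="{b[0]:.6f} 0.0 0.0 0.0 {b[1]:.6f} 0.0 '
                     f'0.0 0.0 {b[2]:.6f}" '
                     'Properties=species:S:1:pos:R:3\n')
            for s, p in zip(species, pos):
                fh.write(f"{s} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def read_xyz(path: Union[str, Path]) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    nframe = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise ParseError(f"line {ln + 1}: expected an atom count")
        if ln + 1 >= len(lines):
            raise ParseError(f"frame {nframe}: missing comment line "
                             f"(line {ln + 2})")
        m = _LATTICE_RE.search(lines[ln + 1])
        if not m:
            raise ParseError(f"frame {nframe}: no Lattice= box in comment "
                             f"(line {ln + 2})")
        lat = np.fromstring(m.group(1), sep=" ").reshape(3, 3)
        box = np.diag(lat)
        body = lines[ln + 2: ln + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(f"frame {nframe}: truncated at line "
                             f"{len(lines)} ({len(body)}/{natoms} atoms)")
        species, pos = [], np.empty((natoms, 3))
        for a, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"frame {nframe}: malformed atom line "
                                 f"{ln + 3 + a}")
            species.append(parts[0])
            pos[a] = [float(v) for v in parts[1:4]]
        frames.append(_frame_from_atoms(species, pos, box,
                                        f"frame {nframe}"))
        ln += 2 + natoms
        nframe += 1
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# PDB via MDAnalysis
# ---------------------------------------------------------------------------

def write_pdb(trajectory: Union[Trajectory, Frame], path: Union[str, Path]
              ) -> None:
    import warnings
    import MDAnalysis as mda
    if isinstance(trajectory, Frame):
        trajectory = Trajectory([trajectory])
    f0 = trajectory[0]
    species = f0.species()
    n = len(species)
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", species)
    u.add_TopologyAttr("resnames", ["SYS"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=len(trajectory) > 1
                        ) as w:
            for frame in trajectory:
                u.atoms.positions = frame.positions().astype(np.float32)
                u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)


def read_pdb(path: Union[str, Path]) -> Trajectory:
    import warnings
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        species = [str(nm) for nm in u.atoms.names]
        frames = []
        for k, ts in enumerate(u.trajectory):
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise ParseError(f"frame {k}: missing CRYST1 box")
            box = np.array(ts.dimensions[:3], dtype=float)
            frames.append(_frame_from_atoms(
                species, u.atoms.positions.astype(float), box, f"frame {k}"))
    return Trajectory(frames)


def read_trajectory(path: Union[str, Path], format: str = "auto") -> Trajectory:
    """Read XYZ (extended) or PDB; format inferred from the suffix."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "pdb":
        return read_pdb(path)
    raise ValueError(f"unsupported trajectory format '{fmt}'")


def write_trajectory(trajectory: Union[Trajectory, Frame],
                     path: Union[str, Path], format: str = "auto") -> None:
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return write_xyz(trajectory, path)
    if fmt == "pdb":
        return write_pdb(trajectory, path)
    raise ValueError(f"unsupported trajectory format '{fmt}'")


# ---------------------------------------------------------------------------
# PMF tables
# ---------------------------------------------------------------------------

def write_pmf(profile: PMFProfile, path: Union[str, Path]) -> None:
    """TSV table: cv_A, mean_force, free_energy_kJmol, samples, converged;
    the header carries the seed and a config hash.  The anchor (largest-CV)
    bin prints a free energy of exactly 0."""
    meta = dict(profile.metadata)
    cfg_hash = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# seed={meta.get('seed')} config_hash={cfg_hash}\n")
        fh.write("cv_A\tmean_force\tfree_energy_kJmol\tsamples\tconverged\n")
        for c, mf, fe, n, conv in zip(profile.bin_centers, profile.mean_force,
                                      profile.free_energy, profile.counts,
                                      profile.converged):
            fh.write(f"{c:.6f}\t{mf:.12g}\t{fe:.12g}\t{int(n)}\t"
                     f"{int(bool(conv))}\n")


def read_pmf(path: Union[str, Path]) -> PMFProfile:
    rows = []
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                m = re.search(r"seed=(\S+)", line)
                if m and m.group(1) != "None":
                    meta["seed"] = int(m.group(1))
                continue
            if line.startswith("cv_A"):
                continue
            parts = line.split()
            if parts:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)
    return PMFProfile(bin_centers=arr[:, 0], mean_force=arr[:, 1],
                      free_energy=arr[:, 2],
                      counts=arr[:, 3].astype(int),
                      converged=arr[:, 4].astype(bool), metadata=meta)


# ---------------------------------------------------------------------------
# run manifests and config
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Snapshot of one CLI run: config, seeds, versions, paths, timings."""

    command: str
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None
    inputs: List[str] = field(default_factory=list)
    outputs: List[str] = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.versions:
            import numpy
            import sys
            from . import __version__
            self.versions = {"poresel": __version__,
                             "numpy": numpy.__version__,
                             "python": sys.version.split()[0]}

    def write(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def timed(cls, command: str, **kwargs) -> "_ManifestTimer":
        return _ManifestTimer(cls(command=command, **kwargs))


class _ManifestTimer:
    def __init__(self, manifest: RunManifest):
        self.manifest = manifest
        self._t0 = time.monotonic()

    def __enter__(self) -> RunManifest:
        return self.manifest

    def __exit__(self, *exc) -> None:
        self.manifest.timings_s["total"] = time.monotonic() - self._t0


def load_config(path: Union[str, Path]) -> dict:
    """YAML/JSON config with blocks water_params, geometry, kappa, units."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
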