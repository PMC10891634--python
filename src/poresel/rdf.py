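"""Radial distribution functions and first-shell coordination numbers.

The RDF is the standard shell-normalised pair histogram under the minimum
image convention; the running number integral n(r) is accumulated by direct
counting, so n(r_max) is exactly the mean number of target atoms within
r_max of a centre.  The first hydration-shell boundary is located as the
first local minimum after the first maximum of a lightly smoothed g(r)
(5-bin moving average, 0.05 Å bins by default), and the coordination number
is the mean target count inside that radius.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .frames import Frame, Trajectory, min_image_dist

__all__ = ["RDFProfile", "select_positions", "rdf", "coordination_number",
           "first_minimum"]


@dataclass
class RDFProfile:
    bin_centers: np.ndarray
    g: np.ndarray
    n_int: np.ndarray            # running coordination number n(r)
    first_minimum: Optional[float]
    coordination_number: Optional[float]
    bin_width: float


def select_positions(frame: Frame, sel: Union[str, np.ndarray]) -> np.ndarray:
    """Positions for a selection: a species label ("OW", "K", "NA", "CL",
    "C"/"wall") or an explicit (n,3) array."""
    if isinstance(sel, np.ndarray):
        return sel.reshape(-1, 3)
    s = sel.upper()
    if s == "OW":
        return frame.water_O
    if s == "HW":
        return np.concatenate([frame.water_H1, frame.water_H2], axis=0)
    if s in ("C", "WALL"):
        return frame.wall_pos
    idx = [i for i, lbl in enumerate(frame.ion_labels) if lbl.upper() == s]
    if not idx:
        raise ValueError(f"selection '{sel}' matches no atoms")
    return frame.ion_pos[idx]


def first_minimum(bin_centers: np.ndarray, g: np.ndarray,
                  smooth_bins: int = 5) -> Optional[float]:
    """First local minimum after the first maximum of the smoothed profile."""
    if len(g) < smooth_bins + 2:
        return None
    kernel = np.ones(smooth_bins) / smooth_bins
    gs = np.convolve(g, kernel, mode="same")
    # first maximum: first interior point exceeding both neighbours, after
    # the profile has risen from zero
    imax = None
    for i in range(1, len(gs) - 1):
        if gs[i] > 0 and gs[i] >= gs[i - 1] and gs[i] > gs[i + 1]:
            imax = i
            break
    if imax is None:
        return None
    for i in range(imax + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] < gs[i + 1]:
            return float(bin_centers[i])
    return None


def rdf(
    trajectory: Trajectory,
    center_sel: Union[str, np.ndarray],
    target_sel: Union[str, np.ndarray],
    bin_width: float = 0.05,
    r_max: Optional[float] = None,
) -> RDFProfile:
    """Centre–target radial distribution function over a trajectory."""
    if len(trajectory) == 0:
        raise ValueError("trajectory must contain at least one frame")
    box0 = trajectory[0].box
    if r_max is None:
        r_max = 0.5 * float(box0.min())
    if r_max > 0.5 * float(box0.min()) * (1 + 1e-12):
        raise ValueError("r_max exceeds half the smallest box edge")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    centers_r = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers_r))
    n_center_total = 0
    rho_sum = 0.0
    for frame in trajectory:
        cpos = select_positions(frame, center_sel)
        tpos = select_positions(frame, target_sel)
        same = (isinstance(center_sel, str) and isinstance(target_sel, str)
                and center_sel.upper() == target_sel.upper())
        vol = float(np.prod(frame.box))
        for i, c in enumerate(cpos):
            d = min_image_dist(tpos, c, frame.box)
            if same:
                d = np.delete(d, i)
            hist += np.histogram(d, bins=edges)[0]
        n_t_eff = len(tpos) - 1 if same else len(tpos)
        n_center_total += len(cpos)
        rho_sum += len(cpos) * (n_t_eff / vol)
    if n_center_total == 0:
        raise ValueError("empty centre selection")
    mean_counts = hist / n_center_total          # mean targets per shell
    rho = rho_sum / n_center_total               # mean target density
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = mean_counts / (rho * shell_vol)
    n_int = np.cumsum(mean_counts)
    fmin = first_minimum(centers_r, g)
    coord = None
    if fmin is not None:
        coord = float(n_int[np.searchsorted(edges[1:], fmin)])
    return RDFProfile(bin_centers=centers_r, g=g, n_int=n_int,
                      first_minimum=fmin, coordination_number=coord,
                      bin_width=bin_width)


def coordination_number(
    trajectory: Trajectory,
    ion_sel: Union[str, np.ndarray],
    cutoff: Union[float, str] = "auto",
    target_sel: str = "OW",
    bin_width: float = 0.05,
) -> float:
    """Mean count of target atoms (water oxygens by default) within ``cutoff``
    of the selected ion; ``cutoff="auto"`` uses the RDF first minimum."""
    if cutoff == "auto":
        prof = rdf(trajectory, ion_sel, target_sel, bin_width=bin_width)
        if prof.first_minimum is None:
            raise ValueError("could not locate an RDF first minimum")
        cutoff = prof.first_minimum
    cutoff = float(cutoff)
    counts = []
    for frame in trajectory:
        cpos = select_positions(frame, ion_sel)
        tpos = select_positions(frame, target_sel)
        if len(tpos) == 0:
            import warnings
            warnings.warn("no target atoms: coordination number is zero")
            counts.append(0.0)
            continue
        for c in cpos:
            d = min_image_dist(tpos, c, frame.box)
            counts.append(float(np.sum(d <= cutoff)))
    return float(np.mean(counts))
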