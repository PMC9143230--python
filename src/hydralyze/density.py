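"""Mass-density profiles along z and profile symmetrization.

The profile is the frame-averaged, mass-weighted histogram of wrapped atom
z-coordinates divided by the bin slab volume Lx*Ly*dz, converted from
amu/nm^3 to g/cm^3 (count/nm^3 on request).  Symmetrization averages the
profile with its mirror image about the membrane centre,
out(z) = [in(z) + in(2c - z)] / 2, which is the standard trick for slab
systems whose two faces are statistically equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Topology, Trajectory, parse_frame_range
from .select import AtomSelection
from .units import AMU_PER_NM3_TO_G_PER_CM3


class DensityError(ValueError):
    pass


@dataclass
class Profile:
    """A binned z-profile; values are g/cm^3 (or count/nm^3)."""

    bin_edges: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = "g_cm3"
    n_frames: int = 1
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise DensityError("values must have one entry per bin")
        if np.any(self.values < -1e-12):
            raise DensityError("densities must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def as_dataframe(self) -> pd.DataFrame:
        col = "density_g_cm3" if self.units == "g_cm3" else "density_per_nm3"
        return pd.DataFrame({"z_nm": self.centers, col: self.values})


def density_profile(
    traj: Trajectory,
    topology: Topology,
    selection: AtomSelection,
    bin_width: float = 0.1,
    frame_range=None,
    units: str = "g_cm3",
) -> Profile:
    """Mass (or number) density along z, averaged over the frame range.

    Bin edges span [0, Lz] of the first selected frame; NPT-style box
    fluctuations are not supported (generated boxes are constant).
    """
    if bin_width <= 0:
        raise DensityError("bin_width must be > 0")
    if selection.empty:
        raise DensityError("density profile requires a non-empty selection")
    if units not in ("g_cm3", "per_nm3"):
        raise DensityError(f"unknown units {units!r}")
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    box = traj.boxes[frames[0]]
    if not np.allclose(traj.boxes[frames], box):
        raise DensityError("density_profile requires a constant box over the frame range")
    lz = box[2]
    n_bins = int(np.ceil(lz / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    weights = (
        topology.masses[selection.atom_ids]
        if units == "g_cm3"
        else np.ones(len(selection.atom_ids))
    )
    hist = np.zeros(n_bins)
    for f in frames:
        z = traj.coords[f, selection.atom_ids, 2]
        hist += np.histogram(z, bins=edges, weights=weights)[0]
    hist /= len(frames)
    bin_volume = box[0] * box[1] * bin_width
    values = hist / bin_volume
    if units == "g_cm3":
        values = values * AMU_PER_NM3_TO_G_PER_CM3
    return Profile(
        bin_edges=edges,
        values=values,
        label=selection.expression,
        units=units,
        n_frames=len(frames),
        params={
            "bin_width_nm": bin_width,
            "selection": selection.expression,
            "units": units,
            "n_frames": len(frames),
        },
    )


def membrane_center(
    traj: Trajectory, topology: Topology, selection: AtomSelection, frame_range=None
) -> float:
    """Centre of mass (z) of a selection, averaged over frames.

    Used as the 'auto' symmetrization centre; assumes the slab does not
    straddle the z-boundary (re-centre first if it does).
    """
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    m = topology.masses[selection.atom_ids]
    z = traj.coords[frames][:, selection.atom_ids, 2]
    return float(np.average(z.mean(axis=0), weights=m))


def symmetrize(profile: Profile, center: float) -> Profile:
    """Average a profile with its reflection about ``center``.

    Reflected positions are evaluated by linear interpolation on the bin
    centres; reflections landing outside the profile range contribute
    zero density.  Applying the operation twice equals applying it once
    up to interpolation error (exactly, when the centre is grid-aligned).
    """
    lo, hi = profile.bin_edges[0], profile.bin_edges[-1]
    if not (lo <= center <= hi):
        raise DensityError(f"center {center} outside profile range [{lo}, {hi}]")
    c = profile.centers
    x = 2 * center - c
    # snap reflections that miss the outermost bin centre by float rounding
    tol = 1e-9 * (c[-1] - c[0])
    x = np.where((x > c[-1]) & (x < c[-1] + tol), c[-1], x)
    x = np.where((x < c[0]) & (x > c[0] - tol), c[0], x)
    mirrored = np.interp(x, c, profile.values, left=0.0, right=0.0)
    return Profile(
        bin_edges=profile.bin_edges.copy(),
        values=0.5 * (profile.values + mirrored),
        label=profile.label,
        units=profile.units,
        n_frames=profile.n_frames,
        params={**profile.params, "symmetrized_about_nm": center},
    )
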