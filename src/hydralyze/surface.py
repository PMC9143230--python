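"""Membrane surface extraction on an xy grid, RMS roughness, contour maps.

The box is tiled with lateral cells (default 0.4 nm x 0.4 nm); within each
cell the extreme-z atom of the selection defines the local surface height
(max z for the upper face, min z for the lower face).  RMS roughness is
the root-mean-square deviation of occupied-cell heights about their mean,

    R = sqrt( sum_i (Z_i - Zbar)^2 / N ).

By default N counts one height per occupied grid cell; ``all_top_atoms``
switches to the per-atom reading (every atom within ``top_layer`` nm of
its cell's extreme height contributes its own z).  Slabs straddling the
periodic z-boundary must be re-centred first
(:func:`hydralyze.core.recenter_slab`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, parse_frame_range
from .select import AtomSelection


class SurfaceError(ValueError):
    pass


@dataclass
class SurfaceGrid:
    """Per-cell surface heights for one face of one frame.

    Cells are half-open intervals [i*s, (i+1)*s) except that a box length
    not divisible by the cell size leaves a final narrower cell (cells are
    never wrapped).  Unoccupied cells are flagged, never silently zero.
    """

    cell_size: float
    heights: np.ndarray  # (nx, ny), NaN where unoccupied
    occupied: np.ndarray  # (nx, ny) bool
    side: str
    frame_index: int
    box: np.ndarray

    @property
    def nx(self) -> int:
        return self.heights.shape[0]

    @property
    def ny(self) -> int:
        return self.heights.shape[1]

    @property
    def n_occupied(self) -> int:
        return int(self.occupied.sum())

    def height_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Surface height at arbitrary (wrapped) lateral positions, from the
        containing cell; NaN over unoccupied cells."""
        ix = np.minimum((np.asarray(x) / self.cell_size).astype(int), self.nx - 1)
        iy = np.minimum((np.asarray(y) / self.cell_size).astype(int), self.ny - 1)
        return self.heights[ix, iy]


def extract_surface(
    traj: Trajectory,
    selection: AtomSelection,
    frame: int = 0,
    cell_size: float = 0.4,
    side: str = "up",
) -> SurfaceGrid:
    """Grid the xy plane and take the extreme z of the selection per cell."""
    if selection.empty:
        raise SurfaceError("surface extraction requires a non-empty selection")
    if cell_size <= 0:
        raise SurfaceError("cell_size must be > 0")
    if side not in ("up", "down"):
        raise SurfaceError(f"side must be 'up' or 'down', got {side!r}")
    box = traj.boxes[frame]
    nx = int(np.ceil(box[0] / cell_size))
    ny = int(np.ceil(box[1] / cell_size))
    pos = traj.coords[frame, selection.atom_ids]
    ix = np.minimum((pos[:, 0] / cell_size).astype(int), nx - 1)
    iy = np.minimum((pos[:, 1] / cell_size).astype(int), ny - 1)
    fill = -np.inf if side == "up" else np.inf
    heights = np.full((nx, ny), fill)
    if side == "up":
        np.maximum.at(heights, (ix, iy), pos[:, 2])
    else:
        np.minimum.at(heights, (ix, iy), pos[:, 2])
    occupied = np.isfinite(heights)
    heights = np.where(occupied, heights, np.nan)
    return SurfaceGrid(
        cell_size=cell_size,
        heights=heights,
        occupied=occupied,
        side=side,
        frame_index=frame,
        box=box.copy(),
    )


def rms_roughness(
    grid: SurfaceGrid,
    traj: Trajectory | None = None,
    selection: AtomSelection | None = None,
    all_top_atoms: bool = False,
    top_layer: float = 0.0,
) -> float:
    """RMS deviation of surface heights about their mean.

    Default: one height per occupied cell.  With ``all_top_atoms`` every
    selection atom within ``top_layer`` nm of its cell's extreme height
    contributes its own z (the per-atom reading of the same statistic);
    this needs the originating trajectory and selection.
    """
    if grid.n_occupied < 2:
        raise SurfaceError("roughness needs at least 2 occupied cells")
    if not all_top_atoms:
        z = grid.heights[grid.occupied]
    else:
        if traj is None or selection is None:
            raise SurfaceError("all_top_atoms mode needs the trajectory and selection")
        pos = traj.coords[grid.frame_index, selection.atom_ids]
        cell_h = grid.height_at(pos[:, 0], pos[:, 1])
        keep = np.abs(pos[:, 2] - cell_h) <= top_layer + 1e-12
        z = pos[keep, 2]
        if len(z) < 2:
            raise SurfaceError("fewer than 2 top atoms selected")
    return float(np.sqrt(np.mean((z - z.mean()) ** 2)))


def roughness_series(
    traj: Trajectory,
    selection: AtomSelection,
    cell_size: float = 0.4,
    side: str = "up",
    frame_range=None,
) -> dict:
    """Per-frame roughness, summarised as mean with SEM (headline) and SD.

    Returns a dict with per-frame values plus mean/sem/sd and the number
    of occupied cells per frame.
    """
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    if len(frames) == 0:
        raise SurfaceError("empty frame range")
    r = np.empty(len(frames))
    occ = np.empty(len(frames), dtype=int)
    for k, f in enumerate(frames):
        grid = extract_surface(traj, selection, frame=int(f), cell_size=cell_size, side=side)
        r[k] = rms_roughness(grid)
        occ[k] = grid.n_occupied
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    return {
        "frames": frames,
        "roughness": r,
        "n_occupied": occ,
        "mean": float(np.mean(r)),
        "sem": sd / np.sqrt(len(r)) if len(r) > 1 else 0.0,
        "sd": sd,
        "side": side,
        "cell_size": cell_size,
    }


def contour_map(grids: SurfaceGrid | list[SurfaceGrid]) -> pd.DataFrame:
    """Time-averaged height matrix for export; never-occupied cells -> NaN.

    Rows are x cells, columns y cells (matching the grid layout).
    """
    if isinstance(grids, SurfaceGrid):
        grids = [grids]
    if not grids:
        raise SurfaceError("contour_map needs at least one grid")
    shape = grids[0].heights.shape
    total = np.zeros(shape)
    count = np.zeros(shape, dtype=int)
    for g in grids:
        if g.heights.shape != shape:
            raise SurfaceError("grids of different shapes cannot be averaged")
        total += np.where(g.occupied, g.heights, 0.0)
        count += g.occupied
    with np.errstate(invalid="ignore"):
        avg = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame(avg)
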