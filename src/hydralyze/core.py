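"""Core containers: Topology, Trajectory and periodic-box helpers.

A :class:`Topology` holds the static per-atom record (name, molecule
membership, mass, partial charge); a :class:`Trajectory` holds frames of
wrapped coordinates in an orthorhombic box.  Coordinates are nm, times ps,
masses amu, charges elementary charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TopologyError(ValueError):
    """Raised for inconsistent atom/molecule records."""


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory data."""


@dataclass
class Topology:
    """Per-atom static data; atom ids are implicit 0..n_atoms-1.

    Parameters
    ----------
    names : array of str
        Atom names as they appear in the coordinate file (e.g. ``OW``).
    molecule_ids : array of int
        0-based molecule index; atoms of one molecule are contiguous.
    molecule_names : array of str
        Residue/molecule name per atom (e.g. ``SOL``).
    masses : array of float, amu
    charges : array of float, e
    """

    names: np.ndarray
    molecule_ids: np.ndarray
    molecule_names: np.ndarray
    masses: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=np.int64)
        self.molecule_names = np.asarray(self.molecule_names, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.names)
        for attr in ("molecule_ids", "molecule_names", "masses", "charges"):
            if len(getattr(self, attr)) != n:
                raise TopologyError(f"{attr} length != number of atoms ({n})")
        if n and not np.all(self.masses > 0):
            bad = np.nonzero(~(self.masses > 0))[0]
            raise TopologyError(f"non-positive masses for atom_ids {bad.tolist()}")
        if n and not np.all(np.isfinite(self.charges)):
            bad = np.nonzero(~np.isfinite(self.charges))[0]
            raise TopologyError(f"non-finite charges for atom_ids {bad.tolist()}")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def atom_ids(self) -> np.ndarray:
        return np.arange(self.n_atoms)

    def molecule_index(self) -> dict[int, np.ndarray]:
        """Mapping molecule_id -> array of atom_ids."""
        order = np.argsort(self.molecule_ids, kind="stable")
        ids, starts = np.unique(self.molecule_ids[order], return_index=True)
        groups = np.split(order, starts[1:])
        return {int(m): np.sort(g) for m, g in zip(ids, groups)}

    def subset(self, atom_ids: np.ndarray) -> "Topology":
        """New Topology restricted to ``atom_ids`` (order preserved)."""
        idx = np.asarray(atom_ids, dtype=np.int64)
        return Topology(
            names=self.names[idx],
            molecule_ids=self.molecule_ids[idx],
            molecule_names=self.molecule_names[idx],
            masses=self.masses[idx],
            charges=self.charges[idx],
        )


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary box [0, L) on each axis.

    Handles a single frame (n_atoms, 3) against box (3,), or a stack of
    frames against per-frame boxes (n_frames, 3).
    """
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    if coords.ndim == 3:
        b = box[:, None, :]
    else:
        b = box
    wrapped = np.mod(coords, b)
    # mod can return L for tiny negative inputs due to rounding
    wrapped = np.where(wrapped >= b, wrapped - b, wrapped)
    return wrapped


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return vectors - box * np.round(vectors / box)


@dataclass
class Trajectory:
    """Frames of wrapped coordinates in orthorhombic periodic boxes.

    Attributes
    ----------
    times : (n_frames,) float, ps, strictly increasing
    boxes : (n_frames, 3) float, nm
    coords : (n_frames, n_atoms, 3) float, nm, wrapped into [0, L)
    metadata : free-form dict (generators record ground truth here)
    """

    times: np.ndarray
    boxes: np.ndarray
    coords: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.n_frames
        if self.times.shape != (n,):
            raise TrajectoryError("times length must equal number of frames")
        if self.boxes.shape != (n, 3):
            raise TrajectoryError("boxes must have shape (n_frames, 3)")
        if n and not np.all(self.boxes > 0):
            raise TrajectoryError("all box lengths must be positive")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            i = int(np.nonzero(~(np.diff(self.times) > 0))[0][0])
            raise TrajectoryError(f"times not strictly increasing at frame {i + 1}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (first interval; generators use a uniform one)."""
        if self.n_frames < 2:
            raise TrajectoryError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    def wrapped(self) -> "Trajectory":
        """Return a copy with coordinates wrapped into the primary box."""
        return Trajectory(
            times=self.times.copy(),
            boxes=self.boxes.copy(),
            coords=wrap_coords(self.coords, self.boxes),
            metadata=dict(self.metadata),
        )

    def check_wrapped(self) -> None:
        b = self.boxes[:, None, :]
        if np.any(self.coords < 0) or np.any(self.coords >= b):
            raise TrajectoryError("coordinates are not wrapped into [0, L)")

    def frame_slice(self, frame_range: tuple[int, int] | None) -> np.ndarray:
        """Frame indices for an inclusive-exclusive (start, stop) range."""
        if frame_range is None:
            return np.arange(self.n_frames)
        start, stop = frame_range
        if not (0 <= start < stop <= self.n_frames):
            raise TrajectoryError(
                f"frame range {frame_range} outside trajectory of {self.n_frames} frames"
            )
        return np.arange(start, stop)


def parse_frame_range(spec: object, n_frames: int) -> tuple[int, int]:
    """Parse a frame-range spec: None/'all', 'last:N', or (start, stop).

    Returns a half-open (start, stop) index pair.
    """
    if spec is None or spec == "all":
        return (0, n_frames)
    if isinstance(spec, str):
        if spec.startswith("last:"):
            n = int(spec.split(":", 1)[1])
            if n <= 0:
                raise ValueError("last:N requires N > 0")
            return (max(0, n_frames - n), n_frames)
        raise ValueError(f"unrecognised frame range {spec!r}")
    start, stop = spec
    return (int(start), int(stop))


def recenter_slab(traj: Trajectory, atom_ids: np.ndarray, axis: int = 2) -> Trajectory:
    """Shift each frame along ``axis`` so the selection's wrapped centre of mass
    sits at the box midpoint, then re-wrap.

    Slab systems whose membrane straddles the periodic z-boundary must pass
    through this before any surface/density analysis; the circular mean makes
    the shift well defined even for a straddling slab.
    """
    idx = np.asarray(atom_ids, dtype=np.int64)
    out = traj.coords.copy()
    for f in range(traj.n_frames):
        L = traj.boxes[f, axis]
        theta = traj.coords[f, idx, axis] / L * 2 * np.pi
        mean_angle = np.arctan2(np.mean(np.sin(theta)), np.mean(np.cos(theta)))
        center = (mean_angle / (2 * np.pi)) % 1.0 * L
        out[f, :, axis] = out[f, :, axis] + (L / 2 - center)
    return Trajectory(
        times=traj.times.copy(),
        boxes=traj.boxes.copy(),
        coords=wrap_coords(out, traj.boxes),
        metadata=dict(traj.metadata),
    )
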