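"""Readers and writers: GRO / XYZ trajectories, charge sidecars, result tables.

GRO and PDB files carry no partial charges, so a topology is always the pair
(coordinate file, charge sidecar TSV).  The sidecar has a header line
``atom_id  mass  charge`` with 1-based atom ids, mirroring GRO numbering;
ids are 0-based everywhere inside the library.

Multi-frame GRO is read and written natively with atom and residue names
preserved verbatim.  XYZ uses an extended comment line
``box Lx Ly Lz time t`` (all nm / ps).  PDB is read-only (via MDAnalysis)
with Angstrom converted to nm on input.  Only orthorhombic boxes are
supported; triclinic input is a hard error.
"""

from __future__ import annotations

import io as _io
import os
from typing import Iterable

import numpy as np
import pandas as pd

from .core import Topology, TopologyError, Trajectory, TrajectoryError, wrap_coords
from .units import ANGSTROM_TO_NM


class FormatError(ValueError):
    """Unparseable or unsupported input file content."""


# ---------------------------------------------------------------------------
# charge sidecar


def read_charges(path: str | os.PathLike, n_atoms: int) -> tuple[np.ndarray, np.ndarray]:
    """Read the mass/charge sidecar TSV; returns (masses, charges) by atom id.

    The file must cover every atom id 1..n_atoms exactly once.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"atom_id", "mass", "charge"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"charge sidecar {path} must have columns atom_id, mass, charge "
            f"(found {list(df.columns)})"
        )
    ids = df["atom_id"].to_numpy(dtype=np.int64)
    dup = ids[pd.Series(ids).duplicated().to_numpy()]
    if dup.size:
        raise TopologyError(f"duplicate atom_ids in charge sidecar: {sorted(set(dup.tolist()))}")
    expected = set(range(1, n_atoms + 1))
    got = set(ids.tolist())
    missing = sorted(expected - got)
    if missing:
        raise TopologyError(f"charge sidecar missing atom_ids: {missing}")
    extra = sorted(got - expected)
    if extra:
        raise TopologyError(f"charge sidecar has unknown atom_ids: {extra}")
    masses = np.empty(n_atoms)
    charges = np.empty(n_atoms)
    masses[ids - 1] = df["mass"].to_numpy(dtype=float)
    charges[ids - 1] = df["charge"].to_numpy(dtype=float)
    return masses, charges


def write_charges(path: str | os.PathLike, masses: np.ndarray, charges: np.ndarray) -> None:
    df = pd.DataFrame(
        {
            "atom_id": np.arange(1, len(masses) + 1),
            "mass": masses,
            "charge": charges,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GRO

_GRO_BOX_TOL = 1e-9


def _parse_gro_box(line: str, frame: int) -> np.ndarray:
    parts = line.split()
    try:
        vals = [float(p) for p in parts]
    except ValueError as exc:
        raise FormatError(f"unparseable box line at frame {frame}: {line!r}") from exc
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > _GRO_BOX_TOL for v in vals[3:]):
            raise FormatError(
                f"triclinic box at frame {frame}; only orthorhombic boxes are supported"
            )
        box = np.array(vals[:3])
    else:
        raise FormatError(f"box line at frame {frame} has {len(vals)} values (need 3 or 9)")
    if not np.all(box > 0):
        raise FormatError(f"non-positive box length at frame {frame}")
    return box


def _parse_gro_time(title: str) -> float | None:
    if "t=" in title:
        tail = title.split("t=")[-1].split()
        if tail:
            try:
                return float(tail[0])
            except ValueError:
                return None
    return None


def _read_gro_frames(path: str | os.PathLike):
    """Yield (title, resids, resnames, names, coords, box) per frame."""
    with open(path) as fh:
        frame = 0
        while True:
            title = fh.readline()
            if not title:
                return
            if not title.strip():
                continue
            count_line = fh.readline()
            try:
                n = int(count_line.split()[0])
            except (IndexError, ValueError) as exc:
                raise FormatError(
                    f"unparseable atom count at frame {frame}: {count_line!r}"
                ) from exc
            resids = np.empty(n, dtype=np.int64)
            resnames = np.empty(n, dtype=object)
            names = np.empty(n, dtype=object)
            coords = np.empty((n, 3))
            for i in range(n):
                line = fh.readline()
                if not line:
                    raise FormatError(f"truncated frame {frame}: expected {n} atoms, got {i}")
                try:
                    resids[i] = int(line[0:5])
                    resnames[i] = line[5:10].strip()
                    names[i] = line[10:15].strip()
                    coords[i, 0] = float(line[20:28])
                    coords[i, 1] = float(line[28:36])
                    coords[i, 2] = float(line[36:44])
                except ValueError as exc:
                    raise FormatError(
                        f"unparseable atom line {i} at frame {frame}: {line!r}"
                    ) from exc
            box = _parse_gro_box(fh.readline(), frame)
            yield title.rstrip("\n"), resids, resnames, names, coords, box
            frame += 1


def write_gro(
    path: str | os.PathLike,
    topology: Topology,
    trajectory: Trajectory,
    title: str = "hydralyze",
) -> None:
    """Write a (multi-frame) GRO file; ids are converted to 1-based."""
    resids = topology.molecule_ids + 1
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            fh.write(f"{title}, t= {trajectory.times[f]:.4f}\n")
            fh.write(f"{topology.n_atoms:5d}\n")
            for i in range(topology.n_atoms):
                x, y, z = trajectory.coords[f, i]
                fh.write(
                    f"{int(resids[i]) % 100000:5d}{str(topology.molecule_names[i])[:5]:<5s}"
                    f"{str(topology.names[i])[:5]:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            bx, by, bz = trajectory.boxes[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ (extended comment line)


def _read_xyz_frames(path: str | os.PathLike):
    with open(path) as fh:
        frame = 0
        while True:
            count_line = fh.readline()
            if not count_line:
                return
            if not count_line.strip():
                continue
            try:
                n = int(count_line.split()[0])
            except ValueError as exc:
                raise FormatError(
                    f"unparseable atom count at frame {frame}: {count_line!r}"
                ) from exc
            comment = fh.readline().split()
            if len(comment) < 6 or comment[0] != "box" or comment[4] != "time":
                raise FormatError(
                    f"frame {frame}: XYZ comment line must read 'box Lx Ly Lz time t'"
                )
            box = np.array([float(v) for v in comment[1:4]])
            time = float(comment[5])
            names = np.empty(n, dtype=object)
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                if len(parts) < 4:
                    raise FormatError(f"truncated/short atom line {i} at frame {frame}")
                names[i] = parts[0]
                coords[i] = [float(v) for v in parts[1:4]]
            yield names, coords, box, time
            frame += 1


def write_xyz(path: str | os.PathLike, topology: Topology, trajectory: Trajectory) -> None:
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            bx, by, bz = trajectory.boxes[f]
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"box {bx:.6f} {by:.6f} {bz:.6f} time {trajectory.times[f]:.6f}\n")
            for i in range(topology.n_atoms):
                x, y, z = trajectory.coords[f, i]
                fh.write(f"{topology.names[i]} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# topology / trajectory entry points


def _molecule_grouping(resids: np.ndarray, resnames: np.ndarray) -> np.ndarray:
    """0-based molecule ids from residue numbering: a new molecule starts
    whenever (resid, resname) changes between consecutive atoms."""
    n = len(resids)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    change = np.ones(n, dtype=bool)
    change[1:] = (resids[1:] != resids[:-1]) | (resnames[1:] != resnames[:-1])
    return np.cumsum(change) - 1


def _read_pdb_single(path: str | os.PathLike):
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    names = np.array([str(n) for n in u.atoms.names], dtype=object)
    resnames = np.array([str(n) for n in u.atoms.resnames], dtype=object)
    resids = np.asarray(u.atoms.resids, dtype=np.int64)
    coords = u.atoms.positions.astype(float) * ANGSTROM_TO_NM
    dims = u.dimensions
    if dims is None or not np.all(dims[:3] > 0):
        raise FormatError(f"PDB {path} carries no usable CRYST1 box")
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise FormatError("triclinic PDB box; only orthorhombic boxes are supported")
    box = dims[:3].astype(float) * ANGSTROM_TO_NM
    return resids, resnames, names, coords, box


def read_topology(coord_path: str | os.PathLike, charge_path: str | os.PathLike) -> Topology:
    """Build a Topology from a single-frame GRO/PDB plus a charge sidecar."""
    ext = os.path.splitext(str(coord_path))[1].lower()
    if ext == ".gro":
        frames = _read_gro_frames(coord_path)
        try:
            _, resids, resnames, names, _, _ = next(frames)
        except StopIteration:
            raise FormatError(f"{coord_path} contains no frames") from None
    elif ext == ".pdb":
        resids, resnames, names, _, _ = _read_pdb_single(coord_path)
    else:
        raise FormatError(f"unsupported topology coordinate format {ext!r} (use .gro/.pdb)")
    masses, charges = read_charges(charge_path, len(names))
    return Topology(
        names=names,
        molecule_ids=_molecule_grouping(resids, resnames),
        molecule_names=resnames,
        masses=masses,
        charges=charges,
    )


def read_trajectory(path: str | os.PathLike, topology: Topology) -> Trajectory:
    """Read a multi-frame GRO or XYZ trajectory; coordinates are wrapped.

    Frames missing a ``t=`` (GRO) time stamp get their frame index as the
    time in ps.  Atom-count mismatches against the topology and
    non-increasing times are hard errors naming the frame.
    """
    ext = os.path.splitext(str(path))[1].lower()
    times: list[float] = []
    boxes: list[np.ndarray] = []
    frames: list[np.ndarray] = []
    if ext == ".gro":
        for f, (title, _, _, _, coords, box) in enumerate(_read_gro_frames(path)):
            if coords.shape[0] != topology.n_atoms:
                raise TrajectoryError(
                    f"frame {f} has {coords.shape[0]} atoms, topology has {topology.n_atoms}"
                )
            t = _parse_gro_time(title)
            times.append(float(f) if t is None else t)
            boxes.append(box)
            frames.append(coords)
    elif ext == ".xyz":
        for f, (_, coords, box, t) in enumerate(_read_xyz_frames(path)):
            if coords.shape[0] != topology.n_atoms:
                raise TrajectoryError(
                    f"frame {f} has {coords.shape[0]} atoms, topology has {topology.n_atoms}"
                )
            times.append(t)
            boxes.append(box)
            frames.append(coords)
    else:
        raise FormatError(f"unsupported trajectory format {ext!r} (use .gro/.xyz)")
    if not frames:
        raise FormatError(f"{path} contains no frames")
    times_arr = np.array(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        i = int(np.nonzero(~(np.diff(times_arr) > 0))[0][0])
        raise TrajectoryError(f"frame times not strictly increasing at frame {i + 1}")
    boxes_arr = np.stack(boxes)
    coords_arr = wrap_coords(np.stack(frames), boxes_arr)
    return Trajectory(times=times_arr, boxes=boxes_arr, coords=coords_arr)


def write_trajectory(path: str | os.PathLike, topology: Topology, trajectory: Trajectory) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".gro":
        write_gro(path, topology, trajectory)
    elif ext == ".xyz":
        write_xyz(path, topology, trajectory)
    else:
        raise FormatError(f"unsupported trajectory format {ext!r} (use .gro/.xyz)")


# ---------------------------------------------------------------------------
# result tables and OpenDX grids


def write_table(
    result,
    path: str | os.PathLike,
    params: dict | None = None,
) -> None:
    """Write a binned result as TSV with a commented parameter header.

    ``result`` is either a pandas DataFrame or any object exposing
    ``as_dataframe()``; parameters come from ``params`` merged over the
    object's own ``params`` attribute when present.
    """
    if isinstance(result, pd.DataFrame):
        df = result
        own: dict = {}
    else:
        df = result.as_dataframe()
        own = dict(getattr(result, "params", {}) or {})
    if params:
        own.update(params)
    buf = _io.StringIO()
    for key in sorted(own):
        buf.write(f"# {key} = {own[key]}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.8g", na_rep="nan")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_table(path: str | os.PathLike) -> tuple[pd.DataFrame, dict]:
    params: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, val = line[1:].split("=", 1)
                params[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    return df, params


def write_dx(
    path: str | os.PathLike,
    values: np.ndarray,
    origin: Iterable[float],
    spacing: Iterable[float],
    comment: str = "hydralyze grid",
) -> None:
    """Write a 3D scalar grid in OpenDX format (nm units)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("OpenDX export requires a 3D grid")
    nx, ny, nz = values.shape
    ox, oy, oz = origin
    sx, sy, sz = spacing
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {sx:.6f} 0 0\n")
        fh.write(f"delta 0 {sy:.6f} 0\n")
        fh.write(f"delta 0 0 {sz:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = values.ravel(order="C")
        for i in range(0, flat.size, 3):
            chunk = flat[i : i + 3]
            fh.write(" ".join(f"{v:.6e}" for v in chunk) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
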