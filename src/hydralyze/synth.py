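"""Synthetic slab + solvent trajectory generators with known ground truth.

Every generator is seeded and reproducible, and records in
``Trajectory.metadata`` the true parameter each downstream estimator is
meant to recover (RMS roughness, diffusion coefficient, residence time,
imposed dipole order, reference density).  The dynamics are deliberately
non-physical — particles do not interact, orientations are resampled per
frame, shell exchange teleports particles — because the analyses operate
on coordinates alone; what matters is that the target observable has a
closed-form true value.

Unit conventions follow the rest of the library (nm, ps, amu, e); the
diffusion input is in the customary 1e-5 cm^2/s scale and converted once
via :data:`hydralyze.units.D_1E5_CM2_PER_S_TO_NM2_PER_PS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Topology, Trajectory, wrap_coords
from .units import (
    D_1E5_CM2_PER_S_TO_NM2_PER_PS,
    SPC_CHARGE_H,
    SPC_CHARGE_O,
    SPC_HOH_ANGLE_DEG,
    SPC_MASS_H,
    SPC_MASS_O,
    SPC_OH_BOND_NM,
)

WATER_MASS = SPC_MASS_O + 2 * SPC_MASS_H


class SpecError(ValueError):
    """A generator spec violates its invariants."""


@dataclass
class Corrugation:
    """Top-surface height modulation dz(x) about the nominal slab top.

    flat: dz = 0; two_level: dz = +A for x < Lx/2 else -A (RMS = A for
    equal areas); sinusoid: dz = A sin(2 pi x / wavelength) (RMS = A/sqrt2
    over whole periods).
    """

    mode: str = "flat"
    amplitude: float = 0.0
    wavelength: float = 1.0


@dataclass
class SlabSpec:
    """A rectangular polymer-slab stand-in on a cubic-ish lattice.

    box : (Lx, Ly, Lz) nm; slab_z_range : (z_lo, z_hi) nm nominal extent;
    atom_spacing : lattice constant nm; charge_pattern : charges assigned
    cyclically along the atom list; n_frames / dt / jitter_z : optional
    rigid per-frame z-jitter for frame-series tests.
    """

    box: tuple[float, float, float] = (4.0, 4.0, 8.0)
    slab_z_range: tuple[float, float] = (1.0, 3.0)
    corrugation: Corrugation = field(default_factory=Corrugation)
    atom_spacing: float = 0.2
    charge_pattern: tuple[float, ...] = (0.0,)
    n_frames: int = 1
    dt: float = 2.0
    jitter_z: float = 0.0

    def validate(self) -> None:
        lx, ly, lz = self.box
        zlo, zhi = self.slab_z_range
        amp = abs(self.corrugation.amplitude)
        if self.atom_spacing <= 0:
            raise SpecError("atom_spacing must be > 0")
        if not (0 < lx and 0 < ly and 0 < lz):
            raise SpecError("box lengths must be positive")
        if not (0 <= zlo < zhi <= lz):
            raise SpecError("slab_z_range must be ordered and inside the box")
        if zhi + amp + self.jitter_z >= lz or zlo - self.jitter_z <= 0:
            raise SpecError("slab (plus corrugation/jitter) must fit inside the box")
        if self.corrugation.mode not in ("flat", "two_level", "sinusoid"):
            raise SpecError(f"unknown corrugation mode {self.corrugation.mode!r}")
        if amp >= (zhi - zlo) / 2:
            raise SpecError("corrugation amplitude must be < slab thickness / 2")
        if self.corrugation.mode == "sinusoid" and self.corrugation.wavelength <= 0:
            raise SpecError("sinusoid wavelength must be > 0")


def _analytic_roughness(corr: Corrugation) -> float:
    if corr.mode == "flat":
        return 0.0
    if corr.mode == "two_level":
        return abs(corr.amplitude)
    return abs(corr.amplitude) / np.sqrt(2.0)


def make_slab(spec: SlabSpec, seed: int = 0) -> tuple[Topology, Trajectory]:
    """Lattice slab whose top surface follows the corrugation exactly.

    The analytic RMS roughness of the corrugation mode is recorded in
    ``metadata['analytic_roughness']``; the RMS of the actually
    constructed top-layer heights (which differs only by lattice
    discretisation) in ``metadata['constructed_roughness']``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    lx, ly, lz = spec.box
    zlo, zhi = spec.slab_z_range
    s = spec.atom_spacing
    xs = np.arange(s / 2, lx, s)
    ys = np.arange(s / 2, ly, s)
    # bulk lattice must stay strictly below the corrugation's lowest point,
    # otherwise extracted surfaces would pick bulk atoms in the troughs
    amp = abs(spec.corrugation.amplitude)
    zs = np.arange(zlo + s / 2, zhi - amp - s / 2, s)
    if len(zs) == 0:
        zs = np.array([zlo + (zhi - amp - zlo) / 2])
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    bulk = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    # top layer carries the corrugation about the nominal top z_hi
    tx, ty = np.meshgrid(xs, ys, indexing="ij")
    corr = spec.corrugation
    if corr.mode == "flat":
        dz = np.zeros_like(tx)
    elif corr.mode == "two_level":
        dz = np.where(tx < lx / 2, corr.amplitude, -corr.amplitude)
    else:
        dz = corr.amplitude * np.sin(2 * np.pi * tx / corr.wavelength)
    top = np.column_stack([tx.ravel(), ty.ravel(), (zhi + dz).ravel()])
    positions = np.vstack([bulk, top])
    n = len(positions)

    charges = np.array(
        [spec.charge_pattern[i % len(spec.charge_pattern)] for i in range(n)]
    )
    top_mask = np.zeros(n, dtype=bool)
    top_mask[len(bulk):] = True
    names = np.where(top_mask, "CT", "CB").astype(object)
    topology = Topology(
        names=names,
        molecule_ids=np.zeros(n, dtype=np.int64),
        molecule_names=np.full(n, "MEM", dtype=object),
        masses=np.full(n, 12.011),
        charges=charges,
    )
    shifts = (
        rng.uniform(-spec.jitter_z, spec.jitter_z, size=spec.n_frames)
        if spec.jitter_z > 0
        else np.zeros(spec.n_frames)
    )
    coords = np.repeat(positions[None, :, :], spec.n_frames, axis=0)
    coords[:, :, 2] += shifts[:, None]
    boxes = np.tile(np.array(spec.box), (spec.n_frames, 1))
    traj = Trajectory(
        times=np.arange(spec.n_frames) * spec.dt,
        boxes=boxes,
        coords=wrap_coords(coords, boxes),
        metadata={
            "analytic_roughness": _analytic_roughness(corr),
            "constructed_roughness": float(np.sqrt(np.mean((dz - dz.mean()) ** 2))),
            "surface_z": float(zhi),
            "top_atom_name": "CT",
            "corrugation_mode": corr.mode,
            "jitter_shifts": shifts,
        },
    )
    return topology, traj


@dataclass
class Orientation:
    """Dipole-orientation law for generated waters.

    random: directions uniform on the sphere; fixed_cos: every dipole at
    cos(theta) = cos_value; decaying: cos(theta) = cos_value *
    exp(-z / decay_length) with z the oxygen height above z = 0.
    """

    mode: str = "random"
    cos_value: float = 0.0
    decay_length: float = 1.0


@dataclass
class ShellKinetics:
    """Exponential-exchange hydration shell: mean in-shell episode tau (ps)
    within shell_cutoff (nm) of the surface plane."""

    tau: float = 25.0
    shell_cutoff: float = 0.5


@dataclass
class SolventSpec:
    n_waters: int = 500
    true_D: float = 2.57  # 1e-5 cm^2/s
    dt: float = 2.0  # ps
    n_frames: int = 2000
    orientation: Orientation = field(default_factory=Orientation)
    shell_kinetics: ShellKinetics | None = None

    def validate(self) -> None:
        if self.n_waters <= 0:
            raise SpecError("n_waters must be > 0")
        if self.true_D < 0:
            raise SpecError("true_D must be >= 0")
        if self.dt <= 0 or self.n_frames <= 0:
            raise SpecError("dt and n_frames must be > 0")
        if not -1.0 <= self.orientation.cos_value <= 1.0:
            raise SpecError("orientation cos_value must lie in [-1, 1]")
        if self.orientation.mode not in ("random", "fixed_cos", "decaying"):
            raise SpecError(f"unknown orientation mode {self.orientation.mode!r}")
        if self.shell_kinetics is not None and not self.shell_kinetics.tau > 0:
            raise SpecError("shell tau must be > 0")


def _point_topology(n: int, name: str = "OW", molname: str = "SOL") -> Topology:
    """Single-site particles, one molecule each (water-mass tracers)."""
    return Topology(
        names=np.full(n, name, dtype=object),
        molecule_ids=np.arange(n, dtype=np.int64),
        molecule_names=np.full(n, molname, dtype=object),
        masses=np.full(n, WATER_MASS),
        charges=np.zeros(n),
    )


def make_brownian_solvent(
    spec: SolventSpec, box: tuple[float, float, float], seed: int = 0
) -> tuple[Topology, Trajectory]:
    """Independent Gaussian random walks with per-axis step variance
    2 D dt, wrapped by PBC; unwrapped ground-truth paths kept in metadata."""
    spec.validate()
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    d_nm2_ps = spec.true_D * D_1E5_CM2_PER_S_TO_NM2_PER_PS
    sigma = np.sqrt(2.0 * d_nm2_ps * spec.dt)
    start = rng.uniform(0, box_arr, size=(spec.n_waters, 3))
    steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_waters, 3))
    unwrapped = np.concatenate(
        [start[None], start[None] + np.cumsum(steps, axis=0)], axis=0
    )
    boxes = np.tile(box_arr, (spec.n_frames, 1))
    traj = Trajectory(
        times=np.arange(spec.n_frames) * spec.dt,
        boxes=boxes,
        coords=wrap_coords(unwrapped, boxes),
        metadata={"true_D": spec.true_D, "unwrapped": unwrapped, "dt": spec.dt},
    )
    return _point_topology(spec.n_waters), traj


def _units_from_cos(cos_theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors with given z-cosines and uniform azimuth."""
    phi = rng.uniform(0, 2 * np.pi, size=len(cos_theta))
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, None))
    return np.column_stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta]
    )


def _water_sites(o_pos: np.ndarray, dipole_dir: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """SPC-geometry 3-site coordinates (O, H1, H2) for each oxygen and
    dipole (H-H bisector) direction; the molecular plane's azimuth about
    the dipole axis is random."""
    n = len(o_pos)
    half = np.deg2rad(SPC_HOH_ANGLE_DEG) / 2
    # random unit vector perpendicular to the dipole
    raw = rng.normal(size=(n, 3))
    perp = raw - np.sum(raw * dipole_dir, axis=1, keepdims=True) * dipole_dir
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    # degenerate draws (parallel to dipole) are vanishingly rare; re-draw defensively
    bad = (norms[:, 0] < 1e-12)
    while np.any(bad):
        raw_b = rng.normal(size=(int(bad.sum()), 3))
        perp_b = raw_b - np.sum(raw_b * dipole_dir[bad], axis=1, keepdims=True) * dipole_dir[bad]
        perp[bad] = perp_b
        norms = np.linalg.norm(perp, axis=1, keepdims=True)
        bad = (norms[:, 0] < 1e-12)
    perp = perp / norms
    h1 = o_pos + SPC_OH_BOND_NM * (np.cos(half) * dipole_dir + np.sin(half) * perp)
    h2 = o_pos + SPC_OH_BOND_NM * (np.cos(half) * dipole_dir - np.sin(half) * perp)
    out = np.empty((3 * n, 3))
    out[0::3] = o_pos
    out[1::3] = h1
    out[2::3] = h2
    return out


def water_topology(n_waters: int, molname: str = "SOL") -> Topology:
    """SPC 3-site water topology (O-H 0.1 nm, H-O-H 109.47 deg; charges
    O -0.82 e, H +0.41 e)."""
    names = np.array(["OW", "HW1", "HW2"] * n_waters, dtype=object)
    mol = np.repeat(np.arange(n_waters, dtype=np.int64), 3)
    return Topology(
        names=names,
        molecule_ids=mol,
        molecule_names=np.full(3 * n_waters, molname, dtype=object),
        masses=np.tile([SPC_MASS_O, SPC_MASS_H, SPC_MASS_H], n_waters),
        charges=np.tile([SPC_CHARGE_O, SPC_CHARGE_H, SPC_CHARGE_H], n_waters),
    )


def make_oriented_waters(
    spec: SolventSpec,
    box: tuple[float, float, float],
    seed: int = 0,
    z_range: tuple[float, float] | None = None,
) -> tuple[Topology, Trajectory]:
    """3-site SPC waters with a prescribed dipole-orientation law.

    Oxygen positions start uniform (optionally restricted to ``z_range``)
    and, when ``spec.true_D`` > 0, perform independent Brownian walks so
    the same system also carries a known diffusion coefficient (set
    ``true_D = 0`` for static oxygens).  Orientations are resampled
    independently every frame according to ``spec.orientation``, so the
    imposed mean cos(theta) law holds per frame by construction; the
    decaying law uses each oxygen's current height above z = 0.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    lo = np.array([0.0, 0.0, z_range[0] if z_range else 0.0])
    hi = np.array([box_arr[0], box_arr[1], z_range[1] if z_range else box_arr[2]])
    start = rng.uniform(lo, hi, size=(spec.n_waters, 3))
    if spec.true_D > 0 and spec.n_frames > 1:
        sigma = np.sqrt(2.0 * spec.true_D * D_1E5_CM2_PER_S_TO_NM2_PER_PS * spec.dt)
        steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_waters, 3))
        o_paths = np.concatenate(
            [start[None], start[None] + np.cumsum(steps, axis=0)], axis=0
        )
    else:
        o_paths = np.repeat(start[None], spec.n_frames, axis=0)
    orient = spec.orientation
    frames = []
    for f in range(spec.n_frames):
        o_pos = o_paths[f]
        o_wrapped_z = np.mod(o_pos[:, 2], box_arr[2])
        if orient.mode == "random":
            cos_theta = rng.uniform(-1.0, 1.0, size=spec.n_waters)
        elif orient.mode == "fixed_cos":
            cos_theta = np.full(spec.n_waters, orient.cos_value)
        else:
            cos_theta = orient.cos_value * np.exp(-o_wrapped_z / orient.decay_length)
        dip = _units_from_cos(cos_theta, rng)
        frames.append(_water_sites(o_pos, dip, rng))
    coords = np.stack(frames)
    boxes = np.tile(box_arr, (spec.n_frames, 1))
    traj = Trajectory(
        times=np.arange(spec.n_frames) * spec.dt,
        boxes=boxes,
        coords=wrap_coords(coords, boxes),
        metadata={
            "orientation_mode": orient.mode,
            "cos_value": orient.cos_value,
            "decay_length": orient.decay_length,
            "true_D": spec.true_D if spec.true_D > 0 and spec.n_frames > 1 else 0.0,
            "unwrapped_oxygen": o_paths,
        },
    )
    return water_topology(spec.n_waters), traj


def make_exchange_shell(
    spec: SolventSpec,
    box: tuple[float, float, float],
    surface_z: float,
    seed: int = 0,
) -> tuple[Topology, Trajectory]:
    """Tracers alternating between a surface shell and the far region.

    Episode lengths are geometric in frames with mean tau/dt (the
    discrete-time law whose dt->0 limit is exponential exchange), so the
    run-length x dt residence estimator is unbiased in expectation.  The
    shell is the slab surface_z <= z <= surface_z + shell_cutoff; on
    leaving, particles teleport well outside it.  ``tau = inf`` keeps
    every particle in the shell for the whole run (fully censored).
    """
    spec.validate()
    if spec.shell_kinetics is None:
        raise SpecError("make_exchange_shell requires shell_kinetics")
    kin = spec.shell_kinetics
    if np.isfinite(kin.tau) and kin.tau < 2 * spec.dt:
        raise SpecError(
            f"tau = {kin.tau} ps is shorter than two frames (dt = {spec.dt} ps); "
            "episodes would be unresolvable"
        )
    rng = np.random.default_rng(seed)
    box_arr = np.asarray(box, dtype=float)
    z_top = surface_z + kin.shell_cutoff
    if z_top >= box_arr[2]:
        raise SpecError("shell does not fit above surface_z inside the box")
    p = 0.0 if not np.isfinite(kin.tau) else spec.dt / kin.tau

    in_shell = np.zeros((spec.n_waters, spec.n_frames), dtype=bool)
    for w in range(spec.n_waters):
        state = True  # start in shell: every particle contributes episodes
        t = 0
        while t < spec.n_frames:
            if state:
                length = spec.n_frames - t if p == 0.0 else rng.geometric(p)
            else:
                length = rng.geometric(p) if p > 0 else spec.n_frames - t
            end = min(t + int(length), spec.n_frames)
            in_shell[w, t:end] = state
            t = end
            state = not state

    # positions: uniform xy; z uniform in the shell band or in the far band
    far_lo = min(z_top + kin.shell_cutoff, box_arr[2] * 0.99)
    xy = rng.uniform(0, box_arr[:2], size=(spec.n_frames, spec.n_waters, 2))
    z_in = rng.uniform(surface_z, z_top, size=(spec.n_frames, spec.n_waters))
    z_out = rng.uniform(far_lo, box_arr[2], size=(spec.n_frames, spec.n_waters))
    z = np.where(in_shell.T, z_in, z_out)
    coords = np.concatenate([xy, z[:, :, None]], axis=2)
    boxes = np.tile(box_arr, (spec.n_frames, 1))
    traj = Trajectory(
        times=np.arange(spec.n_frames) * spec.dt,
        boxes=boxes,
        coords=wrap_coords(coords, boxes),
        metadata={
            "tau": kin.tau,
            "shell_cutoff": kin.shell_cutoff,
            "surface_z": surface_z,
            "true_occupancy": in_shell,
        },
    )
    return _point_topology(spec.n_waters), traj


def make_ideal_gas(
    rho: float,
    box: tuple[float, float, float],
    n_frames: int,
    seed: int = 0,
    dt: float = 2.0,
) -> tuple[Topology, Trajectory]:
    """Homogeneous ideal gas: i.i.d. uniform positions each frame.

    The RDF of such a system is identically 1 and its coordination number
    (4/3) pi rho r^3; used as the null reference for RDF normalisation.
    """
    if rho <= 0:
        raise SpecError("rho must be > 0")
    box_arr = np.asarray(box, dtype=float)
    n = max(2, int(round(rho * np.prod(box_arr))))
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, box_arr, size=(n_frames, n, 3))
    boxes = np.tile(box_arr, (n_frames, 1))
    traj = Trajectory(
        times=np.arange(n_frames) * dt,
        boxes=boxes,
        coords=coords,
        metadata={"rho": n / float(np.prod(box_arr)), "n_particles": n},
    )
    return _point_topology(n, name="IG", molname="GAS"), traj


def make_coordination_lattice(
    box: tuple[float, float, float],
    radius: float = 0.3,
    n_neighbors: int = 6,
    n_frames: int = 1,
    dt: float = 2.0,
) -> tuple[Topology, Trajectory]:
    """One reference site at the box centre with ``n_neighbors`` target
    sites at exactly ``radius`` (octahedral directions first, then random
    but fixed directions); the RDF coordination plateau is exactly
    ``n_neighbors``."""
    box_arr = np.asarray(box, dtype=float)
    if radius >= box_arr.min() / 2:
        raise SpecError("radius must be below half the smallest box length")
    dirs = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    if n_neighbors > len(dirs):
        rng = np.random.default_rng(12345)
        extra = rng.normal(size=(n_neighbors - len(dirs), 3))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        dirs = np.vstack([dirs, extra])
    center = box_arr / 2
    pos = np.vstack([center, center + radius * dirs[:n_neighbors]])
    n = len(pos)
    names = np.array(["REF"] + ["TGT"] * n_neighbors, dtype=object)
    topology = Topology(
        names=names,
        molecule_ids=np.arange(n, dtype=np.int64),
        molecule_names=np.array(["REF"] + ["TGT"] * n_neighbors, dtype=object),
        masses=np.full(n, WATER_MASS),
        charges=np.zeros(n),
    )
    boxes = np.tile(box_arr, (n_frames, 1))
    traj = Trajectory(
        times=np.arange(n_frames) * dt,
        boxes=boxes,
        coords=np.repeat(pos[None], n_frames, axis=0),
        metadata={"coordination": n_neighbors, "radius": radius},
    )
    return topology, traj


def merge_systems(*systems: tuple[Topology, Trajectory]) -> tuple[Topology, Trajectory]:
    """Concatenate compatible (Topology, Trajectory) pairs into one system.

    All trajectories must share times and boxes; molecule ids are offset
    so they stay unique.  Metadata dicts are merged left-to-right.
    """
    if not systems:
        raise ValueError("merge_systems needs at least one system")
    top0, traj0 = systems[0]
    names, molids, molnames, masses, charges = [], [], [], [], []
    coords = []
    meta: dict = {}
    offset = 0
    for top, traj in systems:
        if traj.n_frames != traj0.n_frames or not np.allclose(traj.times, traj0.times):
            raise SpecError("merge_systems: frame times differ")
        if not np.allclose(traj.boxes, traj0.boxes):
            raise SpecError("merge_systems: boxes differ")
        names.append(top.names)
        molids.append(top.molecule_ids + offset)
        offset += int(top.molecule_ids.max()) + 1 if top.n_atoms else 0
        molnames.append(top.molecule_names)
        masses.append(top.masses)
        charges.append(top.charges)
        coords.append(traj.coords)
        meta.update(traj.metadata)
    topology = Topology(
        names=np.concatenate(names),
        molecule_ids=np.concatenate(molids),
        molecule_names=np.concatenate(molnames),
        masses=np.concatenate(masses),
        charges=np.concatenate(charges),
    )
    traj = Trajectory(
        times=traj0.times.copy(),
        boxes=traj0.boxes.copy(),
        coords=np.concatenate(coords, axis=1),
        metadata=meta,
    )
    return topology, traj
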