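"""Interfacial water structure: dipole-orientation profiles, radial
distribution functions with coordination numbers, and spatial distribution
functions in a solute-fixed frame.

The dipole of a (neutral) water is mu = sum_i q_i (r_i - r_O); its
orientation is summarised as cos(theta) against the +z surface normal.
The orientation profile bins waters by the height of their oxygen above
the local membrane surface (per-cell grid height, or a fixed z-plane) and
averages cos(theta) per bin over frames; a uniformly random orientation
distribution averages to 0.

g(r) counts minimum-image reference-target pairs per spherical shell,
normalised by the mean target density N/V; intramolecular and self pairs
are excluded.  The running coordination number n(r) is the raw cumulative
pair count per reference.  The SDF is a 3D histogram of water oxygens in
the molecular frame defined by three anchor atoms (anchor 1 at the
origin, anchor 2 on +x, anchor 3 in the xy-plane), normalised so bulk
density is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Topology, Trajectory, minimum_image, parse_frame_range
from .select import AtomSelection
from .surface import SurfaceGrid


class StructureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dipoles and orientation


def water_dipole(
    coords: np.ndarray,
    charges: np.ndarray,
    box: np.ndarray,
    ref_index: int = 0,
) -> np.ndarray:
    """Normalised dipole of one molecule; coordinates may be wrapped.

    mu = sum_i q_i * min_image(r_i - r_ref) with the reference atom (the
    oxygen for water) anchoring the molecule across the periodic boundary.
    For a neutral molecule the direction is independent of the reference.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if len(np.unique(charges)) < 2:
        raise StructureError("dipole requires at least 2 distinct charges")
    rel = minimum_image(coords - coords[ref_index], np.asarray(box))
    mu = (charges[:, None] * rel).sum(axis=0)
    norm = np.linalg.norm(mu)
    if norm < 1e-12:
        raise StructureError("zero-magnitude dipole")
    return mu / norm


def _water_groups(topology: Topology, selection: AtomSelection) -> np.ndarray:
    """Group selected atoms into molecules; returns (n_mol, k) atom-id array.

    Requires every selected molecule to contribute the same number of
    atoms (true for pure water selections), which keeps the per-frame
    dipole computation vectorised.
    """
    mol = topology.molecule_ids[selection.atom_ids]
    order = np.argsort(mol, kind="stable")
    ids = selection.atom_ids[order]
    mols, counts = np.unique(mol, return_counts=True)
    if len(mols) == 0:
        raise StructureError("selection contains no molecules")
    if counts.min() != counts.max():
        raise StructureError("selected molecules have differing atom counts")
    k = int(counts[0])
    if k < 2:
        raise StructureError("molecules need >= 2 atoms to carry a dipole")
    return ids.reshape(len(mols), k)


def _frame_dipoles(
    coords: np.ndarray, groups: np.ndarray, topology: Topology, box: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(oxygen position, unit dipole) for every molecule in one frame.

    The reference site is each molecule's heaviest atom (the oxygen for
    water)."""
    q = topology.charges[groups]  # (n_mol, k)
    m = topology.masses[groups]
    ref = np.argmax(m, axis=1)
    pos = coords[groups]  # (n_mol, k, 3)
    refpos = pos[np.arange(len(groups)), ref]  # (n_mol, 3)
    rel = minimum_image(pos - refpos[:, None, :], box)
    mu = (q[..., None] * rel).sum(axis=1)
    norm = np.linalg.norm(mu, axis=1, keepdims=True)
    if np.any(norm < 1e-12):
        raise StructureError("zero-magnitude dipole encountered")
    return refpos, mu / norm


@dataclass
class OrientationProfile:
    """Mean cos(theta) vs distance from the surface; zero-count bins NaN."""

    bin_edges: np.ndarray
    mean_cos: np.ndarray
    counts: np.ndarray
    n_below_surface: int = 0
    n_unassigned: int = 0
    params: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_nm": self.centers,
                "mean_cos_theta": self.mean_cos,
                "count": self.counts,
            }
        )


def orientation_profile(
    traj: Trajectory,
    topology: Topology,
    waters: AtomSelection,
    surface: float | SurfaceGrid | list[SurfaceGrid],
    bin_width: float = 0.1,
    frame_range=None,
    max_distance: float | None = None,
) -> OrientationProfile:
    """Mean water-dipole cos(theta) binned by height above the surface.

    ``surface`` is a fixed z-plane (float), one grid, or one grid per
    frame of the range; each water's distance is z_O minus the surface
    height at its xy cell (negative below the surface — those are binned
    too and counted in ``n_below_surface``).  Waters over unoccupied
    cells are dropped (``n_unassigned``).
    """
    if bin_width <= 0:
        raise StructureError("bin_width must be > 0")
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    groups = _water_groups(topology, waters)
    dist_all: list[np.ndarray] = []
    cos_all: list[np.ndarray] = []
    n_unassigned = 0
    for k, f in enumerate(frames):
        box = traj.boxes[f]
        refpos, mu = _frame_dipoles(traj.coords[f], groups, topology, box)
        if isinstance(surface, (int, float)):
            h = np.full(len(refpos), float(surface))
        else:
            grid = surface[k] if isinstance(surface, list) else surface
            h = grid.height_at(refpos[:, 0], refpos[:, 1])
        d = refpos[:, 2] - h
        ok = np.isfinite(d)
        n_unassigned += int((~ok).sum())
        dist_all.append(d[ok])
        cos_all.append(mu[ok, 2])
    dist = np.concatenate(dist_all)
    cos = np.concatenate(cos_all)
    if max_distance is not None:
        keep = dist <= max_distance
        dist, cos = dist[keep], cos[keep]
    if len(dist) == 0:
        raise StructureError("no waters assignable to the surface reference")
    lo = np.floor(dist.min() / bin_width) * bin_width
    hi = np.ceil(dist.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(dist, bins=edges)
    sums, _ = np.histogram(dist, bins=edges, weights=cos)
    with np.errstate(invalid="ignore"):
        mean_cos = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return OrientationProfile(
        bin_edges=edges,
        mean_cos=mean_cos,
        counts=counts,
        n_below_surface=int((dist < 0).sum()),
        n_unassigned=n_unassigned,
        params={
            "bin_width_nm": bin_width,
            "selection": waters.expression,
            "n_frames": len(frames),
            "surface": "plane" if isinstance(surface, (int, float)) else "grid",
        },
    )


# ---------------------------------------------------------------------------
# radial distribution function


@dataclass
class RdfResult:
    bin_edges: np.ndarray
    g: np.ndarray
    n_cum: np.ndarray  # coordination number at the OUTER edge of each bin
    rho_target: float
    params: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r_nm": self.centers, "g": self.g, "n_cumulative": self.n_cum}
        )

    def coordination_number(self, radius: float) -> float:
        """n(r) at ``radius`` (step-interpolated on bin edges)."""
        return float(np.interp(radius, self.bin_edges[1:], self.n_cum))

    def first_minimum(self) -> float | None:
        """r of the first local minimum of g after its first maximum."""
        g = self.g
        c = self.centers
        imax = None
        for i in range(1, len(g) - 1):
            if imax is None and g[i] >= g[i - 1] and g[i] > g[i + 1] and g[i] > 1.0:
                imax = i
            elif imax is not None and g[i] <= g[i - 1] and g[i] < g[i + 1]:
                return float(c[i])
        return None


def rdf(
    traj: Trajectory,
    topology: Topology,
    reference: AtomSelection,
    target: AtomSelection,
    r_max: float = 1.0,
    dr: float = 0.002,
    frame_range=None,
    exclude_same_molecule: bool = True,
) -> RdfResult:
    """Pair distribution g(r) and running coordination number n(r).

    Periodic minimum-image distances; the reference density is the mean
    target count over the whole box volume (the convention under which an
    ideal gas gives g = 1).  Self pairs, and all pairs within one
    molecule unless ``exclude_same_molecule`` is off, are excluded from
    the counts but not from the density.
    """
    if reference.empty or target.empty:
        raise StructureError("rdf requires non-empty reference and target selections")
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    if r_max > traj.boxes[frames].min() / 2:
        raise StructureError(
            f"r_max = {r_max} exceeds half the smallest box length "
            f"({traj.boxes[frames].min() / 2:.4g})"
        )
    if dr <= 0 or r_max <= 0:
        raise StructureError("dr and r_max must be > 0")
    n_bins = int(round(r_max / dr))
    edges = np.arange(n_bins + 1) * dr

    ref_ids = reference.atom_ids
    tgt_ids = target.atom_ids
    # self pairs (shared atoms at distance 0) are always excluded
    n_self = len(np.intersect1d(ref_ids, tgt_ids))
    # intra-molecular exclusions: pairs sharing a molecule id
    excl_pairs: list[tuple[np.ndarray, np.ndarray]] = []
    if exclude_same_molecule:
        ref_mol = topology.molecule_ids[ref_ids]
        tgt_mol = topology.molecule_ids[tgt_ids]
        shared = np.intersect1d(ref_mol, tgt_mol)
        for m in shared:
            excl_pairs.append((ref_ids[ref_mol == m], tgt_ids[tgt_mol == m]))

    counts = np.zeros(n_bins)
    vol = 0.0
    for f in frames:
        box = traj.boxes[f]
        tree_r = cKDTree(traj.coords[f, ref_ids], boxsize=box)
        tree_t = cKDTree(traj.coords[f, tgt_ids], boxsize=box)
        cum = tree_r.count_neighbors(tree_t, edges[1:]).astype(float)
        frame_counts = np.diff(np.concatenate([[0.0], cum]))
        frame_counts[0] -= n_self
        for ra, ta in excl_pairs:
            d = np.linalg.norm(
                minimum_image(
                    traj.coords[f, ra][:, None, :] - traj.coords[f, ta][None, :, :], box
                ),
                axis=2,
            ).ravel()
            d = d[d > 1e-12]  # drop identical-atom self pairs
            frame_counts -= np.histogram(d, bins=edges)[0]
        counts += frame_counts
        vol += float(np.prod(box))
    vol /= len(frames)
    rho = len(tgt_ids) / vol
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = len(ref_ids) * len(frames)
    g = counts / norm / (shell_vol * rho)
    n_cum = np.cumsum(counts) / norm
    return RdfResult(
        bin_edges=edges,
        g=g,
        n_cum=n_cum,
        rho_target=rho,
        params={
            "r_max_nm": r_max,
            "dr_nm": dr,
            "reference": reference.expression,
            "target": target.expression,
            "n_frames": len(frames),
            "exclude_same_molecule": exclude_same_molecule,
        },
    )


# ---------------------------------------------------------------------------
# spatial distribution function


@dataclass
class SdfGrid:
    """Relative solvent density on a cube centred on the solute frame."""

    values: np.ndarray  # (n, n, n)
    spacing: float
    r_max: float
    anchors: tuple[int, int, int]
    params: dict = field(default_factory=dict)

    @property
    def origin(self) -> tuple[float, float, float]:
        return (-self.r_max, -self.r_max, -self.r_max)


def _anchor_frame(coords: np.ndarray, anchors: tuple[int, int, int], box: np.ndarray):
    """Orthonormal molecular frame from three anchor atoms.

    Anchor 1 is the origin, anchor 2 fixes +x, anchor 3 the xy-plane.
    Collinear anchors are a hard error.
    """
    a1, a2, a3 = anchors
    v1 = minimum_image(coords[a2] - coords[a1], box)
    v2 = minimum_image(coords[a3] - coords[a1], box)
    e1 = v1 / np.linalg.norm(v1)
    n = np.cross(e1, v2)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise StructureError("collinear anchor atoms cannot define a molecular frame")
    e3 = n / nn
    e2 = np.cross(e3, e1)
    return coords[a1], np.stack([e1, e2, e3])  # rows are the frame axes


def sdf(
    traj: Trajectory,
    topology: Topology,
    anchors: tuple[int, int, int],
    waters: AtomSelection,
    spacing: float = 0.05,
    r_max: float = 0.8,
    frame_range=None,
) -> SdfGrid:
    """3D water-oxygen density in the anchor-defined molecular frame,
    normalised by the mean water density over the box (bulk = 1)."""
    if waters.empty:
        raise StructureError("sdf requires a non-empty water selection")
    if spacing <= 0 or r_max <= 0:
        raise StructureError("spacing and r_max must be > 0")
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    n_cells = int(np.ceil(2 * r_max / spacing))
    edges = -r_max + np.arange(n_cells + 1) * spacing
    hist = np.zeros((n_cells, n_cells, n_cells))
    vol = 0.0
    for f in frames:
        box = traj.boxes[f]
        origin, axes = _anchor_frame(traj.coords[f], tuple(anchors), box)
        rel = minimum_image(traj.coords[f, waters.atom_ids] - origin, box)
        local = rel @ axes.T
        hist += np.histogramdd(local, bins=(edges, edges, edges))[0]
        vol += float(np.prod(box))
    vol /= len(frames)
    rho_bulk = len(waters.atom_ids) / vol
    voxel = spacing**3
    values = hist / (len(frames) * voxel * rho_bulk)
    return SdfGrid(
        values=values,
        spacing=spacing,
        r_max=r_max,
        anchors=tuple(int(a) for a in anchors),
        params={
            "spacing_nm": spacing,
            "r_max_nm": r_max,
            "anchors": tuple(int(a) for a in anchors),
            "n_frames": len(frames),
            "selection": waters.expression,
        },
    )
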