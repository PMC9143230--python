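"""Solvent-accessible surface area with charge-based hydrophilicity split.

SASA is computed by Shrake-Rupley sphere sampling: each atom's solvent-
expanded sphere (vdW radius + probe) carries a deterministic Fibonacci
point set; a point is accessible if it lies outside every neighbour's
expanded sphere (minimum-image neighbours, so the membrane's periodic
images occlude correctly).  The accessible fraction times the sphere area
gives the per-atom area.

The hydrophilic/hydrophobic partition is by partial charge: an atom whose
charge satisfies -cutoff <= q <= +cutoff (closed interval, default cutoff
0.2 e) is hydrophobic; all other atoms are hydrophilic.  The split is
exact: hydrophilic + hydrophobic = total by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Topology, Trajectory, minimum_image, parse_frame_range
from .select import AtomSelection

#: Bondi van der Waals radii (nm), resolved by element inferred from the
#: first alphabetic character of the atom name.  Override per call.
BONDI_RADII_NM: dict[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
    "F": 0.147,
    "I": 0.198,
    "B": 0.192,  # Br by first letter falls here too; acceptable for coarse use
    "K": 0.275,
    "M": 0.173,  # Mg
}


class SasaError(ValueError):
    pass


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    i = np.arange(n_points) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n_points
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def vdw_radii(names: np.ndarray, table: dict[str, float] | None = None) -> np.ndarray:
    """Radii by atom-name first letter; unresolvable names are a hard error."""
    table = {**BONDI_RADII_NM, **(table or {})}
    out = np.empty(len(names))
    for i, name in enumerate(names):
        letters = [c for c in str(name) if c.isalpha()]
        if not letters or letters[0].upper() not in table:
            raise SasaError(f"cannot resolve vdW radius for atom name {name!r} (atom {i})")
        out[i] = table[letters[0].upper()]
    return out


@dataclass
class SasaResult:
    per_atom: np.ndarray  # nm^2, aligned with atom_ids
    atom_ids: np.ndarray
    hydrophilic: float
    hydrophobic: float
    probe: float
    n_points: int
    cutoff: float = 0.2
    params: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return self.hydrophilic + self.hydrophobic

    @property
    def hydrophilic_fraction(self) -> float:
        return self.hydrophilic / self.total if self.total > 0 else 0.0

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"atom_id": self.atom_ids, "area_nm2": self.per_atom})


def sasa(
    traj: Trajectory,
    topology: Topology,
    selection: AtomSelection,
    frame: int = 0,
    probe: float = 0.14,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom accessible areas (nm^2) for one frame.

    Only selection atoms act as occluders: membrane SASA is the area of
    the membrane alone, with solvent excluded, matching the dry/hydrated
    comparison of a membrane's own surface.
    """
    if selection.empty:
        raise SasaError("SASA requires a non-empty selection")
    if probe < 0 or n_points < 1:
        raise SasaError("probe must be >= 0 and n_points >= 1")
    idx = selection.atom_ids
    pos = traj.coords[frame, idx]
    box = traj.boxes[frame]
    r_exp = vdw_radii(topology.names[idx], radii) + probe
    sphere = fibonacci_sphere(n_points)

    rmax = r_exp.max()
    tree = cKDTree(np.mod(pos, box), boxsize=box)
    areas = np.empty(len(idx))
    for i in range(len(idx)):
        neighbors = tree.query_ball_point(np.mod(pos[i], box), r=r_exp[i] + rmax)
        neighbors = [j for j in neighbors if j != i]
        pts = pos[i] + r_exp[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        # boundary tie-break: a test point exactly on a neighbour's expanded
        # sphere belongs to the lower-index atom, so coincident identical
        # atoms expose exactly one sphere's worth of area between them
        eps = 1e-9
        for j in neighbors:
            d = minimum_image(pts - pos[j], box)
            d2 = np.einsum("ij,ij->i", d, d)
            r2 = r_exp[j] ** 2
            inside = d2 < r2 - eps
            if j < i:
                inside |= d2 < r2 + eps
            accessible &= ~inside
        areas[i] = 4.0 * np.pi * r_exp[i] ** 2 * accessible.sum() / n_points
    return areas


def partition_sasa(
    areas: np.ndarray,
    charges: np.ndarray,
    atom_ids: np.ndarray | None = None,
    cutoff: float = 0.2,
    probe: float = 0.14,
    n_points: int = 960,
) -> SasaResult:
    """Split per-atom areas into hydrophilic/hydrophobic totals by charge."""
    areas = np.asarray(areas, dtype=float)
    charges = np.asarray(charges, dtype=float)
    if areas.shape != charges.shape:
        raise SasaError(
            f"areas ({areas.shape}) and charges ({charges.shape}) must be indexed identically"
        )
    hydrophobic_mask = (charges >= -cutoff) & (charges <= cutoff)
    hydrophobic = float(areas[hydrophobic_mask].sum())
    hydrophilic = float(areas[~hydrophobic_mask].sum())
    if atom_ids is None:
        atom_ids = np.arange(len(areas))
    return SasaResult(
        per_atom=areas,
        atom_ids=np.asarray(atom_ids),
        hydrophilic=hydrophilic,
        hydrophobic=hydrophobic,
        probe=probe,
        n_points=n_points,
        cutoff=cutoff,
        params={"charge_cutoff_e": cutoff, "probe_nm": probe, "n_points": n_points},
    )


def sasa_series(
    traj: Trajectory,
    topology: Topology,
    selection: AtomSelection,
    frame_range=None,
    probe: float = 0.14,
    n_points: int = 960,
    cutoff: float = 0.2,
    radii: dict[str, float] | None = None,
) -> dict:
    """Frame-averaged SASA partition: means with SEM over frames."""
    frames = traj.frame_slice(parse_frame_range(frame_range, traj.n_frames))
    charges = topology.charges[selection.atom_ids]
    phil = np.empty(len(frames))
    phob = np.empty(len(frames))
    for k, f in enumerate(frames):
        areas = sasa(traj, topology, selection, frame=int(f), probe=probe,
                     n_points=n_points, radii=radii)
        res = partition_sasa(areas, charges, selection.atom_ids, cutoff, probe, n_points)
        phil[k] = res.hydrophilic
        phob[k] = res.hydrophobic
    total = phil + phob
    nf = len(frames)

    def _sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(nf)) if nf > 1 else 0.0

    return {
        "n_frames": nf,
        "hydrophilic_mean": float(phil.mean()),
        "hydrophilic_sem": _sem(phil),
        "hydrophobic_mean": float(phob.mean()),
        "hydrophobic_sem": _sem(phob),
        "total_mean": float(total.mean()),
        "total_sem": _sem(total),
        "hydrophilic_fraction": float((phil / total).mean()),
        "probe_nm": probe,
        "n_points": n_points,
        "charge_cutoff_e": cutoff,
    }
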