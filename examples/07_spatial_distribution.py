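"""Spatial distribution function: 3D water density in a solute-fixed
frame, exported as OpenDX for viewing in VMD/PyMOL."""

import numpy as np

import hydralyze as hz
from hydralyze.core import Topology, Trajectory

# a rigid 3-atom "solute" that tumbles, with two waters co-rotating at
# fixed offsets: the SDF must localise them in sharp voxels regardless of
# the lab-frame motion
anchors = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0], [2.0, 2.4, 2.0]])
offsets = np.array([[0.33, 0.05, 0.04], [0.05, 0.04, 0.44]])
pts = np.vstack([anchors, anchors[0] + offsets])
rng = np.random.default_rng(6)
frames = []
for _ in range(20):
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    frames.append((pts - anchors[0]) @ rot.T + anchors[0])

top = Topology(
    names=np.array(["S1", "O1", "O2", "OW", "OW"], dtype=object),
    molecule_ids=np.array([0, 0, 0, 1, 2]),
    molecule_names=np.array(["POL", "POL", "POL", "SOL", "SOL"], dtype=object),
    masses=np.array([32.06, 16.0, 16.0, 18.0, 18.0]),
    charges=np.array([1.1, -0.6, -0.6, 0.0, 0.0]),
)
traj = Trajectory(times=np.arange(20) * 2.0,
                  boxes=np.tile([4.0, 4.0, 4.0], (20, 1)),
                  coords=np.stack(frames))

grid = hz.sdf(traj, top, anchors=(0, 1, 2), waters=hz.select(top, "name OW"),
              spacing=0.1, r_max=0.6)
occ = np.argwhere(grid.values > 0)
print(f"occupied voxels: {len(occ)} of {grid.values.size}")
for ijk in occ:
    center = -0.6 + (ijk + 0.5) * 0.1
    print(f"  voxel {tuple(int(v) for v in ijk)} at local {np.round(center, 2)} nm, "
          f"relative density {grid.values[tuple(ijk)]:.0f}")

hz.write_dx("sdf_example.dx", grid.values, grid.origin, (0.1, 0.1, 0.1))
print("\nwrote sdf_example.dx (anchor 1 at origin, anchor 2 on +x, anchor 3 in xy)")
# Two sharp voxels at the imposed offsets show the frame transform removes
# the solute's tumbling exactly; with real data the bright voxels map where
# hydration water concentrates around a polar group (e.g. sulfonate oxygens).
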