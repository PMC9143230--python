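import numpy as np
import pytest

from hydralyze.core import Topology, Trajectory

WATER_GRO = """SPC water, t= 0.0
    3
    1SOL     OW    1   0.500   0.500   0.500
    1SOL    HW1    2   0.580   0.560   0.500
    1SOL    HW2    3   0.420   0.560   0.500
   2.00000   2.00000   2.00000
"""

WATER_CHARGES = "atom_id\tmass\tcharge\n1\t15.9994\t-0.82\n2\t1.008\t0.41\n3\t1.008\t0.41\n"


@pytest.fixture
def water_files(tmp_path):
    """Single SPC water: GRO coordinate file + charge sidecar TSV."""
    gro = tmp_path / "water.gro"
    gro.write_text(WATER_GRO)
    tsv = tmp_path / "water_charges.tsv"
    tsv.write_text(WATER_CHARGES)
    return gro, tsv


def make_topology(names, molecule_ids=None, molnames=None, masses=None, charges=None):
    n = len(names)
    return Topology(
        names=np.array(names, dtype=object),
        molecule_ids=np.array(
            molecule_ids if molecule_ids is not None else range(n), dtype=np.int64
        ),
        molecule_names=np.array(
            molnames if molnames is not None else ["X"] * n, dtype=object
        ),
        masses=np.array(masses if masses is not None else [12.0] * n),
        charges=np.array(charges if charges is not None else [0.0] * n),
    )


def make_trajectory(coords, box=(5.0, 5.0, 5.0), dt=2.0):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[0]
    return Trajectory(
        times=np.arange(n) * dt,
        boxes=np.tile(np.asarray(box, dtype=float), (n, 1)),
        coords=coords,
    )
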