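"""Dipole orientation, RDF/coordination, SDF."""

import numpy as np
import pytest

import hydralyze as hz
from hydralyze.core import minimum_image
from hydralyze.structure import StructureError, rdf, sdf, water_dipole
from hydralyze.synth import (
    SolventSpec,
    make_coordination_lattice,
    make_ideal_gas,
    make_oriented_waters,
    merge_systems,
    water_topology,
)

from conftest import make_topology, make_trajectory

SPC_Q = np.array([-0.82, 0.41, 0.41])


def _spc_coords(bisector):
    """SPC water with H-H bisector along the given unit vector."""
    b = np.asarray(bisector, dtype=float)
    b = b / np.linalg.norm(b)
    perp = np.array([0.0, 0.0, 1.0]) if abs(b[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = perp - perp.dot(b) * b
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(109.47 / 2)
    o = np.array([1.0, 1.0, 1.0])
    h1 = o + 0.1 * (np.cos(half) * b + np.sin(half) * perp)
    h2 = o + 0.1 * (np.cos(half) * b - np.sin(half) * perp)
    return np.stack([o, h1, h2])


class TestWaterDipole:
    def test_bisector_up_gives_plus_z(self):
        mu = water_dipole(_spc_coords([0, 0, 1]), SPC_Q, np.array([5.0, 5.0, 5.0]))
        assert np.allclose(mu, [0, 0, 1], atol=1e-12)

    def test_reversed_water_gives_minus_z(self):
        mu = water_dipole(_spc_coords([0, 0, -1]), SPC_Q, np.array([5.0, 5.0, 5.0]))
        assert np.allclose(mu, [0, 0, -1], atol=1e-12)

    def test_translation_and_wrap_invariance(self):
        box = np.array([5.0, 5.0, 5.0])
        coords = _spc_coords([0.3, -0.5, 0.8])
        mu0 = water_dipole(coords, SPC_Q, box)
        shifted = np.mod(coords + np.array([4.95, 0.0, 4.99]), box)  # straddles boundary
        mu1 = water_dipole(shifted, SPC_Q, box)
        assert np.allclose(mu0, mu1, atol=1e-9)

    def test_degenerate_charges_rejected(self):
        with pytest.raises(StructureError):
            water_dipole(_spc_coords([0, 0, 1]), np.zeros(3), np.array([5.0, 5.0, 5.0]))


class TestOrientationProfile:
    def test_grid_surface_reference_distances(self):
        # one water 0.75 nm above a flat surface at z = 2.0
        slab_top = make_topology(["CT", "CT"], molecule_ids=[0, 0], molnames=["MEM", "MEM"])
        slab_pos = np.array([[0.5, 0.5, 2.0], [1.5, 1.5, 2.0]])
        wt = water_topology(1)
        wpos = _spc_coords([0, 0, 1]) + np.array([0.0, 0.0, 1.75])  # oxygen at z = 2.75
        top, traj = merge_systems(
            (slab_top, make_trajectory([slab_pos], box=(2, 2, 6))),
            (wt, make_trajectory([wpos], box=(2, 2, 6))),
        )
        grid = hz.extract_surface(traj, hz.select(top, "molname MEM"), cell_size=1.0)
        prof = hz.orientation_profile(
            traj, top, hz.select(top, "molname SOL"), grid, bin_width=0.5
        )
        i = np.nonzero(prof.counts)[0]
        assert len(i) == 1
        assert prof.bin_edges[i[0]] == pytest.approx(0.5)  # distance 0.75 -> bin [0.5, 1)
        assert prof.mean_cos[i[0]] == pytest.approx(1.0)

    def test_below_surface_counted_separately(self):
        wt = water_topology(1)
        wpos = _spc_coords([0, 0, 1])  # oxygen z = 1.0
        traj = make_trajectory([wpos], box=(3, 3, 6))
        prof = hz.orientation_profile(traj, wt, hz.select(wt, "molname SOL"), 2.0,
                                      bin_width=0.5)
        assert prof.n_below_surface == 1


class TestRdf:
    def test_ideal_gas_flat_and_analytic_coordination(self):
        top, traj = make_ideal_gas(15.0, (4, 4, 4), n_frames=30, seed=21)
        sel = hz.select(top, "molname GAS")
        res = rdf(traj, top, sel, sel, r_max=1.2, dr=0.05)
        rho = traj.metadata["rho"]
        assert np.abs(res.g[2:] - 1.0).max() < 0.05
        for r in (0.5, 1.0):
            assert res.coordination_number(r) == pytest.approx(
                4 / 3 * np.pi * rho * r**3, rel=0.03
            )

    def test_lattice_plateau_is_exactly_six(self):
        top, traj = make_coordination_lattice((4, 4, 4), radius=0.3, n_neighbors=6)
        ref = hz.select(top, "name REF")
        tgt = hz.select(top, "name TGT")
        res = rdf(traj, top, ref, tgt, r_max=1.0, dr=0.02)
        # all six neighbours sit at 0.3 nm, a bin boundary: counts may split
        # between the two adjacent bins but nowhere else
        peak_bin = int(0.3 / 0.02)
        assert set(np.nonzero(res.g)[0].tolist()) <= {peak_bin - 1, peak_bin}
        assert res.coordination_number(0.5) == pytest.approx(6.0, abs=0.0)
        assert np.all(np.diff(res.n_cum) >= 0)

    def test_brute_force_pair_count_equivalence(self):
        rng = np.random.default_rng(3)
        n = 50
        box = np.array([3.0, 3.0, 3.0])
        coords = rng.uniform(0, 3, size=(2, n, 3))
        top = make_topology([f"A{i}" for i in range(n)])
        traj = make_trajectory(coords, box=tuple(box))
        sel = hz.select(top, "name A*")
        r_max, dr = 1.4, 0.1
        res = rdf(traj, top, sel, sel, r_max=r_max, dr=dr)
        # O(N^2) oracle, minimum image, self pairs dropped
        n_bins = int(round(r_max / dr))
        counts = np.zeros(n_bins)
        for f in range(2):
            d = minimum_image(coords[f][:, None, :] - coords[f][None, :, :], box)
            r = np.linalg.norm(d, axis=2)[~np.eye(n, dtype=bool)]
            counts += np.histogram(r, bins=np.arange(n_bins + 1) * dr)[0]
        np.testing.assert_allclose(res.n_cum * n * 2, np.cumsum(counts), atol=1e-9)

    def test_doubling_density_quadruples_pair_counts(self):
        box = (4, 4, 4)
        t1, tr1 = make_ideal_gas(6.0, box, n_frames=10, seed=5)
        t2, tr2 = make_ideal_gas(12.0, box, n_frames=10, seed=5)
        r = 0.8
        res1 = rdf(tr1, t1, hz.select(t1, "name IG"), hz.select(t1, "name IG"), r_max=1.0, dr=0.05)
        res2 = rdf(tr2, t2, hz.select(t2, "name IG"), hz.select(t2, "name IG"), r_max=1.0, dr=0.05)
        pairs1 = res1.coordination_number(r) * tr1.metadata["n_particles"]
        pairs2 = res2.coordination_number(r) * tr2.metadata["n_particles"]
        assert pairs2 / pairs1 == pytest.approx(4.0, rel=0.1)

    def test_intramolecular_pairs_excluded(self):
        spec = SolventSpec(n_waters=40, true_D=0.0, n_frames=1)
        top, traj = make_oriented_waters(spec, (4, 4, 4), seed=6)
        ow = hz.select(top, "name OW")
        hw = hz.select(top, "name HW*")
        res = rdf(traj, top, ow, hw, r_max=0.5, dr=0.02)
        # intramolecular O-H at exactly 0.1 nm must not appear
        assert res.g[int(0.1 / 0.02)] < 5.0
        res_incl = rdf(traj, top, ow, hw, r_max=0.5, dr=0.02, exclude_same_molecule=False)
        assert res_incl.g[int(0.1 / 0.02)] > 100.0

    def test_r_max_beyond_half_box_rejected(self):
        top, traj = make_ideal_gas(5.0, (3, 3, 3), n_frames=1, seed=0)
        sel = hz.select(top, "name IG")
        with pytest.raises(StructureError, match="half"):
            rdf(traj, top, sel, sel, r_max=2.0, dr=0.05)


class TestSdf:
    def _frame_system(self):
        # solute: 3 anchors; waters: 2 fixed offsets in the anchor frame
        anchors = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0], [2.0, 2.4, 2.0]])
        # every component off a voxel boundary, so binning is float-robust
        offsets = np.array([[0.33, 0.05, 0.04], [0.05, 0.04, 0.44]])
        return anchors, offsets

    def test_static_lattice_offsets_land_in_expected_voxels(self):
        anchors, offsets = self._frame_system()
        pos = np.vstack([anchors, anchors[0] + offsets])
        top = make_topology(["A1", "A2", "A3", "OW", "OW"],
                            molecule_ids=[0, 0, 0, 1, 2],
                            molnames=["POL"] * 3 + ["SOL"] * 2)
        traj = make_trajectory([pos], box=(4, 4, 4))
        grid = sdf(traj, top, (0, 1, 2), hz.select(top, "name OW"),
                   spacing=0.1, r_max=0.6)
        occ = np.argwhere(grid.values > 0)
        # local frame == lab frame here: offsets (0.3,0,0) and (0,0,0.4)
        expected = {(9, 6, 6), (6, 6, 10)}  # floor((offset + 0.6) / 0.1) per axis
        assert {tuple(i) for i in occ} == expected

    def test_corotating_system_matches_static(self):
        anchors, offsets = self._frame_system()
        frames = []
        rng = np.random.default_rng(8)
        for _ in range(6):
            # random rigid rotation about the box centre
            q = rng.normal(size=(3, 3))
            u, _, vt = np.linalg.svd(q)
            rot = u @ vt
            if np.linalg.det(rot) < 0:
                rot[:, 0] *= -1
            center = np.array([2.0, 2.0, 2.0])
            pts = np.vstack([anchors, anchors[0] + offsets])
            frames.append((pts - center) @ rot.T + center)
        top = make_topology(["A1", "A2", "A3", "OW", "OW"],
                            molecule_ids=[0, 0, 0, 1, 2],
                            molnames=["POL"] * 3 + ["SOL"] * 2)
        traj_rot = make_trajectory(frames, box=(4, 4, 4))
        traj_stat = make_trajectory([np.vstack([anchors, anchors[0] + offsets])] * 6,
                                    box=(4, 4, 4))
        sel = hz.select(top, "name OW")
        g_rot = sdf(traj_rot, top, (0, 1, 2), sel, spacing=0.1, r_max=0.6)
        g_stat = sdf(traj_stat, top, (0, 1, 2), sel, spacing=0.1, r_max=0.6)
        np.testing.assert_allclose(g_rot.values, g_stat.values, atol=1e-9)

    def test_ideal_gas_background_is_unity(self):
        gas_top, gas_traj = make_ideal_gas(30.0, (4, 4, 4), n_frames=40, seed=9)
        solute = make_topology(["A1", "A2", "A3"], molecule_ids=[0, 0, 0], molnames=["POL"] * 3)
        spos = np.array([[2.0, 2.0, 2.0], [2.5, 2.0, 2.0], [2.0, 2.4, 2.0]])
        straj = make_trajectory([spos] * 40, box=(4, 4, 4))
        top, traj = merge_systems((solute, straj), (gas_top, gas_traj))
        grid = sdf(traj, top, (0, 1, 2), hz.select(top, "name IG"),
                   spacing=0.2, r_max=0.6)
        assert grid.values.mean() == pytest.approx(1.0, rel=0.05)

    def test_collinear_anchors_rejected(self):
        top = make_topology(["A1", "A2", "A3", "OW"],
                            molecule_ids=[0, 0, 0, 1],
                            molnames=["POL"] * 3 + ["SOL"])
        pos = np.array([[1, 1, 1], [1.5, 1, 1], [2.0, 1, 1], [2, 2, 2]], dtype=float)
        traj = make_trajectory([pos], box=(4, 4, 4))
        with pytest.raises(StructureError, match="collinear"):
            sdf(traj, top, (0, 1, 2), hz.select(top, "name OW"), spacing=0.1, r_max=0.5)
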