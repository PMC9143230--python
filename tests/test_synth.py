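"""Generators: reproducibility, ground-truth bookkeeping, imposed laws."""

import numpy as np
import pytest

import hydralyze as hz
from hydralyze.synth import (
    Corrugation,
    Orientation,
    ShellKinetics,
    SlabSpec,
    SolventSpec,
    SpecError,
    make_brownian_solvent,
    make_coordination_lattice,
    make_exchange_shell,
    make_ideal_gas,
    make_oriented_waters,
    make_slab,
    merge_systems,
)


class TestSlab:
    @pytest.mark.parametrize(
        "corr, expected",
        [
            (Corrugation("flat"), 0.0),
            (Corrugation("two_level", amplitude=0.5), 0.5),
            (Corrugation("sinusoid", amplitude=0.8, wavelength=2.0), 0.8 / np.sqrt(2)),
        ],
    )
    def test_analytic_roughness_recorded(self, corr, expected):
        spec = SlabSpec(box=(4.0, 4.0, 8.0), slab_z_range=(1.0, 3.0), corrugation=corr)
        _, traj = make_slab(spec, seed=0)
        assert traj.metadata["analytic_roughness"] == pytest.approx(expected)
        # lattice-discretised top layer agrees with the analytic value
        assert traj.metadata["constructed_roughness"] == pytest.approx(expected, abs=1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(SpecError):
            make_slab(SlabSpec(slab_z_range=(3.0, 1.0)))
        with pytest.raises(SpecError):
            make_slab(SlabSpec(atom_spacing=-0.1))
        with pytest.raises(SpecError):
            # amplitude >= half slab thickness
            make_slab(SlabSpec(corrugation=Corrugation("two_level", amplitude=1.5)))

    def test_charge_pattern_cycles(self):
        top, _ = make_slab(SlabSpec(charge_pattern=(-0.5, 0.3)), seed=0)
        assert set(np.unique(top.charges)) == {-0.5, 0.3}


class TestBrownian:
    def test_zero_diffusion_means_static(self):
        spec = SolventSpec(n_waters=10, true_D=0.0, n_frames=50)
        _, traj = make_brownian_solvent(spec, (4, 4, 4), seed=3)
        assert np.allclose(traj.coords, traj.coords[0])

    def test_step_variance_matches_2_d_dt(self):
        spec = SolventSpec(n_waters=2000, true_D=2.0, dt=2.0, n_frames=2)
        _, traj = make_brownian_solvent(spec, (50, 50, 50), seed=4)
        steps = np.diff(traj.metadata["unwrapped"], axis=0)
        # 2 D dt with D = 2.0e-3 nm^2/ps
        assert steps.var() == pytest.approx(2 * 2.0e-3 * 2.0, rel=0.05)

    def test_coarser_dt_covers_same_msd_range_in_fewer_frames(self):
        # MSD at the final lag depends on total time D*t, not on dt
        a = SolventSpec(n_waters=400, true_D=2.0, dt=2.0, n_frames=201)
        b = SolventSpec(n_waters=400, true_D=2.0, dt=4.0, n_frames=101)
        _, ta = make_brownian_solvent(a, (50, 50, 50), seed=5)
        _, tb = make_brownian_solvent(b, (50, 50, 50), seed=6)
        msd_a = ((ta.metadata["unwrapped"][-1] - ta.metadata["unwrapped"][0]) ** 2).sum(1).mean()
        msd_b = ((tb.metadata["unwrapped"][-1] - tb.metadata["unwrapped"][0]) ** 2).sum(1).mean()
        assert msd_a == pytest.approx(msd_b, rel=0.2)


class TestOrientedWaters:
    def test_random_mode_mean_cos_near_zero(self):
        spec = SolventSpec(n_waters=5000, true_D=0.0, n_frames=1,
                           orientation=Orientation("random"))
        top, traj = make_oriented_waters(spec, (10, 10, 10), seed=7)
        sel = hz.select(top, "molname SOL")
        prof = hz.orientation_profile(traj, top, sel, 0.0, bin_width=10.0)
        assert abs(prof.mean_cos[0]) <= 3.0 / np.sqrt(5000)

    def test_fixed_cos_is_exact(self):
        spec = SolventSpec(n_waters=50, true_D=0.0, n_frames=2,
                           orientation=Orientation("fixed_cos", cos_value=1.0))
        top, traj = make_oriented_waters(spec, (5, 5, 5), seed=8)
        sel = hz.select(top, "molname SOL")
        prof = hz.orientation_profile(traj, top, sel, 0.0, bin_width=0.5)
        occupied = prof.counts > 0
        assert np.allclose(prof.mean_cos[occupied], 1.0, atol=1e-9)

    def test_decaying_law_recovered_by_fit(self):
        spec = SolventSpec(n_waters=20000, true_D=0.0, n_frames=1,
                           orientation=Orientation("decaying", cos_value=0.6, decay_length=1.0))
        top, traj = make_oriented_waters(spec, (6, 6, 5), seed=9)
        sel = hz.select(top, "molname SOL")
        prof = hz.orientation_profile(traj, top, sel, 0.0, bin_width=0.25)
        ok = (prof.counts > 200) & (prof.mean_cos > 0.05)
        slope = np.polyfit(prof.centers[ok], np.log(prof.mean_cos[ok]), 1)[0]
        assert -1.0 / slope == pytest.approx(1.0, rel=0.10)

    def test_spc_geometry(self):
        spec = SolventSpec(n_waters=3, true_D=0.0, n_frames=1)
        top, traj = make_oriented_waters(spec, (5, 5, 5), seed=10)
        o, h1, h2 = traj.coords[0, 0], traj.coords[0, 1], traj.coords[0, 2]
        assert np.linalg.norm(h1 - o) == pytest.approx(0.1, abs=1e-9)
        cosang = np.dot(h1 - o, h2 - o) / 0.1**2
        assert np.degrees(np.arccos(cosang)) == pytest.approx(109.47, abs=1e-6)


class TestExchangeShell:
    def test_true_occupancy_mean_episode_matches_tau(self):
        spec = SolventSpec(n_waters=300, dt=2.0, n_frames=1500,
                           shell_kinetics=ShellKinetics(tau=25.0))
        _, traj = make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=11)
        occ = traj.metadata["true_occupancy"]
        assert occ.shape == (300, 1500)
        # coordinates respect the band structure
        z = traj.coords[:, :, 2].T  # (waters, frames)
        assert np.all(z[occ] <= 2.5 + 1e-9)
        assert np.all(z[~occ] > 2.5)

    def test_unresolvable_tau_rejected(self):
        spec = SolventSpec(n_waters=5, dt=2.0, n_frames=10,
                           shell_kinetics=ShellKinetics(tau=3.0))
        with pytest.raises(SpecError, match="two frames"):
            make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=0)

    def test_infinite_tau_never_leaves(self):
        spec = SolventSpec(n_waters=5, dt=2.0, n_frames=50,
                           shell_kinetics=ShellKinetics(tau=np.inf))
        _, traj = make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=0)
        assert traj.metadata["true_occupancy"].all()


class TestReferenceFluids:
    def test_ideal_gas_density_and_uniformity(self):
        _, traj = make_ideal_gas(8.0, (4, 4, 4), n_frames=5, seed=12)
        assert traj.metadata["n_particles"] == 512
        # crude uniformity: mean position near box centre
        assert np.allclose(traj.coords.mean(axis=(0, 1)), [2, 2, 2], atol=0.15)

    def test_lattice_neighbors_at_exact_radius(self):
        top, traj = make_coordination_lattice((4, 4, 4), radius=0.3, n_neighbors=6)
        center = traj.coords[0, 0]
        d = np.linalg.norm(traj.coords[0, 1:] - center, axis=1)
        assert np.allclose(d, 0.3, atol=1e-12)


class TestReproducibility:
    @pytest.mark.parametrize("maker", ["slab", "brownian", "oriented", "exchange", "gas"])
    def test_same_seed_bit_identical(self, maker):
        def build(seed):
            if maker == "slab":
                return make_slab(SlabSpec(n_frames=3, jitter_z=0.1), seed=seed)[1]
            if maker == "brownian":
                return make_brownian_solvent(
                    SolventSpec(n_waters=20, n_frames=30), (4, 4, 4), seed=seed
                )[1]
            if maker == "oriented":
                return make_oriented_waters(
                    SolventSpec(n_waters=20, n_frames=5), (4, 4, 4), seed=seed
                )[1]
            if maker == "exchange":
                return make_exchange_shell(
                    SolventSpec(n_waters=20, n_frames=30,
                                shell_kinetics=ShellKinetics(tau=10.0)),
                    (4, 4, 8), surface_z=2.0, seed=seed,
                )[1]
            return make_ideal_gas(5.0, (3, 3, 3), n_frames=4, seed=seed)[1]

        a, b, c = build(42), build(42), build(43)
        assert np.array_equal(a.coords, b.coords)
        assert not np.array_equal(a.coords, c.coords)


class TestMerge:
    def test_merge_offsets_molecules_and_concatenates(self):
        slab = make_slab(SlabSpec(n_frames=2), seed=0)
        sol = make_brownian_solvent(SolventSpec(n_waters=7, n_frames=2), (4, 4, 8), seed=1)
        top, traj = merge_systems(slab, sol)
        assert top.n_atoms == slab[0].n_atoms + 7
        assert traj.n_atoms == top.n_atoms
        assert len(np.unique(top.molecule_ids)) == len(np.unique(slab[0].molecule_ids)) + 7

    def test_merge_rejects_mismatched_frames(self):
        a = make_slab(SlabSpec(n_frames=2), seed=0)
        b = make_brownian_solvent(SolventSpec(n_waters=3, n_frames=3), (4, 4, 8), seed=1)
        with pytest.raises(SpecError):
            merge_systems(a, b)
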