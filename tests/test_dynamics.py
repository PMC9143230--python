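"""Shell occupancy, residence statistics, MSD, Einstein diffusion."""

import numpy as np
import pytest
import scipy.stats

import hydralyze as hz
from hydralyze.core import TrajectoryError, minimum_image
from hydralyze.dynamics import (
    DynamicsError,
    MsdResult,
    OccupancyMatrix,
    _msd_fft,
    diffusion_coefficient,
    msd,
    residence_distribution,
    residence_times,
    shell_occupancy,
    unwrap,
)
from hydralyze.synth import ShellKinetics, SolventSpec, make_brownian_solvent, make_exchange_shell

from conftest import make_topology, make_trajectory


def occ_from_strings(strings, dt=2.0):
    mat = np.array([[c == "1" for c in s] for s in strings])
    return OccupancyMatrix(
        matrix=mat,
        water_atom_ids=np.arange(mat.shape[0]),
        times=np.arange(mat.shape[1]) * dt,
        cutoff=0.5,
    )


class TestOccupancy:
    def test_boundary_distances(self):
        mem = make_topology(["C1"], molnames=["MEM"])
        w = make_topology(["OW", "OW"], molnames=["SOL", "SOL"])
        from hydralyze.synth import merge_systems

        mem_traj = make_trajectory([[[1.0, 1.0, 1.0]]], box=(6, 6, 6))
        w_traj = make_trajectory([[[1.0, 1.0, 1.3], [1.0, 1.0, 1.51]]], box=(6, 6, 6))
        top, traj = merge_systems((mem, mem_traj), (w, w_traj))
        occ = shell_occupancy(traj, hz.select(top, "name OW"),
                              hz.select(top, "molname MEM"), cutoff=0.5)
        assert occ.matrix[:, 0].tolist() == [True, False]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(13)
        n_mem, n_w = 12, 18
        box = np.array([3.0, 3.0, 3.0])
        mem_pos = rng.uniform(0, 3, size=(2, n_mem, 3))
        w_pos = rng.uniform(0, 3, size=(2, n_w, 3))
        from hydralyze.synth import merge_systems

        mem = make_topology([f"C{i}" for i in range(n_mem)],
                            molecule_ids=[0] * n_mem, molnames=["MEM"] * n_mem)
        w = make_topology(["OW"] * n_w, molnames=["SOL"] * n_w)
        top, traj = merge_systems(
            (mem, make_trajectory(mem_pos, box=tuple(box))),
            (w, make_trajectory(w_pos, box=tuple(box))),
        )
        occ = shell_occupancy(traj, hz.select(top, "name OW"),
                              hz.select(top, "molname MEM"), cutoff=0.5)
        for f in range(2):
            d = np.linalg.norm(
                minimum_image(w_pos[f][:, None, :] - mem_pos[f][None, :, :], box), axis=2
            )
            assert np.array_equal(occ.matrix[:, f], d.min(axis=1) <= 0.5)


class TestResidence:
    def test_scripted_string_strict_runs(self):
        res = residence_times(occ_from_strings(["111000111100"]), gap_tolerance=0)
        durations = sorted(e.duration for e in res.events)
        assert durations == [6.0, 8.0]
        assert res.mean_over("all") == pytest.approx(7.0)
        # the first run touches frame 0: censored, so the default mean keeps
        # only the interior 8 ps event
        assert res.mean_residence == pytest.approx(8.0)
        assert res.censored_count == 1

    def test_scripted_string_with_gap_bridging(self):
        res = residence_times(occ_from_strings(["111000111100"]), gap_tolerance=3)
        assert [e.duration for e in res.events] == [20.0]
        assert res.events[0].censored  # starts at frame 0

    def test_scripted_interior_episodes_mean(self):
        # episodes of 10, 20, 30 ps (5, 10, 15 frames at dt = 2), interior
        s = "0" + "1" * 5 + "0" + "1" * 10 + "0" + "1" * 15 + "0"
        res = residence_times(occ_from_strings([s]), gap_tolerance=0)
        assert sorted(e.duration for e in res.events) == [10.0, 20.0, 30.0]
        assert res.mean_residence == pytest.approx(20.0)

    def test_events_partition_occupancy_when_strict(self):
        rng = np.random.default_rng(17)
        mat = rng.random((20, 200)) < 0.4
        occ = OccupancyMatrix(matrix=mat, water_atom_ids=np.arange(20),
                              times=np.arange(200) * 2.0, cutoff=0.5)
        res = residence_times(occ, gap_tolerance=0)
        assert sum(e.n_frames for e in res.events) == mat.sum()

    def test_exponential_generator_recovery(self):
        spec = SolventSpec(n_waters=500, dt=2.0, n_frames=2000,
                           shell_kinetics=ShellKinetics(tau=25.0))
        _, traj = make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=19)
        occ = OccupancyMatrix(matrix=traj.metadata["true_occupancy"],
                              water_atom_ids=np.arange(500),
                              times=traj.times, cutoff=0.5)
        res = residence_times(occ)
        assert res.mean_residence == pytest.approx(25.0, rel=0.05)

    def test_never_leaving_shell_reports_censored_full_length(self):
        spec = SolventSpec(n_waters=4, dt=2.0, n_frames=100,
                           shell_kinetics=ShellKinetics(tau=np.inf))
        _, traj = make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=0)
        occ = OccupancyMatrix(matrix=traj.metadata["true_occupancy"],
                              water_atom_ids=np.arange(4), times=traj.times, cutoff=0.5)
        res = residence_times(occ)
        assert res.censored_only
        assert res.mean_residence == pytest.approx(100 * 2.0)

    def test_distribution_against_generator_law(self):
        """Event durations follow the generator's geometric frame-count law
        (the discrete-time counterpart of exponential shell exchange)."""
        tau, dt = 25.0, 2.0
        spec = SolventSpec(n_waters=400, dt=dt, n_frames=1500,
                           shell_kinetics=ShellKinetics(tau=tau))
        _, traj = make_exchange_shell(spec, (5, 5, 10), surface_z=2.0, seed=23)
        occ = OccupancyMatrix(matrix=traj.metadata["true_occupancy"],
                              water_atom_ids=np.arange(400), times=traj.times, cutoff=0.5)
        res = residence_times(occ)
        k = (res.uncensored_durations / dt).astype(int)
        # discrete KS: compare ECDF and CDF on the lattice points themselves
        # (the continuous KS formula inflates the statistic by P(k=1) here)
        grid = np.arange(1, k.max() + 1)
        ecdf = np.searchsorted(np.sort(k), grid, side="right") / len(k)
        stat = np.abs(ecdf - scipy.stats.geom(dt / tau).cdf(grid)).max()
        assert stat < 1.63 / np.sqrt(len(k))  # alpha = 0.01 critical value

    def test_distribution_edges(self):
        res = residence_times(occ_from_strings(["0011100"]))
        hist = residence_distribution(res, bin_width=2.0)
        assert (hist["density"] > 0).sum() == 1
        empty = residence_times(occ_from_strings(["0000"]))
        with pytest.warns(UserWarning):
            assert residence_distribution(empty).empty


class TestMsd:
    def test_static_particles_zero(self):
        top = make_topology(["OW"] * 3, molnames=["SOL"] * 3)
        coords = np.tile(np.array([[1.0, 1, 1], [2, 2, 2], [3, 3, 3]]), (5, 1, 1))
        traj = make_trajectory(coords)
        res = msd(traj, hz.select(top, "name OW"))
        assert np.allclose(res.msd, 0.0, atol=1e-12)

    def test_ballistic_exact_quadratic(self):
        v = np.array([0.02, -0.01, 0.03])  # nm/ps
        T, dt = 40, 2.0
        coords = (np.arange(T)[:, None, None] * v[None, None, :] * dt) + 5.0
        top = make_topology(["OW"], molnames=["SOL"])
        traj = make_trajectory(np.mod(coords, 12.0), box=(12, 12, 12), dt=dt)
        res = msd(traj, hz.select(top, "name OW"))
        expected = (v @ v) * res.lags**2
        np.testing.assert_allclose(res.msd, expected, rtol=1e-9, atol=1e-12)

    def test_fft_matches_brute_force_with_and_without_weights(self):
        rng = np.random.default_rng(29)
        T, N = 40, 5
        pos = np.cumsum(rng.normal(size=(T, N, 3)), axis=0)
        w = (rng.random((T, N)) < 0.5).astype(float)
        for weights in (None, w):
            num, cnt = _msd_fft(pos, weights)
            for tau in (0, 1, 7, 19):
                acc = 0.0
                c = 0.0
                ww = np.ones((T, N)) if weights is None else weights
                for t in range(T - tau):
                    for i in range(N):
                        acc += ww[t, i] * ((pos[t + tau, i] - pos[t, i]) ** 2).sum()
                        c += ww[t, i]
                assert num[tau] == pytest.approx(acc, rel=1e-9, abs=1e-7)
                assert cnt[tau] == pytest.approx(c)

    def test_unwrap_reverses_pbc_wrapping(self):
        spec = SolventSpec(n_waters=50, true_D=3.0, dt=2.0, n_frames=300)
        top, traj = make_brownian_solvent(spec, (3, 3, 3), seed=31)
        rec = unwrap(traj, hz.select(top, "name OW").atom_ids)
        true = traj.metadata["unwrapped"]
        # recovered paths differ from truth only by the initial wrap offset
        drift = rec - true
        assert np.abs(drift - drift[0]).max() < 1e-9

    def test_unwrap_rejects_half_box_jumps(self):
        top = make_topology(["OW"], molnames=["SOL"])
        coords = np.array([[[0.2, 1.0, 1.0]], [[1.2, 1.0, 1.0]], [[0.2, 1.0, 1.0]]])
        traj = make_trajectory(coords, box=(2, 2, 2))
        with pytest.raises(TrajectoryError, match="frame 1"):
            unwrap(traj, np.array([0]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(37)
        pos = np.cumsum(rng.normal(scale=0.05, size=(60, 4, 3)), axis=0) + 10.0
        top = make_topology(["OW"] * 4, molnames=["SOL"] * 4)
        t1 = make_trajectory(np.mod(pos, 40.0), box=(40, 40, 40))
        t2 = make_trajectory(np.mod(pos + 3.7, 40.0), box=(40, 40, 40))
        sel = hz.select(top, "name OW")
        np.testing.assert_allclose(msd(t1, sel).msd, msd(t2, sel).msd, atol=1e-9)


class TestDiffusion:
    def test_exact_line_recovers_slope_with_zero_uncertainty(self):
        a = 2.0e-3  # nm^2/ps
        lags = np.arange(0, 101) * 2.0
        curve = 6 * a * lags
        blocks = [(np.arange(0, 21) * 2.0, 6 * a * np.arange(0, 21) * 2.0)] * 4
        res = diffusion_coefficient(
            MsdResult(lags=lags, msd=curve, dt=2.0, n_particles=1, block_curves=blocks)
        )
        assert res.D == pytest.approx(a * 1e3, rel=1e-12)  # 1e-5 cm^2/s scale
        assert res.uncertainty == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_bulk_water_magnitude_recovery(self):
        spec = SolventSpec(n_waters=500, true_D=4.13, dt=2.0, n_frames=2000)
        top, traj = make_brownian_solvent(spec, (6, 6, 6), seed=41)
        res = diffusion_coefficient(msd(traj, hz.select(top, "name OW"), max_lag=200.0))
        assert res.D == pytest.approx(4.13, rel=0.05)

    def test_hydration_layer_origin_restriction(self):
        # restricting origins to half the particles reproduces their own MSD
        spec = SolventSpec(n_waters=40, true_D=2.0, dt=2.0, n_frames=400)
        top, traj = make_brownian_solvent(spec, (5, 5, 5), seed=43)
        sel = hz.select(top, "name OW")
        mat = np.zeros((40, 400), dtype=bool)
        mat[:20] = True
        occ = OccupancyMatrix(matrix=mat, water_atom_ids=sel.atom_ids,
                              times=traj.times, cutoff=0.5)
        restricted = msd(traj, sel, occupancy=occ, max_lag=100.0)
        sub_sel = hz.AtomSelection("first half", sel.atom_ids[:20])
        direct = msd(traj, sub_sel, max_lag=100.0)
        np.testing.assert_allclose(restricted.msd, direct.msd, atol=1e-9)

    def test_block_uncertainty_shrinks_with_particle_count(self):
        uncs = []
        for n, seed in ((100, 47), (1600, 47)):
            spec = SolventSpec(n_waters=n, true_D=2.0, dt=2.0, n_frames=600)
            top, traj = make_brownian_solvent(spec, (6, 6, 6), seed=seed)
            res = diffusion_coefficient(msd(traj, hz.select(top, "name OW"), max_lag=120.0))
            uncs.append(res.uncertainty)
        # 16x the particles: expect ~4x smaller; allow a loose factor
        assert uncs[1] < uncs[0] / 2.0

    def test_too_few_fit_points_rejected(self):
        res = MsdResult(lags=np.arange(0, 5) * 2.0, msd=np.arange(5.0),
                        dt=2.0, n_particles=1)
        with pytest.raises(DynamicsError):
            diffusion_coefficient(res, fit_window=(0.9, 1.0))
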