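"""Voxel binning, energy attribution, entropy estimators, and maps."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.special import digamma

from grandgist.constants import KB
from grandgist.gist import (
    EULER_GAMMA,
    GistFrameSet,
    GistGrid,
    _nn_orientation_distances,
    _orientation_ball_fraction,
    bin_waters,
    density_map,
    pair_voxel_sites,
    read_dx,
    voxel_energies,
    voxel_free_energy,
    voxel_orientational_entropy,
    voxel_translational_entropy,
    write_dx,
)
from grandgist.sampler import random_quaternion
from grandgist.synth import GaussianPeak, SyntheticGistSpec, make_gist_frames

KT300 = KB * 300.0


def identity_quats(n):
    q = np.zeros((n, 4))
    q[:, 3] = 1.0
    return q


def frameset(frames_positions, quats=None, usw=None, uww=None, T=300.0,
             rho0=0.0329):
    frames = []
    for i, pos in enumerate(frames_positions):
        pos = np.asarray(pos, float).reshape(-1, 3)
        n = len(pos)
        frames.append((
            pos,
            quats[i] if quats is not None else identity_quats(n),
            usw[i] if usw is not None else np.zeros(n),
            uww[i] if uww is not None else np.zeros(n),
        ))
    return GistFrameSet(frames=frames, T=T, rho0=rho0)


class TestBinning:
    def test_boundary_point_goes_to_higher_voxel(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(4, 4, 4))
        idx = grid.voxel_indices(np.array([[0.5, 0.0, 0.0]]))
        assert idx[0] == np.ravel_multi_index((1, 0, 0), (4, 4, 4))

    def test_single_observation_counted_once(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(4, 4, 4))
        fs = frameset([[[0.7, 0.7, 0.7]]])
        binned = bin_waters(fs, grid)
        assert binned.counts.sum() == 1

    def test_out_of_grid_observations_dropped_and_counted(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(2, 2, 2))
        fs = frameset([[[0.5, 0.5, 0.5], [5.0, 5.0, 5.0]]])
        binned = bin_waters(fs, grid)
        assert binned.counts.sum() == 1
        assert binned.n_dropped == 1

    def test_uniform_field_occupancy_is_poisson(self, tip3p):
        """Voxel occupancy histogram of a uniform rho0 field passes a
        chi-square test against Poisson(rho0 V_k N_frame) at alpha=0.01."""
        from scipy import stats

        spec = SyntheticGistSpec(bulk_scale=1.0, n_frames=200)
        fs = make_gist_frames(spec, [0, 0, 0], [4.0, 4.0, 4.0], tip3p, seed=21)
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(4, 4, 4))
        binned = bin_waters(fs, grid)
        lam = tip3p.rho0 * 1.0 * 200
        counts = binned.counts.astype(int)
        kmax = max(counts.max(), 12)
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * len(counts)
        # pool tail bins so expected counts stay reasonable
        cut = np.searchsorted(np.cumsum(expected[::-1]), 5.0)
        pool = kmax + 1 - cut
        obs = np.append(observed[:pool], observed[pool:].sum())
        exp = np.append(expected[:pool], expected[pool:].sum())
        exp *= obs.sum() / exp.sum()
        stat = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(stat, df=len(obs) - 1)
        assert p > 0.01


class TestVoxelEnergies:
    def test_single_water_single_host_energy_in_its_voxel(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(4, 4, 4))
        fs = frameset([[[0.25, 0.25, 0.25]]], usw=[np.array([-7.5])])
        binned = bin_waters(fs, grid)
        e_sw, e_ww = voxel_energies(binned)
        assert e_sw[0] == pytest.approx(-7.5)
        assert np.count_nonzero(e_sw) == 1
        assert np.all(e_ww == 0)

    def test_roi_sum_identity(self):
        rng = np.random.default_rng(8)
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(6, 6, 6))
        frames, usws = [], []
        for _ in range(7):
            n = rng.integers(1, 6)
            frames.append(rng.random((n, 3)) * 3.0)
            usws.append(rng.normal(-5, 2, n))
        fs = frameset(frames, usw=usws)
        binned = bin_waters(fs, grid)
        e_sw, _ = voxel_energies(binned)
        direct = sum(u.sum() for u in usws) / len(frames)
        assert e_sw.sum() == pytest.approx(direct, abs=1e-10)

    def test_cross_voxel_pair_energy_split_half_half(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(4, 4, 4))
        # one frame, two waters in different voxels, pair energy -4.2:
        # each water's U_ww is the full pair energy, half-weighted at binning
        fs = frameset([[[0.25, 0.25, 0.25], [1.75, 0.25, 0.25]]],
                      uww=[np.array([-4.2, -4.2])])
        binned = bin_waters(fs, grid)
        _, e_ww = voxel_energies(binned)
        nz = e_ww[e_ww != 0]
        assert len(nz) == 2
        assert np.allclose(nz, -2.1)
        assert e_ww.sum() == pytest.approx(-4.2)


class TestTranslationalEntropy:
    def test_empty_voxel_contributes_zero(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(2, 2, 2))
        fs = frameset([np.zeros((0, 3))])
        binned = bin_waters(fs, grid)
        assert np.all(voxel_translational_entropy(binned, 300.0, 0.0329) == 0)

    def test_bulk_density_gives_zero(self):
        # rho_k = rho0 exactly: N_k = rho0 * V_k * N_frame
        rho0 = 0.032
        n_frames = 250
        v_k = 1.0
        n_k = int(rho0 * v_k * n_frames)  # = 8
        rho_exact = n_k / (v_k * n_frames)
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        frames = [[[0.5, 0.5, 0.5]] if i < n_k else np.zeros((0, 3))
                  for i in range(n_frames)]
        fs = frameset(frames)
        binned = bin_waters(fs, grid)
        ts = voxel_translational_entropy(binned, 300.0, rho_exact)
        assert ts[0] == pytest.approx(0.0, abs=1e-12)

    def test_double_density_matches_discretized_integral(self):
        """rho_k = 2 rho0: formula value equals the discretized
        -kB rho0 Int g ln g over the voxel with constant g = 2."""
        rho0 = 0.0329
        n_frames = 500
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        n_k = int(round(2 * rho0 * 1.0 * n_frames))  # 33 observations
        rho_k = n_k / n_frames
        g = rho_k / rho0
        frames = [[[0.5, 0.5, 0.5]] if i < n_k else np.zeros((0, 3))
                  for i in range(n_frames)]
        fs = frameset(frames)
        binned = bin_waters(fs, grid)
        ts = voxel_translational_entropy(binned, 300.0, rho0)
        # independent discretized-integral evaluation with constant g
        integral = -KB * 300.0 * rho0 * g * math.log(g) * 1.0
        assert ts[0] == pytest.approx(integral, rel=1e-10)
        assert ts[0] < 0  # localization is entropically unfavorable


class TestOrientationalEntropy:
    def test_single_observation_flagged_zero(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        fs = frameset([[[0.5, 0.5, 0.5]]])
        binned = bin_waters(fs, grid)
        ts, flags = voxel_orientational_entropy(binned, 300.0)
        assert ts[0] == 0.0
        assert flags["insufficient_observations"] == 1

    def test_uniform_orientations_near_zero(self):
        rng = np.random.default_rng(4)
        n = 600
        quats = np.array([random_quaternion(rng) for _ in range(n)])
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        fs = frameset([np.full((n, 3), 0.5)], quats=[quats])
        binned = bin_waters(fs, grid)
        ts, _ = voxel_orientational_entropy(binned, 300.0)
        # per-observation entropy (value scaled back by N_frame=1 -> N_k)
        per_water = ts[0] / (KT300 * n)
        assert abs(KT300 * per_water * n / n) < 0.5  # kJ/mol per water

    def test_concentrated_orientations_unfavorable_and_ordered(self):
        rng = np.random.default_rng(9)
        base = Rotation.random(rng=rng)
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        values = []
        for sd in (0.5, 0.25, 0.1):
            rv = rng.normal(0, sd, (400, 3))
            quats = (Rotation.from_rotvec(rv) * base).as_quat()
            fs = frameset([np.full((400, 3), 0.5)], quats=[quats])
            binned = bin_waters(fs, grid)
            ts, _ = voxel_orientational_entropy(binned, 300.0)
            values.append(ts[0])
        assert all(v < 0 for v in values)  # -T dS > 0: unfavorable
        assert values[0] > values[1] > values[2]  # more ordered, more negative

    def test_duplicate_orientations_floored_and_counted(self):
        q = identity_quats(5)
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(1, 1, 1))
        fs = frameset([np.full((5, 3), 0.5)], quats=[q])
        binned = bin_waters(fs, grid)
        ts, flags = voxel_orientational_entropy(binned, 300.0)
        assert flags["degenerate_orientations"] == 5
        assert np.isfinite(ts[0])

    def test_nn_estimator_agrees_with_histogram_oracle(self):
        """Concentrated rotation-vector Gaussian at 1e4 samples: NN entropy
        within 10% of a brute-force histogram entropy."""
        rng = np.random.default_rng(5)
        sd = 0.25
        base = Rotation.random(rng=rng)
        rv = rng.normal(0, sd, (10_000, 3))
        quats = (Rotation.from_rotvec(rv) * base).as_quat()
        d = _nn_orientation_distances(quats)
        n = len(quats)
        h_nn = float(np.mean(np.log(_orientation_ball_fraction(d))
                             + digamma(n) + EULER_GAMMA))
        # histogram estimate in rotation-vector coordinates, with the exact
        # Haar fraction per bin
        rel = (Rotation.from_quat(quats) * base.inv()).as_rotvec()
        w = 0.125
        edges = [np.arange(-1.25, 1.25 + w, w)] * 3
        hist, _ = np.histogramdd(rel, bins=edges)
        p = hist.ravel() / n
        centers = np.meshgrid(*[(e[:-1] + e[1:]) / 2 for e in edges],
                              indexing="ij")
        theta = np.maximum(np.sqrt(sum(c**2 for c in centers)).ravel(), 1e-9)
        vfrac = w**3 * (1 - np.cos(theta)) / (4 * math.pi**2 * theta**2)
        nz = p > 0
        h_hist = float(-(p[nz] * np.log(p[nz] / vfrac[nz])).sum())
        assert h_nn == pytest.approx(h_hist, rel=0.10)


class TestFreeEnergyAndMaps:
    def test_all_zero_components_give_zero(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=1.0, dims=(2, 2, 2))
        fs = frameset([np.zeros((0, 3))] * 3)
        res = voxel_free_energy(fs, grid)
        assert np.all(res.dG == 0)
        assert res.roi_total("dG") == 0.0

    def test_roi_total_invariant_under_integer_grid_shift(self, tip3p):
        spec = SyntheticGistSpec(
            bulk_scale=1.0, n_frames=60,
            peaks=(GaussianPeak(center=(2.0, 2.0, 2.0), width=0.2,
                                amplitude=1.0, orient_sd=0.3),),
            esw_scale=8.0)
        fs = make_gist_frames(spec, [0.5, 0.5, 0.5], [3.0, 3.0, 3.0], tip3p,
                              seed=2)
        g1 = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(8, 8, 8))
        g2 = GistGrid(origin=[-1.0, -0.5, -1.5], spacing=0.5, dims=(10, 9, 11))
        r1 = voxel_free_energy(fs, g1)
        r2 = voxel_free_energy(fs, g2)
        for name in ("E_sw", "E_ww", "TS_trans", "TS_orient", "dG"):
            assert r1.roi_total(name) == pytest.approx(r2.roi_total(name),
                                                       abs=1e-6)

    def test_stationary_water_density_peak(self):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(4, 4, 4))
        fs = frameset([[[0.6, 0.6, 0.6]]] * 40, rho0=0.0329)
        res = voxel_free_energy(fs, grid)
        dmap = density_map(res)
        assert dmap.max() == pytest.approx(1.0 / (0.125 * 0.0329), rel=1e-12)
        assert np.count_nonzero(dmap) == 1

    def test_dx_round_trip(self, tmp_path):
        grid = GistGrid(origin=[1.0, -2.0, 0.5], spacing=0.5, dims=(4, 3, 5))
        rng = np.random.default_rng(0)
        field = rng.random(grid.dims)
        path = tmp_path / "field.dx"
        write_dx(field, grid, path)
        back, grid_back = read_dx(path)
        assert np.allclose(back, field, atol=1e-6)
        assert np.allclose(grid_back.origin, grid.origin, atol=1e-6)
        assert grid_back.dims == grid.dims

    def test_bootstrap_se_present_and_positive(self, tip3p):
        spec = SyntheticGistSpec(bulk_scale=1.0, n_frames=50)
        fs = make_gist_frames(spec, [0, 0, 0], [3.0, 3.0, 3.0], tip3p, seed=3)
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(6, 6, 6))
        res = voxel_free_energy(fs, grid, n_bootstrap=15, seed=1)
        assert set(res.roi_se) == {"E_sw", "E_ww", "TS_trans", "TS_orient", "dG"}
        assert res.roi_se["dG"] > 0


class TestSiteComparisonHarness:
    def _result_with_values(self, centers, values):
        grid = GistGrid(origin=[0, 0, 0], spacing=0.5, dims=(8, 8, 8))
        fs = frameset([centers])
        res = voxel_free_energy(fs, grid)
        res.dG = np.zeros(grid.n_voxels)
        res.dG[grid.voxel_indices(np.asarray(centers))] = values
        return res

    def test_identical_runs_perfect_metrics(self):
        centers = np.array([[0.7, 0.7, 0.7], [2.2, 2.2, 0.7], [3.2, 1.2, 2.2]])
        values = np.array([-20.0, -12.0, -5.0])
        res = self._result_with_values(centers, values)
        m = pair_voxel_sites(res, res, centers, centers)
        assert m.pearson_r == pytest.approx(1.0)
        assert m.mad == 0.0 and m.max_dev == 0.0 and m.mrd == 0.0
        assert m.n_paired == 3

    def test_injected_shift_detected(self):
        centers = np.array([[0.7, 0.7, 0.7], [2.2, 2.2, 0.7], [3.2, 1.2, 2.2]])
        res_a = self._result_with_values(centers, np.array([-20.0, -12.0, -5.0]))
        res_b = self._result_with_values(centers, np.array([-17.0, -9.0, -2.0]))
        m = pair_voxel_sites(res_a, res_b, centers, centers)
        assert m.mad == pytest.approx(3.0)
        assert m.max_dev == pytest.approx(3.0)
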