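import math

import numpy as np
import pandas as pd
import pytest

from gelion.analysis import (GelObservables, WindowPolicy, blocked_se,
                             charged_pair_correlation, fit_scaling,
                             gel_observables, gel_rg, internal_volume_fraction,
                             partition_coefficients, partition_ratio,
                             shell_volumes, sphere_box_volume, unwrap_gel)
from gelion.dynamics import Trajectory
from gelion.errors import AnalysisError, FitRefusedError
from gelion.fixtures import PartitionFixtureSpec, make_partition_fixture
from gelion.model import CATION_1, CATION_2, GEL_SEGMENT


def make_traj(frames, species, box_length, bonds=None, charge=None):
    frames = np.asarray(frames, dtype=float)
    species = np.asarray(species, dtype=np.int64)
    return Trajectory(
        positions=frames,
        times=np.arange(len(frames), dtype=float),
        species=species,
        charge=(np.zeros(len(species), dtype=np.int64) if charge is None
                else np.asarray(charge, dtype=np.int64)),
        bonds=(np.empty((0, 2), dtype=np.int64) if bonds is None
               else np.asarray(bonds, dtype=np.int64).reshape(-1, 2)),
        box_length=float(box_length),
    )


class TestUnwrap:
    def test_identity_inside_box(self):
        pos = np.array([[2.0, 2.0, 2.0], [2.9, 2.0, 2.0]])
        out = unwrap_gel(pos, np.array([[0, 1]]), 10.0)
        np.testing.assert_allclose(out, pos)

    def test_bond_across_boundary(self):
        pos = np.array([[9.9, 5.0, 5.0], [0.1, 5.0, 5.0]])
        out = unwrap_gel(pos, np.array([[0, 1]]), 10.0)
        np.testing.assert_allclose(out[1], [10.1, 5.0, 5.0])

    def test_disconnected_raises(self):
        pos = np.zeros((4, 3))
        with pytest.raises(AnalysisError):
            unwrap_gel(pos, np.array([[0, 1], [2, 3]]), 10.0,
                       gel_indices=np.arange(4))

    def test_rg_roundtrip_random_wrapping(self, rng):
        # random chain, then wrap every bead by random lattice vectors
        n = 30
        steps = rng.normal(0, 0.4, (n - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]) + 5.0
        bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
        L = 8.0
        rg_ref = _rg_oracle(pos)
        wrapped = pos + L * rng.integers(-3, 4, (n, 3))
        wrapped -= L * np.floor(wrapped / L)
        out = unwrap_gel(wrapped, bonds, L)
        assert _rg_oracle(out) == pytest.approx(rg_ref, abs=1e-10)


def _rg_oracle(coords):
    com = coords.mean(axis=0)
    return float(np.sqrt(((coords - com) ** 2).sum(axis=1).mean()))


class TestRg:
    def test_single_point_zero(self):
        traj = make_traj([np.full((1, 3), 5.0)], [GEL_SEGMENT], 10.0)
        rg, se = gel_rg(traj)
        assert rg == 0.0

    def test_two_beads_half_distance(self):
        pos = np.array([[4.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        traj = make_traj([pos], [GEL_SEGMENT] * 2, 10.0, bonds=[[0, 1]])
        rg, _ = gel_rg(traj)
        assert rg == pytest.approx(1.0)  # d/2 with d = 2

    def test_cube_corners(self):
        a = 2.0
        corners = np.array([[i, j, k] for i in (0, a) for j in (0, a)
                            for k in (0, a)], dtype=float) + 4.0
        traj = make_traj([corners], [GEL_SEGMENT] * 8, 20.0)
        rg, _ = gel_rg(traj)
        assert rg == pytest.approx(_rg_oracle(corners), abs=1e-12)
        assert rg == pytest.approx(a * math.sqrt(3) / 2)

    def test_empty_trajectory(self):
        traj = make_traj(np.empty((0, 2, 3)), [GEL_SEGMENT] * 2, 10.0)
        with pytest.raises(AnalysisError):
            gel_rg(traj)


class TestShellVolumes:
    def test_inside_half_box_is_sphere(self):
        L = 10.0
        for r in (1.0, 3.0, 5.0):
            assert sphere_box_volume(r, L) == pytest.approx(
                4 / 3 * math.pi * r ** 3, rel=1e-12)

    def test_saturates_at_box_volume(self):
        assert sphere_box_volume(9.0, 10.0) == 1000.0

    @pytest.mark.parametrize("r_over_L", [0.55, 0.65, 0.75, 0.85])
    def test_against_monte_carlo(self, r_over_L, rng):
        L = 1.0
        r = r_over_L * L
        pts = rng.random((400000, 3)) - 0.5
        frac = (np.einsum("ij,ij->i", pts, pts) <= r * r).mean()
        mc = frac * L ** 3
        exact = sphere_box_volume(r, L)
        se = math.sqrt(frac * (1 - frac) / len(pts))
        assert abs(exact - mc) < 4 * se + 1e-4

    def test_shell_volumes_sum(self):
        edges = np.linspace(0, 0.86, 40)
        vols = shell_volumes(edges, 1.0)
        assert (vols > 0).all()
        assert vols.sum() == pytest.approx(sphere_box_volume(0.86, 1.0))


class TestGq:
    def test_uniform_gas_is_unity(self, rng):
        L = 20.0
        n_ions, n_frames = 500, 20
        frames = []
        gel = np.full((5, 3), L / 2) + rng.normal(0, 0.5, (5, 3))
        for _ in range(n_frames):
            frames.append(np.vstack([gel, rng.random((n_ions, 3)) * L]))
        traj = make_traj(frames, [GEL_SEGMENT] * 5 + [CATION_1] * n_ions, L)
        prof = charged_pair_correlation(traj, CATION_1, bin_width=1.0)
        # per-bin SE from frame scatter
        per_frame_gq = prof.frame_counts / prof.shell_vols / prof.mean_density
        se = per_frame_gq.std(axis=0, ddof=1) / math.sqrt(n_frames)
        dev = np.abs(prof.gq - 1.0)
        assert (dev <= 3 * se + 1e-9).mean() > 0.95  # ~3-sigma band
        assert abs(prof.gq.mean() - 1.0) < 0.05

    def test_absent_species_raises(self):
        traj = make_traj([np.zeros((2, 3))], [GEL_SEGMENT] * 2, 10.0)
        with pytest.raises(AnalysisError):
            charged_pair_correlation(traj, CATION_2)

    def test_counts_bookkeeping(self, rng):
        L = 12.0
        frames = [np.vstack([np.full((1, 3), L / 2),
                             rng.random((50, 3)) * L]) for _ in range(4)]
        traj = make_traj(frames, [GEL_SEGMENT] + [CATION_1] * 50, L)
        prof = charged_pair_correlation(traj, CATION_1, bin_width=0.5,
                                        r_max=0.5 * math.sqrt(3) * L)
        assert prof.counts.sum() == 4 * 50


class TestPartition:
    def test_flat_profile_gives_unity(self):
        from gelion.analysis import RadialProfile
        edges = np.arange(0.0, 10.5, 0.5)
        vols = shell_volumes(edges, 22.0)
        n_frames = 10
        frame_counts = np.tile(vols, (n_frames, 1))  # gq == 1 exactly
        prof = RadialProfile(
            species="cation_1", r_edges=edges,
            r_centers=0.5 * (edges[:-1] + edges[1:]),
            gq=np.ones(len(vols)), counts=frame_counts.sum(axis=0),
            frame_counts=frame_counts, shell_vols=vols, n_frames=n_frames,
            n_particles=100, box_length=22.0, mean_density=1.0)
        obs = GelObservables(rg=4.0, rg_se=0.0, com=np.zeros((1, 3)),
                             phi=0.1, phi_se=0.0, r_interior=2.0)
        res = partition_coefficients(prof, obs)
        assert res.Q == pytest.approx(1.0)

    def test_constructed_ratio_eight(self):
        from gelion.analysis import RadialProfile
        edges = np.arange(0.0, 10.5, 0.5)
        L = 22.0
        vols = shell_volumes(edges, L)
        centers = 0.5 * (edges[:-1] + edges[1:])
        gq = np.where(centers < 3.0, 8.0, 1.0)
        frame_counts = np.tile(gq * vols, (8, 1))
        prof = RadialProfile(
            species="cation_1", r_edges=edges, r_centers=centers, gq=gq,
            counts=frame_counts.sum(axis=0), frame_counts=frame_counts,
            shell_vols=vols, n_frames=8, n_particles=100, box_length=L,
            mean_density=1.0)
        obs = GelObservables(rg=4.0, rg_se=0.0, com=np.zeros((1, 3)),
                             phi=0.1, phi_se=0.0, r_interior=2.0)
        res = partition_coefficients(prof, obs)
        assert res.Q == pytest.approx(8.0)

    def test_fixture_q3_recovery(self):
        spec = PartitionFixtureSpec(Q_targets={CATION_1: 3.0}, r_gel=10.0,
                                    L=44.0, n_ions=1200, n_frames=100, seed=2)
        traj = make_partition_fixture(spec)
        obs = gel_observables(traj, compute_phi=False)
        prof = charged_pair_correlation(traj, CATION_1, 0.5)
        res = partition_coefficients(prof, obs)
        assert res.Q == pytest.approx(3.0, rel=0.05)
        assert res.se_Q < 0.3

    def test_window_ordering(self):
        spec = PartitionFixtureSpec(Q_targets={CATION_1: 2.0}, r_gel=10.0,
                                    L=44.0, n_ions=800, n_frames=20, seed=0)
        traj = make_partition_fixture(spec)
        obs = gel_observables(traj, compute_phi=False)
        prof = charged_pair_correlation(traj, CATION_1, 0.5)
        res = partition_coefficients(prof, obs)
        assert res.r_in_window[1] <= res.r_bulk_window[0]
        assert res.r_bulk_window[1] <= 0.45 * traj.box_length + 1e-9


class TestPartitionRatio:
    def _mk(self, q, se):
        from gelion.analysis import PartitionResult
        return PartitionResult(species="x", Q=q, se_Q=se, c_in=0, c_bulk=0,
                               r_in_window=(0, 1), r_bulk_window=(2, 3))

    def test_equal_gives_one(self):
        r, se = partition_ratio(self._mk(3.0, 0.1), self._mk(3.0, 0.1))
        assert r == 1.0

    def test_fixture_ratio(self):
        r, _ = partition_ratio(self._mk(6.0, 0.1), self._mk(3.0, 0.1))
        assert r == pytest.approx(2.0)

    def test_error_propagation(self):
        r, se = partition_ratio(self._mk(6.0, 0.6), self._mk(3.0, 0.3))
        assert se == pytest.approx(2.0 * math.sqrt(0.01 + 0.01))

    def test_nonpositive_rejected(self):
        with pytest.raises(AnalysisError):
            partition_ratio(self._mk(0.0, 0.1), self._mk(3.0, 0.1))

    def test_propagated_matches_bootstrap(self):
        spec = PartitionFixtureSpec(Q_targets={CATION_1: 3.0, CATION_2: 6.0},
                                    r_gel=10.0, L=44.0, n_ions=1500,
                                    n_frames=120, seed=4)
        traj = make_partition_fixture(spec)
        obs = gel_observables(traj, compute_phi=False)
        res = {}
        for code in (CATION_1, CATION_2):
            prof = charged_pair_correlation(traj, code, 0.5)
            res[code] = partition_coefficients(prof, obs)
        ratio, se_prop = partition_ratio(res[CATION_2], res[CATION_1])
        # bootstrap the ratio directly over frames
        rng = np.random.default_rng(9)
        profs = {c: charged_pair_correlation(traj, c, 0.5) for c in res}
        obs_rg = obs.rg
        ratios = []
        for _ in range(200):
            pick = rng.integers(0, traj.n_frames, traj.n_frames)
            qs = {}
            for c, p in profs.items():
                sel_in = (p.r_edges[1:] <= 0.5 * obs_rg)
                sel_b = (p.r_edges[:-1] >= max(1.5 * obs_rg, obs_rg + 5.0)) \
                    & (p.r_edges[1:] <= 0.45 * traj.box_length)
                ci = p.frame_counts[pick][:, sel_in].mean(axis=0).sum() \
                    / p.shell_vols[sel_in].sum()
                cb = p.frame_counts[pick][:, sel_b].mean(axis=0).sum() \
                    / p.shell_vols[sel_b].sum()
                qs[c] = ci / cb
            ratios.append(qs[CATION_2] / qs[CATION_1])
        se_boot = np.std(ratios, ddof=1)
        assert se_prop == pytest.approx(se_boot, rel=0.35)


class TestPhi:
    def _ball_traj(self, n_beads, r_ball, L, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n_beads, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= r_ball * rng.random(n_beads)[:, None] ** (1 / 3)
        return make_traj([pts + L / 2], [GEL_SEGMENT] * n_beads, L)

    def test_dense_lattice_approaches_pi_over_six(self):
        # unit-spacing lattice ball: one bead per sigma^3 -> phi ~ pi/6
        L = 40.0
        grid = np.arange(-8, 9, 1.0)
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T
        pts = pts[np.linalg.norm(pts, axis=1) <= 8.0] + L / 2
        traj = make_traj([pts], [GEL_SEGMENT] * len(pts), L)
        obs = gel_observables(traj)
        phi, _ = internal_volume_fraction(traj, obs)
        assert phi == pytest.approx(math.pi / 6, rel=0.05)

    def test_linearity_in_bead_count(self):
        L = 40.0
        t1 = self._ball_traj(4000, 8.0, L, seed=1)
        obs1 = gel_observables(t1)
        # drop half the beads inside the SAME interior radius definition
        t2 = make_traj([t1.positions[0][::2]], [GEL_SEGMENT] * 2000, L)
        obs2 = gel_observables(t2)
        assert obs2.phi == pytest.approx(obs1.phi / 2, rel=0.1)

    def test_collapsed_denser_than_swollen(self):
        L = 40.0
        collapsed = gel_observables(self._ball_traj(2000, 5.0, L, seed=2))
        swollen = gel_observables(self._ball_traj(2000, 9.0, L, seed=3))
        assert collapsed.rg < swollen.rg
        assert collapsed.phi > swollen.phi


class TestFitScaling:
    def _table(self, kappa=1.1, mu=0.76, noise=0.0, seed=0, n_reps=1):
        from gelion.fixtures import make_scaling_table
        return make_scaling_table(kappa, mu, noise,
                                  [0.05, 0.1, 0.2, 0.4], [1, 2, 5, 10],
                                  seed=seed, n_reps=n_reps)

    def test_noiseless_exact(self):
        fit = fit_scaling(self._table())
        assert fit.kappa == pytest.approx(1.1, abs=1e-10)
        assert fit.mu == pytest.approx(0.76, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_covariate_kappa(self):
        df = pd.DataFrame({"Q": np.array([0.1, 0.2, 0.4]) ** 1.1,
                           "phi": [0.1, 0.2, 0.4]})
        fit = fit_scaling(df, covariates=("phi",))
        assert fit.kappa == pytest.approx(1.1, abs=1e-10)
        assert math.isnan(fit.mu)

    def test_noisy_recovery(self):
        fit = fit_scaling(self._table(mu=0.89, noise=0.05, seed=1, n_reps=20))
        assert fit.kappa == pytest.approx(1.1, abs=0.1)
        assert fit.mu == pytest.approx(0.89, abs=0.1)

    def test_too_few_points(self):
        df = self._table().iloc[:2]
        with pytest.raises(FitRefusedError):
            fit_scaling(df)

    def test_nonpositive_rejected(self):
        df = self._table()
        df.loc[0, "Q"] = -1.0
        with pytest.raises(FitRefusedError):
            fit_scaling(df)

    def test_collinear_rejected(self):
        df = pd.DataFrame({"Q": [1.0, 2.0, 3.0], "phi": [0.1, 0.1, 0.1],
                           "csalt": [5.0, 5.0, 5.0]})
        with pytest.raises(FitRefusedError):
            fit_scaling(df)

    def test_se_reported(self):
        fit = fit_scaling(self._table(noise=0.05, seed=2, n_reps=5))
        assert fit.se_kappa > 0 and fit.se_mu > 0


class TestBlockedSE:
    def test_iid_matches_naive(self, rng):
        x = rng.normal(size=2000)
        se = blocked_se(x)
        naive = x.std(ddof=1) / math.sqrt(len(x))
        assert se == pytest.approx(naive, rel=0.5)

    def test_correlated_larger_than_naive(self, rng):
        # AR(1) with strong correlation
        n = 4000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = 0.95 * x[i - 1] + eps[i]
        naive = x.std(ddof=1) / math.sqrt(n)
        assert blocked_se(x) > 2 * naive
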