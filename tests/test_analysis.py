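import math

import numpy as np
import pytest

from dsxchange.analysis import (
    angle_probability,
    autocorrelation_stride,
    compare_sasa_groups,
    loop_pca,
    regioselectivity,
    sasa,
    sphere_points,
    ss_distance_distributions,
    unfolding_statistics,
)
from dsxchange.model import ChainTopology, Frame, SwapEvent, Trajectory


def _events(n55, n24, attacker=32):
    evs = []
    t = 0.0
    for tgt, n in ((55, n55), (24, n24)):
        for _ in range(n):
            t += 1.0
            evs.append(SwapEvent(
                time=t, attacker=attacker, target=tgt,
                leaving=24 if tgt == 55 else 55,
                d_ss=0.4, angle=120.0, verdict="accepted",
            ))
    return evs


class TestRegioselectivity:
    def test_printed_counts_give_exact_ratio(self, rng):
        """18 events on 55Cys and 12 on 24Cys give a 1.5-fold preference."""
        res = regioselectivity(_events(18, 12), n_bootstrap=0, rng=rng)
        assert res.n_a == 18 and res.n_b == 12
        assert res.ratio == 1.5
        assert not res.infinite

    def test_bootstrap_se_matches_exact_enumeration(self, rng):
        """Trajectory-resampling SE agrees with the exact resampling SD
        computed by enumerating the binomial resample distribution."""
        from scipy.stats import binom

        n, x = 30, 18
        res = regioselectivity(_events(x, n - x), n_bootstrap=100_000, rng=rng)
        ks = np.arange(n + 1)
        pmf = binom.pmf(ks, n, x / n)
        keep = ks < n  # zero-denominator resamples are redrawn
        pmf = pmf[keep] / pmf[keep].sum()
        r = ks[keep] / (n - ks[keep])
        exact_sd = math.sqrt(float(pmf @ r**2 - (pmf @ r) ** 2))
        assert res.bootstrap_se == pytest.approx(exact_sd, rel=0.03)
        # the first-order delta linearization underestimates the SD of
        # this convex, right-skewed ratio at n=30 — by design we report
        # the resampling SD, not the linearized one
        p = x / n
        delta_se = n / (n - x) ** 2 * math.sqrt(n * p * (1 - p))
        assert res.bootstrap_se > delta_se

    def test_all_one_target_infinite(self, rng):
        res = regioselectivity(_events(5, 0), n_bootstrap=100, rng=rng)
        assert res.infinite
        assert res.ratio == float("inf")

    def test_point_estimate_order_invariant(self, rng):
        evs = _events(7, 4)
        res1 = regioselectivity(evs, n_bootstrap=0)
        res2 = regioselectivity(list(reversed(evs)), n_bootstrap=0)
        assert (res1.n_a, res1.n_b, res1.ratio) == (res2.n_a, res2.n_b, res2.ratio)

    def test_attacker_filter(self, rng):
        evs = _events(3, 1, attacker=32) + _events(0, 4, attacker=47)
        res = regioselectivity(evs, n_bootstrap=0, attacker=32)
        assert (res.n_a, res.n_b) == (3, 1)
        res_all = regioselectivity(evs, n_bootstrap=0)
        assert (res_all.n_a, res_all.n_b) == (3, 5)


class TestAngleProbability:
    def test_uniform_survival(self):
        """Uniform angles on [80, 180] give P(angle>theta)=(180-theta)/100."""
        angles = {55: 80.0 + 100.0 * (np.arange(1000) + 0.5) / 1000}
        df = angle_probability(angles, theta_grid=[0, 80, 100, 130, 180])
        got = df["p_gt_55"].to_numpy()
        assert got[0] == 1.0
        assert got[1] == pytest.approx(1.0, abs=1e-9)
        assert got[2] == pytest.approx(0.8, abs=1e-3)
        assert got[3] == pytest.approx(0.5, abs=1e-3)
        assert got[4] == pytest.approx(0.0, abs=1e-9)

    def test_matches_counting_oracle(self, rng):
        angles = {55: rng.uniform(0, 180, 300), 24: rng.uniform(60, 170, 200)}
        grid = np.array([10.0, 45.0, 90.0, 135.0])
        df = angle_probability(angles, grid)
        for tgt in (55, 24):
            arr = angles[tgt]
            for i, th in enumerate(grid):
                assert df[f"p_gt_{tgt}"][i] == np.sum(arr > th) / len(arr)
        # survival ratio column present and finite on the interior
        assert np.isfinite(df["ratio"]).all()

    def test_empty_set_flagged(self):
        with pytest.warns(UserWarning):
            df = angle_probability({55: [], 24: [100.0]})
        assert df["p_gt_55"].isna().all()


def _ee_traj(ee_values, n=4):
    """Trajectory whose end-to-end distance follows ee_values."""
    topo = ChainTopology(n_residues=n, cysteines=frozenset())
    frames = []
    for t, ee in enumerate(ee_values):
        c = np.zeros((n, 3))
        c[1:, 0] = np.linspace(0.1, 1, n - 1)
        c[-1, 0] = ee
        frames.append(Frame(float(t), c))
    return Trajectory(frames, topo, metadata={"config": {"fixed_residue": 1}})


class TestUnfolding:
    def test_step_function(self):
        trajs = [_ee_traj([5, 25, 26]) for _ in range(4)]
        res = unfolding_statistics(trajs, threshold=20.0)
        assert res.fraction_unfolded == 1.0
        t, frac = res.cumulative_curve()
        assert np.all(t == 1.0)
        assert frac[-1] == 1.0

    def test_no_crossing(self):
        res = unfolding_statistics([_ee_traj([5, 6, 7])], threshold=20.0)
        assert res.fraction_unfolded == 0.0
        assert len(res.unfolding_times) == 0

    def test_curve_monotone_and_bounded(self, rng):
        trajs = []
        for i in range(10):
            ee = np.cumsum(rng.uniform(0, 4, size=12))
            trajs.append(_ee_traj(ee))
        res = unfolding_statistics(trajs, threshold=20.0)
        t, frac = res.cumulative_curve()
        assert np.all(np.diff(t) >= 0)
        assert np.all(np.diff(frac) >= 0)
        if len(frac):
            assert frac[-1] == pytest.approx(res.fraction_unfolded)


def _loop_trajectory(coords_list):
    n = coords_list[0].shape[0]
    topo = ChainTopology(n_residues=n, cysteines=frozenset())
    frames = [Frame(float(i), c) for i, c in enumerate(coords_list)]
    return Trajectory(frames, topo, metadata={"config": {"fixed_residue": 1}})


class TestLoopPCA:
    def test_rigid_motion_gives_zero_variance(self, rng):
        from scipy.spatial.transform import Rotation

        base = rng.normal(size=(10, 3))
        frames = []
        for _ in range(8):
            rot = Rotation.random(random_state=rng).as_matrix()
            frames.append(base @ rot.T + rng.normal(size=3) * 5)
        traj = _loop_trajectory(frames)
        res = loop_pca(traj, loop_range=(1, 10), unfolded_only=False)
        assert np.all(res.eigenvalues < 1e-12)

    def test_planar_breathing_single_mode(self):
        base = np.zeros((6, 3))
        base[:, 0] = np.arange(6) * 0.4
        frames = []
        for a in np.linspace(-0.5, 0.5, 9):
            c = base.copy()
            c[:, 1] = a * np.linspace(-1, 1, 6)  # one collective direction
            frames.append(c)
        res = loop_pca(_loop_trajectory(frames), loop_range=(1, 6),
                       unfolded_only=False, superpose=False)
        total = res.eigenvalues.sum()
        assert res.eigenvalues[0] / total == pytest.approx(1.0, abs=1e-9)
        assert res.variance_fraction_12 == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_eigensolve_oracle(self, rng):
        """Eigenvalues equal an independent dense covariance eigensolve
        on a pre-aligned 10-frame toy set."""
        m, L = 10, 5
        coords = rng.normal(scale=0.2, size=(m, L, 3)) + np.arange(L)[None, :, None]
        res = loop_pca(_loop_trajectory(list(coords)), loop_range=(1, L),
                       unfolded_only=False, superpose=False)
        flat = (coords - coords.mean(axis=1, keepdims=True)).reshape(m, 3 * L)
        cov = np.cov(flat.T, bias=True)
        expect = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, np.clip(expect, 0, None), atol=1e-12)

    def test_reconstruction_identity(self, rng):
        m, L = 12, 6
        coords = list(rng.normal(scale=0.3, size=(m, L, 3)))
        res = loop_pca(_loop_trajectory(coords), loop_range=(1, L),
                       unfolded_only=False)
        for i in (0, 5, 11):
            rec = res.reconstruct(i)
            assert np.allclose(rec, res.aligned[i], atol=1e-10)

    def test_orthonormal_modes_and_unit_fractions(self, rng):
        m, L = 20, 4
        coords = list(rng.normal(scale=0.3, size=(m, L, 3)))
        res = loop_pca(_loop_trajectory(coords), loop_range=(1, L),
                       unfolded_only=False)
        g = res.eigenvectors.T @ res.eigenvectors
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-10)
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)
        assert 0.0 <= res.variance_fraction_12 <= 1.0

    def test_rank_deficiency_warns(self, rng):
        coords = list(rng.normal(size=(4, 10, 3)))
        with pytest.warns(UserWarning):
            loop_pca(_loop_trajectory(coords), loop_range=(1, 10),
                     unfolded_only=False)


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        """A single bead exposes its full probe-expanded sphere."""
        r, p = 0.235, 0.14
        area = sasa(np.zeros((1, 3)), r, probe=p, n_points=960)
        assert area == pytest.approx(4 * math.pi * (r + p) ** 2, rel=1e-12)

    def test_fully_overlapping_beads_count_once(self):
        r, p = 0.2, 0.1
        one = sasa(np.zeros((1, 3)), r, probe=p)
        two = sasa(np.zeros((2, 3)), r, probe=p)
        assert two == pytest.approx(one, rel=1e-12)

    def test_three_bead_toy_vs_monte_carlo_oracle(self, rng):
        """Fibonacci-grid SASA agrees with a dense random-point surface
        integration within 1%."""
        coords = np.array([[0.0, 0, 0], [0.5, 0.1, 0], [0.2, 0.45, 0.1]])
        radii = np.array([0.25, 0.3, 0.2])
        p = 0.14
        got = sasa(coords, radii, probe=p, n_points=960)
        # oracle: uniform random points on each expanded sphere
        expanded = radii + p
        total = 0.0
        nmc = 120_000
        for i in range(3):
            pts = rng.normal(size=(nmc, 3))
            pts /= np.linalg.norm(pts, axis=1)[:, None]
            pts = coords[i] + expanded[i] * pts
            buried = np.zeros(nmc, dtype=bool)
            for j in range(3):
                if j == i:
                    continue
                buried |= np.sum((pts - coords[j]) ** 2, axis=1) < expanded[j] ** 2
            total += (~buried).mean() * 4 * math.pi * expanded[i] ** 2
        assert got == pytest.approx(total, rel=0.01)

    def test_rotation_translation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        coords = rng.normal(scale=0.4, size=(6, 3))
        a0 = sasa(coords, 0.235, n_points=960)
        rot = Rotation.random(random_state=rng).as_matrix()
        a1 = sasa(coords @ rot.T + 3.0, 0.235, n_points=960)
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_probe_monotonic_single_bead(self):
        areas = [sasa(np.zeros((1, 3)), 0.2, probe=p) for p in (0.0, 0.1, 0.2)]
        assert areas[0] < areas[1] < areas[2]

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), -0.1)
        with pytest.raises(ValueError):
            sasa(np.zeros((1, 3)), 0.2, probe=-0.1)

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert abs(pts.mean(axis=0)).max() < 0.01


class TestKS:
    def test_identical_samples(self, rng):
        x = rng.normal(size=400)
        res = compare_sasa_groups(x, x.copy(), stride_a=1, stride_b=1)
        assert res.ks_statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_support(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(5, 6, 200)
        res = compare_sasa_groups(a, b, stride_a=1, stride_b=1)
        assert res.ks_statistic == 1.0
        assert res.p_value < 1e-6
        assert res.more_compact == "32->24"

    def test_too_few_samples_skipped(self):
        with pytest.warns(UserWarning):
            res = compare_sasa_groups([1.0], [2.0, 3.0], stride_a=1, stride_b=1)
        assert res.skipped

    def test_autocorrelation_stride(self, rng):
        white = rng.normal(size=2000)
        assert 1 <= autocorrelation_stride(white) <= 5
        # strongly correlated series decorrelate later
        ar = np.zeros(2000)
        for i in range(1, 2000):
            ar[i] = 0.97 * ar[i - 1] + rng.normal()
        assert autocorrelation_stride(ar) > 10
        assert autocorrelation_stride([1.0, 1.0, 1.0]) == 1


class TestDistanceDistributions:
    def _static_traj(self):
        topo = ChainTopology(
            n_residues=6, cysteines=frozenset({1, 2, 3, 4, 5}),
            disulfide=frozenset({1, 2}),
        )
        c = np.zeros((6, 3))
        c[1] = [0.39, 0, 0]
        c[2] = [1.0, 0, 0]
        c[3] = [0, 2.0, 0]
        c[4] = [0, 0, 3.0]
        c[5] = [1, 1, 1]
        return Trajectory([Frame(0.0, c), Frame(1.0, c)], topo, {}), topo, c

    def test_static_frame_delta_histograms(self):
        traj, topo, c = self._static_traj()
        hists = ss_distance_distributions(traj, topo, bins=40, d_max=4.0)
        assert set(hists) == {(t, s) for t in (3, 4, 5) for s in (1, 2)}
        for (t, s), h in hists.items():
            d = np.linalg.norm(c[t - 1] - c[s - 1])
            nz = np.nonzero(h["density"])[0]
            assert len(nz) == 1
            lo, hi = h["edges"][nz[0]], h["edges"][nz[0] + 1]
            assert lo <= d < hi

    def test_densities_integrate_to_one(self):
        traj, topo, _ = self._static_traj()
        hists = ss_distance_distributions(traj, topo)
        for h in hists.values():
            width = np.diff(h["edges"])
            assert np.sum(h["density"] * width) == pytest.approx(1.0)
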