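import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsxchange.model import ChainTopology, Frame, Trajectory, build_i27_star
from dsxchange.potentials import total_energy
from dsxchange.simulator import SimulationConfig, run_force_clamp
from dsxchange.swap_engine import (
    SwapCriterion,
    attack_angle,
    detect_first_passage,
    metropolis_accept,
    metropolis_swap,
    run_hybrid,
)

TOPO5 = ChainTopology(
    n_residues=5, cysteines=frozenset({1, 2, 3, 4, 5}),
    disulfide=frozenset({1, 2}),
)
# attacker thiols 3, 4, 5 attack the 1-2 disulfide


def _frames_from_distances(d3, d4=None, d5=None):
    """Synthetic frames where bead 3/4/5 sit at given distances from
    bead 1 (and far from bead 2)."""
    m = len(d3)
    d4 = [10.0] * m if d4 is None else d4
    d5 = [10.0] * m if d5 is None else d5
    frames = []
    for t in range(m):
        c = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 3.0, 0.0],      # second disulfide sulfur, well away
            [d3[t], 0.0, 0.0],
            [0.0, 0.0, 20.0 + d4[t]],
            [0.0, 0.0, -20.0 - d5[t]],
        ])
        # beads 4, 5 approach bead 1 only when their distance is small
        if d4[t] < 5:
            c[3] = [0.0, -d4[t], 0.0]
        if d5[t] < 5:
            c[4] = [-d5[t], 0.0, 0.0]
        frames.append(Frame(float(t), c))
    return frames


class TestDetect:
    def test_earliest_event_rule(self):
        """Two dips at t=5 (pair 3-1) and t=7 (pair 4-1): only the
        earliest is reported."""
        d3 = [2, 2, 2, 2, 2, 0.4, 2, 2, 2, 2]
        d4 = [9, 9, 9, 9, 9, 9, 9, 0.3, 9, 9]
        crit = SwapCriterion(d_cutoff=0.5)
        events = detect_first_passage(_frames_from_distances(d3, d4), TOPO5, crit)
        assert len(events) == 1
        assert events[0].attacker == 3
        assert events[0].target == 1
        assert events[0].time == 5.0

    def test_no_approach_empty(self):
        events = detect_first_passage(
            _frames_from_distances([2.0] * 10), TOPO5, SwapCriterion()
        )
        assert events == []

    def test_matches_bruteforce_scan(self, rng):
        """First-passage list equals an exhaustive per-frame scan on a
        1000-frame noisy stream."""
        m = 1000
        walk = np.abs(np.cumsum(rng.normal(scale=0.08, size=(m, 3)), axis=0) + 1.2)
        frames = _frames_from_distances(walk[:, 0], walk[:, 1], walk[:, 2])
        crit = SwapCriterion(d_cutoff=0.5)
        got = detect_first_passage(frames, TOPO5, crit, all_pairs=True)
        # oracle: scan every frame/attacker pair independently
        expected = {}
        for t, fr in enumerate(frames):
            for attacker in (3, 4, 5):
                if attacker in expected:
                    continue
                d1 = np.linalg.norm(fr.coords[attacker - 1] - fr.coords[0])
                d2 = np.linalg.norm(fr.coords[attacker - 1] - fr.coords[1])
                if min(d1, d2) < 0.5:
                    expected[attacker] = (float(t), 1 if d1 <= d2 else 2)
        assert {e.attacker: (e.time, e.target) for e in got} == expected
        # default mode: the single earliest of those
        first = detect_first_passage(frames, TOPO5, crit)
        if expected:
            t0 = min(v[0] for v in expected.values())
            assert len(first) == 1 and first[0].time == t0
        else:
            assert first == []

    def test_detection_monotone_in_cutoff(self, rng):
        """Per-pair first passages at a small cutoff are a subset of (and
        not earlier than) those at a larger cutoff."""
        m = 600
        walk = np.abs(np.cumsum(rng.normal(scale=0.1, size=(m, 3)), axis=0) + 1.0)
        frames = _frames_from_distances(walk[:, 0], walk[:, 1], walk[:, 2])
        lo = detect_first_passage(
            frames, TOPO5, SwapCriterion(d_cutoff=0.3), all_pairs=True
        )
        hi = detect_first_passage(
            frames, TOPO5, SwapCriterion(d_cutoff=0.6), all_pairs=True
        )
        lo_by = {e.attacker: e for e in lo}
        hi_by = {e.attacker: e for e in hi}
        assert set(lo_by) <= set(hi_by)
        for att, e in lo_by.items():
            assert hi_by[att].time <= e.time

    def test_angle_filter(self):
        """A minimum-angle requirement suppresses detections whose
        geometry is far from the in-line S_N2 arrangement."""
        # attacker at 90 degrees from the leaving sulfur
        c = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 0.39, 0.0],
            [0.4, 0.0, 0.0],
            [5.0, 5.0, 0.0],
            [-5.0, 5.0, 0.0],
        ])
        frames = [Frame(0.0, c)]
        assert detect_first_passage(frames, TOPO5, SwapCriterion(angle_min=150.0)) == []
        got = detect_first_passage(frames, TOPO5, SwapCriterion(angle_min=80.0))
        assert len(got) == 1 and got[0].attacker == 3

    def test_nearer_sulfur_is_target(self):
        c = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 0.39, 0.0],
            [0.30, 0.25, 0.0],   # within cutoff of both; nearer to bead 1? no:
            [9.0, 9.0, 9.0],
            [-9.0, 9.0, 9.0],
        ])
        d1 = np.linalg.norm(c[2] - c[0])
        d2 = np.linalg.norm(c[2] - c[1])
        ev = detect_first_passage([Frame(0.0, c)], TOPO5, SwapCriterion())[0]
        assert ev.target == (1 if d1 <= d2 else 2)
        assert ev.d_ss == pytest.approx(min(d1, d2))


class TestAttackAngle:
    def test_collinear_is_180(self):
        c = np.zeros((5, 3))
        c[2] = [1.0, 0, 0]   # attacker
        c[0] = [0.0, 0, 0]   # target
        c[1] = [-1.0, 0, 0]  # leaving
        c[3] = [5, 5, 5]
        c[4] = [6, 6, 6]
        assert attack_angle(Frame(0.0, c), 3, 1, 2) == pytest.approx(180.0)

    def test_right_angle(self):
        c = np.zeros((5, 3))
        c[2] = [1.0, 0, 0]
        c[1] = [0.0, 1.0, 0]
        c[3] = [5, 5, 5]
        c[4] = [6, 6, 6]
        assert attack_angle(Frame(0.0, c), 3, 1, 2) == pytest.approx(90.0)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_vector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.normal(size=(5, 3))
        fr = Frame(0.0, c)
        got = attack_angle(fr, 3, 1, 2)
        u = c[2] - c[0]
        v = c[1] - c[0]
        expect = math.degrees(
            math.acos(
                max(-1.0, min(1.0, np.dot(u, v)
                              / (np.linalg.norm(u) * np.linalg.norm(v))))
            )
        )
        assert got == pytest.approx(expect, abs=1e-9)
        assert 0.0 <= got <= 180.0

    def test_coincident_positions_error(self):
        c = np.zeros((5, 3))
        c[3] = [5, 5, 5]
        c[4] = [6, 6, 6]
        with pytest.raises(ValueError):
            attack_angle(Frame(0.0, c), 3, 1, 2)


class TestMetropolisRule:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-0.1 * i, 2.494, rng) for i in range(1, 50))
        assert metropolis_accept(0.0, 2.494, rng)

    def test_half_acceptance_at_kt_ln2(self, rng):
        kT = 2.494
        dE = kT * math.log(2.0)
        n = 10_000
        acc = sum(metropolis_accept(dE, kT, rng) for _ in range(n)) / n
        assert acc == pytest.approx(0.5, abs=3 * 0.5 / math.sqrt(n))

    def test_frequency_matches_boltzmann_on_grid(self, rng):
        """Acceptance frequency over 10^4 draws matches exp(-dE/kT)
        within binomial error across a dE grid."""
        kT = 2.494
        n = 10_000
        for factor in (0.25, 0.5, 1.0, 2.0, 3.0):
            dE = factor * kT
            p = math.exp(-factor)
            acc = sum(metropolis_accept(dE, kT, rng) for _ in range(n)) / n
            tol = 4 * math.sqrt(p * (1 - p) / n)
            assert abs(acc - p) < tol, (factor, acc, p)

    def test_acceptance_scale_consistent(self):
        """Doubling kT never decreases acceptance probability for dE>0."""
        for dE in (0.5, 1.0, 5.0):
            p1 = math.exp(-dE / 2.494)
            p2 = math.exp(-dE / 4.988)
            assert p2 >= p1


@pytest.fixture(scope="module")
def detected_event(params):
    """A real detected approach on the fixture (arming gate off, so the
    compact globule supplies a contact quickly)."""
    topo, start = build_i27_star(seed=21)
    cfg = SimulationConfig(force_pn=0.0, seed=21, n_steps=30_000,
                           output_stride=50)
    traj = run_force_clamp(start, topo, params, cfg)
    crit = SwapCriterion(d_cutoff=0.55, arm_end_to_end=None)
    events = detect_first_passage(traj, topo, crit)
    assert events, "fixture stream produced no contact; enlarge n_steps"
    ev = events[0]
    frame = next(f for f in traj if f.time == ev.time)
    return topo, frame, ev, crit


class TestMetropolisSwap:
    def test_frozen_environment_bit_identity(self, detected_event, params, rng):
        topo, frame, ev, crit = detected_event
        verdict, dE, product = metropolis_swap(frame, topo, ev, params, crit, rng)
        assert verdict in ("accepted", "rejected")
        if product is not None:
            centers = [ev.attacker, ev.target, ev.leaving]
            d = np.min(
                np.linalg.norm(
                    frame.coords[:, None, :]
                    - frame.coords[np.array(centers) - 1][None, :, :],
                    axis=2,
                ),
                axis=1,
            )
            outside = d > crit.relax_radius
            assert np.array_equal(product.coords[outside], frame.coords[outside])
            assert not np.array_equal(product.coords, frame.coords)

    def test_de_is_minimized_product_minus_reactant(self, detected_event, params):
        from dsxchange.model import apply_swap
        from dsxchange.potentials import minimize
        from dsxchange.swap_engine import _mobile_region

        topo, frame, ev, crit = detected_event
        rng = np.random.default_rng(0)
        _, dE, _ = metropolis_swap(frame, topo, ev, params, crit, rng)
        mobile = _mobile_region(frame, topo, ev, crit.relax_radius)
        _, e_r, _ = minimize(frame.coords, topo, params, mobile=mobile,
                             tol=crit.minimizer_tol,
                             max_steps=crit.minimizer_max_steps)
        ev_acc = type(ev)(time=ev.time, attacker=ev.attacker, target=ev.target,
                          leaving=ev.leaving, d_ss=ev.d_ss, angle=ev.angle,
                          verdict="accepted")
        _, e_p, _ = minimize(frame.coords, apply_swap(topo, ev_acc), params,
                             mobile=mobile, tol=crit.minimizer_tol,
                             max_steps=crit.minimizer_max_steps)
        assert dE == pytest.approx(e_p - e_r, rel=1e-9)


class TestRunHybrid:
    def test_distance_mode_accepts_every_detection(self, params):
        topo, start = build_i27_star(seed=23)
        cfg = SimulationConfig(seed=23, n_steps=60_000, output_stride=5000)
        crit = SwapCriterion(mode="distance", arm_end_to_end=None)
        res = run_hybrid(start, topo, params, cfg, crit)
        assert all(e.verdict == "accepted" for e in res.events)
        if res.events:
            e = res.events[0]
            assert res.final_topology.disulfide == frozenset({e.attacker, e.target})
            assert len(res.final_topology.free_thiols) == 3

    def test_disabled_swapping_equals_plain_run(self, params):
        topo, start = build_i27_star(seed=24)
        cfg = SimulationConfig(seed=24, n_steps=25_000, output_stride=5000)
        res = run_hybrid(start, topo, params, cfg, SwapCriterion(d_cutoff=0.0))
        plain = run_force_clamp(start, topo, params, cfg)
        assert res.events == []
        assert len(res.trajectory) == len(plain)
        for a, b in zip(res.trajectory, plain):
            assert a.time == b.time
            assert np.array_equal(a.coords, b.coords)

    def test_same_seed_reproducible(self, params):
        topo, start = build_i27_star(seed=25)
        cfg = SimulationConfig(seed=25, n_steps=40_000, output_stride=5000)
        crit = SwapCriterion(arm_end_to_end=None)
        r1 = run_hybrid(start, topo, params, cfg, crit)
        r2 = run_hybrid(start, topo, params, cfg, crit)
        assert r1.events == r2.events
        for a, b in zip(r1.trajectory, r2.trajectory):
            assert np.array_equal(a.coords, b.coords)

    def test_stop_after_swap(self, params):
        topo, start = build_i27_star(seed=23)
        cfg = SimulationConfig(seed=23, n_steps=60_000, output_stride=5000)
        crit = SwapCriterion(mode="distance", arm_end_to_end=None)
        res = run_hybrid(start, topo, params, cfg, crit, stop_after_swap=True)
        if res.events:
            assert res.trajectory.frames[-1].time == pytest.approx(
                res.events[0].time
            )
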