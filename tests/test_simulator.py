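import dataclasses

import numpy as np
import pytest
from scipy import stats

from echolag import SimConfig, SonarParams, simulate_ensemble
from echolag.simulate import (
    BatState,
    circular_midpoint,
    desired_heading_independent,
    draw_speed,
    escape_update,
    simulate_pair,
    turn_clamp,
)
from echolag.trajectories import wrap_angle


class TestTurnClamp:
    def test_small_turn_taken_exactly(self):
        cfg = SimConfig()
        assert turn_clamp(0.0, 0.05, 5.0, cfg) == pytest.approx(0.05)

    def test_large_turn_clamped_to_beta_dt(self):
        cfg = SimConfig()
        v = 4.81
        beta_dt = cfg.a_c / v * cfg.dt  # ~0.1632 rad
        assert beta_dt == pytest.approx(0.16316, abs=1e-4)
        assert turn_clamp(0.0, np.pi, v, cfg) == pytest.approx(beta_dt)
        assert turn_clamp(0.0, -np.pi + 0.01, v, cfg) == pytest.approx(-beta_dt)

    def test_empirical_turns_respect_aerodynamic_limit(self):
        cfg = SimConfig(duration=4.0)
        pair, log = simulate_pair(cfg, np.random.default_rng(0))
        h = log["headings"]
        v = log["speeds"]
        for i in range(2):
            dphi = np.abs(wrap_angle(np.diff(h[1:, i])))
            limit = cfg.a_c / v[2:, i] * cfg.dt
            assert np.all(dphi <= limit + 1e-9)


class TestHeadingDraws:
    def test_infinite_concentration_returns_previous_heading(self):
        cfg = dataclasses.replace(SimConfig(), kappa_indep=1e12)
        state = BatState(position=np.zeros(2), heading=1.234)
        rng = np.random.default_rng(0)
        draws = [desired_heading_independent(state, cfg, rng) for _ in range(50)]
        assert np.allclose(draws, 1.234, atol=1e-4)

    def test_circular_spread_matches_large_kappa_approximation(self):
        cfg = SimConfig()
        state = BatState(position=np.zeros(2), heading=0.5)
        rng = np.random.default_rng(1)
        draws = np.array(
            [desired_heading_independent(state, cfg, rng) for _ in range(100_000)]
        )
        resultant = np.abs(np.mean(np.exp(1j * draws)))
        circ_sd = np.sqrt(-2.0 * np.log(resultant))
        assert circ_sd == pytest.approx(1.0 / np.sqrt(557.0), rel=0.02)
        mean_dir = np.angle(np.mean(np.exp(1j * draws)))
        assert mean_dir == pytest.approx(0.5, abs=3.0 * circ_sd / np.sqrt(len(draws)))

    @pytest.mark.parametrize(
        "a, b, mid",
        [(0.3, 0.3, 0.3), (0.0, np.pi / 2, np.pi / 4), (3.0, -3.0, np.pi)],
    )
    def test_circular_midpoint_uses_shortest_arc(self, a, b, mid):
        assert circular_midpoint(a, b) == pytest.approx(mid, abs=1e-9)


class TestSpeeds:
    def test_rician_moments_match_scipy(self):
        cfg = SimConfig()
        rng = np.random.default_rng(2)
        draws = np.array([draw_speed(cfg, rng) for _ in range(100_000)])
        ref = stats.rice(cfg.rician_nu / cfg.rician_sigma, scale=cfg.rician_sigma)
        assert draws.mean() == pytest.approx(ref.mean(), rel=0.01)
        assert draws.std() == pytest.approx(ref.std(), rel=0.02)


class TestBehaviouralStates:
    def test_escape_dwell_is_geometric(self):
        cfg = SimConfig()
        rng = np.random.default_rng(3)
        dwells = []
        for _ in range(5000):
            state = BatState(position=np.zeros(2), heading=0.0, interacting=True)
            k = 0
            while state.interacting:
                k += 1
                escape_update(state, cfg, rng)
            dwells.append(k)
        mean_dwell_s = np.mean(dwells) * cfg.dt
        assert mean_dwell_s == pytest.approx(0.4, rel=0.05)

    @pytest.mark.parametrize("p, expected_max", [(0.0, np.inf), (1.0, 1)])
    def test_escape_probability_extremes(self, p, expected_max):
        cfg = dataclasses.replace(SimConfig(), escape_prob=p)
        rng = np.random.default_rng(4)
        state = BatState(position=np.zeros(2), heading=0.0, interacting=True)
        for _ in range(100):
            escape_update(state, cfg, rng)
            if not state.interacting:
                break
        if p == 0.0:
            assert state.interacting
        else:
            assert not state.interacting

    def test_detection_disabled_keeps_bats_independent(self):
        sonar = SonarParams(B=np.inf)
        cfg = SimConfig(duration=4.0, sonar=sonar)
        _, log = simulate_pair(cfg, np.random.default_rng(5))
        assert not log["interacting"].any()

    def test_close_facing_bats_detect_each_other(self):
        # amplitude at 1 m on-axis is 57.44 dB >= B = 10 dB: first call must
        # switch both bats to interacting once the delay elapses
        cfg = SimConfig(duration=1.0, tau=0.1)
        from echolag.simulate import BatState, emit_calls

        a = BatState(position=np.array([0.0, 0.0]), heading=0.0)
        b = BatState(position=np.array([1.0, 0.0]), heading=np.pi)
        emit_calls((a, b), cfg, 0)
        assert a.call_detected == [True]
        assert b.call_detected == [True]

    def test_rear_detection_range_shorter_than_frontal(self):
        from echolag.simulate import BatState, emit_calls

        cfg = SimConfig()
        # partner 3 m behind: zeta = pi, echo = 57.44-ish minus 36 dB and extra
        # spreading -> below threshold, while frontal at 3 m is detectable
        a_front = BatState(position=np.zeros(2), heading=0.0)
        partner_front = BatState(position=np.array([3.0, 0.0]), heading=0.0)
        emit_calls((a_front, partner_front), cfg, 0)
        assert a_front.call_detected == [True]
        a_rear = BatState(position=np.zeros(2), heading=np.pi)
        partner = BatState(position=np.array([3.0, 0.0]), heading=0.0)
        emit_calls((a_rear, partner), cfg, 0)
        assert a_rear.call_detected == [False]


class TestEnsemble:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(duration=2.0)
        p1, _ = simulate_ensemble(cfg, 3, seed=42)
        p2, _ = simulate_ensemble(cfg, 3, seed=42)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.a.positions, b.a.positions)
            assert np.array_equal(a.b.positions, b.b.positions)

    def test_growing_ensemble_preserves_earlier_pairs(self):
        cfg = SimConfig(duration=1.0)
        small, _ = simulate_ensemble(cfg, 2, seed=7)
        large, _ = simulate_ensemble(cfg, 4, seed=7)
        assert np.array_equal(small[1].a.positions, large[1].a.positions)

    def test_detection_off_mean_speed_matches_rician(self):
        sonar = SonarParams(B=np.inf)
        cfg = SimConfig(duration=10.0, sonar=sonar)
        pairs, logs = simulate_ensemble(cfg, 10, seed=8)
        speeds = np.concatenate([lg["speeds"][1:].ravel() for lg in logs])
        ref = stats.rice(cfg.rician_nu / cfg.rician_sigma, scale=cfg.rician_sigma)
        assert speeds.mean() == pytest.approx(ref.mean(), rel=0.01)

    def test_detection_off_turning_angles_uncorrelated(self):
        sonar = SonarParams(B=np.inf)
        cfg = SimConfig(duration=10.0, sonar=sonar)
        _, logs = simulate_ensemble(cfg, 20, seed=9)
        corrs = []
        for lg in logs:
            dphi = wrap_angle(np.diff(lg["headings"][1:], axis=0))
            corrs.append(np.corrcoef(dphi[:, 0], dphi[:, 1])[0, 1])
        # independent walkers: per-step turning angles are uncorrelated
        assert abs(np.mean(corrs)) < 0.05
        assert np.all(np.abs(corrs) < 0.2)

    def test_default_run_shape(self):
        cfg = SimConfig()
        pairs, _ = simulate_ensemble(cfg, 1, seed=0)
        assert len(pairs[0]) == 500

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(tau=0.03)
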