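"""Diffusive-state HMM: parameter recovery, BIC state-count selection,
dwell-time bookkeeping, Viterbi decoding and windowed transition re-fits."""

import numpy as np
import pytest

from tred.hmm import (
    fit_states,
    select_state_count,
    viterbi_paths,
    windowed_transitions,
)
from tred.simulate import SimulationConfig, StateSpec, Trajectory, simulate_tracks

TRUE_P = np.array([[0.95, 0.05], [0.10, 0.90]])
TRUE_PI = np.array([2 / 3, 1 / 3])  # analytic stationary distribution


def _single_state_tracks(seed, n_tracks=20, n_frames=201, D=0.01):
    cfg = SimulationConfig(
        n_tracks=n_tracks,
        n_frames=n_frames,
        substep_factor=1,
        states=[StateSpec("s", D)],
        loc_noise_sd=0.0,
        seed=seed,
    )
    return simulate_tracks(cfg)


class TestFitStates:
    def test_single_state_recovery(self):
        tracks = _single_state_tracks(1, n_tracks=100, n_frames=1001)
        m = fit_states(tracks, 1, 0.05, seed=0)
        assert np.allclose(m.trans, [[1.0]])
        assert m.D_states[0] == pytest.approx(0.01, rel=0.03)

    def test_two_state_recovery(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        assert np.abs(m.trans - TRUE_P).max() < 0.02
        assert np.abs(m.occupancy - TRUE_PI).max() < 0.03
        assert np.all(np.diff(m.D_states) > 0)

    def test_dwell_time_formula(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        expect = 0.05 / (1.0 - np.diag(m.trans))
        assert np.allclose(m.dwell_times, expect, atol=1e-9)
        # P_ii = 0.9, dt = 0.05 -> tau = 0.5 s at the fitted values' scale
        assert m.dwell_times[1] == pytest.approx(0.5, rel=0.1)

    def test_loglik_monotone_and_occupancy_stationary(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        hist = np.array(m.loglik_history)
        assert np.all(np.diff(hist) >= -1e-6 * np.abs(hist[:-1]))
        assert np.abs(m.occupancy @ m.trans - m.occupancy).max() < 1e-8
        assert np.allclose(m.trans.sum(axis=1), 1.0, atol=1e-9)

    def test_restart_seed_invariance_of_sorted_model(self, two_state_tracks):
        a = fit_states(two_state_tracks, 2, 0.05, seed=0)
        b = fit_states(two_state_tracks, 2, 0.05, seed=99)
        assert np.allclose(a.D_states, b.D_states, rtol=1e-3)
        assert np.allclose(a.trans, b.trans, atol=1e-3)

    def test_parameter_recovery_across_seeds(self):
        errs_P, errs_pi = [], []
        for seed in range(10):
            cfg = SimulationConfig(
                n_tracks=20,
                n_frames=501,
                substep_factor=1,
                states=[StateSpec("slow", 0.001), StateSpec("fast", 0.02)],
                transition_matrix=TRUE_P,
                initial_occupancy=TRUE_PI,
                loc_noise_sd=0.0,
                seed=300 + seed,
            )
            m = fit_states(simulate_tracks(cfg), 2, 0.05, seed=seed)
            errs_P.append(np.abs(m.trans - TRUE_P).max())
            errs_pi.append(np.abs(m.occupancy - TRUE_PI).max())
        assert np.median(errs_P) < 0.02
        assert np.median(errs_pi) < 0.03

    def test_unsupportable_k_raises(self):
        tiny = _single_state_tracks(2, n_tracks=2, n_frames=6)
        with pytest.raises(ValueError, match="smaller K"):
            fit_states(tiny, 5, 0.05, seed=0)


class TestSelectStateCount:
    def test_single_state_data_selects_one(self):
        wins = 0
        for seed in range(20):
            tracks = _single_state_tracks(400 + seed, n_tracks=10, n_frames=101)
            m = select_state_count(tracks, 3, 0.05, seed=seed, n_restarts=2, tol=1e-6)
            wins += m.K == 1
        assert wins >= 18

    def test_three_state_fixture_selects_three(self):
        cfg = SimulationConfig(
            n_tracks=60,
            n_frames=501,
            substep_factor=1,
            states=[
                StateSpec("immobile", 0.0005),
                StateSpec("less_mobile", 0.003),
                StateSpec("mobile", 0.02),
            ],
            transition_matrix=np.array(
                [[0.90, 0.05, 0.05], [0.05, 0.90, 0.05], [0.05, 0.05, 0.90]]
            ),
            loc_noise_sd=0.0,
            seed=41,
        )
        m = select_state_count(simulate_tracks(cfg), 3, 0.05, seed=0)
        assert m.K == 3
        assert m.labels == ["immobile", "less_mobile", "mobile"]

    def test_identical_diffusivities_are_unidentifiable(self):
        cfg = SimulationConfig(
            n_tracks=20,
            n_frames=201,
            substep_factor=1,
            states=[StateSpec("a", 0.01), StateSpec("b", 0.01)],
            transition_matrix=np.array([[0.9, 0.1], [0.1, 0.9]]),
            loc_noise_sd=0.0,
            seed=5,
        )
        m = select_state_count(simulate_tracks(cfg), 2, 0.05, seed=0, n_restarts=2, tol=1e-6)
        assert m.K == 1


class TestViterbi:
    def test_single_state_paths(self):
        tracks = _single_state_tracks(3, n_tracks=5, n_frames=50)
        m = fit_states(tracks, 1, 0.05, seed=0)
        for p, tr in zip(viterbi_paths(tracks, m), tracks):
            assert np.all(p == 0)
            assert len(p) == len(tr) - 1

    def test_two_state_agreement_with_truth(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        agree = np.mean(
            [
                (p == tr.true_states[:-1]).mean()
                for p, tr in zip(viterbi_paths(two_state_tracks, m), two_state_tracks)
            ]
        )
        assert agree >= 0.90  # D ratio 20 >= 10


class TestWindowedTransitions:
    def test_default_windows_count(self, two_state_tracks):
        # tracks cover 50 s here; 10-s windows -> exactly 5
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        wins = windowed_transitions(two_state_tracks, m, window=10.0, total=50.0)
        assert len(wins) == 5
        assert wins[0].window_start == 0.0 and wins[-1].window_end == 50.0

    def test_homogeneous_data_matches_global(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        global_p = m.trans[1, 0]  # mobile -> less mobile
        for w in windowed_transitions(two_state_tracks, m, window=10.0, total=50.0):
            assert abs(w.p_mobile_to_less - global_p) < 0.05

    def test_nonstationary_drop_is_detected(self):
        # mobile->slow probability falls from 0.2 to 0.05 at t = 25 s
        rng = np.random.default_rng(8)
        dt, n_frames = 0.05, 1001
        sds = np.sqrt(2 * np.array([0.001, 0.02]) * dt)
        tracks = []
        for i in range(60):
            s = np.zeros(n_frames, dtype=int)
            s[0] = rng.integers(2)
            for t in range(1, n_frames):
                p21 = 0.2 if t * dt < 25.0 else 0.05
                P = np.array([[0.95, 0.05], [p21, 1 - p21]])
                s[t] = rng.choice(2, p=P[s[t - 1]])
            steps = rng.normal(0, sds[s[:-1], None], size=(n_frames - 1, 2))
            pos = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            frames = np.arange(n_frames)
            tracks.append(
                Trajectory(i, frames, frames * dt, pos[:, 0], pos[:, 1], true_states=s)
            )
        m = fit_states(tracks, 2, dt, seed=0)
        wins = windowed_transitions(tracks, m, window=10.0, total=50.0)
        ps = [w.p_mobile_to_less for w in wins]
        assert ps[0] > ps[-1]
        assert ps[1] - ps[3] > 0.05

    def test_window_must_divide_total(self, two_state_tracks):
        m = fit_states(two_state_tracks, 2, 0.05, seed=0)
        with pytest.raises(ValueError, match="divide"):
            windowed_transitions(two_state_tracks, m, window=15.0, total=50.0)
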