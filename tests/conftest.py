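import numpy as np
import pytest

from tred.simulate import SimulationConfig, StateSpec, Trajectory, simulate_tracks


@pytest.fixture(scope="session")
def free_diffusion_tracks():
    """2,000 free-diffusion tracks, D = 0.01 µm²/s, noiseless."""
    cfg = SimulationConfig(
        n_tracks=2000,
        n_frames=51,
        states=[StateSpec("mobile", 0.01)],
        loc_noise_sd=0.0,
        substep_factor=2,
        seed=11,
    )
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def confined_tracks():
    """300 corral-confined tracks (D = 0.01, L = 0.1 µm), noiseless."""
    cfg = SimulationConfig(
        n_tracks=300,
        n_frames=600,
        states=[StateSpec("confined", 0.01, 0.1)],
        loc_noise_sd=0.0,
        seed=12,
    )
    return simulate_tracks(cfg)


@pytest.fixture(scope="session")
def two_state_tracks():
    """Two-state switching free diffusion: D = 0.001/0.02, P12=0.05, P21=0.10."""
    cfg = SimulationConfig(
        n_tracks=100,
        n_frames=1001,
        substep_factor=1,
        states=[StateSpec("slow", 0.001), StateSpec("fast", 0.02)],
        transition_matrix=np.array([[0.95, 0.05], [0.10, 0.90]]),
        initial_occupancy=np.array([2 / 3, 1 / 3]),
        loc_noise_sd=0.0,
        seed=13,
    )
    return simulate_tracks(cfg)


def make_track(x, y, frames=None, dt=0.05, **kw) -> Trajectory:
    x = np.asarray(x, dtype=float)
    frames = np.arange(len(x)) if frames is None else np.asarray(frames)
    return Trajectory(
        track_id=kw.pop("track_id", 0),
        frames=frames,
        times=frames * dt,
        x=x,
        y=np.asarray(y, dtype=float),
        **kw,
    )
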