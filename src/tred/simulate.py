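"""Synthetic hop-diffusion trajectory generator.

Emulates the statistical structure of membrane-receptor single-particle
tracking data: Brownian motion inside square actin corrals with occasional
barrier hopping (picket-fence model), Markovian switching between discrete
diffusive states (immobile / less mobile / mobile), per-cell heterogeneity
that makes the population distribution of diffusivities approximately
lognormal, and additive Gaussian localization noise.  Positions are in µm,
times in seconds.

The defaults mirror typical receptor-tracking acquisition: 20 frames/s
sampling and corral sizes in the tens-to-hundreds of nanometres range that
cortical-actin microdomains occupy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "StateSpec",
    "SimulationConfig",
    "Trajectory",
    "simulate_tracks",
    "simulate_population",
    "render_stack",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration field is invalid."""


@dataclass(frozen=True)
class StateSpec:
    """One diffusive state: microscopic diffusivity and corral geometry.

    ``corral_L`` may be ``math.inf`` for unconfined (free) diffusion.
    ``hop_prob`` is the probability that an attempted corral-boundary
    crossing succeeds (the particle enters the adjacent corral) instead of
    being reflected.
    """

    label: str
    D_micro: float  # µm²/s
    corral_L: float = math.inf  # µm; inf = free diffusion
    hop_prob: float = 0.0

    def validate(self) -> None:
        if self.D_micro < 0:
            raise ConfigurationError(f"D_micro must be >= 0 (state {self.label!r})")
        if not (self.corral_L > 0):
            raise ConfigurationError(f"corral_L must be > 0 or inf (state {self.label!r})")
        if not (0.0 <= self.hop_prob <= 1.0):
            raise ConfigurationError(f"hop_prob must be in [0, 1] (state {self.label!r})")


@dataclass
class SimulationConfig:
    """Full generative description of a synthetic tracking experiment."""

    n_tracks: int = 200
    n_frames: int = 1200
    frame_interval: float = 0.05  # s (20 frames/s)
    substep_factor: int = 10
    states: Sequence[StateSpec] = field(
        default_factory=lambda: (
            StateSpec("immobile", 0.0005, 0.05),
            StateSpec("less_mobile", 0.003, 0.08),
            StateSpec("mobile", 0.02, 0.15),
        )
    )
    transition_matrix: np.ndarray | None = None  # K×K, per frame
    initial_occupancy: np.ndarray | None = None  # K
    loc_noise_sd: float = 0.02  # µm per coordinate
    cell_heterogeneity_sd: float = 0.0  # log10-scale SD on state diffusivities
    tracks_per_cell: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.states)
        if self.transition_matrix is None:
            # mildly sticky default chain
            tm = np.full((k, k), 0.02 / max(k - 1, 1))
            np.fill_diagonal(tm, 0.98)
            self.transition_matrix = tm if k > 1 else np.ones((1, 1))
        else:
            self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.initial_occupancy is None:
            self.initial_occupancy = np.full(k, 1.0 / k)
        else:
            self.initial_occupancy = np.asarray(self.initial_occupancy, dtype=float)

    def validate(self) -> None:
        if self.n_tracks < 0:
            raise ConfigurationError("n_tracks must be >= 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if not (self.frame_interval > 0):
            raise ConfigurationError("frame_interval must be > 0")
        if self.substep_factor < 1:
            raise ConfigurationError("substep_factor must be >= 1")
        if self.loc_noise_sd < 0:
            raise ConfigurationError("loc_noise_sd must be >= 0")
        if self.cell_heterogeneity_sd < 0:
            raise ConfigurationError("cell_heterogeneity_sd must be >= 0")
        if self.tracks_per_cell < 1:
            raise ConfigurationError("tracks_per_cell must be >= 1")
        if not self.states:
            raise ConfigurationError("states must be non-empty")
        for s in self.states:
            s.validate()
        k = len(self.states)
        tm = self.transition_matrix
        if tm.shape != (k, k):
            raise ConfigurationError(f"transition_matrix must be {k}x{k}, got {tm.shape}")
        if np.any(tm < 0):
            raise ConfigurationError("transition_matrix entries must be >= 0")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-12, rtol=0):
            raise ConfigurationError("transition_matrix rows must each sum to 1")
        occ = self.initial_occupancy
        if occ.shape != (k,):
            raise ConfigurationError(f"initial_occupancy must have length {k}")
        if np.any(occ < 0) or not math.isclose(occ.sum(), 1.0, abs_tol=1e-12):
            raise ConfigurationError("initial_occupancy must be nonnegative and sum to 1")


@dataclass
class Trajectory:
    """One particle's time-ordered 2-D positions.

    ``frames`` are 0-based integer frame indices (strictly increasing, gaps
    allowed); ``times`` are in seconds; ``x``/``y`` in µm.  ``true_states``
    is populated only by the simulator.
    """

    track_id: int | str
    frames: np.ndarray
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cell_id: int | str | None = None
    condition: str | None = None
    true_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise ValueError("frames, times, x, y must have equal length")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("positions must be finite")
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Time span (last time − first time) in seconds."""
        return float(self.times[-1] - self.times[0]) if len(self) else 0.0

    @property
    def frame_interval(self) -> float:
        """Sampling interval inferred from frame indices and times."""
        if len(self) < 2:
            raise ValueError("need >= 2 points to infer frame interval")
        return float((self.times[-1] - self.times[0]) / (self.frames[-1] - self.frames[0]))


def _reflect_axis(
    pos: np.ndarray,
    step: np.ndarray,
    corral_L: np.ndarray,
    hop_u: np.ndarray,
    hop_prob: np.ndarray,
) -> np.ndarray:
    """Advance one coordinate by ``step`` with corral walls at multiples of L.

    An attempted wall crossing succeeds (particle hops to the adjacent
    corral) with probability ``hop_prob``; otherwise the position is
    reflected about the wall.  Infinite L means free diffusion.
    """
    new = pos + step
    finite = np.isfinite(corral_L)
    if not np.any(finite):
        return new
    L = np.where(finite, corral_L, 1.0)  # placeholder avoids inf arithmetic
    c_old = np.floor(pos / L)
    c_new = np.floor(new / L)
    crossing = finite & (c_new != c_old)
    if np.any(crossing):
        hop = crossing & (hop_u < hop_prob)
        reflect = crossing & ~hop
        # wall first crossed: upper wall of old corral when moving up, lower when moving down
        wall = np.where(step > 0, (c_old + 1.0) * L, c_old * L)
        new = np.where(reflect, 2.0 * wall - new, new)
        # guard rare multi-wall crossings: clamp reflected points into the old corral
        lo = c_old * L
        new = np.where(reflect, np.clip(new, lo, lo + L), new)
    return new


def simulate_tracks(config: SimulationConfig) -> list[Trajectory]:
    """Simulate hop-diffusion trajectories with Markov state switching.

    The hidden state is resampled once per frame; within a frame interval
    the particle takes ``substep_factor`` Brownian substeps with per-axis
    variance 2·D·(Δt/substep_factor), reflected at corral walls except that
    each attempted crossing succeeds with the state's ``hop_prob``.
    Reported positions are true positions plus N(0, loc_noise_sd²) noise per
    axis.  Identical configs (including seed) give identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, f, k = config.n_tracks, config.n_frames, len(config.states)
    dt_sub = config.frame_interval / config.substep_factor

    D = np.array([s.D_micro for s in config.states])
    Ls = np.array([s.corral_L for s in config.states])
    hp = np.array([s.hop_prob for s in config.states])
    cum_tm = np.cumsum(config.transition_matrix, axis=1)

    # state chain, one draw per (track, frame)
    states = np.empty((n, f), dtype=np.int64)
    states[:, 0] = rng.choice(k, size=n, p=config.initial_occupancy)
    u_trans = rng.random((n, f - 1)) if f > 1 else np.empty((n, 0))
    for t in range(1, f):
        states[:, t] = (u_trans[:, t - 1, None] >= cum_tm[states[:, t - 1]]).sum(axis=1)

    # initial positions: uniform inside the starting corral (origin-anchored grid)
    L0 = Ls[states[:, 0]]
    finite0 = np.isfinite(L0)
    u0 = rng.random((n, 2))
    pos = np.where(finite0[:, None], u0 * np.where(finite0, L0, 1.0)[:, None], 0.0)

    xs = np.empty((n, f))
    ys = np.empty((n, f))
    xs[:, 0], ys[:, 0] = pos[:, 0], pos[:, 1]
    x, y = pos[:, 0].copy(), pos[:, 1].copy()

    for t in range(1, f):
        st = states[:, t - 1]  # state governs motion over [t-1, t)
        sd = np.sqrt(2.0 * D[st] * dt_sub)
        Lt, hpt = Ls[st], hp[st]
        for _ in range(config.substep_factor):
            steps = rng.standard_normal((n, 2)) * sd[:, None]
            hop_u = rng.random((n, 2))
            x = _reflect_axis(x, steps[:, 0], Lt, hop_u[:, 0], hpt)
            y = _reflect_axis(y, steps[:, 1], Lt, hop_u[:, 1], hpt)
        xs[:, t], ys[:, t] = x, y

    if config.loc_noise_sd > 0:
        xs = xs + rng.normal(0.0, config.loc_noise_sd, size=xs.shape)
        ys = ys + rng.normal(0.0, config.loc_noise_sd, size=ys.shape)

    frames = np.arange(f, dtype=np.int64)
    times = frames * config.frame_interval
    return [
        Trajectory(
            track_id=i,
            frames=frames.copy(),
            times=times.copy(),
            x=xs[i],
            y=ys[i],
            true_states=states[i].copy(),
        )
        for i in range(n)
    ]


def simulate_population(config: SimulationConfig) -> list[Trajectory]:
    """Simulate a heterogeneous cell population.

    Tracks are grouped into synthetic cells of ``tracks_per_cell`` each;
    every cell scales all state diffusivities by 10^ε with
    ε ~ N(0, cell_heterogeneity_sd²), so the population distribution of D
    is approximately lognormal.  ``cell_id`` is recorded on every track.
    """
    config.validate()
    n_cells = math.ceil(config.n_tracks / config.tracks_per_cell)
    rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.cell_heterogeneity_sd, size=n_cells)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_cells)

    out: list[Trajectory] = []
    remaining = config.n_tracks
    for c in range(n_cells):
        n_c = min(config.tracks_per_cell, remaining)
        remaining -= n_c
        scaled = [replace(s, D_micro=s.D_micro * 10.0 ** eps[c]) for s in config.states]
        sub = replace(config, n_tracks=n_c, states=scaled, seed=int(sub_seeds[c]))
        for tr in simulate_tracks(sub):
            tr.track_id = len(out)
            tr.cell_id = c
            out.append(tr)
    return out


def render_stack(
    tracks: Sequence[Trajectory],
    psf_sd: float = 0.15,
    pixel_size: float = 0.107,
    photons: float = 1000.0,
    background: float = 10.0,
    shape: tuple[int, int] | None = None,
    n_frames: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render trajectories into a TIFF-writable image stack.

    Each particle becomes an integrated 2-D Gaussian (SD ``psf_sd``) with
    expected total signal ``photons``; Poisson noise is applied to signal
    plus ``background`` counts/pixel.  Pixel (row, col) spans
    [col·pixel_size, (col+1)·pixel_size) in x and the same in y for rows.
    """
    if not (pixel_size > 0):
        raise ConfigurationError("pixel_size must be > 0")
    if n_frames is None:
        if not tracks:
            raise ValueError("n_frames is required when no tracks are given")
        n_frames = int(max(tr.frames.max() for tr in tracks)) + 1
    if shape is None:
        if tracks:
            max_x = max(tr.x.max() for tr in tracks)
            max_y = max(tr.y.max() for tr in tracks)
            pad = 5 * psf_sd
            shape = (
                int(np.ceil((max_y + pad) / pixel_size)) + 1,
                int(np.ceil((max_x + pad) / pixel_size)) + 1,
            )
        else:
            shape = (32, 32)
    ny, nx = shape
    for tr in tracks:
        bad = (tr.x < 0) | (tr.x > nx * pixel_size) | (tr.y < 0) | (tr.y > ny * pixel_size)
        if np.any(bad):
            fr = tr.frames[bad][0]
            raise ValueError(f"track {tr.track_id} outside field at frame {fr}")

    expected = np.full((n_frames, ny, nx), float(background))
    half = math.sqrt(2.0) * psf_sd
    win = max(1, int(np.ceil(5 * psf_sd / pixel_size)))
    edges_x = np.arange(nx + 1) * pixel_size
    edges_y = np.arange(ny + 1) * pixel_size
    for tr in tracks:
        for fi, px, py in zip(tr.frames, tr.x, tr.y):
            if fi >= n_frames:
                continue
            cx, cy = int(px / pixel_size), int(py / pixel_size)
            x0, x1 = max(0, cx - win), min(nx, cx + win + 1)
            y0, y1 = max(0, cy - win), min(ny, cy + win + 1)
            fx = 0.5 * (erf((edges_x[x0 : x1 + 1] - px) / half))
            fy = 0.5 * (erf((edges_y[y0 : y1 + 1] - py) / half))
            expected[fi, y0:y1, x0:x1] += photons * np.outer(np.diff(fy), np.diff(fx))

    rng = np.random.default_rng(seed)
    return rng.poisson(expected).astype(np.uint16)
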