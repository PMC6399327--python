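"""Diffusive-state hidden Markov model over per-frame displacements.

Receptors switch between discrete diffusive states (immobile, less mobile,
mobile).  Each state i emits per-frame displacement vectors whose two
components are independent zero-mean Gaussians with variance 2·Dᵢ·Δt, and
the state sequence is a first-order Markov chain with per-frame transition
matrix P.  Parameters are estimated by Baum–Welch (EM) jointly over all
trajectories, the number of states is selected by BIC, and per-state dwell
times follow τᵢ = Δt/(1 − Pᵢᵢ).

Localization noise is deliberately not part of the emission model, so the
fitted D of the slowest state is bounded below by σ_loc²/(2Δt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from .simulate import Trajectory

__all__ = [
    "StateModel",
    "WindowedTransition",
    "fit_states",
    "select_state_count",
    "windowed_transitions",
    "viterbi_paths",
]

_STATE_LABELS = {3: ["immobile", "less_mobile", "mobile"]}


class _ZeroMeanGaussianHMM(GaussianHMM):
    """GaussianHMM with emissions pinned at zero mean.

    hmmlearn only accumulates the posterior-count statistics when means are
    being re-estimated, yet its covariance M-step divides by them; with
    means frozen ('m' absent from ``params``) covariances blow up.  Forcing
    the accumulation whenever covariances are updated yields the exact
    zero-mean EM update var_i = E[‖x‖²·γ_i]/(2·Σγ_i).
    """

    def _needs_sufficient_statistics_for_mean(self):
        return "m" in self.params or "c" in self.params


class _RecordingMonitor(ConvergenceMonitor):
    """Keeps the full loglik history and asserts EM monotonicity."""

    def __init__(self, tol: float, n_iter: int):
        super().__init__(tol, n_iter, verbose=False)
        self.full_history: list[float] = []

    def report(self, log_prob: float) -> None:
        if self.full_history:
            prev = self.full_history[-1]
            assert log_prob >= prev - 1e-6 * max(1.0, abs(prev)), (
                f"EM log-likelihood decreased: {prev} -> {log_prob}"
            )
        self.full_history.append(log_prob)
        super().report(log_prob)

    @property
    def converged(self) -> bool:
        # stop on *relative* loglik change < tol (hmmlearn's default is absolute)
        if self.iter == self.n_iter:
            return True
        if len(self.history) >= 2:
            delta = self.history[-1] - self.history[-2]
            return delta < self.tol * max(1.0, abs(self.history[-1]))
        return False


@dataclass
class StateModel:
    """Fitted K-state diffusive HMM, states sorted ascending by D."""

    K: int
    D_states: np.ndarray  # µm²/s, strictly increasing
    trans: np.ndarray  # K×K per-frame transition probabilities
    occupancy: np.ndarray  # stationary distribution of trans
    dwell_times: np.ndarray  # seconds, Δt/(1 − Pᵢᵢ)
    loglik: float
    criterion: float  # BIC
    n_tracks: int
    frame_interval: float
    loglik_history: list[float] = field(default_factory=list, repr=False)

    @property
    def labels(self) -> list[str]:
        return _STATE_LABELS.get(self.K, [f"state_{i}" for i in range(self.K)])

    def emission_variances(self) -> np.ndarray:
        """Per-axis displacement variance of each state: 2·D·Δt."""
        return 2.0 * self.D_states * self.frame_interval


@dataclass
class WindowedTransition:
    window_start: float
    window_end: float
    p_mobile_to_less: float


def _segments(track: Trajectory) -> list[np.ndarray]:
    """Displacement arrays of contiguous frame runs (gaps split a track)."""
    if len(track) < 2:
        return []
    pos = np.column_stack([track.x, track.y])
    breaks = np.where(np.diff(track.frames) > 1)[0] + 1
    out = []
    for chunk in np.split(np.arange(len(track)), breaks):
        if len(chunk) >= 2:
            out.append(np.diff(pos[chunk], axis=0))
    return out


def _displacement_data(tracks: Sequence[Trajectory]) -> tuple[np.ndarray, list[int]]:
    segs: list[np.ndarray] = []
    for tr in tracks:
        segs.extend(_segments(tr))
    if not segs:
        raise ValueError("no displacement steps in the given tracks")
    X = np.concatenate(segs, axis=0)
    return X, [len(s) for s in segs]


def _n_params(K: int) -> int:
    # K diffusivities + K(K−1) free transition entries + (K−1) initial probs
    return K + K * (K - 1) + (K - 1)


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _make_hmm(
    K: int, tol: float, n_iter: int, seed: int, params: str = "stc", init_params: str | None = None
) -> GaussianHMM:
    model = _ZeroMeanGaussianHMM(
        n_components=K,
        covariance_type="spherical",
        min_covar=1e-12,
        covars_prior=0.0,
        init_params=params.replace("m", "") if init_params is None else init_params,
        params=params,
        tol=tol,
        n_iter=n_iter,
        random_state=seed,
        implementation="scaling",
    )
    model.means_ = np.zeros((K, 2))  # displacements are zero-mean by construction
    model.monitor_ = _RecordingMonitor(tol, n_iter)
    return model


def fit_states(
    tracks: Sequence[Trajectory],
    K: int,
    frame_interval: float,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> StateModel:
    """Baum–Welch fit of a K-state diffusive HMM to all tracks jointly.

    Runs ``n_restarts`` seeded initializations and keeps the best
    log-likelihood.  Occupancy is the stationary distribution of the fitted
    transition matrix.  Raises if a state is starved of data in every
    restart (advise a smaller K).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    X, lengths = _displacement_data(tracks)
    if len(X) <= _n_params(K):
        raise ValueError(
            f"{len(X)} displacement steps cannot support {K} states "
            f"({_n_params(K)} free parameters); try a smaller K"
        )
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)

    best = None
    best_ll = -np.inf
    for s in sub_seeds:
        model = _make_hmm(K, tol, max_iter, int(s))
        try:
            model.fit(X, lengths)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.all(np.isfinite(model.transmat_)):
            continue
        # component starvation: a state with (almost) no posterior mass
        post = model.predict_proba(X, lengths).sum(axis=0)
        if post.min() < 1.0:
            continue
        ll = float(model.score(X, lengths))
        if ll > best_ll:
            best, best_ll = model, ll
    if best is None:
        raise ValueError(
            f"could not fit {K} states (component starvation in all restarts); try a smaller K"
        )

    var = np.asarray(best._covars_)  # spherical: one variance per state
    if var.ndim == 2:  # hmmlearn stores (K, n_features) after its M-step
        var = var[:, 0]
    D = var / (2.0 * frame_interval)
    order = np.argsort(D)
    D = D[order]
    P = best.transmat_[np.ix_(order, order)]
    P = P / P.sum(axis=1, keepdims=True)
    diag = np.clip(np.diag(P), 0.0, 1.0 - 1e-15)
    dwell = frame_interval / (1.0 - diag)
    n_steps = len(X)
    bic = _n_params(K) * np.log(n_steps) - 2.0 * best_ll
    return StateModel(
        K=K,
        D_states=D,
        trans=P,
        occupancy=_stationary(P),
        dwell_times=dwell,
        loglik=best_ll,
        criterion=float(bic),
        n_tracks=len(tracks),
        frame_interval=frame_interval,
        loglik_history=list(best.monitor_.full_history),
    )


def select_state_count(
    tracks: Sequence[Trajectory],
    k_max: int,
    frame_interval: float,
    seed: int = 0,
    **fit_kwargs,
) -> StateModel:
    """Fit K = 1 … k_max and return the model with the smallest BIC.

    BIC = p·ln(N_steps) − 2·loglik with p = K + K(K−1) + (K−1).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    best: StateModel | None = None
    for k in range(1, k_max + 1):
        try:
            model = fit_states(tracks, k, frame_interval, seed=seed, **fit_kwargs)
        except ValueError:
            continue  # starved: larger K unsupportable
        if best is None or model.criterion < best.criterion:
            best = model
    if best is None:
        raise ValueError("no state count could be fitted")
    return best


def windowed_transitions(
    tracks: Sequence[Trajectory],
    model: StateModel,
    window: float = 20.0,
    total: float = 100.0,
    seed: int = 0,
) -> list[WindowedTransition]:
    """Re-estimate P(mobile → less_mobile) in consecutive time windows.

    Trajectories are cut at window boundaries; within each window only the
    transition (and initial) probabilities are re-fitted, with emission
    parameters frozen at the global model's diffusivities so state labels
    cannot switch between windows.
    """
    if model.K < 2:
        raise ValueError("windowed_transitions needs a model with >= 2 states")
    n_win = total / window
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("window must divide total")
    n_win = int(round(n_win))
    mobile, less = model.K - 1, model.K - 2

    out: list[WindowedTransition] = []
    for w in range(n_win):
        t0, t1 = w * window, (w + 1) * window
        cut: list[Trajectory] = []
        for tr in tracks:
            sel = (tr.times >= t0 - 1e-9) & (tr.times < t1 - 1e-9)
            if sel.sum() >= 2:
                cut.append(
                    Trajectory(
                        track_id=tr.track_id,
                        frames=tr.frames[sel],
                        times=tr.times[sel],
                        x=tr.x[sel],
                        y=tr.y[sel],
                    )
                )
        X, lengths = _displacement_data(cut)
        hm = _make_hmm(model.K, 1e-8, 500, seed, params="st", init_params="")
        hm.covars_ = model.emission_variances().copy()
        hm.startprob_ = model.occupancy.copy()
        hm.transmat_ = model.trans.copy()
        hm.fit(X, lengths)
        P = hm.transmat_
        out.append(WindowedTransition(t0, t1, float(P[mobile, less])))
    return out


def viterbi_paths(tracks: Sequence[Trajectory], model: StateModel) -> list[np.ndarray]:
    """Most-probable state sequence per track (one state per displacement step).

    Tracks with internal frame gaps are decoded per contiguous segment and
    concatenated.  Ties break deterministically to the lower state index.
    """
    hm = _make_hmm(model.K, 1e-8, 1, 0, params="")
    hm.covars_ = model.emission_variances().copy()
    hm.startprob_ = model.occupancy.copy()
    hm.transmat_ = model.trans.copy()
    out = []
    for tr in tracks:
        parts = [hm.decode(seg)[1] for seg in _segments(tr)]
        out.append(np.concatenate(parts) if parts else np.empty(0, dtype=int))
    return out
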