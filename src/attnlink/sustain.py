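"""SUSTAIN: adaptive cluster learning with per-dimension attention tunings.

SUSTAIN starts with no clusters and recruits one whenever feedback
contradicts its prediction (supervised recruitment).  Each cluster is a
receptive field over stimulus space; per-dimension tunings ``lambda_i``
sharpen around diagnostic dimensions and act as attention.  With binary
dimensions encoded as positions in [0, 1] and per-dimension distance
``mu_ij = |center_ij - x_i|``, a cluster's activation is

    act_j = sum_i lambda_i**r * exp(-lambda_i * mu_ij) / sum_i lambda_i**r

Clusters compete: the most active cluster wins and its output is reduced
by lateral inhibition, ``out_win = act_win**beta / sum_j act_j**beta *
act_win``.  The winner's association weights drive category outputs, and
the response follows a Luce choice over ``exp(d * C_k)``.  On feedback the
winner's center moves toward the stimulus, its associations follow a
delta rule against a humble teacher (no penalty for confident correct
outputs), and tunings update as

    d(lambda_i) = eta * exp(-lambda_i * mu_i_win) * (1 - lambda_i * mu_i_win)

so tunings grow on dimensions where the winner matches the stimulus and
shrink on mismatching ones.  Time-averaged normalized tunings over a late
trial window provide the attention profile used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SustainParams",
    "SustainState",
    "NoClustersError",
    "cluster_activation",
    "respond",
    "learn_trial",
    "run_sequence",
    "extract_attention",
]

CATEGORIES = ("A", "B")


class NoClustersError(RuntimeError):
    """Signals that the state holds no clusters yet (caller should recruit)."""


@dataclass(frozen=True)
class SustainParams:
    """Learning parameters: attention focus r, competition beta, decision d, rate eta."""

    r: float
    beta: float
    d: float
    eta: float

    def __post_init__(self):
        if self.r <= 0 or self.d <= 0:
            raise ValueError("r and d must be positive")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {"r": self.r, "beta": self.beta, "d": self.d, "eta": self.eta}

    @classmethod
    def from_dict(cls, d: dict) -> "SustainParams":
        return cls(r=float(d["r"]), beta=float(d["beta"]), d=float(d["d"]), eta=float(d["eta"]))


@dataclass
class SustainState:
    """Clusters (centers + category associations) and attention tunings lambda."""

    centers: np.ndarray  # (n_clusters, n_dims)
    assoc: np.ndarray    # (n_clusters, 2) association to categories (A, B)
    lam: np.ndarray      # (n_dims,) positive tunings

    @classmethod
    def initial(cls, n_dims: int) -> "SustainState":
        """No clusters; equal tuning on every dimension."""
        return cls(
            centers=np.zeros((0, n_dims)),
            assoc=np.zeros((0, 2)),
            lam=np.ones(n_dims),
        )

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]

    @property
    def n_dims(self) -> int:
        return self.centers.shape[1]

    def copy(self) -> "SustainState":
        return SustainState(self.centers.copy(), self.assoc.copy(), self.lam.copy())

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "assoc": self.assoc.tolist(),
            "lam": self.lam.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SustainState":
        lam = np.asarray(d["lam"], dtype=float)
        n_dims = lam.shape[0]
        centers = np.asarray(d["centers"], dtype=float).reshape(-1, n_dims)
        assoc = np.asarray(d["assoc"], dtype=float).reshape(-1, 2)
        return cls(centers, assoc, lam)


def cluster_activation(stimulus, state: SustainState, params: SustainParams) -> np.ndarray:
    """Receptive-field activation of every cluster for one stimulus."""
    if state.n_clusters == 0:
        raise NoClustersError("state holds no clusters")
    x = np.asarray(stimulus, dtype=float)
    mu = np.abs(state.centers - x[None, :])          # (n_clusters, n_dims)
    lam = state.lam
    num = (lam**params.r)[None, :] * np.exp(-lam[None, :] * mu)
    return num.sum(axis=1) / (lam**params.r).sum()


def _outputs(stimulus, state, params, winner=None):
    act = cluster_activation(stimulus, state, params)
    if winner is None:
        # ties go to the most recently recruited cluster: with discrete
        # stimuli a fresh cluster can sit exactly on an older one, and the
        # newer cluster carries the associations learned for the current
        # problem; preferring the older one would trigger a recruitment
        # on every later encounter.  Still fully deterministic.
        winner = int(len(act) - 1 - np.argmax(act[::-1]))
    with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
        ratio = act[winner] ** params.beta / np.sum(act**params.beta)
    if not np.isfinite(ratio):  # all activations underflow at extreme beta
        ratio = 1.0
    out_win = ratio * act[winner]
    c_out = state.assoc[winner] * out_win  # category outputs (A, B)
    return act, winner, out_win, c_out


def respond(stimulus, state: SustainState, params: SustainParams):
    """Probability of responding "A" and the winning cluster's index.

    The winner is the most active cluster; exact activation ties break
    toward the most recently recruited cluster (see :func:`_outputs`).
    """
    _, winner, _, c_out = _outputs(stimulus, state, params)
    z = params.d * c_out
    z = z - z.max()
    e = np.exp(z)
    prob_a = float(e[0] / e.sum())
    return prob_a, winner


def learn_trial(trial, state: SustainState, params: SustainParams) -> SustainState:
    """Apply one feedback trial; returns the updated state.

    A new cluster centered on the stimulus is recruited when there is no
    cluster yet, or when the winner predicts the wrong category; otherwise
    the winner's center, the tunings and the winner's associations are
    updated.
    """
    if not trial.feedback:
        raise ValueError("learn_trial requires a trial with feedback shown")
    if trial.correct_label not in CATEGORIES:
        raise ValueError(f"trial carries no valid correct label: {trial.correct_label!r}")
    state = state.copy()
    x = np.asarray(trial.features, dtype=float)
    target_idx = CATEGORIES.index(trial.correct_label)

    recruit = state.n_clusters == 0
    if not recruit:
        _, winner, out_win, c_out = _outputs(x, state, params)
        predicted = int(np.argmax(c_out)) if abs(c_out[0] - c_out[1]) > 1e-12 else -1
        recruit = predicted != target_idx
    if recruit:
        state.centers = np.vstack([state.centers, x[None, :]])
        state.assoc = np.vstack([state.assoc, np.zeros((1, 2))])
        # the freshly recruited cluster is the winner by construction
        _, winner, out_win, c_out = _outputs(x, state, params, winner=state.n_clusters - 1)

    mu_win = np.abs(state.centers[winner] - x)
    # humble teacher: no error once the correct output exceeds +1 / wrong < -1
    teacher = np.where(
        np.arange(2) == target_idx,
        np.maximum(c_out, 1.0),
        np.minimum(c_out, -1.0),
    )
    state.assoc[winner] += params.eta * (teacher - c_out) * out_win
    state.lam = state.lam + params.eta * np.exp(-state.lam * mu_win) * (1.0 - state.lam * mu_win)
    state.lam = np.maximum(state.lam, 1e-6)
    state.centers[winner] += params.eta * (x - state.centers[winner])
    return state


def run_sequence(
    trials: Sequence,
    params: SustainParams,
    initial_state: Optional[SustainState] = None,
):
    """Run SUSTAIN over a chronologically ordered trial list.

    Returns ``(final_state, trial_log_liks, lam_trajectory)``.  The
    response probability entering the likelihood is computed from the
    pre-update state (a guess probability of 0.5 before any cluster
    exists); the tuning trajectory records lambda after each trial's
    update.  Chaining two problem sequences via `initial_state` is
    identical to running their concatenation.
    """
    _check_ordering(trials)
    if initial_state is None:
        n_dims = len(trials[0].features) if trials else 0
        state = SustainState.initial(n_dims)
    else:
        state = initial_state.copy()
    log_liks = []
    lam_traj = []
    for t in trials:
        if t.response is not None:
            try:
                p_a, _ = respond(t.features, state, params)
            except NoClustersError:
                p_a = 0.5
            p = p_a if t.response == "A" else 1.0 - p_a
            log_liks.append(float(np.log(max(p, 1e-12))))
        else:
            log_liks.append(0.0)
        if t.feedback:
            state = learn_trial(t, state, params)
        lam_traj.append(state.lam.copy())
    if lam_traj:
        lam_traj = np.vstack(lam_traj)
    else:
        lam_traj = np.zeros((0, state.lam.shape[0]))
    return state, np.array(log_liks), lam_traj


def carryover_state(state: SustainState, mode: str = "tunings") -> SustainState:
    """Initial state for the next problem in a chain.

    ``"tunings"`` (default) carries the attention tunings lambda forward
    but lets the new problem build its own cluster solution; ``"full"``
    carries clusters, associations and tunings unchanged.  Full carryover
    after a problem that forces stimulus memorization leaves a cluster
    sitting exactly on every stimulus, so every later winner has zero
    distance on every dimension and the tuning profile can no longer
    differentiate between rules; carrying the tunings alone preserves
    cross-task influence while keeping each task's attention profile
    expressive of that task's diagnostic dimensions.
    """
    if mode == "full":
        return state.copy()
    if mode == "tunings":
        fresh = SustainState.initial(state.lam.shape[0])
        fresh.lam = state.lam.copy()
        return fresh
    raise ValueError(f"unknown carryover mode {mode!r}")


def _check_ordering(trials) -> None:
    last = {}
    for t in trials:
        key = (t.problem,)
        pos = (t.run, t.trial)
        if key in last and pos < last[key]:
            raise ValueError(f"trials of problem {t.problem!r} are not chronologically ordered")
        last[key] = pos


def extract_attention(lam_trajectory: np.ndarray, window) -> np.ndarray:
    """Attention profile: mean lambda over a trial window, normalized to the simplex.

    `window` is a (start, stop) pair of 0-based trial offsets (stop
    exclusive), e.g. the trials of the last two runs of a problem.  The
    profile is invariant to rescaling all lambdas by a constant.
    """
    start, stop = window
    if stop <= start or start < 0 or stop > lam_trajectory.shape[0]:
        raise ValueError(f"empty or out-of-range window {window!r}")
    mean_lam = lam_trajectory[start:stop].mean(axis=0)
    return mean_lam / mean_lam.sum()
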