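"""Generalized Context Model (GCM): attention-weighted exemplar similarity.

The GCM stores category exemplars and classifies a probe by its summed
similarity to each category.  Attention weights ``w`` (a point on the
simplex) scale each dimension's contribution to psychological distance:
relevant dimensions are stretched, irrelevant ones compressed.  For the
separable binary-dimension stimuli used here the conventional form is the
city-block metric (r = 1) with an exponential similarity kernel:

    d(x, y)   = sum_k w_k |x_k - y_k|
    s(x, y)   = exp(-c * d(x, y))
    P(A | x)  = S_A**gamma / (S_A**gamma + S_B**gamma)

with sensitivity ``c > 0``, response scaling ``gamma > 0`` and summed
category similarities S_A, S_B.  No response-bias parameter is included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GCMParams", "distance", "similarity", "choice_prob", "log_likelihood"]

SIMPLEX_TOL = 1e-10
PROB_CLIP = 1e-12


def _check_simplex(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if (w < -SIMPLEX_TOL).any() or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"attention weights must lie on the simplex; got {w}")
    return w


@dataclass(frozen=True)
class GCMParams:
    """GCM parameters: sensitivity c, attention simplex w, response scaling gamma."""

    c: float
    w: tuple
    gamma: float = 1.0
    metric_order: int = field(default=1)  # city-block; fixed

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("sensitivity c must be positive")
        if self.gamma <= 0:
            raise ValueError("response scaling gamma must be positive")
        w = _check_simplex(np.asarray(self.w, dtype=float))
        object.__setattr__(self, "w", tuple(float(v) for v in w))

    def to_dict(self) -> dict:
        return {"c": self.c, "w": list(self.w), "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: dict) -> "GCMParams":
        return cls(c=float(d["c"]), w=tuple(d["w"]), gamma=float(d.get("gamma", 1.0)))


def distance(x, y, w) -> float:
    """Attention-weighted city-block distance between two feature vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    w = _check_simplex(w)
    if w.shape != x.shape:
        raise ValueError("attention vector length must match feature vectors")
    return float(np.sum(w * np.abs(x - y)))


def similarity(d: float, c: float) -> float:
    """Exponential similarity kernel exp(-c d)."""
    if c <= 0:
        raise ValueError("sensitivity c must be positive")
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return float(np.exp(-c * d))


def _summed_similarities(stimulus, exemplars, labels, params: GCMParams):
    x = np.asarray(stimulus, dtype=float)
    ex = np.asarray(exemplars, dtype=float)
    w = np.asarray(params.w)
    d = np.abs(ex - x[None, :]) @ w
    s = np.exp(-params.c * d)
    labels = np.asarray(labels)
    s_a = float(s[labels == "A"].sum())
    s_b = float(s[labels == "B"].sum())
    return s_a, s_b


def choice_prob(stimulus, exemplars, labels, params: GCMParams) -> float:
    """Probability of responding "A" to `stimulus` given labeled exemplars.

    Luce choice over gamma-scaled summed similarities.  The exemplar set
    must contain at least one member of each category (the nine 5/4
    training items, in the packaged design).
    """
    labels_arr = np.asarray(labels)
    if (labels_arr == "A").sum() == 0 or (labels_arr == "B").sum() == 0:
        raise ValueError("exemplar set must contain at least one A and one B member")
    s_a, s_b = _summed_similarities(stimulus, exemplars, labels, params)
    denom = s_a**params.gamma + s_b**params.gamma
    if denom <= 0:  # unreachable for the exponential kernel; guarded anyway
        return 0.5
    return float(s_a**params.gamma / denom)


def choice_prob_table(structure, params: GCMParams, problem: str = "5_4") -> np.ndarray:
    """P(A) for every stimulus in `structure`, memory set = training items."""
    exemplars, labels = structure.exemplar_set(problem)
    return np.array(
        [choice_prob(s, exemplars, labels, params) for s in structure.stimuli]
    )


def log_likelihood(trials, structure, params: GCMParams, problem: str = "5_4") -> float:
    """Summed log probability of the observed responses of one participant.

    Response probabilities are clipped at 1e-12 so a forced-impossible
    response cannot produce an infinite penalty.
    """
    table = choice_prob_table(structure, params, problem)
    ll = 0.0
    for t in trials:
        if t.response is None:
            continue
        if not 0 <= t.stimulus_index < structure.n_stimuli:
            raise ValueError(f"trial stimulus index {t.stimulus_index} not in structure")
        p_a = table[t.stimulus_index]
        p = p_a if t.response == "A" else 1.0 - p_a
        ll += float(np.log(max(p, PROB_CLIP)))
    return ll
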