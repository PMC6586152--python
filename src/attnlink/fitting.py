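"""Maximum-likelihood fitting of the categorization models via a genetic algorithm.

Both models are fit per participant by maximizing the likelihood of the
observed trial-by-trial choices.  Parameters live on an unconstrained
genome: box-bounded parameters pass through a scaled logistic, and the GCM
attention simplex through a softmax, so every genome decodes to a valid
parameter set.  The GA is strictly elitist (the best individual always
survives), uses tournament selection, uniform crossover and Gaussian
mutation on the unconstrained scale, and is restarted from several seeds
with the best run reported.

For SUSTAIN, one learning-parameter set is fit jointly across the whole
problem chain (the state at the end of one problem seeds the next).  Once
fit, the parameters are frozen and the tuning trajectories are replayed to
extract per-problem attention profiles from the late learning window (the
last two runs of each problem, where behavior has largely stabilized).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import gcm as gcm_mod
from . import sustain as sustain_mod
from .gcm import GCMParams
from .structures import TrialRecord
from .sustain import SustainParams, SustainState

__all__ = [
    "GAConfig",
    "FitResult",
    "ga_minimize",
    "fit_gcm",
    "fit_sustain_chain",
    "GCMEstimator",
    "SustainEstimator",
    "DEFAULT_GCM_BOUNDS",
    "DEFAULT_SUSTAIN_BOUNDS",
]

DEFAULT_GCM_BOUNDS = {"c": (0.1, 20.0), "gamma": (0.1, 10.0)}
DEFAULT_SUSTAIN_BOUNDS = {
    "r": (0.5, 20.0),
    "beta": (0.0, 20.0),
    "d": (0.5, 30.0),
    "eta": (0.01, 1.0),
}


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; defaults chosen for desk-scale reliability."""

    population: int = 100
    generations: int = 200
    tournament_k: int = 3
    mutation_sigma: float = 0.1
    crossover_rate: float = 0.9
    elitism: int = 1
    n_starts: int = 5

    def small(self) -> "GAConfig":
        """A reduced-budget configuration for simulation studies and tests."""
        return replace(self, population=24, generations=40, n_starts=2)


@dataclass
class FitResult:
    """Best parameters, negative log-likelihood and attention profiles."""

    participant: str
    model: str
    params: dict
    nll: float
    attention: dict            # rule name -> attention weights (simplex)
    ga: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "participant": self.participant,
            "model": self.model,
            "params": self.params,
            "nll": self.nll,
            "attention": {k: list(map(float, v)) for k, v in self.attention.items()},
            "ga": self.ga,
        }


def _bounded(z: float, lo: float, hi: float) -> float:
    return lo + (hi - lo) * expit(z)


def ga_minimize(
    objective: Callable[[np.ndarray], float],
    n_genes: int,
    config: GAConfig,
    seed: int,
):
    """Minimize `objective` over R^n_genes; returns (best_genome, best_value, history).

    `history` is the per-generation best value; elitism makes it
    non-increasing.  Multi-start behavior is handled by the caller.
    """
    rng = np.random.default_rng(seed)

    raw_objective = objective

    def objective(genome):  # non-finite objective values lose outright
        value = raw_objective(genome)
        return float(value) if np.isfinite(value) else np.inf

    pop = rng.normal(0.0, 1.0, size=(config.population, n_genes))
    fitness = np.array([objective(g) for g in pop])
    history = []
    for _ in range(config.generations):
        order = np.argsort(fitness)
        elite = pop[order[: config.elitism]]
        children = [e.copy() for e in elite]
        while len(children) < config.population:
            i = rng.integers(0, config.population, size=config.tournament_k)
            p1 = pop[i[np.argmin(fitness[i])]]
            j = rng.integers(0, config.population, size=config.tournament_k)
            p2 = pop[j[np.argmin(fitness[j])]]
            child = p1.copy()
            if rng.random() < config.crossover_rate:
                mask = rng.random(n_genes) < 0.5
                child[mask] = p2[mask]
            child += rng.normal(0.0, config.mutation_sigma, size=n_genes)
            children.append(child)
        pop = np.array(children)
        fitness = np.array([objective(g) for g in pop])
        # elitist guarantee: elite individuals were copied unmutated
        history.append(float(fitness.min()))
    best = int(np.argmin(fitness))
    return pop[best], float(fitness[best]), np.array(history)


def _multi_start(objective, n_genes, config: GAConfig, seed: int):
    children = np.random.SeedSequence(seed).spawn(config.n_starts)
    best = (None, np.inf, None)
    for ss in children:
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        genome, value, hist = ga_minimize(objective, n_genes, config, sub_seed)
        if value < best[1]:
            best = (genome, value, hist)
    return best


# --- GCM ---------------------------------------------------------------------


def _gcm_decode(genome: np.ndarray, n_dims: int, bounds: dict) -> GCMParams:
    wz = genome[:n_dims] - genome[:n_dims].max()
    w = np.exp(wz)
    w = w / w.sum()
    c = _bounded(genome[n_dims], *bounds["c"])
    gamma = _bounded(genome[n_dims + 1], *bounds["gamma"])
    return GCMParams(c=c, w=tuple(w), gamma=gamma)


def _gcm_counts(trials, n_stimuli: int):
    """Per-stimulus counts of A responses and of responded trials."""
    n_a = np.zeros(n_stimuli)
    n_tot = np.zeros(n_stimuli)
    for t in trials:
        if t.response is None:
            continue
        n_tot[t.stimulus_index] += 1
        if t.response == "A":
            n_a[t.stimulus_index] += 1
    return n_a, n_tot


def fit_gcm(
    trials,
    structure,
    ga_config: Optional[GAConfig] = None,
    seed: int = 0,
    problem: str = "5_4",
    bounds: Optional[dict] = None,
) -> FitResult:
    """Fit GCM (c, w, gamma) to one participant's choices by maximum likelihood."""
    config = ga_config or GAConfig()
    bounds = bounds or DEFAULT_GCM_BOUNDS
    n_dims = structure.n_dims
    exemplars, labels = structure.exemplar_set(problem)
    labels_arr = np.asarray(labels)
    is_a = labels_arr == "A"
    n_a, n_tot = _gcm_counts(trials, structure.n_stimuli)
    responded = [t for t in trials if t.response is not None]
    if responded and len({t.response for t in responded}) == 1:
        warnings.warn("degenerate behavior: all responses identical; fit proceeds")
    ex = np.asarray(exemplars, dtype=float)
    stim = np.asarray(structure.stimuli, dtype=float)
    absdiff = np.abs(stim[:, None, :] - ex[None, :, :])  # (n_stim, n_ex, n_dims)

    def nll(genome):
        p = _gcm_decode(genome, n_dims, bounds)
        d = absdiff @ np.asarray(p.w)
        s = np.exp(-p.c * d)
        s_a = s[:, is_a].sum(axis=1) ** p.gamma
        s_b = s[:, ~is_a].sum(axis=1) ** p.gamma
        p_a = np.clip(s_a / (s_a + s_b), gcm_mod.PROB_CLIP, 1 - gcm_mod.PROB_CLIP)
        return -float(n_a @ np.log(p_a) + (n_tot - n_a) @ np.log(1 - p_a))

    genome, value, hist = _multi_start(nll, n_dims + 2, config, seed)
    params = _gcm_decode(genome, n_dims, bounds)
    participant = trials[0].participant if trials else "unknown"
    return FitResult(
        participant=participant,
        model="gcm",
        params=params.to_dict(),
        nll=value,
        attention={problem: np.asarray(params.w)},
        ga={
            "population": config.population,
            "generations": config.generations,
            "n_starts": config.n_starts,
            "seed": seed,
            "history": hist.tolist(),
        },
    )


# --- SUSTAIN -----------------------------------------------------------------


def _sustain_decode(genome: np.ndarray, bounds: dict) -> SustainParams:
    names = ("r", "beta", "d", "eta")
    vals = {n: _bounded(genome[i], *bounds[n]) for i, n in enumerate(names)}
    return SustainParams(**vals)


def _late_window(trials, n_late_runs: int = 2):
    """(start, stop) offsets of the trials in the last `n_late_runs` runs."""
    runs = sorted({t.run for t in trials})
    late = set(runs[-n_late_runs:])
    idx = [i for i, t in enumerate(trials) if t.run in late]
    return idx[0], idx[-1] + 1


def replay_attention(
    trials_by_problem: dict,
    params: SustainParams,
    n_late_runs: int = 2,
    carryover: str = "tunings",
) -> dict:
    """Replay the chain under frozen parameters; extract late-window attention."""
    state = None
    profiles = {}
    for problem, trials in trials_by_problem.items():
        if state is not None:
            state = sustain_mod.carryover_state(state, carryover)
        state, _, lam_traj = sustain_mod.run_sequence(trials, params, state)
        profiles[problem] = sustain_mod.extract_attention(
            lam_traj, _late_window(trials, n_late_runs)
        )
    return profiles


def fit_sustain_chain(
    trials_by_problem: dict,
    ga_config: Optional[GAConfig] = None,
    seed: int = 0,
    bounds: Optional[dict] = None,
    n_late_runs: int = 2,
    carryover: str = "tunings",
) -> FitResult:
    """Fit one SUSTAIN learning-parameter set jointly over a problem chain.

    `trials_by_problem` maps problem name -> ordered trial list, in the
    order the participant experienced the problems (Type VI first in the
    packaged design).  `carryover` controls what crosses a problem
    boundary (see :func:`attnlink.sustain.carryover_state`).  Attention
    profiles are extracted per problem from the late window after
    freezing the fitted parameters.
    """
    config = ga_config or GAConfig()
    bounds = bounds or DEFAULT_SUSTAIN_BOUNDS
    if not trials_by_problem or any(len(v) == 0 for v in trials_by_problem.values()):
        raise ValueError("every problem in the chain needs a nonempty trial list")

    def nll(genome):
        params = _sustain_decode(genome, bounds)
        state = None
        total = 0.0
        for trials in trials_by_problem.values():
            if state is not None:
                state = sustain_mod.carryover_state(state, carryover)
            state, lls, _ = sustain_mod.run_sequence(trials, params, state)
            total += lls.sum()
        return -float(total)

    genome, value, hist = _multi_start(nll, 4, config, seed)
    params = _sustain_decode(genome, bounds)
    profiles = replay_attention(trials_by_problem, params, n_late_runs, carryover)
    first = next(iter(trials_by_problem.values()))
    return FitResult(
        participant=first[0].participant,
        model="sustain",
        params=params.to_dict(),
        nll=value,
        attention=profiles,
        ga={
            "population": config.population,
            "generations": config.generations,
            "n_starts": config.n_starts,
            "seed": seed,
            "history": hist.tolist(),
        },
    )


# --- sklearn-style estimators ------------------------------------------------


class GCMEstimator(BaseEstimator):
    """GCM as a probabilistic classifier fit by GA maximum likelihood.

    Parameters
    ----------
    structure : CategoryStructure
        Supplies the exemplar memory set (training items of `problem`).
    problem : str
        Labeling name within the structure.
    ga_config : GAConfig or None
    seed : int

    Attributes (after fit)
    ----------------------
    c_, w_, gamma_ : fitted parameters (w_ on the simplex)
    nll_ : best negative log-likelihood
    result_ : full :class:`FitResult`
    """

    def __init__(self, structure=None, problem="5_4", ga_config=None, seed=0):
        self.structure = structure
        self.problem = problem
        self.ga_config = ga_config
        self.seed = seed

    def fit(self, X, y, participant="sim"):
        """Fit to trials given stimulus feature rows X and responses y ('A'/'B')."""
        X = np.asarray(X, dtype=int)
        trials = []
        index = {tuple(s): i for i, s in enumerate(self.structure.stimuli)}
        for i, (row, resp) in enumerate(zip(X, y)):
            trials.append(
                TrialRecord(
                    participant=participant, problem=self.problem, run=1, trial=i + 1,
                    stimulus_index=index[tuple(row)], features=tuple(row), response=str(resp),
                )
            )
        self.result_ = fit_gcm(
            trials, self.structure, ga_config=self.ga_config, seed=self.seed,
            problem=self.problem,
        )
        p = GCMParams.from_dict(self.result_.params)
        self.c_, self.w_, self.gamma_ = p.c, np.asarray(p.w), p.gamma
        self.nll_ = self.result_.nll
        return self

    def predict_proba(self, X):
        p = GCMParams.from_dict(self.result_.params)
        exemplars, labels = self.structure.exemplar_set(self.problem)
        pa = np.array([gcm_mod.choice_prob(x, exemplars, labels, p) for x in np.asarray(X)])
        return np.column_stack([pa, 1 - pa])

    def predict(self, X):
        return np.where(self.predict_proba(X)[:, 0] >= 0.5, "A", "B")


class SustainEstimator(BaseEstimator):
    """SUSTAIN chain fit as an estimator; fit consumes a problem->trials map.

    Attributes (after fit): ``params_`` (SustainParams), ``nll_``,
    ``attention_profiles_`` (problem -> simplex weights), ``result_``.
    """

    def __init__(self, ga_config=None, seed=0, n_late_runs=2):
        self.ga_config = ga_config
        self.seed = seed
        self.n_late_runs = n_late_runs

    def fit(self, trials_by_problem, y=None):
        self.result_ = fit_sustain_chain(
            trials_by_problem, ga_config=self.ga_config, seed=self.seed,
            n_late_runs=self.n_late_runs,
        )
        self.params_ = SustainParams.from_dict(self.result_.params)
        self.nll_ = self.result_.nll
        self.attention_profiles_ = self.result_.attention
        return self
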