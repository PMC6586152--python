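"""Synthetic participants and synthetic neural data with attention-scaled signal.

The generator emulates the two study designs end to end:

* behavioral choices sampled from a known model — GCM with attention
  weights drawn from a Dirichlet over the simplex (5/4 design), or
  SUSTAIN learners run through the Type VI -> I/II problem chain (SHJ
  design) — with the true attention profile recorded per participant
  (and per rule for SUSTAIN);
* trial-by-unit activity patterns in which each binary feature is carried
  by a dedicated selectivity map (random sign patterns over units,
  orthogonalized across dimensions and scaled to unit norm) whose
  amplitude is the coupling strength kappa times that participant's
  attention weight on the feature, plus Gaussian noise.  This makes the
  hypothesis under test — more-attended features are more decodable — the
  generative ground truth, with kappa = 0 as the exact null;
* optionally, BOLD time series per run: double-gamma HRF-convolved trial
  amplitudes on a 2-s TR grid with AR(1) noise, for exercising the
  single-trial (LSS) estimation path.

Pattern runs are balanced by construction: 5/4 pattern runs are built
from complementary stimulus pairs so every binary feature splits 50/50
within every run; SHJ runs contain all eight stimuli and are balanced
automatically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import gcm as gcm_mod
from . import structures as st
from . import sustain as su
from .neuro import TrialPatternMatrix

__all__ = [
    "SynthConfig",
    "simulate_participants",
    "simulate_patterns",
    "simulate_bold",
    "simulate_bold_session",
    "balanced_5_4_scan",
    "shj_problem_trials",
]

#: coupling strength (signal amplitude per unit attention weight, in noise-SD
#: units) calibrated once so that the linking slope of decoding accuracy on
#: attention weight is about 0.08 under the default configuration.
DEFAULT_KAPPA = 0.8


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort."""

    n_participants: int = 20
    model: str = "gcm"                     # "gcm" or "sustain"
    dirichlet_alpha: float = 1.0           # concentration of the attention law
    gcm_c: float = 4.0                     # generating sensitivity
    gcm_gamma: float = 1.0
    sustain_params: dict = field(default_factory=lambda: {
        # in the range typical of fits to the six classic problems
        "r": 9.0, "beta": 1.25, "d": 16.9, "eta": 0.092,
    })
    n_behavior_reps: int = 18              # stimulus repetitions for GCM behavior (18*16=288)
    runs: int = 5                          # pattern runs
    trials_per_run: int = 16
    shj_runs_per_problem: int = 4
    sustain_carryover: str = "tunings"     # what crosses problem boundaries
    kappa: float = DEFAULT_KAPPA           # signal per unit attention weight
    sigma: float = 1.0                     # unit noise SD (white for direct patterns)
    n_units: int = 100
    hrf: bool = False
    tr: float = 2.0
    stim_duration: float = 3.5
    iti_range: tuple = (4.0, 8.0)
    ar_rho: float = 0.12                   # AR(1) coefficient for BOLD noise
    seed: int = 0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.model not in ("gcm", "sustain"):
            raise ValueError("model must be 'gcm' or 'sustain'")


@dataclass
class SimulatedCohort:
    """Output of :func:`simulate_participants`."""

    participants: list
    trials: dict          # pid -> trials (gcm) or {problem: trials} (sustain)
    profiles: dict        # pid -> {rule: attention simplex}
    mappings: dict        # pid -> PerceptualMapping
    structure_name: str


def _participant_rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def balanced_5_4_scan(structure, n_runs: int, trials_per_run: int, rng,
                      participant: str = "sim") -> list:
    """Pattern-run builder for the 5/4 space with per-run feature balance.

    Runs are assembled from complementary stimulus pairs (a stimulus and
    its bitwise complement), so every binary dimension is split evenly
    within every run.  `trials_per_run` must be even.
    """
    if trials_per_run % 2:
        raise ValueError("trials_per_run must be even for balanced runs")
    stim = structure.stimuli
    index = {tuple(s): i for i, s in enumerate(stim)}
    pairs = []
    seen = set()
    for i, s in enumerate(stim):
        j = index[tuple(1 - s)]
        if i not in seen and j not in seen:
            pairs.append((i, j))
            seen |= {i, j}
    labels = structure.labels("5_4")
    trials = []
    pairs_per_run = trials_per_run // 2
    for run in range(1, n_runs + 1):
        chosen = [pairs[k] for k in rng.choice(len(pairs), size=pairs_per_run, replace=True)]
        order = rng.permutation([i for pr in chosen for i in pr])
        for pos, sidx in enumerate(order):
            trials.append(st.TrialRecord(
                participant=participant, problem="5_4", run=run, trial=pos + 1,
                stimulus_index=int(sidx), features=tuple(int(v) for v in stim[sidx]),
                correct_label=labels[sidx], feedback=False,
            ))
    return trials


def shj_problem_trials(structure, problem: str, n_runs: int, rng,
                       participant: str = "sim") -> list:
    """`n_runs` SHJ learning runs (32 trials each) with 1-based run numbers."""
    trials = []
    for run in range(1, n_runs + 1):
        run_seed = int(rng.integers(0, 2**31))
        block = st.build_trial_sequence(structure, "shj_run", run_seed,
                                        participant=participant, problem=problem)
        trials += [dataclasses.replace(t, run=run) for t in block]
    return trials


def _simulate_gcm_participant(structure, config, rng, pid):
    w = rng.dirichlet(np.full(structure.n_dims, config.dirichlet_alpha))
    params = gcm_mod.GCMParams(c=config.gcm_c, w=tuple(w), gamma=config.gcm_gamma)
    table = gcm_mod.choice_prob_table(structure, params)
    order = rng.permutation(np.repeat(np.arange(structure.n_stimuli), config.n_behavior_reps))
    trials = []
    for pos, sidx in enumerate(order):
        t = st.TrialRecord(
            participant=pid, problem="5_4", run=1 + pos // structure.n_stimuli,
            trial=1 + pos % structure.n_stimuli, stimulus_index=int(sidx),
            features=tuple(int(v) for v in structure.stimuli[sidx]),
            correct_label=structure.labels("5_4")[sidx], feedback=False,
        )
        resp = "A" if rng.random() < table[sidx] else "B"
        trials.append(t.with_response(resp))
    return trials, {"5_4": w}


def _simulate_sustain_participant(structure, config, rng, pid, order_flip):
    params = su.SustainParams.from_dict(config.sustain_params)
    problems = ["VI", "I", "II"] if not order_flip else ["VI", "II", "I"]
    state = su.SustainState.initial(structure.n_dims)
    trials_by_problem = {}
    profiles = {}
    for pos, problem in enumerate(problems):
        if pos > 0:
            state = su.carryover_state(state, config.sustain_carryover)
        trials = shj_problem_trials(structure, problem, config.shj_runs_per_problem,
                                    rng, participant=pid)
        answered = []
        lam_traj = []
        for t in trials:
            try:
                p_a, _ = su.respond(t.features, state, params)
            except su.NoClustersError:
                p_a = 0.5
            resp = "A" if rng.random() < p_a else "B"
            t = t.with_response(resp)
            state = su.learn_trial(t, state, params)
            lam_traj.append(state.lam.copy())
            answered.append(t)
        trials_by_problem[problem] = answered
        lam_traj = np.array(lam_traj)
        runs = sorted({t.run for t in answered})
        late = set(runs[-2:])
        idx = [i for i, t in enumerate(answered) if t.run in late]
        profiles[problem] = su.extract_attention(lam_traj, (idx[0], idx[-1] + 1))
    return trials_by_problem, profiles


def simulate_participants(structure, config: SynthConfig,
                          seed: Optional[int] = None) -> SimulatedCohort:
    """Simulate a cohort of behavioral participants with known attention.

    Returns trials with sampled responses, the true attention profile per
    participant (per rule for SUSTAIN, where the profile is the model's
    own late-window tuning profile), and each participant's random
    perceptual mapping.  Behavioral output does not depend on `kappa`.
    """
    seed = config.seed if seed is None else seed
    rngs = _participant_rngs(seed, config.n_participants)
    cohort = SimulatedCohort([], {}, {}, {}, structure.name)
    for i, rng in enumerate(rngs):
        pid = f"sub-{i + 1:02d}"
        cohort.participants.append(pid)
        cohort.mappings[pid] = st.random_mapping(structure, pid, rng)
        if config.model == "gcm":
            trials, profiles = _simulate_gcm_participant(structure, config, rng, pid)
        else:
            trials, profiles = _simulate_sustain_participant(
                structure, config, rng, pid, order_flip=bool(i % 2))
        cohort.trials[pid] = trials
        cohort.profiles[pid] = profiles
    return cohort


def _selectivity_maps(n_units: int, n_dims: int, rng) -> np.ndarray:
    """Unit-norm selectivity maps: orthogonalized random sign patterns."""
    signs = rng.choice((-1.0, 1.0), size=(n_units, n_dims))
    q, r = np.linalg.qr(signs)
    return q * np.sign(np.diag(r))[None, :]


def _pattern_matrix(trial_features, runs, w, config, rng, pid):
    features = np.asarray(trial_features, dtype=int)
    n_trials, n_dims = features.shape
    maps = _selectivity_maps(config.n_units, n_dims, rng)
    signed = 2.0 * features - 1.0                       # (n_trials, n_dims)
    amplitudes = signed * (config.kappa * np.asarray(w))[None, :]
    clean = amplitudes @ maps.T                          # (n_trials, n_units)
    noisy = clean + rng.normal(0.0, config.sigma, size=clean.shape)
    return TrialPatternMatrix(pid, noisy, np.asarray(runs), features), clean


def simulate_patterns(cohort: SimulatedCohort, structure, config: SynthConfig,
                      seed: Optional[int] = None) -> dict:
    """Trial-by-unit pattern matrices whose feature signal scales with attention.

    Returns ``{pid: {rule: TrialPatternMatrix}}``.  For the 5/4 design the
    pattern trials are a fresh balanced scan sequence; for the SHJ design
    they are the participant's own learning trials of each problem.
    """
    seed = (config.seed + 1) if seed is None else seed
    rngs = _participant_rngs(seed, len(cohort.participants))
    out = {}
    for rng, pid in zip(rngs, cohort.participants):
        out[pid] = {}
        if config.model == "gcm":
            trials = balanced_5_4_scan(structure, config.runs, config.trials_per_run,
                                       rng, participant=pid)
            w = cohort.profiles[pid]["5_4"]
            pm, _ = _pattern_matrix([t.features for t in trials],
                                    [t.run for t in trials], w, config, rng, pid)
            out[pid]["5_4"] = pm
        else:
            for rule, trials in cohort.trials[pid].items():
                w = cohort.profiles[pid][rule]
                pm, _ = _pattern_matrix([t.features for t in trials],
                                        [t.run for t in trials], w, config, rng, pid)
                out[pid][rule] = pm
    return out


# --- BOLD --------------------------------------------------------------------


def simulate_bold(amplitudes: np.ndarray, config: SynthConfig, rng):
    """One run of BOLD: HRF-convolved trial amplitudes plus AR(1) noise.

    `amplitudes` is (n_trials, n_units); trial onsets follow the packaged
    timing (3.5-s stimulus, jittered 4-8 s intertrial interval, TR 2 s).
    Returns ``(bold, events)`` with `events` holding onset and duration in
    seconds.
    """
    from .neuro import _boxcar_regressor

    n_trials, n_units = np.asarray(amplitudes).shape
    onsets = []
    t = 10.0
    for _ in range(n_trials):
        onsets.append(t)
        t += config.stim_duration + rng.uniform(*config.iti_range)
    n_scans = int(np.ceil((t + 20.0) / config.tr))
    X = np.column_stack([
        _boxcar_regressor(o, config.stim_duration, n_scans, config.tr) for o in onsets
    ])
    clean = X @ np.asarray(amplitudes, dtype=float)
    noise = rng.normal(0.0, 1.0, size=clean.shape)
    for i in range(1, n_scans):
        noise[i] = config.ar_rho * noise[i - 1] + noise[i] * np.sqrt(1 - config.ar_rho**2)
    bold = clean + config.sigma * noise
    events = pd.DataFrame({
        "onset": onsets,
        "duration": config.stim_duration,
        "trial": np.arange(1, n_trials + 1),
    })
    return bold, events


def simulate_bold_session(patterns: TrialPatternMatrix, config: SynthConfig,
                          seed: int = 0):
    """Per-run BOLD series for every run of a pattern matrix.

    Returns a list of ``(run_label, bold, events)`` triples; the noiseless
    trial amplitudes are the rows of `patterns.data` (use a small-sigma
    config and a clean matrix for recovery checks).
    """
    rng = np.random.default_rng(seed)
    out = []
    for run in np.unique(patterns.runs):
        sel = patterns.runs == run
        bold, events = simulate_bold(patterns.data[sel], config, rng)
        events["run"] = run
        out.append((int(run), bold, events))
    return out
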