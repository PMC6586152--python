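"""Stimulus spaces, category labelings and trial-sequence builders.

Two classic category-learning designs are packaged:

* the "5/4" problem (Medin & Schaffer): 16 stimuli over four binary
  dimensions, nine of which (five A, four B) are used in training while the
  remaining seven are transfer items with no trained label;
* the Shepard-Hovland-Jenkins (SHJ) problems over three binary dimensions,
  with the Type I (one relevant dimension), Type II (XOR of two dimensions)
  and Type VI (all dimensions relevant) labelings.

All modeling downstream operates on *abstract* dimensions.  The mapping of
abstract dimensions onto perceptual features (color/size/shape/position, or
legs/antennae/mandible) is participant-specific metadata carried by
:class:`PerceptualMapping`; it exists to decouple perceptual salience from
behavioral relevance and is only consumed by the synthetic-data generator
and by reporting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CategoryStructure",
    "PerceptualMapping",
    "TrialRecord",
    "StructureError",
    "load_structure",
    "apply_mapping",
    "random_mapping",
    "invert_mapping",
    "build_trial_sequence",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials_tsv",
    "read_trials_tsv",
]

FIVE_FOUR_FEATURES = ("color", "size", "shape", "position")
SHJ_FEATURES = ("legs", "antennae", "mandible")


class StructureError(ValueError):
    """Raised for unknown structures/designs or inconsistent mappings."""


@dataclass(frozen=True)
class CategoryStructure:
    """A binary stimulus space plus one or more category labelings.

    Parameters
    ----------
    name : str
        Structure identifier ("5_4" or "shj").
    stimuli : ndarray of shape (n_stimuli, n_dims)
        Binary feature vectors, one row per stimulus.
    stimulus_names : tuple of str
        Printed stimulus identifiers (A1..B4/T1..T7 or 1..8).
    labelings : dict
        Problem name -> tuple of labels in {"A", "B"} (None for transfer
        items that carry no trained label).
    roles : tuple of str
        Per stimulus: "training", "transfer" or "both".
    """

    name: str
    stimuli: np.ndarray
    stimulus_names: tuple
    labelings: dict
    roles: tuple

    @property
    def n_dims(self) -> int:
        return self.stimuli.shape[1]

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.shape[0]

    def training_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r in ("training", "both")])

    def transfer_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.roles) if r in ("transfer", "both")])

    def labels(self, problem: str) -> tuple:
        if problem not in self.labelings:
            raise StructureError(
                f"unknown problem {problem!r} for structure {self.name!r}; "
                f"available: {sorted(self.labelings)}"
            )
        return self.labelings[problem]

    def exemplar_set(self, problem: str):
        """Training feature vectors and their labels for `problem`."""
        idx = self.training_indices()
        labels = self.labels(problem)
        return self.stimuli[idx], tuple(labels[i] for i in idx)

    def __post_init__(self):
        stim = np.asarray(self.stimuli, dtype=int)
        if not np.isin(stim, (0, 1)).all():
            raise StructureError("stimulus features must be strictly binary")
        if len({tuple(row) for row in stim}) != len(stim):
            raise StructureError("stimulus vectors must be unique")
        object.__setattr__(self, "stimuli", stim)


@dataclass(frozen=True)
class PerceptualMapping:
    """Participant-specific bijection abstract dimension <-> perceptual feature.

    ``permutation[j]`` is the abstract dimension displayed by perceptual
    feature ``feature_names[j]``; ``polarity[j]`` flips that feature's
    binary coding when True.
    """

    participant: str
    permutation: tuple
    polarity: tuple
    feature_names: tuple

    def __post_init__(self):
        n = len(self.permutation)
        if sorted(self.permutation) != list(range(n)):
            raise StructureError("permutation must be a bijection over dimensions")
        if len(self.polarity) != n or len(self.feature_names) != n:
            raise StructureError("mapping fields must have equal lengths")


@dataclass
class TrialRecord:
    """One behavioral trial.

    Run and trial indices are 1-based in I/O (TSV) and in this record;
    internal array code uses 0-based offsets.  `response`, `accuracy` are
    None until a (simulated or real) choice is attached; `correct_label`
    is None for unlabeled transfer items.
    """

    participant: str
    problem: str
    run: int
    trial: int
    stimulus_index: int
    features: tuple
    response: Optional[str] = None
    correct_label: Optional[str] = None
    feedback: bool = False
    accuracy: Optional[int] = None

    def with_response(self, response: str) -> "TrialRecord":
        acc = None
        if self.correct_label is not None:
            acc = int(response == self.correct_label)
        return dataclasses.replace(self, response=response, accuracy=acc)


def _data_frame(fname: str) -> pd.DataFrame:
    with resources.files("attnlink.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_structure(name: str) -> CategoryStructure:
    """Load a packaged category structure by name ("5_4" or "shj")."""
    if name == "5_4":
        df, problems = _data_frame("structure_5_4.tsv"), ["5_4"]
    elif name == "shj":
        df, problems = _data_frame("structure_shj.tsv"), ["I", "II", "VI"]
    else:
        raise StructureError(f"unknown structure {name!r}; expected '5_4' or 'shj'")
    dim_cols = [c for c in df.columns if c.startswith("D")]
    stimuli = df[dim_cols].astype(int).to_numpy()
    labelings = {
        p: tuple(None if v == "-" else v for v in df[p]) for p in problems
    }
    return CategoryStructure(
        name=name,
        stimuli=stimuli,
        stimulus_names=tuple(df["stimulus"]),
        labelings=labelings,
        roles=tuple(df["role"]),
    )


def random_mapping(
    structure: CategoryStructure,
    participant: str,
    rng: np.random.Generator,
    feature_names: Optional[Sequence[str]] = None,
) -> PerceptualMapping:
    """Draw a participant's random perceptual mapping (permutation + polarity).

    For the SHJ structure, any bijection automatically satisfies the
    counterbalancing constraint that the perceptual feature irrelevant to
    the Type II (XOR) rule is the one relevant to the Type I rule, because
    in abstract coordinates both roles are played by dimension D1.
    """
    if feature_names is None:
        feature_names = FIVE_FOUR_FEATURES if structure.n_dims == 4 else SHJ_FEATURES
    if len(feature_names) != structure.n_dims:
        raise StructureError("feature_names length must equal n_dims")
    perm = tuple(int(i) for i in rng.permutation(structure.n_dims))
    polarity = tuple(bool(b) for b in rng.integers(0, 2, structure.n_dims))
    return PerceptualMapping(participant, perm, polarity, tuple(feature_names))


def apply_mapping(structure: CategoryStructure, mapping: PerceptualMapping) -> CategoryStructure:
    """Re-express a structure in a participant's perceptual coordinates.

    Dimensions are permuted and optionally bit-flipped; each stimulus keeps
    its identity, labels and role.
    """
    if len(mapping.permutation) != structure.n_dims:
        raise StructureError(
            f"mapping has {len(mapping.permutation)} dims, structure has {structure.n_dims}"
        )
    perm = np.array(mapping.permutation)
    flips = np.array(mapping.polarity, dtype=int)
    stimuli = structure.stimuli[:, perm] ^ flips[None, :]
    return dataclasses.replace(structure, stimuli=stimuli)


def invert_mapping(mapping: PerceptualMapping) -> PerceptualMapping:
    """The inverse mapping: applying a mapping then its inverse is identity."""
    n = len(mapping.permutation)
    inv = [0] * n
    for j, a in enumerate(mapping.permutation):
        inv[a] = j
    pol = tuple(bool(mapping.polarity[inv[a]]) for a in range(n))
    return PerceptualMapping(mapping.participant, tuple(inv), pol, mapping.feature_names)


DESIGNS = ("5_4_train", "5_4_scan", "shj_run")


def build_trial_sequence(
    structure: CategoryStructure,
    design: str,
    seed: int,
    participant: str = "sim",
    problem: Optional[str] = None,
) -> list:
    """Build a seeded trial sequence for one of the packaged designs.

    Designs
    -------
    ``5_4_train``
        Pre-scan training: 20 blocked repetitions of each of the 9 training
        items (each block is a shuffled pass through all nine), feedback on.
    ``5_4_scan``
        Six runs of eight trials; each of the 16 stimuli appears exactly
        three times overall, order uniformly random within the session;
        no feedback.
    ``shj_run``
        One SHJ learning run: 32 trials, four shuffled presentations of
        each of the eight stimuli, feedback on.  `problem` selects the
        labeling (I, II or VI).
    """
    rng = np.random.default_rng(seed)
    if design == "5_4_train":
        problem = problem or "5_4"
        labels = structure.labels(problem)
        train = structure.training_indices()
        order = np.concatenate([rng.permutation(train) for _ in range(20)])
        runs = np.ones(len(order), dtype=int)
        feedback = True
    elif design == "5_4_scan":
        problem = problem or "5_4"
        labels = structure.labels(problem)
        order = rng.permutation(np.repeat(np.arange(structure.n_stimuli), 3))
        runs = 1 + np.arange(len(order)) // 8
        feedback = False
    elif design == "shj_run":
        if problem is None:
            raise StructureError("shj_run requires a problem name (I, II or VI)")
        labels = structure.labels(problem)
        order = rng.permutation(np.repeat(np.arange(structure.n_stimuli), 4))
        runs = np.ones(len(order), dtype=int)
        feedback = True
    else:
        raise StructureError(f"unknown design {design!r}; expected one of {DESIGNS}")

    trials = []
    trial_in_run = {}
    for pos, stim in enumerate(order):
        run = int(runs[pos])
        trial_in_run[run] = trial_in_run.get(run, 0) + 1
        trials.append(
            TrialRecord(
                participant=participant,
                problem=problem,
                run=run,
                trial=trial_in_run[run],
                stimulus_index=int(stim),
                features=tuple(int(v) for v in structure.stimuli[stim]),
                correct_label=labels[stim],
                feedback=feedback,
            )
        )
    return trials


# --- TSV I/O -----------------------------------------------------------------

_TRIAL_COLUMNS = [
    "participant", "problem", "run", "trial", "stimulus_index",
    "features", "response", "correct_label", "feedback", "accuracy",
]


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append({
            "participant": t.participant,
            "problem": t.problem,
            "run": t.run,
            "trial": t.trial,
            "stimulus_index": t.stimulus_index + 1,  # 1-based in I/O
            "features": "".join(str(v) for v in t.features),
            "response": t.response if t.response is not None else "-",
            "correct_label": t.correct_label if t.correct_label is not None else "-",
            "feedback": int(t.feedback),
            "accuracy": t.accuracy if t.accuracy is not None else "-",
        })
    return pd.DataFrame(rows, columns=_TRIAL_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list:
    trials = []
    for _, r in df.iterrows():
        trials.append(
            TrialRecord(
                participant=str(r["participant"]),
                problem=str(r["problem"]),
                run=int(r["run"]),
                trial=int(r["trial"]),
                stimulus_index=int(r["stimulus_index"]) - 1,
                features=tuple(int(ch) for ch in str(r["features"])),
                response=None if str(r["response"]) == "-" else str(r["response"]),
                correct_label=None if str(r["correct_label"]) == "-" else str(r["correct_label"]),
                feedback=bool(int(r["feedback"])),
                accuracy=None if str(r["accuracy"]) == "-" else int(r["accuracy"]),
            )
        )
    return trials


def write_trials_tsv(trials: Sequence[TrialRecord], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


def read_trials_tsv(path) -> list:
    return frame_to_trials(pd.read_csv(path, sep="\t", dtype=str))
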