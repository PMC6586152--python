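"""Single-trial estimation and multivariate decoding of binary stimulus features.

The decoding pathway mirrors standard MVPA practice: single-trial response
estimates (t-statistic patterns from a least-squares-separate GLM, or
directly simulated trial-by-unit matrices) are classified with a linear
support vector classifier under leave-one-run-out cross-validation.
Features are standardized per fold using training-fold statistics only, so
no test-run information leaks into training.  A toy volumetric searchlight
and a group-level sign-flip permutation test (max-statistic familywise
control) complete the group analysis, and a t-threshold turns the group
map into a region of interest.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

__all__ = [
    "TrialPatternMatrix",
    "DecodingResult",
    "lss_estimate",
    "decode_feature",
    "searchlight",
    "signflip_test",
    "threshold_roi",
]


@dataclass
class TrialPatternMatrix:
    """Trials x units activity with run and per-dimension condition labels."""

    participant: str
    data: np.ndarray        # (n_trials, n_units)
    runs: np.ndarray        # (n_trials,) int run label
    conditions: np.ndarray  # (n_trials, n_dims) binary feature values

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.runs = np.asarray(self.runs, dtype=int)
        self.conditions = np.asarray(self.conditions, dtype=int)
        n = self.data.shape[0]
        if self.runs.shape[0] != n or self.conditions.shape[0] != n:
            raise ValueError("runs and conditions must have one entry per trial")
        if np.isnan(self.data).any():
            raise ValueError("pattern matrix contains missing entries")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]

    @property
    def n_dims(self) -> int:
        return self.conditions.shape[1]

    def save(self, path) -> None:
        """Write the array (.npy) plus a JSON sidecar with the labels."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        sidecar = {
            "participant": self.participant,
            "runs": self.runs.tolist(),
            "conditions": self.conditions.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "TrialPatternMatrix":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            participant=sidecar["participant"],
            data=data,
            runs=np.asarray(sidecar["runs"]),
            conditions=np.asarray(sidecar["conditions"]),
        )


@dataclass
class DecodingResult:
    """Cross-validated accuracy for one participant x dimension."""

    participant: str
    dimension: int
    accuracy: float
    fold_accuracies: dict      # run label -> accuracy on that held-out run
    n_folds: int
    scheme: str

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


# --- least-squares separate (LSS) -------------------------------------------


def _boxcar_regressor(onsets, duration, n_scans, tr, hrf_oversampling=16):
    """HRF-convolved boxcar sampled at the scan times."""
    from nilearn.glm.first_level import glover_hrf

    dt = tr / hrf_oversampling
    n_hi = n_scans * hrf_oversampling
    neural = np.zeros(n_hi)
    for onset in np.atleast_1d(onsets):
        a = int(round(onset / dt))
        b = int(round((onset + duration) / dt))
        neural[a:min(b, n_hi)] = 1.0
    hrf = glover_hrf(tr, oversampling=hrf_oversampling)
    conv = np.convolve(neural, hrf)[:n_hi]
    return conv[::hrf_oversampling]


def lss_estimate(bold: np.ndarray, events, tr: float = 2.0) -> np.ndarray:
    """Single-trial t-statistic patterns via the least-squares-separate GLM.

    For each trial a GLM is fit with one regressor for that trial, one for
    all other trials combined, a linear drift and an intercept; the
    returned row is the trial regressor's t statistic per unit.

    Parameters
    ----------
    bold : (n_scans, n_units) array for one run.
    events : DataFrame with `onset` and `duration` columns (seconds),
        chronologically ordered.
    """
    bold = np.asarray(bold, dtype=float)
    n_scans = bold.shape[0]
    onsets = np.asarray(events["onset"], dtype=float)
    durations = np.asarray(events["duration"], dtype=float)
    if (onsets + durations).max() > n_scans * tr:
        raise ValueError("events extend past the end of the time series")
    trial_regs = np.column_stack([
        _boxcar_regressor(o, d, n_scans, tr) for o, d in zip(onsets, durations)
    ])
    drift = np.linspace(-1, 1, n_scans)
    tmaps = np.empty((len(onsets), bold.shape[1]))
    for i in range(len(onsets)):
        others = trial_regs.sum(axis=1) - trial_regs[:, i]
        X = np.column_stack([trial_regs[:, i], others, drift, np.ones(n_scans)])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise np.linalg.LinAlgError(f"rank-deficient LSS design at trial {i + 1}")
        beta, _, _, _ = np.linalg.lstsq(X, bold, rcond=None)
        resid = bold - X @ beta
        dof = n_scans - X.shape[1]
        mse = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.maximum(mse * xtx_inv[0, 0], 1e-300))
        tmaps[i] = beta[0] / se
    return tmaps


# --- decoding ----------------------------------------------------------------


def _svc(C: float):
    return make_pipeline(StandardScaler(), LinearSVC(C=C))


def decode_feature(
    patterns: TrialPatternMatrix,
    dimension: int,
    C: float = 1.0,
    retain_runs: Optional[Sequence[int]] = None,
) -> DecodingResult:
    """Leave-one-run-out decoding of one binary feature dimension.

    Trains on all runs but the held-out one and tests on it, for every
    run; `retain_runs` restricts which held-out folds enter the reported
    mean (the late-learning analysis trains on all runs but reports only
    the last two).  Requires both feature values in every run.
    """
    y = patterns.conditions[:, dimension]
    runs = patterns.runs
    unique_runs = np.unique(runs)
    if unique_runs.size < 2:
        raise ValueError("leave-one-run-out decoding needs at least two runs")
    for r in unique_runs:
        if np.unique(y[runs == r]).size < 2:
            raise ValueError(f"run {r} contains a single class for dimension {dimension}")
    fold_acc = {}
    logo = LeaveOneGroupOut()
    for train, test in logo.split(patterns.data, y, groups=runs):
        clf = _svc(C)
        clf.fit(patterns.data[train], y[train])
        acc = float(np.mean(clf.predict(patterns.data[test]) == y[test]))
        fold_acc[int(runs[test][0])] = acc
    if retain_runs is not None:
        retained = {r: a for r, a in fold_acc.items() if r in set(retain_runs)}
        if not retained:
            raise ValueError("retain_runs matches no held-out fold")
        scheme = f"loro-{len(fold_acc)}fold-retain{sorted(retained)}"
    else:
        retained = fold_acc
        scheme = f"loro-{len(fold_acc)}fold"
    return DecodingResult(
        participant=patterns.participant,
        dimension=dimension,
        accuracy=float(np.mean(list(retained.values()))),
        fold_accuracies=retained,
        n_folds=len(fold_acc),
        scheme=scheme,
    )


# --- searchlight -------------------------------------------------------------


def _sphere_offsets(radius_mm: float, voxel_size) -> np.ndarray:
    vs = np.asarray(voxel_size, dtype=float)
    if radius_mm < 0:
        raise ValueError("radius must be nonnegative")
    max_off = np.floor(radius_mm / vs).astype(int)
    ranges = [np.arange(-m, m + 1) for m in max_off]
    grid = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.sqrt(((grid * vs) ** 2).sum(axis=1))
    offsets = grid[dist <= radius_mm + 1e-9]
    if len(offsets) == 0:
        raise ValueError("searchlight radius smaller than one voxel")
    return offsets


def searchlight(
    volume: np.ndarray,
    mask: np.ndarray,
    runs: np.ndarray,
    conditions: np.ndarray,
    radius_mm: float = 10.0,
    voxel_size=(3.0, 3.0, 3.0),
    C: float = 0.1,
    participant: str = "sim",
) -> np.ndarray:
    """Toy volumetric searchlight: per-voxel mean above-chance accuracy.

    `volume` is (nx, ny, nz, n_trials); for each in-mask center voxel the
    in-mask voxels whose centers fall within `radius_mm` (inclusive) form
    the sphere, every condition dimension is decoded leave-one-run-out,
    and accuracies are centered at chance (0.5) and averaged across
    dimensions.  Out-of-mask voxels hold NaN.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = _sphere_offsets(radius_mm, voxel_size)
    shape = np.array(mask.shape)
    out = np.full(mask.shape, np.nan)
    conditions = np.atleast_2d(conditions)
    if conditions.shape[0] != volume.shape[3]:
        conditions = conditions.T
    for center in np.argwhere(mask):
        vox = center[None, :] + offsets
        keep = ((vox >= 0) & (vox < shape[None, :])).all(axis=1)
        vox = vox[keep]
        vox = vox[mask[vox[:, 0], vox[:, 1], vox[:, 2]]]
        data = volume[vox[:, 0], vox[:, 1], vox[:, 2], :].T  # trials x voxels
        accs = []
        for k in range(conditions.shape[1]):
            pm = TrialPatternMatrix(participant, data, runs, conditions[:, [k]])
            accs.append(decode_feature(pm, 0, C=C).accuracy - 0.5)
        out[tuple(center)] = float(np.mean(accs))
    return out


# --- group inference ---------------------------------------------------------


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    n = maps.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def signflip_test(subject_maps, n_perm: int = 10000, seed: int = 0):
    """Group one-sample sign-flip permutation test with max-|t| FWE control.

    Returns ``(t_map, p_map)``: the observed one-sample t per voxel and
    the familywise-corrected p, the proportion of sign-flip null maxima
    (of |t| over voxels) at or above the observed |t|.  When all sign
    patterns can be enumerated within `n_perm`, the null is exhaustive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    maps = np.stack([np.asarray(m, dtype=float) for m in subject_maps])
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("sign-flip test needs at least two subjects")
    t_obs = _one_sample_t(maps)
    flat = maps.reshape(n_sub, -1)
    if 2**n_sub <= n_perm:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n_sub)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n_sub))
    null_max = np.empty(len(signs))
    for i, s in enumerate(signs):
        null_max[i] = np.abs(_one_sample_t(flat * s[:, None])).max()
    p_map = (null_max[None, :] >= np.abs(t_obs).reshape(-1, 1) - 1e-12).mean(axis=1)
    return t_obs, p_map.reshape(t_obs.shape)


def threshold_roi(t_map: np.ndarray, min_t: float) -> np.ndarray:
    """Boolean ROI mask of voxels with t >= min_t (nested in the threshold)."""
    t_map = np.asarray(t_map, dtype=float)
    if not np.isfinite(t_map).all():
        raise ValueError("t-map must be finite")
    return t_map >= min_t


# --- volumetric interoperability --------------------------------------------


def patterns_from_nifti(img, mask_img, runs, conditions,
                        participant: str = "sub") -> TrialPatternMatrix:
    """Build a trial-pattern matrix from a 4D NIfTI image and an ROI mask.

    `img` / `mask_img` may be file paths or loaded nibabel images; the 4th
    axis of `img` indexes trials.  In-mask voxels become units.
    """
    import nibabel as nib

    if not hasattr(img, "get_fdata"):
        img = nib.load(str(img))
    if not hasattr(mask_img, "get_fdata"):
        mask_img = nib.load(str(mask_img))
    data4d = np.asarray(img.get_fdata())
    mask = np.asarray(mask_img.get_fdata()).astype(bool)
    if data4d.shape[:3] != mask.shape:
        raise ValueError("image and mask grids differ")
    data = data4d[mask].T  # (n_trials, n_voxels)
    return TrialPatternMatrix(participant, data, np.asarray(runs),
                              np.atleast_2d(conditions))


def patterns_to_nifti(patterns: TrialPatternMatrix, shape=None):
    """Export a pattern matrix as a 4D NIfTI image (units on a flat grid)."""
    import nibabel as nib

    n_units = patterns.n_units
    if shape is None:
        shape = (n_units, 1, 1)
    if int(np.prod(shape)) != n_units:
        raise ValueError("shape must hold exactly one voxel per unit")
    vol = patterns.data.T.reshape(*shape, patterns.n_trials)
    return nib.Nifti1Image(vol, affine=np.eye(4))
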