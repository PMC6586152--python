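"""Linking attention weights to decoding accuracy.

The headline analysis regresses feature decoding accuracy on the
model-derived attention weight for that feature, with mixed effects:
fixed terms for the intercept, the attention weight and each abstract
dimension (plus rule and run for the learning design), and random
intercept and attention slope per participant (plus run for the learning
design).  A positive slope means more-attended features are more
decodable.

Because slope estimates from a small cohort can be driven by group-level
structure, participant specificity is tested with a between-participant
permutation: whole attention-weight vectors are reassigned across
participants (dimension — and rule — correspondence preserved), the model
is refit per permutation, and the observed slope's percentile within the
permuted-slope null is reported.  A perceptual-salience control checks,
with a repeated-measures ANOVA over perceptual features (and a
BIC-approximated Bayes factor), that attention is not simply drawn to
salient features.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "LinkResult",
    "build_link_table",
    "fit_link_model",
    "ols_slope",
    "attention_shuffle_test",
    "salience_anova",
]

DESIGN_SPECS = {
    "5_4": {
        "formula": "accuracy ~ weight + C(dimension)",
        "re_formula": "~weight",
        "covariates": ["dimension"],
    },
    "shj": {
        "formula": "accuracy ~ weight + C(dimension) + C(rule) + run_c",
        "re_formula": "~weight + run_c",
        "covariates": ["dimension", "rule", "run_c"],
    },
}


@dataclass
class LinkResult:
    """Attention slope, parametric inference and (optionally) its permutation null."""

    slope: float
    se: float
    df: float
    ci: tuple
    p: float
    design: str
    n_participants: int
    singular_fallback: bool = False
    null: Optional[np.ndarray] = None
    percentile: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None
    engine: Optional[str] = None

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope, "se": self.se, "df": self.df,
            "ci": list(self.ci), "p": self.p, "design": self.design,
            "n_participants": self.n_participants,
            "singular_fallback": self.singular_fallback,
        }
        if self.null is not None:
            d.update(percentile=self.percentile, n_perm=self.n_perm,
                     seed=self.seed, engine=self.engine)
        return d

    def summary(self) -> str:
        lines = [
            f"attention slope b = {self.slope:.4f} (SE {self.se:.4f}), "
            f"95% CI [{self.ci[0]:.4f}, {self.ci[1]:.4f}], "
            f"t({self.df:.0f}), p = {self.p:.4f}",
        ]
        if self.percentile is not None:
            lines.append(
                f"permutation P = {self.percentile:.2f} "
                f"({self.n_perm} permutations, engine={self.engine}, seed={self.seed})"
            )
        return "\n".join(lines)


def build_link_table(profiles: dict, decoding: list, design: str,
                     per_run: Optional[bool] = None) -> pd.DataFrame:
    """Assemble the (participant, rule, dimension, run, weight, accuracy) table.

    `profiles` maps participant -> {rule: weight simplex}; `decoding` is a
    list of DecodingResult.  The 5/4 design uses fold-averaged accuracy
    (one row per participant x dimension); the learning design keeps one
    row per retained run.
    """
    if per_run is None:
        per_run = design == "shj"
    rows = []
    for res in decoding:
        rule = getattr(res, "rule", None) or ("5_4" if design == "5_4" else None)
        w = profiles[res.participant][rule][res.dimension]
        if per_run:
            for run, acc in res.fold_accuracies.items():
                rows.append(dict(participant=res.participant, rule=rule,
                                 dimension=res.dimension, run=run,
                                 weight=float(w), accuracy=acc))
        else:
            rows.append(dict(participant=res.participant, rule=rule,
                             dimension=res.dimension, run=None,
                             weight=float(w), accuracy=res.accuracy))
    return pd.DataFrame(rows)


def _prepare(table: pd.DataFrame, design: str) -> pd.DataFrame:
    if design not in DESIGN_SPECS:
        raise ValueError(f"unknown design {design!r}")
    df = table.copy()
    if design == "shj":
        if df["run"].isna().any():
            raise ValueError("the shj design needs per-run accuracies")
        df["run_c"] = df["run"].astype(float) - df["run"].astype(float).mean()
    return df


def _mixed_slope(df: pd.DataFrame, design: str):
    spec = DESIGN_SPECS[design]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(spec["formula"], df, groups=df["participant"],
                            re_formula=spec["re_formula"])
        try:
            res = model.fit(reml=True)
            ok = res.converged and np.isfinite(res.bse.get("weight", np.nan))
        except (np.linalg.LinAlgError, ValueError):
            ok = False
        if not ok:  # singular random-effects fit: drop the random slopes
            try:
                model = smf.mixedlm(spec["formula"], df, groups=df["participant"],
                                    re_formula="~1")
                res = model.fit(reml=True)
            except (np.linalg.LinAlgError, ValueError):
                # fully degenerate (e.g. zero residual variance): the
                # zero-random-variance limit is plain OLS
                res = smf.ols(spec["formula"], df).fit()
            return res, True
    return res, False


def fit_link_model(table: pd.DataFrame, design: str, n_boot: int = 0,
                   seed: int = 0) -> LinkResult:
    """REML mixed-effects fit; returns the attention slope and its inference.

    The parametric t uses a between-cluster degrees of freedom
    (n_participants - 1).  With `n_boot` > 0, the CI is a participant-level
    (cluster) bootstrap percentile interval; otherwise a Wald interval.
    """
    df = _prepare(table, design)
    n_sub = df["participant"].nunique()
    if n_sub < 5:
        raise ValueError("the linking model needs at least 5 participants")
    res, fallback = _mixed_slope(df, design)
    slope = float(res.params["weight"])
    se = float(res.bse["weight"])
    ddf = float(n_sub - 1)
    from scipy import stats as sps
    tval = slope / se if se > 0 else np.inf
    p = float(2 * sps.t.sf(abs(tval), ddf))
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pids = df["participant"].unique()
        boots = []
        for _ in range(n_boot):
            chosen = rng.choice(pids, size=len(pids), replace=True)
            parts = [df[df["participant"] == p_].assign(participant=f"b{j}")
                     for j, p_ in enumerate(chosen)]
            bdf = pd.concat(parts, ignore_index=True)
            try:
                bres, _ = _mixed_slope(bdf, design)
                boots.append(float(bres.params["weight"]))
            except (np.linalg.LinAlgError, ValueError):
                continue
        ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    else:
        half = sps.t.ppf(0.975, ddf) * se
        ci = (slope - half, slope + half)
    return LinkResult(slope=slope, se=se, df=ddf, ci=ci, p=p, design=design,
                      n_participants=n_sub, singular_fallback=fallback)


# --- fast OLS statistic ------------------------------------------------------


def _covariate_matrix(df: pd.DataFrame, design: str,
                      participant_intercepts: bool) -> np.ndarray:
    cols = [np.ones(len(df))]
    for cov in DESIGN_SPECS[design]["covariates"]:
        if cov == "run_c":
            cols.append(df["run_c"].to_numpy(float))
        else:
            dummies = pd.get_dummies(df[cov], drop_first=True)
            cols.extend(dummies[c].to_numpy(float) for c in dummies)
    if participant_intercepts:
        dummies = pd.get_dummies(df["participant"], drop_first=True)
        cols.extend(dummies[c].to_numpy(float) for c in dummies)
    return np.column_stack(cols)


def ols_slope(table: pd.DataFrame, design: str,
              participant_intercepts: bool = False) -> float:
    """Ordinary-least-squares attention slope on the design's fixed effects.

    This is the zero-random-variance limit of the mixed model, and (with
    `participant_intercepts`) the fast statistic used inside permutation
    loops via Frisch-Waugh-Lovell residualization.
    """
    df = _prepare(table, design)
    Z = _covariate_matrix(df, design, participant_intercepts)
    y = df["accuracy"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    zw = w - Z @ np.linalg.lstsq(Z, w, rcond=None)[0]
    zy = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    return float(zw @ zy / (zw @ zw))


# --- between-participant permutation test ------------------------------------


def _weight_lookup(df: pd.DataFrame):
    """weight as a function of (participant, rule, dimension)."""
    key = df[["participant", "rule", "dimension"]].astype(str).agg("|".join, axis=1)
    lut = dict(zip(key, df["weight"]))
    return key, lut


def attention_shuffle_test(table: pd.DataFrame, design: str, n_perm: int = 10000,
                           seed: int = 0, engine: str = "mixed",
                           parametric: Optional[bool] = None) -> LinkResult:
    """Between-participant shuffle of whole attention-weight vectors.

    For each permutation, the full weight vector of one participant (all
    dimensions, and all rules for the learning design) is reassigned to
    another participant and the linking slope recomputed; correspondence
    of dimension and rule is preserved, so each participant's simplex
    constraint survives by construction.  The reported percentile is the
    mid-p proportion of null slopes below the observed slope (ties count
    half); the identity assignment is a valid member of the null set.
    When all participant assignments can be enumerated within `n_perm`,
    the null is exhaustive.

    `engine` selects the per-permutation statistic: "mixed" refits the
    mixed model (matching :func:`fit_link_model`); "ols" uses the
    residualized OLS slope with participant intercepts, vectorized over
    permutations — the choice of statistic does not affect the validity
    of the permutation null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    df = _prepare(table, design)
    pids = list(df["participant"].unique())
    n_sub = len(pids)
    if n_sub < 3:
        raise ValueError("the shuffle test needs at least 3 participants")

    rng = np.random.default_rng(seed)
    if math.factorial(n_sub) <= n_perm:
        perms = [list(p) for p in itertools.permutations(range(n_sub))]
    else:
        perms = [list(rng.permutation(n_sub)) for _ in range(n_perm)]

    pid_index = {p: i for i, p in enumerate(pids)}
    row_pid = df["participant"].map(pid_index).to_numpy()
    # weight of row r under permutation pi: weight(pids[pi[pid(r)]], rule(r), dim(r))
    base = (df.drop_duplicates(["participant", "rule", "dimension"])
              .set_index(["participant", "rule", "dimension"])["weight"])
    w_by_sub = np.empty((n_sub, len(df)))
    rules = df["rule"].to_numpy(object)
    dims = df["dimension"].to_numpy()
    for j, donor in enumerate(pids):
        w_by_sub[j] = [base[(donor, rules[r], dims[r])] for r in range(len(df))]

    base_res = None
    if engine == "mixed":
        base_res = fit_link_model(table, design)
        observed = base_res.slope
        null = np.empty(len(perms))
        for i, perm in enumerate(perms):
            dfp = df.copy()
            dfp["weight"] = w_by_sub[np.asarray(perm)[row_pid], np.arange(len(df))]
            res, _ = _mixed_slope(dfp, design)
            null[i] = float(res.params["weight"])
    elif engine == "ols":
        Z = _covariate_matrix(df, design, participant_intercepts=True)
        y = df["accuracy"].to_numpy(float)
        Q, _ = np.linalg.qr(Z)
        ry = y - Q @ (Q.T @ y)
        W = np.stack([w_by_sub[np.asarray(p)[row_pid], np.arange(len(df))]
                      for p in perms], axis=1)           # (n_obs, n_perm)
        RW = W - Q @ (Q.T @ W)
        denom = np.einsum("ij,ij->j", RW, RW)
        # residual weight variance ~ 0 (e.g. identical weight vectors across
        # participants): the slope is undefined; define it as 0 uniformly so
        # degenerate permutations tie instead of amplifying rounding noise
        degenerate = denom <= 1e-10 * (W**2).sum(axis=0)
        null = np.where(degenerate, 0.0,
                        (RW.T @ ry) / np.where(degenerate, 1.0, denom))
        w0 = df["weight"].to_numpy(float)
        rw0 = w0 - Q @ (Q.T @ w0)
        d0 = rw0 @ rw0
        observed = 0.0 if d0 <= 1e-10 * (w0**2).sum() else float(rw0 @ ry / d0)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    below = np.sum(null < observed - 1e-12)
    ties = np.sum(np.abs(null - observed) <= 1e-12)
    percentile = float((below + 0.5 * ties) / len(null))
    if parametric is None:
        parametric = engine == "mixed"
    if parametric:
        if base_res is None:
            base_res = fit_link_model(table, design)
        se, ddf, ci, p, fb = (base_res.se, base_res.df, base_res.ci, base_res.p,
                              base_res.singular_fallback)
        if engine == "mixed":
            observed = base_res.slope
    else:
        se = ddf = p = np.nan
        ci, fb = (np.nan, np.nan), False
    return LinkResult(
        slope=float(observed), se=se, df=ddf, ci=ci, p=p,
        design=design, n_participants=n_sub, singular_fallback=fb,
        null=np.asarray(null), percentile=percentile, n_perm=len(null),
        seed=seed, engine=engine,
    )


# --- perceptual-salience control ---------------------------------------------


def salience_anova(weights: pd.DataFrame):
    """Repeated-measures ANOVA of attention weight on perceptual feature.

    `weights` has columns participant, feature, weight, one row per
    participant x perceptual feature (weights expressed in perceptual
    coordinates via each participant's mapping).  Returns
    ``(F, (df1, df2), p, bf_null)`` where `bf_null` is the
    BIC-approximated Bayes factor in favor of the no-feature-effect
    model (values > 1 favor the null).
    """
    counts = weights.groupby("participant")["feature"].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced table: every participant needs every feature")
    per_sub_var = weights.groupby("participant")["weight"].var().fillna(0)
    if np.allclose(per_sub_var, 0):  # identical weights across features: F undefined
        n_feat = weights["feature"].nunique()
        n_sub = weights["participant"].nunique()
        return 0.0, (n_feat - 1, (n_feat - 1) * (n_sub - 1)), 1.0, np.inf
    import pingouin as pg

    aov = pg.rm_anova(data=weights, dv="weight", within="feature",
                      subject="participant", detailed=True)
    row = aov.loc[aov["Source"] == "feature"].iloc[0]
    F = float(row["F"])
    df1, df2 = float(row["DF"]), float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
    p = float(row["p_unc"])
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    null_fit = smf.ols("weight ~ C(participant)", weights).fit()
    alt_fit = smf.ols("weight ~ C(participant) + C(feature)", weights).fit()
    bf_null = float(np.exp((alt_fit.bic - null_fit.bic) / 2.0))
    return F, (df1, df2), p, bf_null


class AttentionLinkModel:
    """sklearn-style wrapper around the linking analysis.

    Parameters mirror :func:`fit_link_model` / :func:`attention_shuffle_test`;
    ``fit`` consumes a link table (DataFrame) and exposes ``slope_``,
    ``se_``, ``percentile_`` and the full ``result_``.
    """

    def __init__(self, design="5_4", n_perm=0, seed=0, engine="mixed", n_boot=0):
        self.design = design
        self.n_perm = n_perm
        self.seed = seed
        self.engine = engine
        self.n_boot = n_boot

    def get_params(self, deep=True):
        return {"design": self.design, "n_perm": self.n_perm, "seed": self.seed,
                "engine": self.engine, "n_boot": self.n_boot}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        if self.n_perm > 0:
            self.result_ = attention_shuffle_test(X, self.design, n_perm=self.n_perm,
                                                  seed=self.seed, engine=self.engine)
            self.percentile_ = self.result_.percentile
        else:
            self.result_ = fit_link_model(X, self.design, n_boot=self.n_boot,
                                          seed=self.seed)
            self.percentile_ = None
        self.slope_ = self.result_.slope
        self.se_ = self.result_.se
        return self
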