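"""Mixed-effects linking model, shuffle permutation test, salience controls."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from attnlink import linking
from attnlink.linking import AttentionLinkModel


def _table_54(n_sub=10, b=0.08, sd_int=0.0, sd_slope=0.0, sd_eps=0.0, seed=0,
              identical_weights=False):
    rng = np.random.default_rng(seed)
    rows = []
    shared = rng.dirichlet(np.ones(4))
    for i in range(n_sub):
        w = shared if identical_weights else rng.dirichlet(np.ones(4))
        a_i = rng.normal(0, sd_int)
        b_i = rng.normal(0, sd_slope)
        for k in range(4):
            acc = 0.55 + a_i + (b + b_i) * w[k] + 0.02 * k + rng.normal(0, sd_eps)
            rows.append(dict(participant=f"s{i:02d}", rule="5_4", dimension=k,
                             run=None, weight=float(w[k]), accuracy=acc))
    return pd.DataFrame(rows)


def test_exact_slope_recovery_without_noise():
    """With accuracy an exact linear function of weight (no noise, no random
    effects), the fitted slope equals the generating slope."""
    table = _table_54(n_sub=8, b=0.08)
    res = linking.fit_link_model(table, "5_4")
    assert res.slope == pytest.approx(0.08, abs=1e-8)


def test_mixed_model_matches_ols_in_zero_variance_limit():
    table = _table_54(n_sub=9, b=0.05, seed=3)
    mixed = linking.fit_link_model(table, "5_4").slope
    ols = linking.ols_slope(table, "5_4")
    assert mixed == pytest.approx(ols, abs=1e-6)
    # and both match an independent statsmodels formula fit
    ref = smf.ols("accuracy ~ weight + C(dimension)", table).fit().params["weight"]
    assert ols == pytest.approx(ref, abs=1e-10)


def test_slope_recovery_from_known_mixed_model():
    """Mean estimated slope within 0.02 of the generating b = 0.08 across
    replicates of a 20-participant mixed model with realistic variances."""
    slopes = []
    for seed in range(100):
        table = _table_54(n_sub=20, b=0.08, sd_int=0.03, sd_slope=0.03,
                          sd_eps=0.04, seed=seed)
        slopes.append(linking.fit_link_model(table, "5_4").slope)
    assert np.mean(slopes) == pytest.approx(0.08, abs=0.02)


def test_link_model_requires_enough_participants():
    with pytest.raises(ValueError):
        linking.fit_link_model(_table_54(n_sub=4), "5_4")


def test_bootstrap_ci_brackets_estimate():
    table = _table_54(n_sub=12, b=0.5, sd_eps=0.01, seed=1)
    res = linking.fit_link_model(table, "5_4", n_boot=60, seed=2)
    assert res.ci[0] <= res.slope <= res.ci[1]
    assert res.ci[1] - res.ci[0] < 0.2  # low-noise design gives a tight CI


def test_shj_design_needs_run_information():
    table = _table_54(n_sub=6)
    table["rule"] = "I"
    with pytest.raises(ValueError):
        linking.fit_link_model(table, "shj")


def test_shuffle_identical_weights_gives_half_percentile():
    """When every participant carries the same weight vector, all permuted
    slopes tie with the observed one and the mid-p rule yields 0.5."""
    table = _table_54(n_sub=6, b=0.08, sd_eps=0.01, seed=5, identical_weights=True)
    res = linking.attention_shuffle_test(table, "5_4", n_perm=300, seed=0,
                                         engine="ols", parametric=False)
    assert res.percentile == pytest.approx(0.5, abs=1e-12)


def test_shuffle_matches_exhaustive_enumeration_oracle():
    """At 4 participants the permutation null must equal an independent
    enumeration over all 4! whole-vector reassignments, with the slope
    recomputed per assignment by a separate statsmodels fit."""
    table = _table_54(n_sub=4, b=0.2, sd_eps=0.03, seed=7)
    res = linking.attention_shuffle_test(table, "5_4", n_perm=5000, seed=0,
                                         engine="ols", parametric=False)
    assert res.n_perm == 24
    pids = sorted(table["participant"].unique())
    w_of = {p: table.loc[table["participant"] == p]
                  .set_index("dimension")["weight"] for p in pids}
    null = []
    for perm in itertools.permutations(range(4)):
        t = table.copy()
        for i, p in enumerate(pids):
            donor = pids[perm[i]]
            mask = t["participant"] == p
            t.loc[mask, "weight"] = t.loc[mask, "dimension"].map(w_of[donor]).to_numpy()
            assert t.loc[mask, "weight"].sum() == pytest.approx(1.0)  # simplex kept
        slope = smf.ols("accuracy ~ weight + C(dimension) + C(participant)",
                        t).fit().params["weight"]
        null.append(slope)
    null = np.sort(null)
    assert np.allclose(np.sort(res.null), null, atol=1e-10)
    observed = null[np.argmin(np.abs(null - res.slope))]
    below = (null < res.slope - 1e-12).sum()
    ties = (np.abs(null - res.slope) <= 1e-12).sum()
    assert res.percentile == pytest.approx((below + 0.5 * ties) / 24)


def test_shuffle_percentile_invariant_to_affine_accuracy_rescaling():
    table = _table_54(n_sub=6, b=0.1, sd_eps=0.05, seed=11)
    res1 = linking.attention_shuffle_test(table, "5_4", n_perm=200, seed=4,
                                          engine="ols", parametric=False)
    table2 = table.copy()
    table2["accuracy"] = 3.0 * table2["accuracy"] + 10.0
    res2 = linking.attention_shuffle_test(table2, "5_4", n_perm=200, seed=4,
                                          engine="ols", parametric=False)
    assert res2.percentile == pytest.approx(res1.percentile, abs=1e-12)


def test_shuffle_engines_agree_on_strong_effect():
    """Mixed and OLS engines are different statistics over the same null;
    on a strong, low-noise effect both should flag the observed slope as
    extreme."""
    table = _table_54(n_sub=6, b=0.6, sd_eps=0.01, seed=2)
    p_mixed = linking.attention_shuffle_test(table, "5_4", n_perm=100, seed=1,
                                             engine="mixed").percentile
    p_ols = linking.attention_shuffle_test(table, "5_4", n_perm=100, seed=1,
                                           engine="ols").percentile
    assert p_mixed > 0.9 and p_ols > 0.9


def test_shuffle_validation():
    table = _table_54(n_sub=6)
    with pytest.raises(ValueError):
        linking.attention_shuffle_test(table, "5_4", n_perm=0)
    with pytest.raises(ValueError):
        linking.attention_shuffle_test(table[table["participant"] == "s00"], "5_4")


def test_estimator_wrapper_roundtrip():
    table = _table_54(n_sub=8, b=0.3, sd_eps=0.02, seed=9)
    m = AttentionLinkModel(design="5_4", n_perm=50, engine="ols").fit(table)
    assert m.slope_ == pytest.approx(linking.ols_slope(table, "5_4",
                                                       participant_intercepts=True))
    assert 0.0 <= m.percentile_ <= 1.0
    m2 = AttentionLinkModel().set_params(design="5_4").fit(table)
    assert m2.percentile_ is None and np.isfinite(m2.slope_)


# --- salience ANOVA ----------------------------------------------------------

# a printed toy table: 3 participants x 3 perceptual features
TOY = pd.DataFrame({
    "participant": ["s1"] * 3 + ["s2"] * 3 + ["s3"] * 3,
    "feature": ["color", "size", "shape"] * 3,
    "weight": [0.5, 0.3, 0.2,
               0.6, 0.2, 0.2,
               0.4, 0.4, 0.2],
})


def hand_rm_anova_f(df):
    """Textbook repeated-measures ANOVA, computed from sums of squares."""
    wide = df.pivot(index="participant", columns="feature", values="weight")
    n, k = wide.shape
    grand = wide.to_numpy().mean()
    ss_feature = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subject = k * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((wide.to_numpy() - grand) ** 2).sum()
    ss_error = ss_total - ss_feature - ss_subject
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_feature / df1) / (ss_error / df2), df1, df2


def test_salience_anova_matches_hand_computation():
    F, (df1, df2), p, bf = linking.salience_anova(TOY)
    F_hand, d1, d2 = hand_rm_anova_f(TOY)
    assert (df1, df2) == (d1, d2)
    assert F == pytest.approx(F_hand, abs=1e-8)


def test_salience_anova_degenerate_identical_weights():
    df = TOY.copy()
    df["weight"] = 1 / 3
    F, _, p, bf = linking.salience_anova(df)
    assert F == 0.0 and p == 1.0 and bf > 1


def test_salience_anova_detects_injected_feature_effect():
    rng = np.random.default_rng(0)
    rows = []
    effect = {"color": 0.45, "size": 0.30, "shape": 0.15, "position": 0.10}
    for i in range(20):
        for feat, mu in effect.items():
            rows.append(dict(participant=f"s{i}", feature=feat,
                             weight=mu + rng.normal(0, 0.05)))
    F, _, p, bf = linking.salience_anova(pd.DataFrame(rows))
    assert p < 0.05 and bf < 1  # alternative favored


def test_salience_anova_rejects_unbalanced_table():
    with pytest.raises(ValueError):
        linking.salience_anova(TOY.iloc[:-1])
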