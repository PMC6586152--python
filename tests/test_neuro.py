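"""Single-trial estimation, decoding, searchlight and group inference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from attnlink import neuro, synth
from attnlink.neuro import TrialPatternMatrix


def _patterns(rng, n_runs=4, per_run=8, n_units=20, gap=0.0, participant="s"):
    n = n_runs * per_run
    runs = np.repeat(np.arange(1, n_runs + 1), per_run)
    y = np.tile([0, 1], n // 2)
    data = rng.normal(0, 1, (n, n_units))
    data[y == 1, 0] += gap
    return TrialPatternMatrix(participant, data, runs, y[:, None])


def test_pattern_matrix_validation_and_roundtrip(tmp_path, rng):
    pm = _patterns(rng)
    with pytest.raises(ValueError):
        TrialPatternMatrix("s", pm.data, pm.runs[:-1], pm.conditions)
    bad = pm.data.copy()
    bad[0, 0] = np.nan
    with pytest.raises(ValueError):
        TrialPatternMatrix("s", bad, pm.runs, pm.conditions)
    pm.save(tmp_path / "pat")
    back = TrialPatternMatrix.load(tmp_path / "pat")
    assert np.array_equal(back.data, pm.data)
    assert np.array_equal(back.runs, pm.runs)
    assert back.participant == "s"


def test_decode_perfectly_separable_is_perfect(rng):
    pm = _patterns(rng, gap=50.0)
    res = neuro.decode_feature(pm, 0, C=1.0)
    assert res.accuracy == 1.0
    assert res.n_folds == 4
    assert set(res.fold_accuracies) == {1, 2, 3, 4}


def test_decode_label_permutation_centers_at_chance(rng):
    """Destroying the label-pattern correspondence drives accuracy to 50%."""
    accs = []
    for seed in range(40):
        r = np.random.default_rng(seed)
        pm = _patterns(r, gap=3.0)
        perm = np.concatenate([r.permutation(np.where(pm.runs == k)[0])
                               for k in range(1, 5)])
        shuffled = TrialPatternMatrix("s", pm.data, pm.runs, pm.conditions[perm])
        accs.append(neuro.decode_feature(shuffled, 0).accuracy)
    assert np.mean(accs) == pytest.approx(0.5, abs=0.04)


def test_decode_mean_equals_fold_mean_and_unit_permutation_invariance(rng):
    pm = _patterns(rng, gap=1.0)
    res = neuro.decode_feature(pm, 0)
    assert res.accuracy == pytest.approx(np.mean(list(res.fold_accuracies.values())))
    perm = rng.permutation(pm.n_units)
    res2 = neuro.decode_feature(
        TrialPatternMatrix("s", pm.data[:, perm], pm.runs, pm.conditions), 0)
    assert res2.accuracy == pytest.approx(res.accuracy)


def test_decode_errors(rng):
    pm = _patterns(rng)
    single = TrialPatternMatrix("s", pm.data, np.ones_like(pm.runs), pm.conditions)
    with pytest.raises(ValueError):
        neuro.decode_feature(single, 0)
    y = pm.conditions.copy()
    y[pm.runs == 2] = 1  # run 2 becomes single-class
    with pytest.raises(ValueError, match="single class"):
        neuro.decode_feature(TrialPatternMatrix("s", pm.data, pm.runs, y), 0)


def test_decode_retain_runs_late_folds_only(rng):
    pm = _patterns(rng, gap=2.0)
    res = neuro.decode_feature(pm, 0, retain_runs=[3, 4])
    assert set(res.fold_accuracies) == {3, 4}
    assert res.n_folds == 4  # trained on all leave-one-run-out folds


def test_decoding_improves_as_noise_shrinks(s54):
    means = []
    for sigma in (3.0, 1.0, 0.3):
        accs = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            cfg = synth.SynthConfig(kappa=1.0, sigma=sigma, n_units=40)
            trials = synth.balanced_5_4_scan(s54, 3, 16, r)
            pm, _ = synth._pattern_matrix([t.features for t in trials],
                                          [t.run for t in trials],
                                          np.full(4, 0.25), cfg, r, "s")
            accs.append(neuro.decode_feature(pm, 0).accuracy)
        means.append(np.mean(accs))
    assert means[0] < means[1] < means[2]


# --- LSS ---------------------------------------------------------------------


def test_lss_recovers_injected_amplitudes():
    rng = np.random.default_rng(0)
    amps = rng.normal(0, 1, (16, 30))
    cfg = synth.SynthConfig(sigma=0.2)
    bold, events = synth.simulate_bold(amps, cfg, rng)
    tmaps = neuro.lss_estimate(bold, events, tr=cfg.tr)
    r = np.corrcoef(tmaps.ravel(), amps.ravel())[0, 1]
    assert r > 0.9
    # noiseless sign check on a strongly signed pattern
    signed = np.sign(rng.normal(size=(6, 10))) * 2.0
    clean, ev = synth.simulate_bold(signed, synth.SynthConfig(sigma=1e-9),
                                    np.random.default_rng(1))
    t_clean = neuro.lss_estimate(clean, ev)
    assert (np.sign(t_clean) == np.sign(signed)).mean() > 0.99


def test_lss_shuffled_onsets_break_recovery():
    rng = np.random.default_rng(3)
    amps = rng.normal(0, 1, (16, 30))
    cfg = synth.SynthConfig(sigma=0.2)
    bold, events = synth.simulate_bold(amps, cfg, rng)
    shuffled = events.copy()
    shuffled["onset"] = rng.permutation(events["onset"].to_numpy())
    tmaps = neuro.lss_estimate(bold, shuffled, tr=cfg.tr)
    # estimates no longer line up with the amplitudes they were matched to
    r = np.corrcoef(tmaps.ravel(), amps.ravel())[0, 1]
    assert abs(r) < 0.3


def test_lss_rejects_out_of_range_events():
    bold = np.zeros((20, 3))
    events = pd.DataFrame({"onset": [100.0], "duration": [3.5]})
    with pytest.raises(ValueError):
        neuro.lss_estimate(bold, events)


# --- searchlight -------------------------------------------------------------


def _toy_volume(rng, shape=(7, 7, 7), n_trials=32, region=slice(0, 3), gap=2.0):
    runs = np.repeat(np.arange(1, 5), 8)
    cond = np.tile([0, 1], 16)
    vol = rng.normal(0, 1, shape + (n_trials,))
    vol[region, region, region, :] += gap * (2 * cond - 1)
    return vol, runs, cond


def test_searchlight_localizes_injected_signal(rng):
    vol, runs, cond = _toy_volume(rng)
    mask = np.ones(vol.shape[:3], bool)
    out = neuro.searchlight(vol, mask, runs, cond[:, None], radius_mm=3.5,
                            voxel_size=(3, 3, 3))
    peak = np.unravel_index(np.nanargmax(out), out.shape)
    assert all(p <= 3 for p in peak)  # inside/adjacent to the signal corner
    assert abs(np.nanmean(out[4:, 4:, 4:])) < 0.1  # noise region near chance


def test_searchlight_single_voxel_sphere_reduces_to_per_voxel_decoding(rng):
    vol, runs, cond = _toy_volume(rng, shape=(2, 1, 1))
    mask = np.ones((2, 1, 1), bool)
    out = neuro.searchlight(vol, mask, runs, cond[:, None], radius_mm=1.0,
                            voxel_size=(3, 3, 3))
    pm = neuro.TrialPatternMatrix("s", vol[0, 0, 0][:, None], runs, cond[:, None])
    direct = neuro.decode_feature(pm, 0, C=0.1).accuracy - 0.5
    assert out[0, 0, 0] == pytest.approx(direct)


def test_searchlight_input_validation(rng):
    vol, runs, cond = _toy_volume(rng, shape=(2, 2, 2))
    with pytest.raises(ValueError):
        neuro.searchlight(vol, np.zeros((2, 2, 2), bool), runs, cond[:, None])


# --- sign-flip group test ----------------------------------------------------


def test_signflip_all_zero_maps_nothing_significant():
    maps = [np.zeros(12) for _ in range(6)]
    t, p = neuro.signflip_test(maps, n_perm=200, seed=0)
    assert (t == 0).all() and (p == 1.0).all()


def test_signflip_matches_exhaustive_enumeration_oracle(rng):
    """With 3 subjects the internal null must equal a hand-enumerated null
    over all 2^3 sign patterns (t computed independently with scipy)."""
    maps = [rng.normal(0.5, 1.0, 6) for _ in range(3)]
    t_obs, p = neuro.signflip_test(maps, n_perm=1000, seed=1)
    stacked = np.stack(maps)
    t_scipy = sps.ttest_1samp(stacked, 0.0, axis=0).statistic
    assert np.allclose(t_obs, t_scipy, atol=1e-10)
    null_max = []
    for signs in itertools.product((1, -1), repeat=3):
        flipped = stacked * np.array(signs)[:, None]
        null_max.append(np.abs(sps.ttest_1samp(flipped, 0.0, axis=0).statistic).max())
    null_max = np.array(null_max)
    expected_p = [(null_max >= abs(t) - 1e-12).mean() for t in t_obs]
    assert np.allclose(p, expected_p)


def test_signflip_familywise_error_calibration():
    """Under a pure-noise null the familywise rejection rate at alpha=.05
    stays within binomial error of nominal."""
    alpha = 0.05
    rejections = 0
    n_rep = 120
    for seed in range(n_rep):
        r = np.random.default_rng(seed)
        maps = [r.normal(0, 1, 25) for _ in range(7)]
        _, p = neuro.signflip_test(maps, n_perm=128, seed=seed)
        rejections += int(p.min() <= alpha)
    rate = rejections / n_rep
    assert rate <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_rep)


def test_signflip_validation():
    with pytest.raises(ValueError):
        neuro.signflip_test([np.zeros(3)], n_perm=10)
    with pytest.raises(ValueError):
        neuro.signflip_test([np.zeros(3), np.zeros(3)], n_perm=0)


def test_threshold_roi_monotone_nesting(rng):
    t_map = rng.normal(0, 3, (5, 5))
    lo = neuro.threshold_roi(t_map, 1.0)
    hi = neuro.threshold_roi(t_map, 2.5)
    assert (hi <= lo).all()  # raising the threshold nests the mask
    assert neuro.threshold_roi(t_map, -np.inf).all()
    assert not neuro.threshold_roi(t_map, t_map.max() + 1).any()


def test_nifti_roundtrip_matches_direct_decoding(tmp_path, rng):
    nib = pytest.importorskip("nibabel")
    pm = _patterns(rng, gap=2.0, n_units=12)
    img = neuro.patterns_to_nifti(pm, shape=(3, 2, 2))
    mask = nib.Nifti1Image(np.ones((3, 2, 2)), affine=np.eye(4))
    nib.save(img, tmp_path / "pat.nii.gz")
    back = neuro.patterns_from_nifti(tmp_path / "pat.nii.gz", mask,
                                     pm.runs, pm.conditions)
    assert neuro.decode_feature(back, 0).accuracy == pytest.approx(
        neuro.decode_feature(pm, 0).accuracy)
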