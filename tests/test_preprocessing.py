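"""Notch filter and the three-step artifact detection + exclusion rules."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as spstats

from accumloc.containers import ArtifactMask, EpochedData, TrialRecord
from accumloc.preprocessing import (
    apply_exclusion_rules,
    compute_artifact_mask,
    detect_amplitude_artifacts,
    detect_kurtosis_artifacts,
    detect_variance_artifacts,
    notch_filter,
)


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def test_notch_attenuates_stopband_and_passes_passband():
    fs = 250.0
    t = np.arange(int(10 * fs)) / fs
    line = np.sin(2 * np.pi * 50 * t)
    tone = np.sin(2 * np.pi * 10 * t)
    assert _rms(notch_filter(line, fs)[250:-250]) < 0.03 * _rms(line)
    out = notch_filter(tone, fs)[250:-250]
    assert abs(_rms(out) - _rms(tone)) < 0.01 * _rms(tone)
    assert np.allclose(notch_filter(np.zeros(1000), fs), 0.0)


def test_notch_rejects_stopband_at_nyquist():
    with pytest.raises(ValueError):
        notch_filter(np.zeros(1000), 100.0, stopband=(48, 52))


def _epochs(data):
    n_tr, n_ch, n_s = data.shape
    trials = [
        TrialRecord(i, "face", 2, True, 1.0, True, 1.0, 10.0 * i, 10.0 * i + 5, 10.0 * i + 6)
        for i in range(n_tr)
    ]
    return EpochedData(
        data=data,
        fs=250.0,
        window=(-0.3, 2.8),
        channel_labels=[f"ch{c}" for c in range(n_ch)],
        channel_areas=["BA9"] * n_ch,
        subject_id="T",
        trials=trials,
    )


def test_amplitude_detector_matches_gaussian_tail_rate():
    rng = np.random.default_rng(4)
    n_tr, n_ch, n_s = 40, 10, 1000
    epochs = _epochs(rng.standard_normal((n_tr, n_ch, n_s)))
    flags = detect_amplitude_artifacts(epochs)
    p_cell = 1 - (1 - 2 * spstats.norm.cdf(-4)) ** n_s
    lo, hi = spstats.binom.interval(0.999, n_tr * n_ch, p_cell)
    assert lo <= flags.sum() <= hi


def test_amplitude_detector_forced_and_silent_cases():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((5, 4, 500))
    data[2, 1, 100] = 10.0 * data.std()
    flags = detect_amplitude_artifacts(_epochs(data))
    assert flags[2, 1]
    # bounded (uniform) noise can never reach 4 global SDs
    quiet = rng.uniform(-1, 1, size=(5, 4, 500)) + 7.0
    assert not detect_amplitude_artifacts(_epochs(quiet)).any()
    with pytest.raises(ValueError):
        detect_amplitude_artifacts(_epochs(np.full((3, 3, 10), 2.0)))


def test_kurtosis_detector_examples():
    rng = np.random.default_rng(1)
    data = np.empty((2, 2, 1000))
    data[0, 0] = 0.0
    data[0, 0, 17] = 1.0  # 999 zeros and a single one: kurtosis ~ 999
    data[0, 1] = rng.standard_normal(1000)  # ~3, below threshold
    data[1, 0] = rng.uniform(-1, 1, 1000)  # ~1.8
    data[1, 1] = rng.standard_normal(1000)
    flags = detect_kurtosis_artifacts(_epochs(data))
    assert flags[0, 0] and not flags[0, 1] and not flags[1, 0] and not flags[1, 1]
    assert spstats.kurtosis(data[0, 0], fisher=False) == pytest.approx(999, rel=0.01)


def test_kurtosis_detector_flags_constant_cells_with_warning():
    data = np.random.default_rng(0).standard_normal((2, 2, 100))
    data[1, 1] = 5.0
    with pytest.warns(UserWarning):
        flags = detect_kurtosis_artifacts(_epochs(data))
    assert flags[1, 1]


def test_variance_detector_examples():
    rng = np.random.default_rng(2)
    equal = np.tile(rng.standard_normal(500), (4, 5, 1))
    assert not detect_variance_artifacts(_epochs(equal)).any()
    data = rng.standard_normal((10, 10, 500))
    data[3, 7] *= np.sqrt(10.0)
    flags = detect_variance_artifacts(_epochs(data))
    assert flags[3, 7]
    assert flags.sum() <= 3  # the inflated cell dominates the tail


def test_variance_detector_gaussian_rate():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((20, 20, 500))
    rate = detect_variance_artifacts(_epochs(data)).mean()
    expected = spstats.norm.cdf(-1.75)
    assert 0.3 * expected <= rate <= 2.0 * expected


def test_detectors_are_permutation_equivariant():
    rng = np.random.default_rng(9)
    data = rng.standard_normal((8, 6, 400))
    data[1, 2, 5] = 30.0
    data[4, 0] *= 3.0
    ep = _epochs(data)
    pt, pc = rng.permutation(8), rng.permutation(6)
    ep_p = _epochs(data[np.ix_(pt, pc)])
    for det in (detect_amplitude_artifacts, detect_kurtosis_artifacts, detect_variance_artifacts):
        np.testing.assert_array_equal(det(ep)[np.ix_(pt, pc)], det(ep_p))


def _mask(flags):
    return ArtifactMask(flags=flags, provenance={})


def _behavior_epochs(n_tr=30, n_ch=10, correct=None, rts=None, classes=None, seed=0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_tr, n_ch, 200))
    trials = []
    for i in range(n_tr):
        rt = 1.0 if rts is None else rts[i]
        trials.append(
            TrialRecord(
                i,
                "face" if classes is None else classes[i],
                2,
                True,
                1.0,
                True if correct is None else bool(correct[i]),
                rt,
                20.0 * i,
                20.0 * i + 5,
                20.0 * i + 5 + rt,
            )
        )
    ep = _epochs(data)
    ep = dataclasses.replace(ep, trials=trials)
    return ep


def test_exclusion_identity_on_clean_data():
    ep = _behavior_epochs()
    flags = np.zeros((30, 10, 3), dtype=bool)
    res = apply_exclusion_rules(ep, _mask(flags), min_correct_per_class=0)
    assert res.retained_trials.size == 30
    assert res.retained_channels.size == 10
    assert res.report["trials_dropped_behavior"] == 0
    assert res.report["cells_excluded"] == 0
    assert not res.participant_excluded


def test_trial_dropped_when_over_half_channels_flagged():
    ep = _behavior_epochs()
    flags = np.zeros((30, 10, 3), dtype=bool)
    flags[4, :6, 0] = True  # 6 of 10 channels > 50%
    res = apply_exclusion_rules(ep, _mask(flags), min_correct_per_class=0)
    assert 4 not in res.retained_trials
    assert res.retained_trials.size == 29


def test_channel_dropped_when_flagged_on_over_half_trials():
    ep = _behavior_epochs()
    flags = np.zeros((30, 10, 3), dtype=bool)
    flags[:16, 3, 1] = True
    res = apply_exclusion_rules(ep, _mask(flags), min_correct_per_class=0)
    assert 3 not in res.retained_channels


def test_behavioral_filter_rt_cap_and_errors():
    correct = [True] * 28 + [False] * 2
    rts = [1.0] * 27 + [2.6, 1.0, 1.0]
    ep = _behavior_epochs(correct=correct, rts=rts)
    res = apply_exclusion_rules(ep, _mask(np.zeros((30, 10, 3), bool)), min_correct_per_class=0)
    assert res.report["trials_dropped_behavior"] == 3  # 2 errors + 1 slow


def test_participant_excluded_below_twenty_correct_per_class():
    classes = ["face"] * 30 + ["letter"] * 30
    correct = [True] * 19 + [False] * 11 + [True] * 25 + [False] * 5
    ep = _behavior_epochs(n_tr=60, correct=correct, classes=classes)
    res = apply_exclusion_rules(ep, _mask(np.zeros((60, 10, 3), bool)))
    assert res.participant_excluded
    assert res.report["n_correct_face"] == 19


def test_exclusion_is_idempotent():
    rng = np.random.default_rng(123)
    ep = _behavior_epochs(n_tr=40, n_ch=12, seed=5)
    flags = rng.random((40, 12, 3)) < 0.25
    res = apply_exclusion_rules(ep, _mask(flags), min_correct_per_class=0)
    sub = dataclasses.replace(
        ep,
        data=ep.data[np.ix_(res.retained_trials, res.retained_channels)],
        trials=[ep.trials[i] for i in res.retained_trials],
        channel_labels=[ep.channel_labels[i] for i in res.retained_channels],
        channel_areas=[ep.channel_areas[i] for i in res.retained_channels],
    )
    sub_flags = flags[np.ix_(res.retained_trials, res.retained_channels)]
    res2 = apply_exclusion_rules(sub, _mask(sub_flags), min_correct_per_class=0)
    assert res2.retained_trials.size == res.retained_trials.size
    assert res2.retained_channels.size == res.retained_channels.size
    np.testing.assert_array_equal(res2.cell_excluded, res.cell_excluded)


def test_mask_alignment_checked():
    ep = _behavior_epochs()
    with pytest.raises(ValueError):
        apply_exclusion_rules(ep, _mask(np.zeros((5, 10, 3), bool)))


def test_compute_artifact_mask_records_thresholds():
    rng = np.random.default_rng(0)
    ep = _epochs(rng.standard_normal((6, 4, 300)))
    mask = compute_artifact_mask(ep)
    assert mask.provenance == {"amplitude_sd": 4.0, "kurtosis": 4.5, "variance_sd": 1.75}
    assert mask.flags.shape == (6, 4, 3)
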