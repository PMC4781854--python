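"""Vincentization and accumulator diagnostics on constructed geometries."""

import numpy as np
import pytest

from accumloc.bands import FEATURES
from accumloc.containers import TrialRecord
from accumloc.spectral import FeatureBundle, WindowTable
from accumloc.timecourse import (
    VincentizedAverage,
    accumulator_diagnostics,
    binned_average,
    rt_bin_label,
    vincentize_trial,
)


def test_vincentize_constant_and_identity():
    const = np.full(37, 2.5)
    np.testing.assert_allclose(vincentize_trial(const, 12), 2.5)
    x = np.random.default_rng(0).standard_normal(50)
    np.testing.assert_allclose(vincentize_trial(x, 50), x, atol=1e-12)


def test_vincentize_preserves_linear_ramps():
    for n_src, n_dst in [(30, 100), (100, 30), (7, 2), (2, 9)]:
        ramp = np.linspace(0.0, 1.0, n_src)
        out = vincentize_trial(ramp, n_dst)
        assert out[0] == 0.0 and out[-1] == 1.0
        np.testing.assert_allclose(out, np.linspace(0, 1, n_dst), atol=1e-9)


def test_vincentize_commutes_with_affine_transforms():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(40)
    a, b = 2.3, -0.7
    np.testing.assert_allclose(
        vincentize_trial(a * x + b, 23), a * vincentize_trial(x, 23) + b, atol=1e-12
    )


def test_vincentize_input_validation():
    with pytest.raises(ValueError):
        vincentize_trial(np.zeros(10), 1)
    with pytest.raises(ValueError):
        vincentize_trial(np.zeros(1), 5)


def test_rt_bin_edges():
    assert rt_bin_label(0.8) == "short"
    assert rt_bin_label(0.9) == "medium"
    assert rt_bin_label(1.7) == "medium"
    assert rt_bin_label(1.71) == "long"


def _make_bundle(subject, rts, trial_values, n_channels=2, area="BA19"):
    """Bundle whose theta feature holds a given per-trial decision profile."""
    fs, buffer = 50.0, 0.3
    nb = int(buffer * fs)
    n = np.array([len(v) + 2 * nb for v in trial_values])
    table = WindowTable(
        trial_ids=np.arange(len(rts)),
        rts=np.asarray(rts, float),
        start_idx=np.concatenate([[0], np.cumsum(n)[:-1]]),
        n_samples=n,
        fs=fs,
        buffer=buffer,
    )
    data = np.zeros((len(FEATURES), n_channels, table.total_length))
    fi = FEATURES.index("theta")
    for i, v in enumerate(trial_values):
        o = table.offsets[i]
        data[fi, :, o + nb : o + nb + len(v)] = v
    trials = []
    for i, rt in enumerate(rts):
        onset = 20.0 * i
        probe = onset + 5.0
        trials.append(
            TrialRecord(i, "face", 2, True, 1.0, True, float(rt), onset, probe, probe + float(rt))
        )
    bundle = FeatureBundle(
        subject_id=subject,
        channel_labels=[f"{subject}c{j}" for j in range(n_channels)],
        channel_areas=[area] * n_channels,
        data=data,
        table=table,
        cell_excluded=np.zeros((len(rts), n_channels), bool),
    )
    return bundle, trials


def _ramp_to_peak(rt, amp=1.0):
    """Threshold-crossing profile: rises linearly, peaks at the response."""
    n = int(round(rt * 50))
    return amp * np.linspace(0, 1, n)


def test_binned_average_rt_counts_and_identity():
    rts = [0.8, 1.0, 2.0]
    bundle, trials = _make_bundle("S0", rts, [_ramp_to_peak(r) for r in rts])
    avgs = binned_average([(bundle, trials)], "BA19", "theta", binning="rt")
    by_label = {a.label: a for a in avgs}
    assert set(by_label) == {"short", "medium", "long"}
    assert all(a.n_trials == 2 for a in avgs)  # 2 electrodes x 1 trial
    # single trial per bin: the average is that trial's (vincentized) course
    a = by_label["short"]
    assert len(a.values) == round(0.8 * 50)
    np.testing.assert_allclose(a.values, _ramp_to_peak(0.8), atol=1e-9)


def test_binned_average_equal_subject_weighting():
    """Duplicating one subject's electrodes must not move the cohort mean."""
    rts = [1.0, 1.0]
    b1, t1 = _make_bundle("S0", rts, [_ramp_to_peak(r) for r in rts], n_channels=2)
    b2, t2 = _make_bundle("S1", rts, [0.5 * _ramp_to_peak(r) for r in rts], n_channels=2)
    b2_dup, _ = _make_bundle("S1", rts, [0.5 * _ramp_to_peak(r) for r in rts], n_channels=6)
    a = binned_average([(b1, t1), (b2, t2)], "BA19", "theta")[0]
    b = binned_average([(b1, t1), (b2_dup, t2)], "BA19", "theta")[0]
    np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_binned_average_evidence_and_class_filter():
    rts = [1.0, 1.2, 1.4, 1.6]
    bundle, trials = _make_bundle("S0", rts, [_ramp_to_peak(r) for r in rts])
    for i, t in enumerate(trials):
        t.summed_similarity = float(i)
    avgs = binned_average(
        [(bundle, trials)], "BA19", "theta", binning="evidence",
        evidence_levels=2, stimulus_class="face",
    )
    assert len(avgs) == 2
    assert binned_average([(bundle, trials)], "BA19", "theta", stimulus_class="letter") == []


def _diag_bins(kind="accumulator"):
    """Constructed RT-bin averages with known peak geometry."""
    bins = []
    for label, rt in [("short", 0.8), ("medium", 1.3), ("long", 2.0)]:
        n = int(round(rt * 50))
        if kind == "accumulator":
            values = np.linspace(0, 1, n)  # peaks at the response, amplitude 1
        elif kind == "stimulus_locked":
            # fixed-duration bump peaking 0.4 s after the probe in every bin
            t = np.arange(n) / 50.0
            values = np.exp(-((t - 0.4) ** 2) / (2 * 0.05**2))
        else:  # boxcar
            values = np.ones(n)
        bins.append(
            VincentizedAverage(label, f"rt={label}", "theta", "BA19", 10, rt, values)
        )
    return bins


def _evidence_bins(slopes=(0.2, 0.5, 1.0)):
    out = []
    for i, s in enumerate(slopes):
        n = 60
        values = s * np.arange(n) / 50.0
        out.append(
            VincentizedAverage(f"evidence{i}", f"evidence={i}", "theta", "BA19", 10, 1.2, values)
        )
    return out


def test_diagnostics_ideal_accumulator_passes_all_criteria():
    diag = accumulator_diagnostics(_diag_bins("accumulator"), _evidence_bins())
    assert diag.latency_scales_with_rt
    assert diag.amplitude_rt_invariant
    assert diag.slope_scales_with_evidence
    # de-vincentized peak latency within one sample of the crossing time
    for label, rt in [("short", 0.8), ("medium", 1.3), ("long", 2.0)]:
        assert abs(diag.peak_latency[label] - (rt - 1 / 50.0)) <= 1 / 50.0 + 1e-9


def test_diagnostics_reject_stimulus_locked_bump():
    """A fixed-latency bump is the signature the method must *not* accept."""
    diag = accumulator_diagnostics(_diag_bins("stimulus_locked"))
    assert not diag.latency_scales_with_rt
    assert diag.stats["latency_rt_spearman"] < 0.9


def test_diagnostics_boxcar_fails_evidence_criterion():
    diag = accumulator_diagnostics(
        _diag_bins("accumulator"), _evidence_bins(slopes=(0.0, 0.0, 0.0))
    )
    assert not diag.slope_scales_with_evidence


def test_diagnostics_amplitude_criterion_detects_threshold_violation():
    bins = _diag_bins("accumulator")
    bins[2] = VincentizedAverage(
        "long", "rt=long", "theta", "BA19", 10, 2.0,
        2.0 * np.linspace(0, 1, int(2.0 * 50)),
    )
    diag = accumulator_diagnostics(bins)
    assert not diag.amplitude_rt_invariant
    assert diag.stats["amplitude_max_ratio"] == pytest.approx(2.0)


def test_diagnostics_flat_bins_flagged():
    bins = _diag_bins("accumulator")
    bins[0] = VincentizedAverage("short", "rt=short", "theta", "BA19", 10, 0.8,
                                 np.zeros(40))
    diag = accumulator_diagnostics(bins, noise_floor=0.01)
    assert "short" in diag.flat_bins
    assert diag.latency_scales_with_rt is None
    with pytest.raises(ValueError):
        accumulator_diagnostics(bins[:1])
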