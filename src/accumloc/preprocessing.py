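"""Notch filtering, three-step artifact detection, and exclusion rules.

Detection runs per session on fixed epochs around each probe (decision-
relevant window plus baseline margin).  The three criteria:

1. amplitude: after normalizing across *all* electrodes and trials, flag a
   (trial, channel) cell if any sample exceeds 4 SD in magnitude;
2. kurtosis: flag if the cell's fourth standardized moment (non-excess,
   Gaussian reference 3) exceeds 4.5;
3. variance: flag if the cell variance exceeds the mean cell variance plus
   1.75 SD, with the population being all cells of the session.

Exclusion then keeps correct trials with RT <= 2.5 s, drops trials with
> 50% of channels flagged, channels flagged on > 50% of trials, and
participants with fewer than 20 correct face or letter trials remaining.
The trial/channel rules are iterated to a fixed point so that re-running
exclusion on its own output changes nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .containers import (
    ArtifactMask,
    DETECTION_WINDOW,
    EpochedData,
    Session,
    detection_window_samples,
)

__all__ = [
    "notch_filter",
    "epoch_session",
    "detect_amplitude_artifacts",
    "detect_kurtosis_artifacts",
    "detect_variance_artifacts",
    "compute_artifact_mask",
    "apply_exclusion_rules",
    "ExclusionResult",
]

AMPLITUDE_SD_THRESHOLD = 4.0
KURTOSIS_THRESHOLD = 4.5
VARIANCE_SD_THRESHOLD = 1.75


def notch_filter(
    signal: np.ndarray, fs: float, stopband: tuple[float, float] = (48.0, 52.0)
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-stop (applied forward-backward)."""
    lo, hi = stopband
    if not 0.0 < lo < hi:
        raise ValueError("stopband must satisfy 0 < lo < hi")
    if hi >= fs / 2.0:
        raise ValueError(f"stopband upper edge {hi} Hz reaches the Nyquist rate {fs / 2} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandstop", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, float), axis=-1)


def epoch_session(
    session: Session, window: tuple[float, float] = DETECTION_WINDOW
) -> EpochedData:
    """Cut fixed-length detection epochs around every probe onset."""
    fs = session.fs
    n_samp = int(round((window[1] - window[0]) * fs))
    data = np.empty((len(session.trials), session.n_channels, n_samp))
    for i, tr in enumerate(session.trials):
        i0, i1 = detection_window_samples(tr, fs, window)
        if i0 < 0 or i1 > session.n_samples:
            raise ValueError(f"trial {tr.trial_index} epoch extends beyond the recording")
        data[i] = session.signal[:, i0:i1]
    return EpochedData(
        data=data,
        fs=fs,
        window=window,
        channel_labels=list(session.channel_labels),
        channel_areas=list(session.channel_areas),
        subject_id=session.subject_id,
        trials=list(session.trials),
    )


def detect_amplitude_artifacts(
    epochs: EpochedData, threshold: float = AMPLITUDE_SD_THRESHOLD
) -> np.ndarray:
    """Flag cells with any |sample| > threshold after global normalization.

    Normalization uses one mean/SD across all electrodes and trials of the
    session, per the per-session artifact pass.
    """
    data = epochs.data
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need at least 2 trials and 2 channels")
    mu = data.mean()
    sd = data.std()
    if sd == 0:
        raise ValueError("degenerate input: zero global standard deviation")
    z = np.abs(data - mu) / sd
    return (z > threshold).any(axis=2)


def detect_kurtosis_artifacts(
    epochs: EpochedData, threshold: float = KURTOSIS_THRESHOLD
) -> np.ndarray:
    """Flag cells whose (non-excess) sample kurtosis exceeds the threshold."""
    data = epochs.data
    if data.shape[2] < 4:
        raise ValueError("need at least 4 samples per cell for kurtosis")
    var = data.var(axis=2)
    degenerate = var == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        kurt = spstats.kurtosis(data, axis=2, fisher=False, bias=True)
    flags = kurt > threshold
    if degenerate.any():
        warnings.warn("zero-variance cells flagged in kurtosis detection", stacklevel=2)
        flags |= degenerate
    return flags


def detect_variance_artifacts(
    epochs: EpochedData, threshold: float = VARIANCE_SD_THRESHOLD
) -> np.ndarray:
    """Flag cells with variance > population mean + threshold * population SD.

    The population is every (trial, channel) cell of the session.
    """
    data = epochs.data
    if data.shape[0] * data.shape[1] < 2:
        raise ValueError("variance rule needs at least two cells")
    var = data.var(axis=2)
    cutoff = var.mean() + threshold * var.std()
    return var > cutoff


def compute_artifact_mask(
    epochs: EpochedData,
    amplitude_sd: float = AMPLITUDE_SD_THRESHOLD,
    kurtosis: float = KURTOSIS_THRESHOLD,
    variance_sd: float = VARIANCE_SD_THRESHOLD,
) -> ArtifactMask:
    """Run all three detectors and bundle the flags with their thresholds."""
    flags = np.stack(
        [
            detect_amplitude_artifacts(epochs, amplitude_sd),
            detect_kurtosis_artifacts(epochs, kurtosis),
            detect_variance_artifacts(epochs, variance_sd),
        ],
        axis=2,
    )
    return ArtifactMask(
        flags=flags,
        provenance={
            "amplitude_sd": amplitude_sd,
            "kurtosis": kurtosis,
            "variance_sd": variance_sd,
        },
    )


@dataclass
class ExclusionResult:
    """Retained indices, residual cell-level exclusions, and step counts."""

    retained_trials: np.ndarray  # indices into the session's trial list
    retained_channels: np.ndarray
    #: retained-trials x retained-channels: cells still excluded per-electrode
    cell_excluded: np.ndarray
    participant_excluded: bool
    report: dict = field(default_factory=dict)


def apply_exclusion_rules(
    epochs: EpochedData,
    mask: ArtifactMask,
    rt_cap: float = 2.5,
    trial_channel_frac: float = 0.5,
    channel_trial_frac: float = 0.5,
    min_correct_per_class: int = 20,
) -> ExclusionResult:
    """Apply the trial / channel / participant exclusion rules.

    Steps, per session: (1) keep correct trials with rt <= rt_cap;
    (2) drop trials where more than ``trial_channel_frac`` of channels are
    flagged on any criterion; (3) drop channels flagged on more than
    ``channel_trial_frac`` of trials; (4) exclude the participant if fewer
    than ``min_correct_per_class`` correct face or letter trials survive.
    Steps 2-3 iterate to a fixed point, making the rule idempotent.
    """
    if mask.flags.shape[:2] != epochs.data.shape[:2]:
        raise ValueError("artifact mask is not aligned with the epochs")
    trials = epochs.trials
    any_flag = mask.any_flag

    behavioral_keep = np.array([t.correct and t.rt <= rt_cap for t in trials])

    trial_keep = behavioral_keep.copy()
    chan_keep = np.ones(epochs.n_channels, dtype=bool)
    n_iter = 0
    first_pass: dict[str, int] = {}
    while True:
        n_iter += 1
        sub = any_flag[np.ix_(trial_keep.nonzero()[0], chan_keep.nonzero()[0])]
        drop_trial = np.zeros_like(trial_keep)
        drop_chan = np.zeros_like(chan_keep)
        if sub.size:
            frac_ch = sub.mean(axis=1)
            drop_trial[trial_keep.nonzero()[0][frac_ch > trial_channel_frac]] = True
            frac_tr = sub.mean(axis=0)
            drop_chan[chan_keep.nonzero()[0][frac_tr > channel_trial_frac]] = True
        if n_iter == 1:
            first_pass = {
                "trials_dropped_artifact": int(drop_trial.sum()),
                "channels_dropped": int(drop_chan.sum()),
            }
        if not drop_trial.any() and not drop_chan.any():
            break
        trial_keep &= ~drop_trial
        chan_keep &= ~drop_chan

    retained_trials = trial_keep.nonzero()[0]
    retained_channels = chan_keep.nonzero()[0]
    cell_excluded = any_flag[np.ix_(retained_trials, retained_channels)].copy()

    n_face = sum(1 for i in retained_trials if trials[i].stimulus_class == "face")
    n_letter = sum(1 for i in retained_trials if trials[i].stimulus_class == "letter")
    participant_excluded = (
        n_face < min_correct_per_class or n_letter < min_correct_per_class
    )

    report = {
        "n_trials": len(trials),
        "n_channels": epochs.n_channels,
        "trials_dropped_behavior": int((~behavioral_keep).sum()),
        **first_pass,
        "exclusion_iterations": n_iter,
        "trials_retained": int(retained_trials.size),
        "channels_retained": int(retained_channels.size),
        "pct_channels_removed": 100.0 * (1.0 - retained_channels.size / epochs.n_channels),
        "cells_excluded": int(cell_excluded.sum()),
        "n_correct_face": n_face,
        "n_correct_letter": n_letter,
        "participant_excluded": participant_excluded,
    }
    return ExclusionResult(
        retained_trials=retained_trials,
        retained_channels=retained_channels,
        cell_excluded=cell_excluded,
        participant_excluded=participant_excluded,
        report=report,
    )
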