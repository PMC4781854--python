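"""Core in-memory containers shared across the pipeline stages.

A *session* is one continuous multi-channel intracranial recording from one
participant together with its trial table (Sternberg recognition-memory
trials).  Channels carry an anatomical (Brodmann-area) label that downstream
statistics use to group electrodes; nothing in this package computes
anatomy — labels are consumed as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TrialRecord",
    "Session",
    "EpochedData",
    "ArtifactMask",
    "DETECTION_WINDOW",
    "BASELINE_DURATION",
    "detection_window_samples",
    "baseline_window_samples",
]

#: Detection epoch relative to probe onset, seconds.  Wide enough to cover
#: the decision period at the 2.5 s analysis RT cap plus the 300 ms buffers
#: used by the feature windows.
DETECTION_WINDOW = (-0.3, 2.8)

#: Pre-trial baseline duration in seconds (window ends at trial onset).
BASELINE_DURATION = 0.3


@dataclass
class TrialRecord:
    """One trial's design, behavior, and session-clock timing anchors.

    ``rt`` is seconds from probe onset to the response;
    ``response_time_abs - probe_onset == rt`` always holds.
    """

    trial_index: int
    stimulus_class: str  # "face" | "letter"
    list_length: int  # 1..4
    is_target: bool
    summed_similarity: float
    correct: bool
    rt: float
    trial_onset: float
    probe_onset: float
    response_time_abs: float

    def __post_init__(self) -> None:
        if self.stimulus_class not in ("face", "letter"):
            raise ValueError(f"unknown stimulus class {self.stimulus_class!r}")
        if self.list_length not in (1, 2, 3, 4):
            raise ValueError("list_length must be in {1,2,3,4}")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if abs((self.response_time_abs - self.probe_onset) - self.rt) > 1e-9:
            raise ValueError("rt must equal response_time_abs - probe_onset")


@dataclass
class SessionGroundTruth:
    """Generator-side truth attached to synthetic sessions for recovery tests."""

    planted_effects: list = field(default_factory=list)
    #: trials x channels x 3 booleans (amplitude, kurtosis, variance)
    artifact_mask_true: np.ndarray | None = None
    ddm_params: dict = field(default_factory=dict)
    n_timeouts: int = 0


@dataclass
class Session:
    """Continuous recording plus trial table for one participant session."""

    subject_id: str
    fs: float
    signal: np.ndarray  # channels x samples
    channel_labels: list[str]
    channel_areas: list[str]
    trials: list[TrialRecord]
    ground_truth: SessionGroundTruth | None = None

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_signal(self, signal: np.ndarray) -> "Session":
        return replace(self, signal=signal)


@dataclass
class EpochedData:
    """Fixed-window epochs (trials x channels x samples) for artifact detection.

    ``window`` is in seconds relative to probe onset.
    """

    data: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_labels: list[str]
    channel_areas: list[str]
    subject_id: str
    trials: list[TrialRecord]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class ArtifactMask:
    """Per (trial, channel) flags for the three artifact criteria.

    ``flags[..., 0]`` amplitude, ``flags[..., 1]`` kurtosis,
    ``flags[..., 2]`` variance.  ``provenance`` records the thresholds used.
    """

    flags: np.ndarray  # trials x channels x 3 bool
    provenance: dict

    CRITERIA = ("amplitude", "kurtosis", "variance")

    def __post_init__(self) -> None:
        if self.flags.ndim != 3 or self.flags.shape[2] != 3:
            raise ValueError("flags must be trials x channels x 3")

    @property
    def any_flag(self) -> np.ndarray:
        """trials x channels boolean: any of the three criteria."""
        return self.flags.any(axis=2)


def detection_window_samples(
    trial: TrialRecord, fs: float, window: tuple[float, float] = DETECTION_WINDOW
) -> tuple[int, int]:
    """Sample range (start, stop) of a trial's detection epoch in the session."""
    start = int(round((trial.probe_onset + window[0]) * fs))
    stop = start + int(round((window[1] - window[0]) * fs))
    return start, stop


def baseline_window_samples(
    trial: TrialRecord, fs: float, duration: float = BASELINE_DURATION
) -> tuple[int, int]:
    """Sample range of a trial's pre-trial baseline (ends at trial onset)."""
    stop = int(round(trial.trial_onset * fs))
    start = stop - int(round(duration * fs))
    return start, stop


def trials_to_arrays(trials: Sequence[TrialRecord]) -> dict[str, np.ndarray]:
    """Column-wise view of a trial list (convenience for vectorized code)."""
    return {
        "trial_index": np.array([t.trial_index for t in trials]),
        "stimulus_class": np.array([t.stimulus_class for t in trials]),
        "list_length": np.array([t.list_length for t in trials]),
        "is_target": np.array([t.is_target for t in trials]),
        "summed_similarity": np.array([t.summed_similarity for t in trials]),
        "correct": np.array([t.correct for t in trials]),
        "rt": np.array([t.rt for t in trials]),
        "trial_onset": np.array([t.trial_onset for t in trials]),
        "probe_onset": np.array([t.probe_onset for t in trials]),
        "response_time_abs": np.array([t.response_time_abs for t in trials]),
    }
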