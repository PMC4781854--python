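"""Model-predicted activity regressors aligned to the feature windows.

Three hypothesized decision-window profiles: a linear ramp 0 -> 1 (evidence
accumulation), a downramp 1 -> 0 (onset-triggered decay), and a boxcar
(sustained "attention on" state).  Each trial's active segment spans the
decision period minus the participant's non-decision time Ter, split half
before and half after; the 300 ms buffers and the Ter margins are zero.
The per-trial segments are concatenated in trial order using the *same*
window table as the features, so lengths and boundaries match exactly.

Permutation variants rearrange the per-trial durations (the multiset of
segment lengths is preserved, total length unchanged) so regressor onsets
no longer correspond to probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectral import WindowTable

__all__ = [
    "Regressor",
    "REGRESSOR_KINDS",
    "build_trial_segment",
    "build_segments",
    "build_regressor",
    "permute_trial_durations",
    "concatenate_segments",
]

logger = logging.getLogger(__name__)

REGRESSOR_KINDS = ("ramp", "downramp", "boxcar")


@dataclass
class Regressor:
    """Concatenated regressor samples aligned to a FeatureSeries."""

    kind: str
    values: np.ndarray
    table: WindowTable

    def __post_init__(self) -> None:
        if self.kind not in REGRESSOR_KINDS:
            raise ValueError(f"unknown regressor kind {self.kind!r}")
        if len(self.values) != self.table.total_length:
            raise ValueError("regressor length does not match its window table")


def build_trial_segment(
    kind: str,
    rt: float,
    ter: float,
    n_total: int,
    fs: float = 50.0,
    buffer: float = 0.3,
) -> np.ndarray:
    """One trial's regressor segment on the 50 Hz grid.

    The active segment spans [Ter/2, rt - Ter/2] within the decision window;
    endpoints are rounded to the sample grid.  A ramp over n active points
    is i/(n-1), i = 0..n-1; the downramp is its exact reversal, so
    ramp + downramp == boxcar pointwise on the active segment.  Pathological
    trials with rt <= Ter are clamped to the central 20% of the decision
    window (and logged) rather than dropped, preserving feature/regressor
    alignment.
    """
    if kind not in REGRESSOR_KINDS:
        raise ValueError(f"unknown regressor kind {kind!r}")
    seg = np.zeros(n_total)
    nb = int(round(buffer * fs))
    i0 = int(round((buffer + ter / 2.0) * fs))
    i1 = int(round((buffer + rt - ter / 2.0) * fs))
    if rt <= ter or i1 - i0 < 2:
        n_dec = n_total - 2 * nb
        mid = nb + n_dec / 2.0
        half = max(n_dec * 0.1, 1.0)
        i0, i1 = int(round(mid - half)), int(round(mid + half))
        logger.info(
            "trial with rt=%.3f <= Ter=%.3f: active segment clamped to central 20%%",
            rt,
            ter,
        )
    i0 = max(i0, 0)
    i1 = min(i1, n_total)
    n_active = i1 - i0
    if n_active < 2:
        return seg
    if kind == "ramp":
        seg[i0:i1] = np.linspace(0.0, 1.0, n_active)
    elif kind == "downramp":
        # 1 - ramp, so ramp + downramp == boxcar exactly (to the last bit)
        seg[i0:i1] = 1.0 - np.linspace(0.0, 1.0, n_active)
    else:
        seg[i0:i1] = 1.0
    return seg


def build_segments(
    kind: str, table: WindowTable, ter: float
) -> list[np.ndarray]:
    """Per-trial segments for every retained trial in a window table."""
    return [
        build_trial_segment(
            kind,
            float(table.rts[i]),
            ter,
            int(table.n_samples[i]),
            fs=table.fs,
            buffer=table.buffer,
        )
        for i in range(table.n_trials)
    ]


def concatenate_segments(segments: list[np.ndarray], order: np.ndarray | None = None) -> np.ndarray:
    if order is None:
        order = np.arange(len(segments))
    if len(segments) == 0:
        return np.zeros(0)
    return np.concatenate([segments[i] for i in order])


def build_regressor(
    kind: str,
    table: WindowTable,
    ter: float,
    order: np.ndarray | None = None,
) -> Regressor:
    """Regressor aligned to (or, with ``order``, permuted against) a table.

    With ``order`` given, segments are built from the permuted duration
    sequence but concatenated into the same total length, so the feature
    series stays fixed while regressor onsets no longer match probes.
    """
    segments = build_segments(kind, table, ter)
    if order is None:
        values = concatenate_segments(segments)
    else:
        values = concatenate_segments(segments, np.asarray(order))
    return Regressor(kind=kind, values=values, table=table)


def permute_trial_durations(
    n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniformly random rearrangement of the per-trial durations."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials to permute durations")
    return rng.permutation(n_trials)
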