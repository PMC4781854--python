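"""Vincentized event-related averages and accumulator diagnostics.

Trials of unequal duration are resampled ("vincentized") to a common
length — the bin's median RT at the 50 Hz feature rate — before averaging,
so that processes occupying a fixed *fraction* of the decision period line
up across trials.  Averages are built per electrode, then across a cell's
electrodes, then across subjects with equal subject weight.

Diagnostics quantify three accumulator signatures on the binned averages:
the peak should arrive later on slow trials, peak at a response-invariant
amplitude (the decision threshold), and rise more steeply when more
decision evidence is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

from .bands import FEATURES
from .containers import TrialRecord
from .spectral import FeatureBundle

__all__ = [
    "vincentize_trial",
    "VincentizedAverage",
    "binned_average",
    "AccumulatorDiagnostics",
    "accumulator_diagnostics",
    "rt_bin_label",
]

FEATURE_FS = 50.0


def vincentize_trial(values: np.ndarray, n_target: int) -> np.ndarray:
    """Linear-interpolation resampling onto n_target equally spaced points.

    Endpoints are preserved exactly; with ``n_target == len(values)`` this
    is the identity to machine precision.
    """
    values = np.asarray(values, float)
    if n_target < 2:
        raise ValueError("n_target must be at least 2")
    if len(values) < 2:
        raise ValueError("trial must have at least 2 samples")
    src = np.arange(len(values), dtype=float)
    dst = np.linspace(0.0, len(values) - 1.0, n_target)
    return np.interp(dst, src, values)


def rt_bin_label(rt: float, edges: tuple[float, float] = (0.9, 1.7)) -> str:
    if rt < edges[0]:
        return "short"
    if rt <= edges[1]:
        return "medium"
    return "long"


@dataclass
class VincentizedAverage:
    """One bin's mean decision-period time course at the bin's median-RT length."""

    label: str
    definition: str
    band: str
    area: str
    n_trials: int
    median_rt: float
    values: np.ndarray
    fs: float = FEATURE_FS

    @property
    def times(self) -> np.ndarray:
        """Real-time axis in seconds (de-vincentized via the median RT)."""
        return np.arange(len(self.values)) / self.fs


def _assign_bins(
    trials: list[TrialRecord],
    binning: str,
    rt_edges: tuple[float, float],
    evidence_levels: int,
    evidence_edges: np.ndarray | None,
) -> dict[str, list[int]]:
    bins: dict[str, list[int]] = {}
    if binning == "rt":
        for i, tr in enumerate(trials):
            bins.setdefault(rt_bin_label(tr.rt, rt_edges), []).append(i)
    elif binning == "list_length":
        for i, tr in enumerate(trials):
            bins.setdefault(f"ll{tr.list_length}", []).append(i)
    elif binning == "evidence":
        s = np.array([tr.summed_similarity for tr in trials])
        if evidence_edges is None:
            qs = np.linspace(0, 100, evidence_levels + 1)[1:-1]
            evidence_edges = np.percentile(s, qs)
        lvl = np.searchsorted(evidence_edges, s)
        for i in range(len(trials)):
            bins.setdefault(f"evidence{int(lvl[i])}", []).append(i)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    return bins


def binned_average(
    cohort: list[tuple[FeatureBundle, list[TrialRecord]]],
    area: str,
    band: str,
    binning: str = "rt",
    stimulus_class: str | None = None,
    rt_edges: tuple[float, float] = (0.9, 1.7),
    evidence_levels: int = 5,
    evidence_edges: np.ndarray | None = None,
) -> list[VincentizedAverage]:
    """Vincentized bin averages for one (area, band) cell across a cohort.

    ``cohort`` pairs each subject's FeatureBundle with the retained trials
    the bundle's window table refers to.  Bins: ``rt`` (<0.9 / 0.9-1.7 /
    >1.7 s by default), ``evidence`` (summed-similarity levels), or
    ``list_length``.  Each trial's decision window (buffers removed) is
    resampled to the bin's pooled median-RT length, averaged within
    electrode, across the cell's electrodes, then across subjects with
    equal weight.  Empty bins are skipped.
    """
    if band not in FEATURES:
        raise ValueError(f"unknown band {band!r}")
    fi = FEATURES.index(band)

    # pool trials across subjects to fix each bin's median RT
    pooled: dict[str, list[float]] = {}
    per_subject_bins = []
    for bundle, trials in cohort:
        use = [
            i
            for i, tr in enumerate(trials)
            if stimulus_class is None or tr.stimulus_class == stimulus_class
        ]
        sub_trials = [trials[i] for i in use]
        bins = _assign_bins(sub_trials, binning, rt_edges, evidence_levels, evidence_edges)
        bins = {k: [use[j] for j in v] for k, v in bins.items()}
        per_subject_bins.append(bins)
        for k, idx in bins.items():
            pooled.setdefault(k, []).extend(trials[i].rt for i in idx)

    out = []
    for label in sorted(pooled):
        median_rt = float(np.median(pooled[label]))
        n_target = max(int(round(median_rt * FEATURE_FS)), 2)
        subject_means = []
        n_trials = 0
        for (bundle, trials), bins in zip(cohort, per_subject_bins):
            idx = bins.get(label, [])
            chans = [c for c, a in enumerate(bundle.channel_areas) if a == area]
            if not idx or not chans:
                continue
            nb = bundle.table.buffer_samples()
            electrode_means = []
            for c in chans:
                tracks = []
                for i in idx:
                    if bundle.cell_excluded[i, c]:
                        continue
                    o0 = int(bundle.table.offsets[i])
                    o1 = int(bundle.table.offsets[i + 1])
                    win = bundle.data[fi, c, o0 + nb : o1 - nb]  # probe -> response
                    if len(win) >= 2:
                        tracks.append(vincentize_trial(win, n_target))
                if tracks:
                    electrode_means.append(np.mean(tracks, axis=0))
                    n_trials += len(tracks)
            if electrode_means:
                subject_means.append(np.mean(electrode_means, axis=0))
        if not subject_means:
            continue
        out.append(
            VincentizedAverage(
                label=label,
                definition=f"{binning}={label}"
                + (f", class={stimulus_class}" if stimulus_class else ""),
                band=band,
                area=area,
                n_trials=n_trials,
                median_rt=median_rt,
                values=np.mean(subject_means, axis=0),
            )
        )
    return out


@dataclass
class AccumulatorDiagnostics:
    """Per-bin peak geometry plus the three accumulator criteria."""

    peak_latency: dict[str, float]
    peak_amplitude: dict[str, float]
    mean_slope: dict[str, float]
    latency_scales_with_rt: bool | None
    amplitude_rt_invariant: bool | None
    slope_scales_with_evidence: bool | None
    stats: dict = field(default_factory=dict)
    flat_bins: list[str] = field(default_factory=list)


def _peak(avg: VincentizedAverage, noise_floor: float) -> tuple[float, float, float] | None:
    """(latency s, signed amplitude, mean slope z/s); None if flat."""
    dev = np.abs(avg.values)
    if dev.max() <= noise_floor:
        return None
    i = int(dev.argmax())
    latency = i / avg.fs
    t = np.arange(len(avg.values)) / avg.fs
    slope = float(np.polyfit(t, avg.values, 1)[0]) if len(avg.values) > 2 else 0.0
    return latency, float(avg.values[i]), slope


def accumulator_diagnostics(
    rt_bins: list[VincentizedAverage],
    evidence_bins: list[VincentizedAverage] | None = None,
    amplitude_ratio_bound: float = 1.5,
    latency_rho_min: float = 0.9,
    noise_floor: float = 0.0,
) -> AccumulatorDiagnostics:
    """Test the three accumulator signatures on binned averages.

    (1) peak latency increases with the bin's median RT (Spearman rho >
    ``latency_rho_min``); (2) peak magnitude is RT-invariant (max pairwise
    ratio < ``amplitude_ratio_bound``); (3) the mean slope magnitude is
    strictly ordered across evidence levels (steeper with more evidence).
    The rho and ratio bounds are package defaults, not literature values.
    Flat bins (no deviation above ``noise_floor``) make the affected
    criteria undefined (None) and are listed in ``flat_bins``.
    """
    if len(rt_bins) < 2:
        raise ValueError("need at least 2 RT bins")

    peak_latency: dict[str, float] = {}
    peak_amplitude: dict[str, float] = {}
    mean_slope: dict[str, float] = {}
    flat: list[str] = []
    rts, lats, amps = [], [], []
    for avg in rt_bins:
        p = _peak(avg, noise_floor)
        if p is None:
            flat.append(avg.label)
            continue
        lat, amp, slope = p
        peak_latency[avg.label] = lat
        peak_amplitude[avg.label] = amp
        mean_slope[avg.label] = slope
        rts.append(avg.median_rt)
        lats.append(lat)
        amps.append(abs(amp))

    stats: dict = {}
    if len(lats) >= 2 and not flat:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = float(spstats.spearmanr(rts, lats).statistic)
        if not np.isfinite(rho):  # constant latencies: no monotone relation
            rho = 0.0
        stats["latency_rt_spearman"] = rho
        latency_ok: bool | None = rho > latency_rho_min
        ratio = float(max(amps) / min(amps)) if min(amps) > 0 else np.inf
        stats["amplitude_max_ratio"] = ratio
        amplitude_ok: bool | None = ratio < amplitude_ratio_bound
    else:
        latency_ok = amplitude_ok = None

    slope_ok: bool | None = None
    if evidence_bins:
        ev_slopes = []
        for avg in sorted(evidence_bins, key=lambda a: a.label):
            p = _peak(avg, noise_floor)
            if p is None:
                flat.append(avg.label)
                ev_slopes = []
                break
            mean_slope[avg.label] = p[2]
            ev_slopes.append(abs(p[2]))
        if ev_slopes:
            stats["evidence_slopes"] = ev_slopes
            slope_ok = all(b > a for a, b in zip(ev_slopes, ev_slopes[1:]))

    return AccumulatorDiagnostics(
        peak_latency=peak_latency,
        peak_amplitude=peak_amplitude,
        mean_slope=mean_slope,
        latency_scales_with_rt=latency_ok,
        amplitude_rt_invariant=amplitude_ok,
        slope_scales_with_evidence=slope_ok,
        stats={
            **stats,
            "latency_rho_min": latency_rho_min,
            "amplitude_ratio_bound": amplitude_ratio_bound,
        },
        flat_bins=flat,
    )
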