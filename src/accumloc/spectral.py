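"""Morlet wavelet power, baseline normalization, and feature assembly.

Power is computed by convolution with complex Morlet wavelets (width 5
cycles) at 53 log-spaced frequencies between 1 and 100 Hz, z-scored per
electrode and frequency against the pooled 300 ms pre-trial baselines,
averaged into six bands, downsampled to 50 Hz, and cut into decision
windows (probe - 0.3 s to response + 0.3 s) that are concatenated per
electrode into one long feature per band.  The seventh feature is the
baseline-z-scored broadband signal itself.

Signals sampled above 250 Hz are decimated to 250 Hz before the wavelet
transform; all feature tracks end up at 50 Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
import scipy.fft

from .bands import BANDS, FEATURES, band_members, morlet_freqs
from .containers import Session, TrialRecord, baseline_window_samples

__all__ = [
    "morlet_power",
    "baseline_normalize",
    "aggregate_features",
    "downsample_tracks",
    "WindowTable",
    "FeatureSeries",
    "FeatureBundle",
    "build_window_table",
    "build_feature_series",
    "compute_feature_bundle",
]

WAVELET_FS = 250.0
FEATURE_FS = 50.0
BUFFER = 0.3


def _sigma_t(freq: float, width: float) -> float:
    return width / (2.0 * np.pi * freq)


def _morlet_spectrum(n: int, fs: float, freq: float, width: float) -> np.ndarray:
    """Fourier transform of the energy-normalized complex Morlet wavelet.

    Analytic (negative frequencies zero); the time-domain wavelet is
    (sigma_t sqrt(pi))^(-1/2) exp(-t^2 / 2 sigma_t^2) exp(i 2 pi f t).
    """
    st = _sigma_t(freq, width)
    nu = np.fft.fftfreq(n, d=1.0 / fs)
    amp = (4.0 * np.pi * st**2) ** 0.25
    spec = amp * np.exp(-2.0 * (np.pi * st * (nu - freq)) ** 2)
    spec[nu < 0] = 0.0
    return spec


def _decimate_to(signal: np.ndarray, fs: float, target: float) -> np.ndarray:
    frac = Fraction(target / fs).limit_denominator(1000)
    return sps.resample_poly(signal, frac.numerator, frac.denominator, axis=-1)


def morlet_power(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    width: float = 5.0,
    edge_sigmas: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-resolved wavelet power at each grid frequency.

    Parameters
    ----------
    signal : (..., n_samples) array; the transform runs along the last axis.
    fs : sampling rate, >= 250 Hz (higher rates are decimated to 250 first).
    freqs : frequency grid; defaults to the 53-point log grid.
    edge_sigmas : half-length of the wavelet, in units of its Gaussian SD,
        used to flag edge samples.

    Returns
    -------
    power : (n_freqs, ..., n_samples) squared magnitude of the convolution.
    edge : (n_freqs, n_samples) boolean; True within one wavelet half-length
        of either end, where power is contaminated by the boundary.
    """
    if fs < 250.0:
        raise ValueError("sampling rate must be at least 250 Hz")
    x = np.asarray(signal, float)
    if fs > WAVELET_FS:
        x = _decimate_to(x, fs, WAVELET_FS)
        fs = WAVELET_FS
    if freqs is None:
        freqs = morlet_freqs()
    n = x.shape[-1]
    longest = int(math.ceil(edge_sigmas * _sigma_t(float(np.min(freqs)), width) * fs))
    if n <= 2 * longest:
        raise ValueError(
            f"signal of {n} samples is shorter than the longest wavelet "
            f"({2 * longest} samples at {np.min(freqs):.2f} Hz)"
        )
    nfft = scipy.fft.next_fast_len(n + 2 * longest)
    xf = scipy.fft.fft(x, nfft, axis=-1)
    power = np.empty((len(freqs),) + x.shape, dtype=float)
    edge = np.zeros((len(freqs), n), dtype=bool)
    for i, f in enumerate(freqs):
        wf = _morlet_spectrum(nfft, fs, float(f), width)
        coef = scipy.fft.ifft(xf * wf, axis=-1)[..., :n]
        power[i] = np.abs(coef) ** 2
        half = int(math.ceil(edge_sigmas * _sigma_t(float(f), width) * fs))
        edge[i, :half] = True
        edge[i, n - half :] = True
    return power, edge


def baseline_normalize(
    power: np.ndarray, baseline_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score power against the pooled pre-trial baseline samples.

    ``power`` has time on the last axis; ``baseline_idx`` indexes the pooled
    baseline samples of all retained trials.  Mean and SD are computed per
    leading slice (e.g. per electrode and frequency).  Raises if any slice
    has zero baseline SD, naming the offending slice.
    """
    base = power[..., baseline_idx]
    mu = base.mean(axis=-1)
    sd = base.std(axis=-1)
    bad = np.argwhere(sd == 0)
    if bad.size:
        raise ValueError(f"zero baseline SD at slice index {tuple(bad[0])}")
    z = (power - mu[..., None]) / sd[..., None]
    return z, mu, sd


def aggregate_features(
    z_power: np.ndarray, raw_z: np.ndarray, freqs: np.ndarray | None = None
) -> np.ndarray:
    """Average z-power into the six bands and append the raw track.

    ``z_power`` is (n_freqs, channels, time); ``raw_z`` the baseline-z-scored
    broadband signal (channels, time).  Returns (7, channels, time).
    """
    if freqs is None:
        freqs = morlet_freqs()
    tracks = np.empty((len(FEATURES),) + z_power.shape[1:], dtype=z_power.dtype)
    for b, band in enumerate(BANDS):
        tracks[b] = z_power[band_members(freqs, band)].mean(axis=0)
    tracks[-1] = raw_z
    return tracks


def downsample_tracks(tracks: np.ndarray, fs: float, target: float = FEATURE_FS) -> np.ndarray:
    """Anti-aliased polyphase resampling of feature tracks to 50 Hz."""
    if fs == target:
        return tracks
    frac = Fraction(target / fs).limit_denominator(1000)
    return sps.resample_poly(tracks, frac.numerator, frac.denominator, axis=-1)


@dataclass
class WindowTable:
    """Decision-window layout shared by features and regressors.

    One row per retained trial, in trial order: the window covers
    [probe - buffer, response + buffer) at the feature rate, and
    ``n_samples[i] = round((rt + 2 * buffer) * fs)``.  ``offsets`` are the
    start indices in the concatenated series; identical tables on the
    feature and regressor side are a hard invariant of the pipeline.
    """

    trial_ids: np.ndarray
    rts: np.ndarray
    start_idx: np.ndarray  # window start sample in the continuous 50 Hz track
    n_samples: np.ndarray
    fs: float = FEATURE_FS
    buffer: float = BUFFER

    def __post_init__(self) -> None:
        self.offsets = np.concatenate([[0], np.cumsum(self.n_samples)])

    @property
    def total_length(self) -> int:
        return int(self.offsets[-1])

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def subset(self, keep: np.ndarray) -> "WindowTable":
        return WindowTable(
            trial_ids=self.trial_ids[keep],
            rts=self.rts[keep],
            start_idx=self.start_idx[keep],
            n_samples=self.n_samples[keep],
            fs=self.fs,
            buffer=self.buffer,
        )

    def buffer_samples(self) -> int:
        return int(round(self.buffer * self.fs))


@dataclass
class FeatureSeries:
    """One electrode's concatenated decision-window activity for one feature."""

    electrode: str
    area: str
    feature: str
    values: np.ndarray
    table: WindowTable

    def __post_init__(self) -> None:
        if len(self.values) != self.table.total_length:
            raise ValueError("feature length does not match its window table")


def build_window_table(
    trials: list[TrialRecord],
    fs: float = FEATURE_FS,
    buffer: float = BUFFER,
) -> WindowTable:
    """Window table for a list of retained trials, with overlap truncation.

    Overlapping adjacent windows (response + buffer crossing the next
    probe - buffer) are truncated at the midpoint with a warning; with the
    Sternberg timing and the 2.5 s RT cap this cannot occur.
    """
    starts, lengths, ids, rts = [], [], [], []
    for tr in trials:
        s0 = int(round((tr.probe_onset - buffer) * fs))
        n = int(round((tr.rt + 2 * buffer) * fs))
        starts.append(s0)
        lengths.append(n)
        ids.append(tr.trial_index)
        rts.append(tr.rt)
    starts_a = np.array(starts)
    lengths_a = np.array(lengths)
    for i in range(len(starts) - 1):
        end = starts_a[i] + lengths_a[i]
        if end > starts_a[i + 1]:
            warnings.warn(
                f"decision windows of trials {ids[i]} and {ids[i + 1]} overlap; "
                "truncating at the midpoint",
                stacklevel=2,
            )
            mid = (end + starts_a[i + 1]) // 2
            lengths_a[i] = mid - starts_a[i]
            shift = mid - starts_a[i + 1]
            starts_a[i + 1] = mid
            lengths_a[i + 1] -= shift
    return WindowTable(
        trial_ids=np.array(ids),
        rts=np.array(rts),
        start_idx=starts_a,
        n_samples=lengths_a,
        fs=fs,
        buffer=buffer,
    )


@dataclass
class FeatureBundle:
    """All seven features of one session, concatenated over retained trials.

    ``data`` is (7, channels, total_length) aligned to ``table``;
    ``cell_excluded`` marks (retained trial, channel) cells whose windows
    must be omitted — from the feature *and* its matching regressor — for
    that electrode.
    """

    subject_id: str
    channel_labels: list[str]
    channel_areas: list[str]
    data: np.ndarray
    table: WindowTable
    cell_excluded: np.ndarray

    def electrode_keep(self, channel: int) -> np.ndarray:
        return ~self.cell_excluded[:, channel]

    def series(self, feature: str, channel: int) -> FeatureSeries:
        """Per-electrode feature with excluded trials' windows removed."""
        fi = FEATURES.index(feature)
        keep = self.electrode_keep(channel)
        tab = self.table.subset(keep)
        chunks = [
            self.data[fi, channel, self.table.offsets[i] : self.table.offsets[i + 1]]
            for i in np.nonzero(keep)[0]
        ]
        values = np.concatenate(chunks) if chunks else np.zeros(0)
        return FeatureSeries(
            electrode=self.channel_labels[channel],
            area=self.channel_areas[channel],
            feature=feature,
            values=values,
            table=tab,
        )


def build_feature_series(
    tracks_50: np.ndarray,
    table: WindowTable,
    channel_labels: list[str],
    channel_areas: list[str],
    subject_id: str,
    cell_excluded: np.ndarray | None = None,
) -> FeatureBundle:
    """Cut the 50 Hz feature tracks into concatenated decision windows."""
    n_ch = tracks_50.shape[1]
    total = table.total_length
    data = np.empty((tracks_50.shape[0], n_ch, total), dtype=tracks_50.dtype)
    for i in range(table.n_trials):
        s0 = int(table.start_idx[i])
        n = int(table.n_samples[i])
        o = int(table.offsets[i])
        if s0 < 0 or s0 + n > tracks_50.shape[-1]:
            raise ValueError("decision window falls outside the recorded signal")
        data[:, :, o : o + n] = tracks_50[:, :, s0 : s0 + n]
    if cell_excluded is None:
        cell_excluded = np.zeros((table.n_trials, n_ch), dtype=bool)
    return FeatureBundle(
        subject_id=subject_id,
        channel_labels=list(channel_labels),
        channel_areas=list(channel_areas),
        data=data,
        table=table,
        cell_excluded=cell_excluded,
    )


def _baseline_indices(trials: list[TrialRecord], fs: float, n: int) -> np.ndarray:
    idx = np.concatenate([np.arange(*baseline_window_samples(tr, fs)) for tr in trials])
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("baseline windows fall outside the recorded signal")
    return idx


def compute_feature_bundle(
    session: Session,
    retained_trials: np.ndarray,
    retained_channels: np.ndarray,
    cell_excluded: np.ndarray | None = None,
    width: float = 5.0,
    buffer: float = BUFFER,
) -> FeatureBundle:
    """Full spectral stage for one (cleaned) session.

    Streams over the 53 wavelet frequencies: per frequency, power is
    z-scored against the pooled baselines of the retained trials and
    accumulated into its band's mean; the raw track is the baseline-z-scored
    broadband signal.  All tracks are resampled to 50 Hz and cut into
    decision windows.

    Wavelet coefficients for bands up to beta are evaluated on a decimated
    time grid by inverse-transforming only the occupied part of the product
    spectrum — exact samples of the full-rate convolution, since the Morlet
    spectrum is (numerically) band-limited — which keeps the transform
    affordable on long sessions.
    """
    x = session.signal[retained_channels].astype(float)
    fs = session.fs
    if fs > WAVELET_FS:
        x = _decimate_to(x, fs, WAVELET_FS)
        fs = WAVELET_FS
    trials = [session.trials[i] for i in retained_trials]

    freqs = morlet_freqs()
    n = x.shape[-1]
    longest = int(math.ceil(3.0 * _sigma_t(float(freqs.min()), width) * fs))
    # nfft divisible by 4 so the decimated spectra slice evenly
    nfft = 4 * scipy.fft.next_fast_len(-(-(n + 2 * longest) // 4))
    xf = scipy.fft.fft(x.astype(np.complex64), nfft, axis=-1)

    band_of_freq = np.full(len(freqs), -1)
    band_counts = np.zeros(len(BANDS))
    for b, band in enumerate(BANDS):
        m = band_members(freqs, band)
        band_of_freq[m] = b
        band_counts[b] = m.sum()

    def decimation_factor(f: float) -> int:
        # occupied width of the one-sided product spectrum, Nyquist-clipped
        sig_f = f / width
        w = min(f + 4.0 * sig_f, fs / 2.0) - max(f - 4.0 * sig_f, 0.0)
        for d in (4, 2):
            if fs / d > 1.02 * w:
                return d
        return 1

    band_d = {
        b: min(decimation_factor(float(f)) for f in freqs[band_of_freq == b])
        for b in range(len(BANDS))
    }
    band_tracks: dict[int, np.ndarray] = {}
    band_rates: dict[int, float] = {}
    base_idx_cache: dict[int, np.ndarray] = {}
    df = fs / nfft
    for i, f in enumerate(freqs):
        b = band_of_freq[i]
        if b < 0:
            continue
        d = band_d[b]
        m = nfft // d
        n_d = -(-n // d)  # samples of the decimated track covering the session
        if b not in band_tracks:
            band_tracks[b] = np.zeros((x.shape[0], n_d))
            band_rates[b] = fs / d
            base_idx_cache[b] = _baseline_indices(trials, fs / d, n_d)
        # demodulated slice of the product spectrum; |coef| is unaffected
        k0 = int(max(float(f) - 4.0 * float(f) / width, 0.0) / df)
        k0 = min(k0, nfft - m)
        wf = _morlet_spectrum(nfft, fs, float(f), width)[k0 : k0 + m].astype(np.float32)
        coef = scipy.fft.ifft(xf[:, k0 : k0 + m] * wf, axis=-1)[..., :n_d] / d
        power = (np.abs(coef) ** 2).astype(float)
        z, _, _ = baseline_normalize(power, base_idx_cache[b])
        band_tracks[b] += z / band_counts[b]

    raw_z, _, _ = baseline_normalize(x, _baseline_indices(trials, fs, n))

    n50 = int(round(n / fs * FEATURE_FS))
    tracks_50 = np.empty((len(FEATURES), x.shape[0], n50))
    for b in band_tracks:
        t50 = downsample_tracks(band_tracks[b], band_rates[b], FEATURE_FS)
        tracks_50[b] = t50[..., :n50]
    tracks_50[-1] = downsample_tracks(raw_z, fs, FEATURE_FS)[..., :n50]

    table = build_window_table(trials, FEATURE_FS, buffer)
    return build_feature_series(
        tracks_50,
        table,
        [session.channel_labels[i] for i in retained_channels],
        [session.channel_areas[i] for i in retained_channels],
        session.subject_id,
        cell_excluded,
    )
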