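"""Synthetic Sternberg-session generator with known ground truth.

Generates (i) trial-by-trial behavior from a drift-diffusion process whose
drift is a monotone function of exemplar-model summed similarity, (ii)
continuous multi-channel field potentials (1/f background plus per-band
oscillatory carriers), with accumulation-like amplitude envelopes planted
in designated (area, band) pairs during decision windows, and (iii)
optional injected artifacts with a ground-truth mask.  Every planted
quantity is recorded so recovery tests are well posed.

Timing follows the jittered Sternberg structure: fixation 1000-1075 ms,
1-4 items of 700-775 ms separated by 275-350 ms, retention 3000-3300 ms,
then probe and response.  Stimulus classes alternate between 30-trial
blocks of synthetic faces and consonants; only face trials vary summed
similarity systematically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bands import BANDS, FEATURES
from .behavior import summed_similarity
from .containers import (
    Session,
    SessionGroundTruth,
    TrialRecord,
    detection_window_samples,
)
from .ddm import DDMParams, sample_ddm_trials

__all__ = [
    "TaskTiming",
    "BehaviorDesign",
    "PlantedEffect",
    "NoiseConfig",
    "ArtifactSpec",
    "generate_behavior",
    "synthesize_recording",
    "inject_artifacts",
    "simulate_session",
]


@dataclass(frozen=True)
class TaskTiming:
    """Jitter ranges (seconds) of the Sternberg trial; all uniform."""

    fixation: tuple[float, float] = (1.000, 1.075)
    item: tuple[float, float] = (0.700, 0.775)
    isi: tuple[float, float] = (0.275, 0.350)
    retention: tuple[float, float] = (3.000, 3.300)
    feedback: float = 0.5
    iti: float = 0.5
    lead_in: float = 5.0
    lead_out: float = 5.0


@dataclass(frozen=True)
class BehaviorDesign:
    """Experiment design plus the behavior-generating model.

    Drift on each trial is v = v_max * tanh(k * (S - criterion)) with S the
    summed similarity of the probe to the memory set; the upper boundary is
    the "target" response.  Faces vary probe-to-set distance over
    ``face_target_distances`` / ``face_lure_distances``; letters are one-hot
    items, so their summed similarity is fixed given list length.
    """

    n_blocks: int = 2
    trials_per_block: int = 30
    block_classes: tuple[str, ...] = ("face", "letter")
    list_lengths: tuple[int, ...] = (1, 2, 3, 4)
    p_target: float = 0.5
    item_dim: int = 8
    similarity_decay: float = 3.0
    face_target_distances: tuple[float, ...] = (0.0, 0.08, 0.18, 0.3, 0.5)
    face_lure_distances: tuple[float, ...] = (0.5, 0.65, 0.85, 1.05, 1.3)
    v_max: float = 0.17
    k: float = 2.4
    criterion: float = 0.3
    a: float = 0.18
    z_frac: float = 0.5
    ter: float = 0.63
    s: float = 0.1
    dt: float = 0.001
    max_time: float = 5.0

    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def drift(self, s_sim: float) -> float:
        return self.v_max * float(np.tanh(self.k * (s_sim - self.criterion)))


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth decision-window envelope planted in one (area, band).

    ``amplitude`` is the envelope gain as a fraction of the band carrier's
    baseline amplitude; ``profile`` is one of ramp/downramp/boxcar/none.
    """

    area: str
    band: str
    profile: str = "ramp"
    amplitude: float = 0.75
    sign: int = 1

    def __post_init__(self) -> None:
        if self.profile not in ("ramp", "downramp", "boxcar", "none"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.band not in FEATURES:
            raise ValueError(f"unknown band {self.band!r}")


@dataclass(frozen=True)
class NoiseConfig:
    """Background-signal parameters for the field-potential generator."""

    pink_sd: float = 1.0
    pink_exponent: float = 1.0  # 0 gives white noise
    carrier_amplitude: float = 0.5
    carrier_amplitudes: dict | None = None  # per-band overrides
    phase_jitter: float = 0.0  # rad/sqrt(s) Wiener phase noise on carriers

    def amplitude_for(self, band_name: str) -> float:
        if self.carrier_amplitudes and band_name in self.carrier_amplitudes:
            return float(self.carrier_amplitudes[band_name])
        return self.carrier_amplitude


@dataclass(frozen=True)
class ArtifactSpec:
    """Injection rates (per trial x channel cell) and magnitudes."""

    amplitude_rate: float = 0.0
    kurtosis_rate: float = 0.0
    variance_rate: float = 0.0
    amplitude_size: float = 8.0  # in global SDs of the clean signal
    amplitude_duration: float = 0.1  # s
    n_spikes: int = 5
    spike_size: float = 6.0  # in cell SDs
    variance_factor: float = 3.0

    def __post_init__(self) -> None:
        for r in (self.amplitude_rate, self.kurtosis_rate, self.variance_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must lie in [0, 1]")


def _uniform(rng: np.random.Generator, rng_bounds: tuple[float, float]) -> float:
    lo, hi = rng_bounds
    return float(rng.uniform(lo, hi))


def _face_item(rng: np.random.Generator, dim: int) -> np.ndarray:
    x = rng.standard_normal(dim)
    return x / np.linalg.norm(x)


def _perturb(item: np.ndarray, dist: float, rng: np.random.Generator) -> np.ndarray:
    if dist == 0.0:
        return item.copy()
    d = rng.standard_normal(item.size)
    d /= np.linalg.norm(d)
    return item + dist * d


def generate_behavior(
    design: BehaviorDesign,
    rng: np.random.Generator,
    params_map: dict[str, DDMParams] | None = None,
    timing: TaskTiming | None = None,
) -> tuple[list[TrialRecord], SessionGroundTruth]:
    """Simulate one session's trials: design, diffusion behavior, timing.

    ``params_map`` optionally overrides the diffusion parameters per
    stimulus class (the ``v`` field of a supplied ``DDMParams`` is used as
    that class's ``v_max``).  Returns the trial list plus ground truth
    (generating parameters, timeout count).
    """
    if design.n_trials() == 0:
        raise ValueError("empty design: no trials to generate")
    timing = timing or TaskTiming()

    classes: list[str] = []
    for b in range(design.n_blocks):
        cls = design.block_classes[b % len(design.block_classes)]
        classes.extend([cls] * design.trials_per_block)

    n = len(classes)
    list_lengths = rng.choice(design.list_lengths, size=n)
    is_target = rng.random(n) < design.p_target

    # summed similarity and drift per trial
    s_sim = np.empty(n)
    drifts = np.empty(n)
    a_arr = np.empty(n)
    z_arr = np.empty(n)
    ter_arr = np.empty(n)
    s_scale = design.s
    params_used: dict[str, DDMParams] = {}
    n_letters = 26

    for i, cls in enumerate(classes):
        ll = int(list_lengths[i])
        if cls == "face":
            items = [_face_item(rng, design.item_dim) for _ in range(ll)]
            anchor = items[int(rng.integers(ll))]
            levels = design.face_target_distances if is_target[i] else design.face_lure_distances
            dist = float(levels[int(rng.integers(len(levels)))])
            probe = _perturb(anchor, dist, rng)
        else:
            # letters: one-hot consonants; distinct letters sit sqrt(2) apart
            letters = rng.choice(n_letters, size=ll, replace=False)
            items = [np.eye(n_letters)[j] for j in letters]
            if is_target[i]:
                probe = items[int(rng.integers(ll))].copy()
            else:
                others = np.setdiff1d(np.arange(n_letters), letters)
                probe = np.eye(n_letters)[int(rng.choice(others))]
        s_sim[i] = summed_similarity(probe, np.array(items), c=design.similarity_decay)

        if params_map and cls in params_map:
            p = params_map[cls]
            v_max, a_i, z_i, ter_i = p.v, p.a, p.z_frac, p.ter
            s_scale = p.s
        else:
            v_max, a_i, z_i, ter_i = design.v_max, design.a, design.z_frac, design.ter
        drifts[i] = v_max * np.tanh(design.k * (s_sim[i] - design.criterion))
        a_arr[i], z_arr[i], ter_arr[i] = a_i, z_i, ter_i
        params_used.setdefault(
            cls, DDMParams(v=v_max, a=a_i, z_frac=z_i, ter=ter_i, s=s_scale)
        )

    upper, rts, n_timeouts = sample_ddm_trials(
        drifts, a_arr, z_arr, ter_arr, s_scale, rng, dt=design.dt, max_time=design.max_time
    )
    correct = upper == is_target

    trials: list[TrialRecord] = []
    cursor = timing.lead_in
    for i, cls in enumerate(classes):
        trial_onset = cursor
        t = trial_onset + _uniform(rng, timing.fixation)
        ll = int(list_lengths[i])
        for j in range(ll):
            t += _uniform(rng, timing.item)
            if j < ll - 1:
                t += _uniform(rng, timing.isi)
        t += _uniform(rng, timing.retention)
        probe_onset = t
        response = probe_onset + float(rts[i])
        trials.append(
            TrialRecord(
                trial_index=i,
                stimulus_class=cls,
                list_length=ll,
                is_target=bool(is_target[i]),
                summed_similarity=float(s_sim[i]),
                correct=bool(correct[i]),
                rt=float(rts[i]),
                trial_onset=trial_onset,
                probe_onset=probe_onset,
                response_time_abs=response,
            )
        )
        cursor = response + timing.feedback + timing.iti

    truth = SessionGroundTruth(ddm_params=params_used, n_timeouts=n_timeouts)
    return trials, truth


def _profile_values(profile: str, n: int) -> np.ndarray:
    if n < 2:
        return np.ones(max(n, 0))
    if profile == "ramp":
        return np.linspace(0.0, 1.0, n)
    if profile == "downramp":
        return np.linspace(1.0, 0.0, n)
    if profile == "boxcar":
        return np.ones(n)
    raise ValueError(f"unknown profile {profile!r}")


def _pink_noise(n: int, rng: np.random.Generator, exponent: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with a 1/f^exponent power spectrum."""
    nf = n // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    f = np.fft.rfftfreq(n)
    scale = np.zeros(nf)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def planted_envelope(
    trials: list[TrialRecord],
    effect: PlantedEffect,
    n_samples: int,
    fs: float,
    ter: float,
) -> np.ndarray:
    """Multiplicative envelope implementing one planted effect.

    The profile spans each decision window minus the generating
    non-decision time, split half before / half after — mirroring the
    assumption the analysis regressors make — and is 1 elsewhere.
    """
    env = np.ones(n_samples)
    if effect.profile == "none" or effect.amplitude == 0.0:
        return env
    for tr in trials:
        t0 = tr.probe_onset + ter / 2.0
        t1 = tr.response_time_abs - ter / 2.0
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        i0, i1 = max(i0, 0), min(i1, n_samples)
        if i1 - i0 < 2:
            continue
        prof = _profile_values(effect.profile, i1 - i0)
        env[i0:i1] = np.maximum(1.0 + effect.sign * effect.amplitude * prof, 0.0)
    return env


def synthesize_recording(
    trials: list[TrialRecord],
    channel_areas: list[str],
    planted: list[PlantedEffect],
    noise_cfg: NoiseConfig,
    fs: float,
    rng: np.random.Generator,
    ter: float = 0.63,
    lead_out: float = 5.0,
) -> np.ndarray:
    """Continuous multi-channel signal: pink noise + band carriers + plants.

    Each channel is 1/f noise plus one sinusoidal carrier per band at the
    band's geometric-mean frequency with random (optionally drifting)
    phase.  Channels in a planted area have that band's carrier amplitude
    modulated by the planted profile during decision windows; a "raw" plant
    modulates broadband gain instead.
    """
    if not 250.0 <= fs <= 1024.0:
        raise ValueError("sampling rate must lie in [250, 1024] Hz")
    if not channel_areas:
        raise ValueError("channel map must not be empty")
    if not trials:
        raise ValueError("no trials to synthesize")
    areas = set(channel_areas)
    for p in planted:
        if p.profile != "none" and p.area not in areas:
            raise ValueError(f"planted area {p.area!r} absent from channel map")

    duration = trials[-1].response_time_abs + lead_out
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    envelopes: dict[tuple[str, str], np.ndarray] = {}
    for p in planted:
        if p.profile != "none" and p.amplitude > 0:
            envelopes[(p.area, p.band)] = planted_envelope(trials, p, n, fs, ter)

    n_ch = len(channel_areas)
    signal = np.empty((n_ch, n), dtype=np.float32)
    for c, area in enumerate(channel_areas):
        x = _pink_noise(n, rng, noise_cfg.pink_exponent) * noise_cfg.pink_sd
        for band in BANDS:
            amp = noise_cfg.amplitude_for(band.name)
            if amp == 0.0:
                continue
            phase = 2.0 * np.pi * band.carrier_frequency() * t + rng.uniform(0, 2 * np.pi)
            if noise_cfg.phase_jitter > 0:
                phase = phase + np.cumsum(rng.standard_normal(n)) * (
                    noise_cfg.phase_jitter / np.sqrt(fs)
                )
            carrier = np.cos(phase)
            env = envelopes.get((area, band.name))
            if env is not None:
                carrier *= env
            x += amp * carrier
        gain = envelopes.get((area, "raw"))
        if gain is not None:
            x *= gain
        signal[c] = x
    return signal


def inject_artifacts(
    session: Session, spec: ArtifactSpec, rng: np.random.Generator
) -> Session:
    """Insert amplitude / kurtosis / variance artifacts into trial epochs.

    Each (trial, channel) cell is independently hit per criterion at the
    configured rate, inside the detection window; the ground-truth mask
    (trials x channels x 3) is recorded on the returned session.  With all
    rates zero the signal is returned unchanged bit-for-bit.
    """
    n_trials, n_ch = len(session.trials), session.n_channels
    mask = np.zeros((n_trials, n_ch, 3), dtype=bool)
    truth = session.ground_truth or SessionGroundTruth()

    if spec.amplitude_rate == spec.kurtosis_rate == spec.variance_rate == 0.0:
        out = replace(session, signal=session.signal.copy())
        out.ground_truth = replace(truth, artifact_mask_true=mask)
        return out

    mask[..., 0] = rng.random((n_trials, n_ch)) < spec.amplitude_rate
    mask[..., 1] = rng.random((n_trials, n_ch)) < spec.kurtosis_rate
    mask[..., 2] = rng.random((n_trials, n_ch)) < spec.variance_rate

    signal = session.signal.astype(np.float64, copy=True)
    fs = session.fs
    global_sd = float(signal.std())

    for ti, tr in enumerate(session.trials):
        i0, i1 = detection_window_samples(tr, fs)
        i0, i1 = max(i0, 0), min(i1, session.n_samples)
        n_win = i1 - i0
        if n_win < 8:
            continue
        for ci in range(n_ch):
            cell = signal[ci, i0:i1]
            if mask[ti, ci, 2]:
                m = cell.mean()
                cell[:] = m + (cell - m) * np.sqrt(spec.variance_factor)
            if mask[ti, ci, 0]:
                dur = int(round(spec.amplitude_duration * fs))
                dur = min(max(dur, 2), n_win)
                pos = int(rng.integers(0, n_win - dur + 1))
                bump = np.sin(np.linspace(0, np.pi, dur)) * spec.amplitude_size * global_sd
                cell[pos : pos + dur] += bump * (1 if rng.random() < 0.5 else -1)
            if mask[ti, ci, 1]:
                sd = cell.std()
                pos = rng.choice(n_win, size=min(spec.n_spikes, n_win), replace=False)
                signs = np.where(rng.random(pos.size) < 0.5, -1.0, 1.0)
                cell[pos] += signs * spec.spike_size * sd

    out = replace(session, signal=signal.astype(session.signal.dtype))
    out.ground_truth = replace(truth, artifact_mask_true=mask)
    return out


def simulate_session(
    subject_id: str,
    rng: np.random.Generator,
    design: BehaviorDesign | None = None,
    timing: TaskTiming | None = None,
    channel_areas: list[str] | None = None,
    planted: list[PlantedEffect] | None = None,
    noise_cfg: NoiseConfig | None = None,
    artifact_spec: ArtifactSpec | None = None,
    fs: float = 250.0,
) -> Session:
    """Full synthetic session: behavior, signals, plants, artifacts."""
    design = design or BehaviorDesign()
    timing = timing or TaskTiming()
    channel_areas = channel_areas or ["BA9"] * 4
    planted = planted or []
    noise_cfg = noise_cfg or NoiseConfig()

    trials, truth = generate_behavior(design, rng, timing=timing)
    signal = synthesize_recording(
        trials, channel_areas, planted, noise_cfg, fs, rng,
        ter=design.ter, lead_out=timing.lead_out,
    )
    truth = replace(truth, planted_effects=list(planted))
    labels = [f"{subject_id}_ch{i:03d}" for i in range(len(channel_areas))]
    session = Session(
        subject_id=subject_id,
        fs=fs,
        signal=signal,
        channel_labels=labels,
        channel_areas=list(channel_areas),
        trials=trials,
        ground_truth=truth,
    )
    if artifact_spec is not None:
        session = inject_artifacts(session, artifact_spec, rng)
    return session
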