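# Methods

This note documents the models, parameter choices, and numerical decisions
behind `accumloc`, and what its synthetic test bed does and does not
establish about real recordings.

## Decision model and behavior generation

Choices and response times are generated by a Wiener diffusion with
absorbing boundaries {0, a}, start point `z_frac·a`, drift `v`, diffusion
scale `s = 0.1` (the conventional scaling constant of the
diffusion-modeling literature; it is not identifiable and is exposed in the
config), and additive non-decision time `Ter`.  Sampling is
Euler–Maruyama at `dt = 1 ms` with first-crossing detection on the
discrete path; walks exceeding 5 s are counted and resampled.  The
discretization biases boundary crossings slightly outward (≈ 0.58·s·√dt in
boundary units, ~1 % here), visible as a small upward shift of hit
probabilities relative to the closed form; tests allow 3 Monte-Carlo
standard errors plus 0.01 for it.

Per-trial drift is a monotone map of exemplar-model familiarity:
`v = v_max · tanh(k · (S − criterion))` with summed similarity
`S = Σᵢ exp(−c·dᵢ)` over the memory set.  No specific functional form is
established for this mapping in the literature this package follows; the
saturating tanh is the simplest bounded monotone choice and its parameters
are config values.  Faces are random unit vectors in R⁸ with probe-to-set
distance manipulated over five levels separately for targets and lures;
letters are one-hot vectors, so their summed similarity is fixed given list
length, mirroring a design in which only face similarity is varied.

Generator defaults (`v_max = 0.17, k = 2.4, criterion = 0.3, a = 0.18,
Ter = 0.63 s, s = 0.1`) were chosen once to produce realistic behavior —
~80–85 % accuracy with letters easier than faces, mean correct RT
~1.2 s, a guessing-level lowest-evidence bin, and RT tails cut by the
2.5 s analysis cap — and are not tuned per experiment.

## Signal generation

Each channel is 1/f^1 spectrally-shaped Gaussian noise (unit SD) plus one
sinusoidal carrier per band at the band's geometric-mean frequency
(amplitude 0.5, random initial phase; optional Wiener phase jitter).
Planted effects multiply one band's carrier envelope during each decision
window by `1 + sign·amplitude·profile(t)`, where the profile (ramp,
downramp, or boxcar) spans the window minus the generating non-decision
time split half before / half after — the same placement the analysis
regressors assume, so recovery is well-posed.  A "raw" plant modulates
broadband gain instead.  Artifact injection adds, per flagged
(trial, channel) cell: a 100 ms half-sine excursion of 8 global SD
(amplitude criterion), five spikes of 6 cell-SD (kurtosis criterion), or a
3× variance inflation (variance criterion), each recorded in the
ground-truth mask.

What the generator does **not** emulate: spatially correlated noise across
electrodes, non-stationary background power, epileptiform activity,
volume-conducted artifacts, multi-session drift, or realistic stimulus
content.  Passing recovery tests therefore show the *analysis chain* is
correct and calibrated under its own assumptions — not that those
assumptions hold in patient data.

## Preprocessing decisions

Kurtosis is the plain fourth standardized moment (Gaussian = 3, no
small-sample bias correction): a threshold of 4.5 only separates Gaussian
from spiky data under the non-excess convention.  The "population" for the
variance rule is all (trial, channel) cells of one session.  Amplitude
normalization is per session (one mean/SD over all electrodes and trials),
matching the per-session artifact pass.  The trial- and channel-level 50 %
rules are iterated to a fixed point so that exclusion is idempotent;
in practice the first pass almost always suffices.  The detection epoch is
probe − 0.3 s to probe + 2.8 s (decision-relevant window plus buffers at
the 2.5 s RT cap).

## Spectral decisions

Baseline normalization is a z-score per electrode × frequency (subtract
pooled baseline mean, divide pooled baseline SD, over all retained trials'
300 ms pre-trial windows): division alone would not give the zero-baseline
convention the time-course figures rely on.  Band membership on the
frequency grid is half-open [lo, hi), so 4 Hz is theta.  The 53-point grid
is uniform in log₁₀ between 1 and 100 Hz inclusive.  The raw feature is the
signed broadband voltage z-scored against the same baselines (not a
rectified envelope); this is configurable in principle but is the package
default.  Downsampling to 50 Hz uses polyphase anti-aliased resampling.

For long sessions the per-frequency wavelet convolution is evaluated on a
decimated time grid by inverse-transforming only the occupied slice of the
product spectrum (the analytic Morlet spectrum is numerically band-limited
and one-sided).  The decimated values are exact samples of the full-rate
convolution; the only differences from the reference path are the baseline
statistics (estimated from the decimated baseline samples) and the
resampler's filter, both at the few-percent level on z tracks and
irrelevant to correlations.  `morlet_power` itself always returns the
full-rate transform; samples within 3 wavelet SDs of the signal edge are
flagged.

## Regressors

Active segments are rounded to the 20 ms grid; a ramp on n points is
i/(n−1) and the downramp is literally `1 − ramp`, making
ramp + downramp = boxcar exact to the last bit.  Trials with rt ≤ Ter
(possible for fast guesses with a long estimated Ter) are clamped to the
central 20 % of the decision window and logged rather than dropped, to
preserve feature/regressor alignment.  Permutation nulls rearrange the
multiset of per-trial durations (length-preserving permutation, not
resampling with replacement), reusing the same Ter split.

## Statistics

Non-decision time is estimated once per participant by the closed-form EZ
inversion of accuracy, mean and variance of correct RTs (pooled across
stimulus classes), with a 1/(2n) edge correction for degenerate accuracies;
an externally supplied Ter and a Ter = 0 sensitivity variant are config
options.  A robust-mixture variant of EZ is out of scope; the closed form
is the deterministic core the regressors need, and its round-trip accuracy
(|ΔTer| < 0.05 s, <10 % bias in v and a at n = 10,000) is verified
directly against the simulator.

Canonical correlation with a one-dimensional regressor set reduces to the
multiple correlation of regressing the regressor on the electrode matrix;
it is computed by QR projection, with a ridge-regularized fallback
(λ = 1e−6·trace/E) flagged on rank-deficient inputs.  It runs whole-brain
per participant by default (a per-area mode exists), on all retained
trials — the per-electrode cell exclusions cannot apply because CCA needs a
common sample axis.  Observed and null canonical correlations are
Fisher-transformed and averaged across participants so each contributes
equally; significance is read against the 99th percentile of the averaged
null.

The cell model fits grand-mean-centered Fisher-z ramp correlations with no
global intercept, a fixed effect per band × area cell (areas with ≥ 10
electrodes only), and random intercepts for subject and electrode
(electrode as a variance component nested in subject groups; REML).  The
centering constant is computed once over the full ramp table and stored.
On degenerate (e.g. noiseless) input where variance components are
unestimable the fit falls back to OLS with a warning — on balanced data the
fixed-effect estimates coincide.  Per-cell regressor contrasts use the same
random structure with ramp as the reference level.  Benjamini–Hochberg FDR
(q = 0.05) is applied to the cell p-values and, separately, to the contrast
family.  Candidate selection requires: cell significantly above average
with positive estimate; no alternative regressor significantly better; and,
in the default variant, the ramp significantly better than the downramp
(cells where the downramp merely ties are excluded — boxcar ties are
allowed).  A config switch restores the symmetric "at least as good" rule.

## Time courses

Vincentization resamples each trial's decision window onto the bin's
median-RT length (at 50 Hz) by linear interpolation, preserving endpoints
exactly; fixed-duration sub-processes are distorted by construction and no
correction is applied.  Averaging is electrode → area → subject with equal
subject weight.  Peaks are defined on |z| because planted and observed
deviations may go below baseline.  The diagnostic thresholds — Spearman
ρ > 0.9 for latency-RT scaling and a 1.5 maximum pairwise peak-amplitude
ratio — are package defaults chosen as round operating points, not values
from the literature.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run: the EZ round trip on a
12-triple grid × 10,000 trials; planted-signal localization on cohorts of
8 subjects × 40 electrodes × 60 trials (theta ramp and alpha boxcar at
0.75× carrier amplitude) over 20 seeds in the suite and 5 in the script;
permutation calibration at 100 signal-free runs × 200 shuffles (pink and
white noise); detector fidelity at 5 % injection rates on a white-noise
session; and the exact identities (CCA ≡ OLS, BH ≡ brute force,
ramp + downramp ≡ boxcar, vincentization of linear signals).  These sizes
keep a full run to a few minutes on one CPU while leaving the binomial
margins of the rate criteria intact.

## Known limitations

- The mixed models report Wald (normal-approximation) p-values from the
  REML fit; no Satterthwaite/Kenward-Roger small-sample correction.
- The subject-level variance component is estimated from few subjects and
  is correspondingly noisy; only the electrode and residual components are
  recovered tightly in tests.
- EDF files are read (via mne) but not written; the package's own HDF5
  epoch container is the primary signal format.
- Whole-session Morlet power assumes the recording is continuous; gaps are
  not modeled.
- The generator's envelope plants are multiplicative on a single carrier
  per band; mixed or cross-frequency effects are not emulated.
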