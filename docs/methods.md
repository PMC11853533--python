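# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Stimulus model

Four LEDs, two stimulation modes. In *frequency* mode each LED is a 50 %
duty-cycle square wave at 6.6, 7.5, 8.57 or 10 Hz for the 5 s trial. In
*pattern* mode the LEDs follow slow on/off schedules chosen so both a flash
VEP (every luminance transition) and a distinguishable pupil trace (pattern
timing) are evoked: LED 1 — no delay, 500/500 ms; LED 2 — 500 ms delay,
350/350 ms, dark from 2.5 s; LED 3 — 500 ms delay, 450/450 ms; LED 4 — no
delay, 400/400 ms, dark from 2.5 s. The 2.5 s full-off cutoff is read as
*trial-relative* (both a delayed and a non-delayed LED carry it, and trial
time is their only shared clock); an on-phase truncated by the cutoff keeps
its onset and records the forced darkening as an offset, so offset-locked
epoching sees every dark transition. Transition times are enumerated as
exact rationals on the millisecond grid; schedules regenerate
bit-identically.

Trial protocol: 2 s cue, 5 s stimulation, 3 s rest; analysis uses 0–4.5 s
except the FVEP pipeline, which uses the full 5 s (and its ITR is computed
at T = 5 s accordingly).

## Synthetic signals

The generator is the package's test bed; its defaults define the study
conditions and are not tuned per test.

**EEG background.** Broadband noise with a mild 1/f amplitude tilt
(amplitude ∝ f^−0.2) plus a shared narrowband 8–12 Hz alpha rhythm with a
fixed random spatial pattern (0.8 × noise SD). Two reasons for this choice
over a strict 1/f spectrum: (i) strict 1/f concentrates power below a few
hertz, leaving a 35-trough covariance window with so few effective degrees
of freedom that its eigenvalues are essentially noise — no covariance-based
statistic could work on such data, and real dry-EEG recordings are not that
degenerate over a 0.7–54 Hz band; (ii) the alpha rhythm paces the global
field power, so GFP troughs recur at realistic microstate-like intervals
(~25 ms here) rather than at the sample-to-sample jitter rate of white
noise.

**Evoked components.** FVEP transients are difference-of-gammas biphasic
kernels (positive lobe ≈ 0.8 × latency, whole deflection < 350 ms),
peak-to-valley-normalised and scaled by `fvep_amplitude` (default 14 µV)
with an occipital-dominant topography; one is added at every on *and* off
transition of the gazed LED. In frequency mode occipital channels
additionally carry the fundamental plus 0.4 × second harmonic at
`ssvep_amplitude` (default 3 µV).

**Covariance regime change at task onset.** A fixed direction *u*
concentrates baseline variance (low eigenvalue entropy — what the
reference-selection step looks for). At rest, smooth Hanning-shaped bursts
of isotropic noise (≈ every 1.6 s, 0.6 s long, 3 × noise SD ×
`covariance_shift_scale`) scatter the sliding covariances away from that
baseline; quiet gaps between bursts are longer than one covariance window,
so the lowest-entropy rest windows approximate the unperturbed baseline.
At the true onset a sharp-fronted, smoothly decaying 0.25 s broadband
transient (24 × noise SD × scale, fresh random direction) models the
attention-shift/flash response and gives the change detector its edge;
afterwards the bursts cease and a modest 10 Hz oscillation along *u* locks
the state near the baseline. Net effect, matching the qualitative finding
the hybrid design relies on: the distance-to-reference series fluctuates at
rest, spikes at onset, and settles *below* its rest mean during the task.

**Pupil.** First-order constriction/redilation dynamics (τ = 0.40 s /
1.10 s) toward a luminance-driven target diameter, after a 250 ms reflex
latency; baseline 4 mm, constriction gain 0.8 mm, 0.2 Hz hippus,
binocular gain asymmetry ~3 %, measurement noise 15 µm, and Poisson blink
dropouts written as low-confidence samples. Euler integration at 5
substeps per 30 Hz sample.

**EMG.** 20–150 Hz band-limited noise; chewing adds ~0.2 s Hanning-shaped
40 µV bursts at `chew_rate` (default 1.5 Hz).

**Subject effects.** Log-normal amplitude scalings (σ = 0.2) of the evoked
amplitudes and the constriction gain, plus ~8 % latency jitter — the
between-subject variability that motivates subject-independent validation.

What the generator does *not* model: volume-conduction-realistic
topographies, non-stationary electrode impedance, gaze drift, saccade
artifacts, or any biophysical pupil muscle model. Passing tests therefore
demonstrate that the pipelines recover the structure they assume when it
is present — not field performance on recordings.

## Pipelines

**SSVEP.** Cz re-reference, elliptic band-pass 2–54 Hz (order 4, 1 dB
ripple, 40 dB stopband — the order/ripple are config defaults, not values
taken from elsewhere), channels O1/Oz/O2, 0–4.5 s. The MSI uses the joint
correlation matrix of the EEG and a sin/cos bank at the fundamental and
second harmonic, whitens the two diagonal blocks, and scores
`1 − entropy(λ)/log M`; argmax over the four-frequency bank, ties to the
lowest LED id. Correlation (not covariance) makes the index
amplitude-invariant.

**FVEP.** Butterworth 3rd-order 2–30 Hz zero-phase, channels Pz/O1/O2.
Zero-phase (forward–backward) filtering is used everywhere because epochs
are cut at millisecond offsets and group delay would shift component
latencies. Per LED: epochs −100…+350 ms at that LED's onsets and offsets
separately, averaged; the feature is max − min of the channel-mean
waveform in 0–350 ms. The per-LED (onset, offset) pair feeds that LED's
binary RBF SVM (standardised inputs; grid C ∈ {0.1, 1, 10, 100},
γ ∈ {scale, 0.1, 1}; 5-fold internal CV); the four signed margins are
combined by argmax, which always yields a unique decision even when zero
or several binary models fire.

**PLR.** Trials are rejected when either eye has a low-confidence run
longer than 0.5 s or more than 25 % low-confidence samples. Short gaps are
linearly interpolated; each eye is divided by its own 0–0.5 s baseline
mean (a baseline-ratio normalisation — the convention is a package choice).
The analytic generalised Morse wavelet (γ = 3, β = P²/γ = 20) is applied
in the FFT domain on reflect-padded series; 61 log-spaced frequencies per
eye in 0.5–1.75 Hz (the band bracketing the slowest and fastest luminance
cycle rates), eyes stacked left-then-right into 122 rows. The 135 samples
of 4.5 s at 30 Hz are edge-padded symmetrically to 139 time points so the
tensor matches the classifier's input contract exactly.

**TCN.** Depthwise frequency-smoothing convolution (kernel 3), three
blocks of four causal convolutions (kernel 2, dilations 1/2/4/8, ReLU,
1×1-projected residual) with 512/512/64 filters, max-pool over time
(size 2, stride 2; 139 → 69, flatten 64 × 69 = 4416), dropout 0.5, dense
to 4 classes. Loss = sparse categorical cross-entropy + 0.7 × center loss
on the flattened features, with per-class centroids updated at rate 0.5
per batch. Adam at 10⁻³, batch 32 (16 in the reduced configuration).
Inputs are log1p-transformed and per-row standardised. Implemented
directly on numpy with hand-written backpropagation (verified against
finite differences); training is bit-deterministic given the seed. The
test suite and acceptance script train a reduced-width variant
(16/16/64 — the last block keeps 64 filters so the 4416-dimensional
contract is unchanged) for speed; the full-width forward pass is exercised
by the shape-contract test.

**Riemannian onset detection.** Butterworth 3rd-order 0.7–54 Hz on the
8-channel dry montage. GFP troughs (strict 3-sample local minima, plateaus
resolved to their first sample) define dynamic windows of 35 consecutive
troughs advancing one trough at a time; each window's uncentered covariance
X Xᵀ/(N−1) gets +10⁻⁸·trace/C·I regularisation before any inversion. Each
distance is stamped at its window's *last* trough — the causal "current
time point" — so a detected index maps onto the moment evidence entered
the window. The reference matrix is the arithmetic mean of the five
lowest-eigenvalue-entropy windows from the latter half of the reference
epoch (entropy of trace-normalised eigenvalues; arithmetic rather than
geometric mean, with the Riemannian mean left as an option). Epoch pairs
(−4,−3|−3,0), (−3,0|0,5), (0,5|5,8) relative to nominal onset; detection
runs on the second pair, with a 1.2 s warm-up before the target range so
changes right at its start are observable. The AIR distance is computed
from the generalised eigenvalues of (B, A) as √Σ log²λ (natural logs) —
algebraically `‖Log(A^{-1/2} B A^{-1/2})‖_F` without forming matrix roots.

Change detection uses first differences of the trough-indexed series (the
series is defined at troughs; no resampling): the earliest index whose
arriving first difference exceeds 3 SD *and* whose second difference
exceeds 4 SD (SDs over the whole per-trial series; the 3-to-first /
4-to-second pairing is a config default, both exposed). The crossing sits
partway up the change, so the index is refined by walking back to the
ramp foot (while the per-step change stays above 0.5 SD). If the mean
distance over the three troughs after minus before the index differs by
at least 0.1, the shift is deemed unrelated to a stimulus response and the
pupil must adjudicate: no detectable constriction excludes the trial, a
constriction near the index (within 0.6 s, after subtracting the 0.3 s
reflex latency) confirms the EEG timing, and a grossly different
constriction time overrides it. No candidate at all excludes the trial.

**Hybrid decoding.** Detected (and possibly pupil-adjusted) onset →
re-epoch the pupil series to 0–4.5 s from it → PLR network. The default
fusion weight is 1.0 (pure PLR after EEG onset correction): the EEG's role
is timing and validity, the pupil's is class identity. A softmax-margin
blend with the FVEP models is available as an extension. Excluded trials
never enter accuracy denominators (a strict mode counting them as errors
is a one-line change in the caller); exclusion counts are always reported.

## Evaluation

Wolpaw bits per trial with 0·log 0 := 0, scaled by Q = 60/T trials/min
(T = 4.5 s, or 5 s for FVEP). The formula is never clamped; note it is
non-negative, with its zero exactly at chance. Mean ITRs are means of
per-fold (or per-subject) ITRs, not the ITR of the mean accuracy — this is
the convention that reproduces the published per-participant table, whose
averages are means of the 2-decimal rounded per-subject values. LOSOCV
folds one subject out at a time; repeated hold-out uses 30 stratified
70/30 splits. PERMANOVA uses Euclidean distances on flattened feature
vectors, the between/within pseudo-F, and p = (1 + #{F* ≥ F})/(1 + n_perm)
with 1000 permutations (199 in the null-calibration loop, where only
uniformity is at stake). Wilcoxon signed-rank drops zero differences.

## Meal-cycle state machine

STANDBY → (PLR start trigger: sustained constriction ≥ 4.5 s while the
always-lit LED 4 is fixated) → PLR_CONFIRMED → (2 s) → FLICKER (4.5 s) →
SELECTING → GRAB → LIFTED → (EMG chew trigger, or a fixed 10 s safety
timeout) → LOWERING → STANDBY. The PLR trigger is armed only in STANDBY,
the EMG trigger only in LIFTED; any other event is logged and ignored. The
EMG detector band-passes 20–124 Hz, rectifies, smooths (50 ms), and fires
on a 100 ms-sustained crossing of baseline mean + 5 SD. Robot commands are
symbolic strings; no motor protocol is modelled.

## Problem sizes

The suite and acceptance script use: 100 trials for SSVEP recognition; one
subject × 48 trials with 30 hold-out repeats for FVEP; four subjects × 24
trials for PLR LOSOCV; three training subjects plus one held-out subject
(24 jittered trials) for the hybrid comparison; 30 high-shift trials
(covariance_shift_scale = 1.5, onset jitter 0.3–1.0 s) for onset
localisation and the pre/post Wilcoxon test. These sizes give stable
statistics while keeping the whole suite around a minute per block on one
CPU.

## Known limitations

* Onset localisation accuracy is quoted among detected trials; the
  detection rate itself (~90–100 % at high shift scale) is reported
  separately, mirroring the valid-trial convention of the experimental
  protocol.
* The distance-series noise floor is set by covariance estimation from
  ~0.9 s windows; detection of shifts much weaker than the synthetic
  defaults is not expected to work at this window length.
* The MSI "extension" point is the harmonic count and joint-matrix
  construction; canonical-correlation or filter-bank SSVEP variants are
  out of scope.
* The TCN is a compact numpy implementation: single-threaded, float32,
  no GPU path; training beyond a few hundred trials per fold is slow by
  design and out of scope.
* Whether detection SD thresholds should come from a baseline period
  rather than the whole per-trial series is undecided in principle;
  per-trial is implemented and exposed in config.
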