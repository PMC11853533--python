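"""Synthetic EEG, pupil and EMG trials with the structure the decoders assume.

No recordings ship with this package; every pipeline is exercised on signals
generated here.  The generator emulates, with deliberately simple models:

* stimulus-locked FVEP transients (difference-of-gammas kernel, peak inside
  the configured latency bound) after every luminance transition of the
  gazed LED;
* SSVEP oscillations (fundamental + 2nd harmonic) on occipital channels in
  frequency mode;
* a spatial-covariance regime change at task onset: at rest a shared
  "idle" source waxes and wanes in slow bursts, while from ``true_onset``
  onward it locks to a constant amplitude.  Sliding-window covariances are
  therefore variable before the onset and stable (and close to the
  low-entropy reference) after it, which is the geometry the Riemannian
  onset detector keys on;
* light-driven pupil constriction/redilation (first-order dynamics with
  separate time constants) following the gazed LED's luminance pattern,
  plus hippus, blink dropouts and binocular measurement noise;
* band-limited temporal-muscle EMG bursts during chewing.

All generators are pure functions of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng

from .sigproc import MultichannelSegment
from .stimuli import StimulusSchedule, build_default_schedule

__all__ = [
    "SynthConfig",
    "SynthTrial",
    "SynthDataset",
    "synth_eeg_trial",
    "synth_pupil_trial",
    "synth_emg",
    "synth_dataset",
    "DRY_CHANNELS",
    "WET_CHANNELS",
]

#: Dry-headset montage used in the pattern / hybrid experiments.
DRY_CHANNELS = ("Fz", "Pz", "P4", "P3", "O1", "O2", "C3", "C4")
#: Wet montage subset used by the SSVEP baseline (Cz is the reference).
WET_CHANNELS = ("O1", "Oz", "O2", "Cz")


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic cohort.  Defaults are the study conditions."""

    n_subjects: int = 5
    n_trials: int = 60
    eeg_rate: float = 500.0
    pupil_rate: float = 30.0
    eeg_channels: tuple[str, ...] = DRY_CHANNELS
    fvep_amplitude: float = 14.0       # uV, kernel peak-to-valley
    fvep_latency: float = 120.0        # ms, transient peak; must stay < 200
    ssvep_amplitude: float = 3.0       # uV
    noise_sd: float = 5.0              # uV, pink background
    covariance_shift_scale: float = 1.0
    plr_latency: float = 250.0         # ms
    plr_constriction_gain: float = 0.8 # mm
    pupil_baseline: float = 4.0        # mm
    blink_rate: float = 2.0            # events / min
    chew_rate: float = 1.5             # Hz
    subject_sd: float = 0.2            # log-normal sigma of subject effects
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.eeg_rate, self.pupil_rate) <= 0:
            raise ValueError("sampling rates must be positive")
        if not self.eeg_channels:
            raise ValueError("eeg_channels must not be empty")
        if not 0 < self.fvep_latency < 200:
            raise ValueError("fvep_latency must lie in (0, 200) ms")
        if self.covariance_shift_scale < 0:
            raise ValueError("covariance_shift_scale must be >= 0")


@dataclass
class SynthTrial:
    """One generated trial with its ground truth."""

    eeg: MultichannelSegment
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    confidence_left: np.ndarray
    confidence_right: np.ndarray
    pupil_rate: float
    pupil_t0: float
    target_led: int
    schedule: StimulusSchedule
    true_onset: float = 0.0
    subject_id: int = 0
    trial_id: int = 0
    emg: np.ndarray | None = None


@dataclass
class SynthDataset:
    config: SynthConfig
    mode: str
    trials: list[SynthTrial]

    def by_subject(self) -> dict[int, list[SynthTrial]]:
        out: dict[int, list[SynthTrial]] = {}
        for tr in self.trials:
            out.setdefault(tr.subject_id, []).append(tr)
        return out


# ---------------------------------------------------------------------------
# building blocks


def _pink_noise(rng: Generator, shape: tuple[int, int], sd: float,
                rate: float, exponent: float = 0.2) -> np.ndarray:
    """Broadband noise with a mild 1/f amplitude tilt, scaled to ``sd``.

    The tilt (amplitude ~ f^-exponent) keeps the spectrum EEG-like without
    letting sub-3 Hz power dominate short-window covariance estimates.
    """
    c, n = shape
    white = rng.standard_normal((c, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** -exponent
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale[None, :], n=n, axis=1)
    s = out.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return out / s * sd


def _alpha_rhythm(rng: Generator, c: int, n: int, rate: float,
                  amp: float) -> np.ndarray:
    """Shared narrowband 8-12 Hz rhythm with a fixed spatial pattern.

    Besides being the dominant rhythm of resting EEG, it paces the global
    field power so its local troughs recur at realistic microstate-like
    intervals, which sets the sliding covariance window length.
    """
    from scipy import signal as sps
    w = rng.standard_normal(c)
    w /= np.linalg.norm(w) / np.sqrt(c)
    sos = sps.butter(4, (8.0, 12.0), btype="bandpass", fs=rate, output="sos")
    a = sps.sosfilt(sos, rng.standard_normal(n))
    a /= a.std() or 1.0
    return amp * w[:, None] * a[None, :]


def _fvep_kernel(rate: float, latency_ms: float,
                 duration_ms: float = 350.0) -> np.ndarray:
    """Biphasic difference-of-gammas transient, peak-to-valley normalised to 1.

    The positive lobe peaks at roughly 0.8x the configured latency and the
    whole deflection is over within ~350 ms, mimicking the early flash-locked
    components of a visual evoked response.
    """
    t = np.arange(int(round(duration_ms / 1000.0 * rate))) / rate
    p1 = 0.8 * latency_ms / 1000.0
    p2 = 1.7 * latency_ms / 1000.0
    g1 = (t / p1) ** 2 * np.exp(2 * (1 - t / p1))
    g2 = (t / p2) ** 2 * np.exp(2 * (1 - t / p2))
    k = g1 - 0.7 * g2
    return k / (k.max() - k.min())


_FVEP_TOPO = {"O": 1.0, "P": 0.8, "C": 0.25, "F": 0.15}


def _topo_weight(label: str) -> float:
    return _FVEP_TOPO.get(label[0].upper(), 0.2)


def _burst_envelope(rng: Generator, t: np.ndarray, period: float = 1.6,
                    duration: float = 0.6) -> np.ndarray:
    """Intermittent smooth burst envelope (idle-state variability).

    Hanning-shaped bursts of ``duration`` recur roughly every ``period``
    seconds with small timing and amplitude jitter, leaving quiet gaps of
    about ``period - duration`` between them — long enough that some sliding
    covariance windows see the unperturbed baseline state.
    """
    env = np.zeros_like(t)
    k0 = int(np.floor((t[0]) / period)) - 1
    k1 = int(np.ceil((t[-1]) / period)) + 1
    for k in range(k0, k1 + 1):
        center = k * period + rng.normal(0, 0.1)
        amp = max(0.3, 1.0 + rng.normal(0, 0.25))
        mask = np.abs(t - center) < duration / 2
        if mask.any():
            env[mask] += amp * np.hanning(mask.sum())
    return env


# ---------------------------------------------------------------------------
# generators


def synth_eeg_trial(config: SynthConfig, schedule: StimulusSchedule,
                    target_led: int, rng: Generator | None = None,
                    t_start: float = 0.0, t_stop: float | None = None,
                    true_onset: float = 0.0) -> MultichannelSegment:
    """One EEG trial.

    ``t_start``/``t_stop`` set the recorded span (seconds relative to the
    *nominal* stimulus onset); ``true_onset`` shifts the actual stimulus
    timeline, emulating a participant whose task engagement starts late.
    Evoked components are locked to ``true_onset + transition_time``.
    """
    if not 1 <= target_led <= 4:
        raise ValueError(f"target_led must be 1-4, got {target_led}")
    if rng is None:
        rng = default_rng(config.seed)
    if t_stop is None:
        t_stop = schedule.trial_length
    rate = config.eeg_rate
    n = int(round((t_stop - t_start) * rate))
    labels = list(config.eeg_channels)
    c = len(labels)
    t = t_start + np.arange(n) / rate

    x = _pink_noise(rng, (c, n), config.noise_sd, rate)
    x += _alpha_rhythm(rng, c, n, rate, 0.8 * config.noise_sd)

    # flash-locked transients at every on AND off transition of the target
    if config.fvep_amplitude > 0:
        kernel = _fvep_kernel(rate, config.fvep_latency)
        topo = np.array([_topo_weight(l) for l in labels])
        events = schedule.onsets(target_led) + schedule.offsets(target_led)
        for ev in events:
            i0 = int(round((true_onset + ev - t_start) * rate))
            if i0 < 0 or i0 >= n:
                continue
            seg = kernel[: n - i0]
            x[:, i0:i0 + seg.size] += config.fvep_amplitude * topo[:, None] * seg[None, :]

    # steady-state oscillation on occipital channels in frequency mode
    pat = schedule.pattern(target_led)
    if pat.mode == "frequency" and config.ssvep_amplitude > 0:
        f = pat.frequency
        stim = (t >= true_onset) & (t < true_onset + schedule.trial_length)
        wave = (np.sin(2 * np.pi * f * (t - true_onset))
                + 0.4 * np.sin(2 * np.pi * 2 * f * (t - true_onset))) * stim
        for i, lab in enumerate(labels):
            if lab.upper().startswith("O"):
                x[i] += config.ssvep_amplitude * wave

    # spatial-covariance regime change at task onset:
    #  * a fixed direction u concentrates baseline variance (low-entropy
    #    spatial structure that the reference selection finds);
    #  * at rest, channel-specific slow-envelope perturbation noise scatters
    #    the sliding covariances away from that baseline;
    #  * a brief broadband transient at the onset (attention shift / flash
    #    response) gives the change detector a sharp edge;
    #  * from the onset onward the perturbation ceases and a modest
    #    synchronized oscillation along u locks the state near the baseline.
    if config.covariance_shift_scale > 0:
        scale = config.covariance_shift_scale
        u = rng.standard_normal(c)
        u /= np.linalg.norm(u)
        x = x + 1.5 * u[:, None] * (u @ x)[None, :]   # variance concentration
        rest = t < true_onset
        if rest.any():
            amp_r = 3.0 * scale * config.noise_sd
            env = _burst_envelope(rng, t, period=1.6, duration=0.6)
            x += amp_r * (env * rest)[None, :] * rng.standard_normal((c, n))
        # onset transient, ~300 ms
        q = rng.standard_normal(c)
        q /= np.linalg.norm(q)
        i0 = int(round((true_onset - t_start) * rate))
        tlen = int(round(0.4 * rate))
        if 0 <= i0 < n:
            seg_len = min(tlen, n - i0)
            carrier_t = rng.standard_normal(seg_len)
            carrier_t /= carrier_t.std() or 1.0
            env_t = np.hanning(2 * tlen)[tlen:tlen + seg_len]  # sharp front
            burst = 24.0 * scale * config.noise_sd * env_t * carrier_t
            x[:, i0:i0 + seg_len] += q[:, None] * burst[None, :]
        task = t >= true_onset
        x += (0.8 * scale * config.noise_sd * u[:, None]
              * (np.sin(2 * np.pi * 10.0 * (t - true_onset)) * task)[None, :])

    return MultichannelSegment(x, rate, labels, t0=t_start)


def synth_pupil_trial(config: SynthConfig, schedule: StimulusSchedule,
                      gazed_led: int, rng: Generator | None = None,
                      t_start: float = 0.0, t_stop: float | None = None,
                      true_onset: float = 0.0,
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Binocular pupil-diameter series (mm) with per-sample confidence.

    Returns ``(left, right, conf_left, conf_right)``.  Each on-phase of the
    gazed LED drives an exponential constriction after the PLR latency; each
    off-phase drives a slower redilation.  Blinks appear as short
    low-confidence dropouts.  The two eyes share the drive but differ in gain
    and measurement noise.
    """
    if not 1 <= gazed_led <= 4:
        raise ValueError(f"gazed_led must be 1-4, got {gazed_led}")
    if rng is None:
        rng = default_rng(config.seed)
    if t_stop is None:
        t_stop = schedule.trial_length
    rate = config.pupil_rate
    n = int(round((t_stop - t_start) * rate))
    t = t_start + np.arange(n) / rate

    d0 = config.pupil_baseline
    tau_con, tau_re = 0.40, 1.10
    latency = config.plr_latency / 1000.0
    phase = rng.uniform(0, 2 * np.pi)
    gain_r = 1.0 + rng.normal(0, 0.03)

    # luminance drive of the gazed LED, delayed by the reflex latency
    ons = np.array(schedule.onsets(gazed_led)) + true_onset
    offs = np.array(schedule.offsets(gazed_led)) + true_onset

    def lum(tt: float) -> float:
        q = tt - latency
        return float((ons <= q).sum() > (offs <= q).sum())

    sub = 5  # integration substeps per sample
    dt = 1.0 / (rate * sub)
    eyes = []
    for gain_scale in (1.0, gain_r):
        d = d0
        series = np.empty(n)
        tt = t_start
        for i in range(n):
            for _ in range(sub):
                target = d0 - gain_scale * config.plr_constriction_gain * lum(tt)
                tau = tau_con if target < d else tau_re
                d += (target - d) / tau * dt
                tt += dt
            series[i] = d
        eyes.append(series)
    left, right = eyes
    hippus = 0.08 * np.sin(2 * np.pi * 0.2 * t + phase)
    left = left + hippus + rng.normal(0, 0.015, n)
    right = right + hippus + rng.normal(0, 0.015, n)

    conf_l = np.clip(rng.normal(0.97, 0.01, n), 0, 1)
    conf_r = np.clip(rng.normal(0.97, 0.01, n), 0, 1)
    n_blinks = rng.poisson(config.blink_rate * (t_stop - t_start) / 60.0)
    for _ in range(n_blinks):
        b0 = rng.uniform(t_start, t_stop - 0.3)
        dur = rng.uniform(0.15, 0.35)
        mask = (t >= b0) & (t < b0 + dur)
        for arr, conf in ((left, conf_l), (right, conf_r)):
            conf[mask] = rng.uniform(0.05, 0.4)
            arr[mask] += rng.normal(-1.5, 0.5)
    return left, right, conf_l, conf_r


def synth_emg(config: SynthConfig, chewing: bool, duration: float,
              rng: Generator | None = None) -> MultichannelSegment:
    """Two-channel temporal-muscle EMG (T3, T4).

    ``chewing=True`` adds ~200 ms band-limited bursts at ``chew_rate`` Hz on
    top of the baseline noise floor.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = default_rng(config.seed)
    rate = config.eeg_rate
    n = int(round(duration * rate))
    base = rng.standard_normal((2, n)) * 3.0
    if chewing:
        period = 1.0 / config.chew_rate
        t_burst = period * 0.3
        while t_burst < duration - 0.25:
            i0 = int(round((t_burst + rng.normal(0, 0.03)) * rate))
            blen = int(round(rng.uniform(0.15, 0.25) * rate))
            i0 = max(0, min(i0, n - blen))
            burst = rng.standard_normal((2, blen)) * 40.0
            window = np.hanning(blen)[None, :]
            base[:, i0:i0 + blen] += burst * window
            t_burst += period
    # keep energy in the 20-150 Hz muscle band
    from scipy import signal as sps
    sos = sps.butter(4, (20, min(150, rate / 2 - 1)), btype="bandpass",
                     fs=rate, output="sos")
    out = sps.sosfiltfilt(sos, base, axis=1)
    return MultichannelSegment(out, rate, ["T3", "T4"], 0.0)


def _balanced_targets(n_trials: int, rng: Generator) -> np.ndarray:
    reps = np.tile(np.arange(1, 5), n_trials // 4 + 1)[:n_trials]
    return rng.permutation(reps)


def synth_dataset(config: SynthConfig, mode: str = "pattern",
                  context: bool = False,
                  onset_jitter: tuple[float, float] = (0.0, 0.0),
                  with_emg: bool = False) -> SynthDataset:
    """A full multi-subject dataset of :class:`SynthTrial`.

    Target LEDs are balanced within each subject and presented in random
    order.  Subject-level random effects (log-normal amplitude scalings and
    latency jitter) create the inter-subject variability that motivates
    subject-independent validation.  With ``context=True`` each trial spans
    [-4, +8] s around the nominal stimulus onset and the true onset is
    jittered uniformly within ``onset_jitter``.
    """
    schedule = build_default_schedule(mode)
    t_start, t_stop = (-4.0, 8.0) if context else (0.0, schedule.trial_length)
    ss = SeedSequence(config.seed)
    subj_seeds = ss.spawn(config.n_subjects)
    trials: list[SynthTrial] = []
    for s in range(config.n_subjects):
        s_rng = default_rng(subj_seeds[s])
        fvep_scale = float(np.exp(s_rng.normal(0, config.subject_sd)))
        plr_scale = float(np.exp(s_rng.normal(0, config.subject_sd)))
        lat_scale = float(np.exp(s_rng.normal(0, 0.08)))
        subj_cfg = replace(
            config,
            fvep_amplitude=config.fvep_amplitude * fvep_scale,
            ssvep_amplitude=config.ssvep_amplitude * fvep_scale,
            plr_constriction_gain=config.plr_constriction_gain * plr_scale,
            plr_latency=min(config.plr_latency * lat_scale, 450.0),
            fvep_latency=min(config.fvep_latency * lat_scale, 195.0),
        )
        targets = _balanced_targets(config.n_trials, s_rng)
        for k, led in enumerate(targets):
            rng = default_rng(s_rng.integers(2 ** 31))
            onset = float(rng.uniform(*onset_jitter))
            eeg = synth_eeg_trial(subj_cfg, schedule, int(led), rng,
                                  t_start=t_start, t_stop=t_stop,
                                  true_onset=onset)
            l, r, cl, cr = synth_pupil_trial(subj_cfg, schedule, int(led), rng,
                                             t_start=t_start, t_stop=t_stop,
                                             true_onset=onset)
            emg = synth_emg(subj_cfg, True, 5.0, rng).samples if with_emg else None
            trials.append(SynthTrial(
                eeg=eeg, pupil_left=l, pupil_right=r,
                confidence_left=cl, confidence_right=cr,
                pupil_rate=config.pupil_rate, pupil_t0=t_start,
                target_led=int(led), schedule=schedule, true_onset=onset,
                subject_id=s, trial_id=k, emg=emg))
    return SynthDataset(config=config, mode=mode, trials=trials)
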