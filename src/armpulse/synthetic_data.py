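"""Seeded generator of coupled arm-ECG / arm-PPG sessions with ground truth.

No public recording exists for this device class, so every pipeline stage
is exercised on synthetic sessions that emulate the acquisition protocol:
13 two-minute trials; the subject exercises in minute one of the middle
trials (raising HR, SBP and the motion-artifact rate) and rests in minute
two, which is the analysis window where the cuff reference is taken.

Construction:

* Beat times come from integrating a per-trial HR profile with optional
  beat-to-beat RR jitter.
* The chest ECG is a difference-of-Gaussians QRS template (dominant R,
  smaller delayed S) at the beat times; the arm ECG is the same waveform
  scaled by ``ecg_amplitude_ratio`` (default 0.10 - the arm lead is about
  ten times weaker than the chest lead) plus baseline wander, EMG-band
  white noise, powerline interference and Poisson motion-artifact spikes.
* Each beat's true PTT inverts the generative SBP model at that beat's
  instantaneous SBP and HR, so ground-truth SBP, HR and PTT are mutually
  consistent by construction; the PPG foot falls at beat time + PTT.
* The PPG pulse is a cosine-harmonic shape whose minima align exactly at
  the feet and are locally symmetric, so the between-beat minimum survives
  zero-phase band-pass filtering without shifting - a shape with a shallow
  decay into the foot and a steep upstroke out of it would let the 8 Hz
  low-pass drag the minimum many milliseconds early.

Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .sbp_models import SbpModelSpec, predict
from .signal_io import (
    BeatAnnotation,
    ReferenceSeries,
    Session,
    SessionLayout,
    SignalChannel,
)

__all__ = [
    "NoiseConfig",
    "ArtifactConfig",
    "SyntheticConfig",
    "GroundTruth",
    "generate_session",
    "invert_sbp_model",
    "inject_artifacts",
]

ECG_RATE_HZ = 500.0
PPG_RATE_HZ = 128.0

# QRS template geometry (seconds / relative amplitude)
_R_SIGMA = 0.009
_S_SIGMA = 0.012
_S_DELAY = 0.045
_S_AMP = -0.30

# PPG pulse: cosine harmonics with minima aligned at the foot
_PPG_HARMONICS = (1.0, 0.4, 0.15)


@dataclass
class NoiseConfig:
    """Additive noise terms of the arm channels (filtered-unit amplitudes)."""

    emg_sd: float = 0.012
    baseline_amp: float = 0.05
    baseline_freq_hz: float = 0.3
    powerline_amp: float = 0.02
    powerline_freq_hz: float = 50.0
    ppg_sd: float = 0.015
    ppg_baseline_amp: float = 0.05
    chest_sd: float = 0.005

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(
            emg_sd=0.0, baseline_amp=0.0, powerline_amp=0.0,
            ppg_sd=0.0, ppg_baseline_amp=0.0, chest_sd=0.0,
        )


@dataclass
class ArtifactConfig:
    """Poisson motion-artifact spikes on the arm ECG."""

    rate_per_min: float = 8.0
    amp_low: float = 0.06
    amp_high: float = 0.20
    width_lo_s: float = 0.005
    width_hi_s: float = 0.018
    exercise_multiplier: float = 2.0

    @classmethod
    def none(cls) -> "ArtifactConfig":
        return cls(rate_per_min=0.0)


def _default_true_model() -> SbpModelSpec:
    # Linear PTT&HR model with a < 0: SBP falls as PTT rises.
    return SbpModelSpec(model_id=10, coefficients=(-200.0, 0.5, 120.0))


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic subject/session."""

    seed: int = 0
    layout: SessionLayout = field(default_factory=SessionLayout)
    hr_rest_bpm: float = 72.0
    hr_peak_bpm: float = 105.0
    sbp_rest_mmhg: float = 112.0
    sbp_peak_mmhg: float = 140.0
    trial_hr_jitter_bpm: float = 3.0
    trial_sbp_jitter_mmhg: float = 3.0
    hr_jitter_s: float = 0.015
    sbp_ref_noise_mmhg: float = 1.0
    true_model: SbpModelSpec = field(default_factory=_default_true_model)
    ecg_amplitude_ratio: float = 0.10
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)

    def __post_init__(self) -> None:
        if not 0 < self.ecg_amplitude_ratio <= 1:
            raise ValueError("ecg_amplitude_ratio must be in (0, 1]")
        if self.hr_jitter_s < 0 or self.sbp_ref_noise_mmhg < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def clean(cls, seed: int = 0, **kw) -> "SyntheticConfig":
        """Noise-free conditions: no waveform noise, artifacts or RR jitter.

        The deterministic per-trial HR/SBP variation is kept - it is the
        physiology being simulated, not noise, and the calibration fit
        needs it for identifiability.
        """
        return cls(
            seed=seed,
            noise=NoiseConfig.none(),
            artifacts=ArtifactConfig.none(),
            hr_jitter_s=0.0,
            sbp_ref_noise_mmhg=0.0,
            **kw,
        )


@dataclass
class GroundTruth:
    """Everything the generator knows; consistent with the waveforms."""

    beat_times_s: np.ndarray
    hr_bpm: np.ndarray  # per-beat IHR (60/RR, stamped at the beat)
    sbp_mmhg: np.ndarray  # per-beat SBP
    ptt_s: np.ndarray  # per-beat transit time
    foot_times_s: np.ndarray
    artifact_times_s: np.ndarray
    window_trials: np.ndarray
    window_hr_bpm: np.ndarray
    window_sbp_mmhg: np.ndarray
    window_ptt_s: np.ndarray


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _trial_levels(layout: SessionLayout) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial exercise level in [0, 1] and an is-exercise-trial flag."""
    n = layout.trial_count
    levels = np.zeros(n)
    exercise = np.zeros(n, dtype=bool)
    if n >= 4:
        n_ex = n - 3
        for k in range(n_ex):
            levels[1 + k] = (k + 1) / n_ex
            exercise[1 + k] = True
        levels[n - 2] = 0.5
        levels[n - 1] = 0.2
    elif n >= 2:
        levels[1:] = 0.5
        exercise[1:] = True
    return levels, exercise


class _Profile:
    """Piecewise trial profile: cosine ramp in minute 1, constant in minute 2."""

    def __init__(self, layout: SessionLayout, targets: np.ndarray):
        self.layout = layout
        self.targets = np.asarray(targets, dtype=float)

    def __call__(self, t: float) -> float:
        lay = self.layout
        i = min(int(t // lay.trial_duration_s), lay.trial_count - 1)
        offset = t - i * lay.trial_duration_s
        target = self.targets[i]
        prev = self.targets[i - 1] if i > 0 else target
        if offset >= lay.window_offset_s:
            return float(target)
        u = offset / lay.window_offset_s
        return float(prev + (target - prev) * 0.5 * (1.0 - np.cos(np.pi * u)))


# ---------------------------------------------------------------------------
# Model inversion
# ---------------------------------------------------------------------------

def invert_sbp_model(spec: SbpModelSpec, sbp_mmhg, hr_bpm=None):
    """PTT such that ``predict(spec, ptt, hr) == sbp`` (to 1e-9).

    Closed forms where available; bisection on [1 ms, 2 s] otherwise.
    Raises if the requested SBP is outside the model's attainable range.
    """
    scalar = np.isscalar(sbp_mmhg)
    sbp = np.atleast_1d(np.asarray(sbp_mmhg, dtype=float))
    hr = None
    if spec.uses_hr:
        if hr_bpm is None:
            raise ValueError(f"model {spec.model_id} requires HR")
        hr = np.broadcast_to(np.atleast_1d(np.asarray(hr_bpm, dtype=float)), sbp.shape)
    c = spec.coefficients
    with np.errstate(divide="raise", invalid="raise"):
        try:
            if spec.model_id == 1:
                ptt = np.exp((sbp - c[1]) / c[0])
            elif spec.model_id == 2:
                ptt = c[0] / (sbp - c[1])
            elif spec.model_id == 3:
                ptt = (sbp - c[1]) / c[0]
            elif spec.model_id == 4:
                ptt = np.array(
                    [_bisect_ptt(spec, s, None) for s in sbp]
                )
            elif spec.model_id == 5:
                ptt = np.sqrt((sbp - c[1]) / c[0])
            elif spec.model_id == 6:
                ptt = np.log(sbp / c[0]) / c[1]
            elif spec.model_id == 7:
                ptt = np.sqrt(c[0] / (sbp - c[1]))
            elif spec.model_id == 8:
                ptt = np.sqrt(c[0] / (sbp - c[1] * hr**-2.0 - c[2]))
            elif spec.model_id == 9:
                ptt = np.exp((sbp - c[1] * np.log(hr) - c[2]) / c[0])
            elif spec.model_id == 10:
                ptt = (sbp - c[1] * hr - c[2]) / c[0]
            else:  # pragma: no cover
                raise ValueError(f"unknown model id {spec.model_id}")
        except FloatingPointError as exc:
            raise ValueError("SBP outside the model's attainable range") from exc
    ptt = np.asarray(ptt, dtype=float)
    if np.any(~np.isfinite(ptt)) or np.any(ptt <= 0):
        raise ValueError("SBP outside the model's attainable range")
    back = predict(spec, ptt, hr)
    if np.max(np.abs(np.atleast_1d(back) - sbp)) > 1e-9 * max(1.0, float(np.max(np.abs(sbp)))):
        raise ValueError("model inversion failed to round-trip")
    return float(ptt[0]) if scalar else ptt


def _bisect_ptt(spec: SbpModelSpec, sbp: float, hr: float | None) -> float:
    # bracket restricted to the physiologic range where the model is monotone
    f = lambda p: predict(spec, p, hr) - sbp
    try:
        return brentq(f, 0.05, 0.5, xtol=1e-12)
    except ValueError as exc:
        raise ValueError("SBP outside the model's attainable range") from exc


# ---------------------------------------------------------------------------
# Waveform synthesis
# ---------------------------------------------------------------------------

def _qrs_train(beat_times: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Sum of difference-of-Gaussians QRS complexes (R amplitude 1)."""
    x = np.zeros(n)
    half = int(round(0.12 * fs))
    for t in beat_times:
        k = int(round(t * fs))
        lo, hi = max(0, k - half), min(n, k + half + int(round(_S_DELAY * fs)))
        if hi <= lo:
            continue
        tt = np.arange(lo, hi) / fs - t
        x[lo:hi] += np.exp(-(tt**2) / (2 * _R_SIGMA**2))
        x[lo:hi] += _S_AMP * np.exp(-((tt - _S_DELAY) ** 2) / (2 * _S_SIGMA**2))
    return x


def _ppg_train(foot_times: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Cosine-harmonic pulse train with minima exactly at the feet."""
    if foot_times.size < 2:
        raise ValueError("need at least two feet for a PPG pulse train")
    f = foot_times
    feet_ext = np.concatenate([[f[0] - (f[1] - f[0])], f, [f[-1] + (f[-1] - f[-2])]])
    t = np.arange(n) / fs
    idx = np.clip(np.searchsorted(feet_ext, t, side="right") - 1, 0, feet_ext.size - 2)
    phase = (t - feet_ext[idx]) / (feet_ext[idx + 1] - feet_ext[idx])
    x = np.zeros(n)
    for j, cj in enumerate(_PPG_HARMONICS, start=1):
        x += cj * 0.5 * (1.0 - np.cos(2.0 * np.pi * j * phase))
    return x


def inject_artifacts(
    channel: SignalChannel,
    rate_per_min: float,
    amplitude_dist=None,
    seed: int | np.random.Generator | None = 0,
    width_range_s: tuple[float, float] = (0.005, 0.018),
    rate_multiplier=None,
) -> tuple[SignalChannel, np.ndarray]:
    """Add short Gaussian spike transients at Poisson times.

    ``amplitude_dist(rng, size)`` draws spike amplitudes (default uniform on
    [0.06, 0.20]); ``rate_multiplier(t)`` optionally modulates the rate
    (Poisson thinning), e.g. to double it during exercise minutes.  Spike
    widths are bounded so each transient spans at most ~80 ms.  Returns the
    new channel and the injected spike times.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if rate_per_min == 0:
        return channel.with_samples(channel.samples.copy()), np.array([])
    if amplitude_dist is None:
        amplitude_dist = lambda r, size: r.uniform(0.06, 0.20, size)
    duration = channel.duration_s
    max_mult = 1.0
    if rate_multiplier is not None:
        probe = np.linspace(0, duration, 512)
        max_mult = max(float(rate_multiplier(t)) for t in probe)
    lam = rate_per_min / 60.0 * max_mult
    n_events = rng.poisson(lam * duration)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    if rate_multiplier is not None and times.size:
        accept = rng.uniform(0, 1, times.size) <= np.array(
            [rate_multiplier(t) / max_mult for t in times]
        )
        times = times[accept]
    amps = amplitude_dist(rng, times.size)
    signs = rng.choice([-1.0, 1.0], times.size)
    widths = rng.uniform(width_range_s[0], width_range_s[1], times.size)

    fs = channel.sampling_rate_hz
    x = channel.samples.copy()
    for t, a, sgn, w in zip(times, amps, signs, widths):
        half = int(round(4 * w * fs))  # +-4 sigma <= 80 ms support
        k = int(round((t - channel.start_time_s) * fs))
        lo, hi = max(0, k - half), min(x.size, k + half + 1)
        if hi <= lo:
            continue
        tt = (np.arange(lo, hi) - (t - channel.start_time_s) * fs) / fs
        x[lo:hi] += sgn * a * np.exp(-(tt**2) / (2 * w**2))
    return channel.with_samples(x), times + channel.start_time_s


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def generate_session(cfg: SyntheticConfig) -> Session:
    """Generate one coupled chest-ECG / arm-ECG / arm-PPG session.

    Returns a :class:`Session` whose ``truth`` field is the
    :class:`GroundTruth`, ``beats``/``feet`` carry the true annotations and
    ``refs`` the (optionally noisy) per-window cuff reference.
    """
    rng = np.random.default_rng(cfg.seed)
    lay = cfg.layout
    duration = lay.session_duration_s

    levels, exercise = _trial_levels(lay)
    hr_targets = (
        cfg.hr_rest_bpm
        + (cfg.hr_peak_bpm - cfg.hr_rest_bpm) * levels
        + rng.normal(0.0, cfg.trial_hr_jitter_bpm, lay.trial_count)
    )
    sbp_targets = (
        cfg.sbp_rest_mmhg
        + (cfg.sbp_peak_mmhg - cfg.sbp_rest_mmhg) * levels
        + rng.normal(0.0, cfg.trial_sbp_jitter_mmhg, lay.trial_count)
    )
    hr_profile = _Profile(lay, hr_targets)
    sbp_profile = _Profile(lay, sbp_targets)

    # --- beat times from integrating the HR profile -----------------------
    # Start after a 2 s burn-in so filter edge transients never touch the
    # first beats; analysis windows begin at 60 s regardless.
    beats = []
    t = 2.0
    while t < duration - 1.0:
        beats.append(t)
        rr = 60.0 / hr_profile(t)
        if cfg.hr_jitter_s > 0:
            rr += rng.normal(0.0, cfg.hr_jitter_s)
        t += float(np.clip(rr, 0.3, 2.0))
    beat_times = np.asarray(beats)
    if beat_times.size < 3:
        raise ValueError("session too short to hold beats")
    rr = np.diff(beat_times)
    hr_per_beat = np.concatenate([[hr_profile(beat_times[0])], 60.0 / rr])
    sbp_per_beat = np.array([sbp_profile(tb) for tb in beat_times])
    ptt = invert_sbp_model(
        cfg.true_model, sbp_per_beat, hr_per_beat if cfg.true_model.uses_hr else None
    )
    ptt = np.atleast_1d(ptt)
    if np.any(ptt <= 0) or np.any(ptt[:-1] >= rr):
        raise ValueError("true model yields PTT outside (0, RR); adjust the config")
    foot_times = beat_times + ptt

    # --- per-window ground truth ------------------------------------------
    win_trials, win_hr, win_sbp, win_ptt = [], [], [], []
    for trial in range(lay.trial_count):
        lo, hi = lay.window_bounds(trial)
        mask = (beat_times >= lo) & (beat_times < hi)
        mask[0] = False  # first beat has no RR-based IHR
        if int(mask.sum()) < 2:
            continue
        win_trials.append(trial)
        win_hr.append(float(np.mean(hr_per_beat[mask])))
        win_sbp.append(float(np.mean(sbp_per_beat[mask])))
        win_ptt.append(float(np.mean(ptt[mask])))
    win_trials = np.asarray(win_trials, dtype=int)
    win_hr = np.asarray(win_hr)
    win_sbp = np.asarray(win_sbp)
    win_ptt = np.asarray(win_ptt)
    ref_sbp = win_sbp.copy()
    if cfg.sbp_ref_noise_mmhg > 0:
        ref_sbp = ref_sbp + rng.normal(0.0, cfg.sbp_ref_noise_mmhg, ref_sbp.size)

    # --- waveforms ---------------------------------------------------------
    n_ecg = int(round(duration * ECG_RATE_HZ))
    qrs = _qrs_train(beat_times, n_ecg, ECG_RATE_HZ)
    chest = qrs.copy()
    if cfg.noise.chest_sd > 0:
        chest = chest + rng.normal(0.0, cfg.noise.chest_sd, n_ecg)
    chest_ch = SignalChannel(chest, ECG_RATE_HZ, 0.0, "chest_ecg")

    t_ecg = np.arange(n_ecg) / ECG_RATE_HZ
    arm = cfg.ecg_amplitude_ratio * qrs
    nz = cfg.noise
    if nz.baseline_amp > 0:
        arm = arm + nz.baseline_amp * np.sin(
            2 * np.pi * nz.baseline_freq_hz * t_ecg + rng.uniform(0, 2 * np.pi)
        )
    if nz.powerline_amp > 0:
        arm = arm + nz.powerline_amp * np.sin(
            2 * np.pi * nz.powerline_freq_hz * t_ecg + rng.uniform(0, 2 * np.pi)
        )
    if nz.emg_sd > 0:
        arm = arm + rng.normal(0.0, nz.emg_sd, n_ecg)
    arm_ch = SignalChannel(arm, ECG_RATE_HZ, 0.0, "arm_ecg")

    art = cfg.artifacts
    artifact_times = np.array([])
    if art.rate_per_min > 0:
        def in_exercise_minute(tt: float) -> float:
            i = min(int(tt // lay.trial_duration_s), lay.trial_count - 1)
            offset = tt - i * lay.trial_duration_s
            return (
                art.exercise_multiplier
                if exercise[i] and offset < lay.window_offset_s
                else 1.0
            )

        arm_ch, artifact_times = inject_artifacts(
            arm_ch,
            art.rate_per_min,
            amplitude_dist=lambda r, size: r.uniform(art.amp_low, art.amp_high, size),
            seed=rng,
            width_range_s=(art.width_lo_s, art.width_hi_s),
            rate_multiplier=in_exercise_minute,
        )

    n_ppg = int(round(duration * PPG_RATE_HZ))
    ppg = _ppg_train(foot_times, n_ppg, PPG_RATE_HZ)
    t_ppg = np.arange(n_ppg) / PPG_RATE_HZ
    if nz.ppg_baseline_amp > 0:
        ppg = ppg + nz.ppg_baseline_amp * np.sin(
            2 * np.pi * 0.2 * t_ppg + rng.uniform(0, 2 * np.pi)
        )
    if nz.ppg_sd > 0:
        ppg = ppg + rng.normal(0.0, nz.ppg_sd, n_ppg)
    ppg_ch = SignalChannel(ppg, PPG_RATE_HZ, 0.0, "arm_ppg")

    truth = GroundTruth(
        beat_times_s=beat_times,
        hr_bpm=hr_per_beat,
        sbp_mmhg=sbp_per_beat,
        ptt_s=ptt,
        foot_times_s=foot_times,
        artifact_times_s=artifact_times,
        window_trials=win_trials,
        window_hr_bpm=win_hr,
        window_sbp_mmhg=win_sbp,
        window_ptt_s=win_ptt,
    )
    refs = ReferenceSeries(window_index=win_trials, sbp_mmhg=ref_sbp)
    return Session(
        chest_ecg=chest_ch,
        arm_ecg=arm_ch,
        arm_ppg=ppg_ch,
        refs=refs,
        layout=lay,
        beats=BeatAnnotation(times_s=beat_times, modality="ecg_r_peak"),
        feet=BeatAnnotation(times_s=foot_times, modality="ppg_foot"),
        truth=truth,
    )
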