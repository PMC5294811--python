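"""PPG foot detection, pulse transit time, and heart-rate estimation.

The PPG-based heartbeat location is the minimum point of the PPG between
two adjacent ECG R peaks; the pulse transit time of beat *i* is

    PTT_i = t(PPG foot_i) - t(R peak_i),

i.e. the delay between the electrical heartbeat and the mechanical pulse
arrival at the arm sensor.  Instantaneous heart rate is 60/RR from
successive beats; per-trial means of PTT and IHR over the analysis window
(the rest minute of each trial) feed the blood-pressure models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .beat_detection import greedy_match
from .signal_io import BeatAnnotation, ReferenceSeries, SessionLayout, SignalChannel

logger = logging.getLogger(__name__)

__all__ = [
    "BeatPair",
    "WindowedMeasurement",
    "EventSeries",
    "find_ppg_feet",
    "compute_ptt",
    "instantaneous_hr",
    "window_average",
    "windowed_measurements",
    "match_beats",
]


@dataclass(frozen=True)
class BeatPair:
    """(R peak, PPG foot) pair and its transit time."""

    ecg_r_time_s: float
    ppg_foot_time_s: float

    @property
    def ptt_s(self) -> float:
        return self.ppg_foot_time_s - self.ecg_r_time_s


@dataclass
class WindowedMeasurement:
    """Per-trial window means, optionally with the cuff reference SBP."""

    trial_index: int
    mean_ptt_s: float
    mean_hr_bpm: float
    sbp_ref_mmhg: float | None = None


@dataclass
class EventSeries:
    """Time-stamped scalar events (e.g. IHR stamped at each beat)."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must align")


def find_ppg_feet(ppg: SignalChannel, r_peaks: BeatAnnotation) -> BeatAnnotation:
    """One PPG foot per adjacent R-peak pair: the interval's global minimum.

    The PPG should already be resampled to the ECG rate and band-passed.
    Ties are broken by the earliest time.
    """
    r = r_peaks.times_s
    if r.size < 2:
        raise ValueError("need at least 2 R peaks to bracket a PPG foot")
    fs = ppg.sampling_rate_hz
    t0 = ppg.start_time_s
    # sample index strictly after r_i / strictly before r_{i+1}
    feet = []
    for a, b in zip(r[:-1], r[1:]):
        lo = int(np.floor((a - t0) * fs)) + 1
        hi = int(np.ceil((b - t0) * fs))  # exclusive
        lo = max(lo, 0)
        hi = min(hi, ppg.n)
        if hi <= lo:
            raise ValueError(f"no PPG samples strictly between R peaks at {a:.3f}-{b:.3f}s")
        k = lo + int(np.argmin(ppg.samples[lo:hi]))  # argmin returns first minimum
        feet.append(t0 + k / fs)
    return BeatAnnotation(times_s=np.asarray(feet), modality="ppg_foot")


def compute_ptt(r_peaks: BeatAnnotation, feet: BeatAnnotation) -> list[BeatPair]:
    """Pair each foot with the R peak preceding it; PTT = foot - R.

    Pairs violating 0 < PTT < RR (foot not strictly inside its R-R
    interval) or sharing an R peak with an earlier foot are dropped and
    logged.
    """
    r = r_peaks.times_s
    pairs: list[BeatPair] = []
    dropped = 0
    used_r: set[int] = set()
    for f in feet.times_s:
        i = int(np.searchsorted(r, f, side="right")) - 1
        if i < 0 or i >= r.size - 1:
            dropped += 1
            continue
        if not (r[i] < f < r[i + 1]) or i in used_r:
            dropped += 1
            continue
        used_r.add(i)
        pairs.append(BeatPair(ecg_r_time_s=float(r[i]), ppg_foot_time_s=float(f)))
    if dropped:
        logger.warning("compute_ptt: dropped %d feet outside their R-R interval", dropped)
    return pairs


def instantaneous_hr(
    beats: BeatAnnotation,
    rr_gate_s: tuple[float, float] = (0.25, 2.0),
) -> EventSeries:
    """IHR_i = 60 / (t_i - t_{i-1}) in BPM, stamped at t_i.

    R-R intervals outside the physiologic gate are dropped (and logged) so
    that residual false or missed beats do not contaminate windowed means.
    """
    t = beats.times_s
    if t.size < 2:
        raise ValueError("need at least 2 beats for IHR")
    rr = np.diff(t)
    ok = (rr >= rr_gate_s[0]) & (rr <= rr_gate_s[1])
    if not ok.all():
        logger.warning("instantaneous_hr: dropped %d out-of-gate intervals", int((~ok).sum()))
    return EventSeries(times_s=t[1:][ok], values=60.0 / rr[ok])


def window_average(
    events: EventSeries,
    layout: SessionLayout,
    min_events: int = 2,
) -> dict[int, float]:
    """Mean event value inside each half-open analysis window.

    Windows holding fewer than ``min_events`` events are omitted.
    """
    out: dict[int, float] = {}
    for trial in range(layout.trial_count):
        lo, hi = layout.window_bounds(trial)
        mask = (events.times_s >= lo) & (events.times_s < hi)
        if int(mask.sum()) >= min_events:
            out[trial] = float(np.mean(events.values[mask]))
    return out


def windowed_measurements(
    pairs: list[BeatPair],
    ihr: EventSeries,
    layout: SessionLayout,
    refs: ReferenceSeries | None = None,
    min_events: int = 2,
) -> list[WindowedMeasurement]:
    """Assemble per-trial (mean PTT, mean HR, reference SBP) measurements.

    PTT values are stamped at their R-peak times.  A trial yields a
    measurement only when both series populate its window.
    """
    ptt_events = EventSeries(
        times_s=np.array([p.ecg_r_time_s for p in pairs]),
        values=np.array([p.ptt_s for p in pairs]),
    )
    ptt_means = window_average(ptt_events, layout, min_events)
    hr_means = window_average(ihr, layout, min_events)
    ref_map = refs.as_dict() if refs is not None else {}
    out = []
    for trial in sorted(set(ptt_means) & set(hr_means)):
        out.append(
            WindowedMeasurement(
                trial_index=trial,
                mean_ptt_s=ptt_means[trial],
                mean_hr_bpm=hr_means[trial],
                sbp_ref_mmhg=ref_map.get(trial),
            )
        )
    return out


def match_beats(
    a: BeatAnnotation, b: BeatAnnotation, tol_s: float = 0.15
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of two annotations.

    Used to align beat series across modalities (e.g. arm-ECG vs chest-ECG
    IHR) before computing correlation matrices.
    """
    return greedy_match(a.times_s, b.times_s, tol_s)
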