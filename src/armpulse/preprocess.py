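"""Band-pass filtering and resampling of the raw channels.

The ECG stream is band-passed at 2–30 Hz (baseline wander, powerline and
much of the motion-artifact energy removed), the PPG stream at 0.5–8 Hz,
and the PPG is then resampled to 500 Hz so both channels share one time
grid for pulse-transit-time subtraction.

Filters are 4th-order Butterworth applied forward–backward (zero phase):
PTT subtracts time stamps across two differently filtered channels, so a
causal filter would add modality-dependent group delay and bias PTT.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .signal_io import SignalChannel

__all__ = ["FilterSpec", "ECG_FILTER", "PPG_FILTER", "bandpass", "resample"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification."""

    low_cut_hz: float
    high_cut_hz: float
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sampling_rate_hz: float):
        nyq = sampling_rate_hz / 2.0
        if self.high_cut_hz >= nyq:
            raise ValueError(
                f"high cutoff {self.high_cut_hz} Hz >= Nyquist {nyq} Hz"
            )
        return signal.butter(
            self.order,
            [self.low_cut_hz, self.high_cut_hz],
            btype="bandpass",
            fs=sampling_rate_hz,
            output="sos",
        )

    def gain_at(self, freq_hz: float, sampling_rate_hz: float) -> float:
        """Magnitude response at one frequency (squared when zero-phase)."""
        sos = self.sos(sampling_rate_hz)
        _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=sampling_rate_hz)
        g = float(np.abs(h[0]))
        return g * g if self.zero_phase else g


ECG_FILTER = FilterSpec(2.0, 30.0)
PPG_FILTER = FilterSpec(0.5, 8.0)


def bandpass(channel: SignalChannel, spec: FilterSpec) -> SignalChannel:
    """Apply the band-pass; length, rate and time origin are preserved."""
    sos = spec.sos(channel.sampling_rate_hz)
    if channel.n == 0:
        raise ValueError("empty channel")
    if spec.zero_phase:
        padlen = min(channel.n - 1, 3 * (2 * spec.order + 1) * 10)
        out = signal.sosfiltfilt(sos, channel.samples, padlen=padlen)
    else:
        out = signal.sosfilt(sos, channel.samples)
    return channel.with_samples(out)


def resample(channel: SignalChannel, target_rate_hz: float) -> SignalChannel:
    """Polyphase band-limited resampling to ``target_rate_hz``.

    Duration is preserved to within one output sample; resampling to the
    channel's own rate is the identity.
    """
    if not target_rate_hz > 0:
        raise ValueError("target_rate_hz must be > 0")
    if channel.n == 0:
        raise ValueError("empty channel")
    ratio = Fraction(target_rate_hz / channel.sampling_rate_hz).limit_denominator(10000)
    if ratio == 1:
        return channel.with_samples(channel.samples.copy())
    out = signal.resample_poly(channel.samples, ratio.numerator, ratio.denominator)
    return channel.with_samples(out, sampling_rate_hz=target_rate_hz)
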