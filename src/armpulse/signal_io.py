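"""Data model and on-disk formats for single-arm ECG/PPG recordings.

A recording session is a set of uniformly sampled channels (chest ECG at
500 Hz, arm ECG at 500 Hz, arm PPG at 128 Hz), beat annotations, and a
per-trial reference systolic blood pressure series.  The session layout is
13 two-minute trials; the analysis window of each trial is its second
minute, during which the subject is at rest and the cuff reference is taken.

Time convention: seconds from the recording start; sample ``k`` of a channel
lies at ``start_time_s + k / sampling_rate_hz``.  All intervals are half-open
``[start, end)``.

On-disk formats are plain text: signal CSV with ``# key=value`` header lines
followed by one sample per line, and annotation / reference CSVs with a
single header row.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalChannel",
    "SessionLayout",
    "BeatAnnotation",
    "ReferenceSeries",
    "Session",
    "read_channel",
    "write_channel",
    "read_annotation",
    "write_annotation",
    "read_references",
    "write_references",
    "window_bounds",
    "save_session",
    "load_session",
]

CHANNEL_LABELS = ("chest_ecg", "arm_ecg", "arm_ppg")
MODALITIES = ("ecg_r_peak", "ppg_foot")


@dataclass
class SignalChannel:
    """A uniformly sampled waveform with its rate, origin and label."""

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.sampling_rate_hz

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.duration_s

    def times(self) -> np.ndarray:
        """Sample times: ``start_time_s + k / rate``."""
        return self.start_time_s + np.arange(self.n) / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray, sampling_rate_hz: float | None = None) -> "SignalChannel":
        return SignalChannel(
            samples=np.asarray(samples, dtype=float),
            sampling_rate_hz=self.sampling_rate_hz if sampling_rate_hz is None else sampling_rate_hz,
            start_time_s=self.start_time_s,
            label=self.label,
        )

    def index_of(self, time_s: float) -> int:
        """Nearest sample index for a time stamp (clipped to the record)."""
        k = int(round((time_s - self.start_time_s) * self.sampling_rate_hz))
        return min(max(k, 0), self.n - 1)


@dataclass(frozen=True)
class SessionLayout:
    """Trial structure of a recording session.

    Defaults follow the acquisition protocol this package targets: 13 trials
    of 120 s each, with the analysis window covering the second minute of
    every trial.
    """

    trial_count: int = 13
    trial_duration_s: float = 120.0
    window_offset_s: float = 60.0
    window_duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.trial_count < 1:
            raise ValueError("trial_count must be >= 1")
        if self.window_offset_s + self.window_duration_s > self.trial_duration_s + 1e-12:
            raise ValueError("analysis window must fit inside the trial")

    @property
    def session_duration_s(self) -> float:
        return self.trial_count * self.trial_duration_s

    def window_bounds(self, trial_index: int) -> tuple[float, float]:
        return window_bounds(self, trial_index)

    def all_window_bounds(self) -> list[tuple[float, float]]:
        return [window_bounds(self, i) for i in range(self.trial_count)]

    def trial_bounds(self, trial_index: int) -> tuple[float, float]:
        if not 0 <= trial_index < self.trial_count:
            raise IndexError(f"trial_index {trial_index} out of range")
        start = trial_index * self.trial_duration_s
        return (start, start + self.trial_duration_s)


def window_bounds(layout: SessionLayout, trial_index: int) -> tuple[float, float]:
    """Half-open analysis window ``[start, end)`` of one trial."""
    if not 0 <= trial_index < layout.trial_count:
        raise IndexError(
            f"trial_index {trial_index} out of range [0, {layout.trial_count})"
        )
    start = trial_index * layout.trial_duration_s + layout.window_offset_s
    return (start, start + layout.window_duration_s)


@dataclass
class BeatAnnotation:
    """Strictly increasing event times of one modality.

    ``labels`` optionally classifies each event as ``beat`` (+1) or
    ``artifact`` (-1); ``None`` means unknown.
    """

    times_s: np.ndarray
    modality: str = "ecg_r_peak"
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.ndim != 1:
            raise ValueError("times_s must be one-dimensional")
        if self.times_s.size and not np.all(np.isfinite(self.times_s)):
            raise ValueError("event times must be finite")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("event times must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.times_s.shape:
                raise ValueError("labels must match times_s in shape")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class ReferenceSeries:
    """Per-analysis-window reference systolic blood pressure (mmHg)."""

    window_index: np.ndarray
    sbp_mmhg: np.ndarray
    bounds_mmhg: tuple[float, float] = (60.0, 220.0)

    def __post_init__(self) -> None:
        self.window_index = np.asarray(self.window_index, dtype=int)
        self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)
        if self.window_index.shape != self.sbp_mmhg.shape:
            raise ValueError("window_index and sbp_mmhg must align")
        if len(np.unique(self.window_index)) != self.window_index.size:
            raise ValueError("one reference value per analysis window")
        lo, hi = self.bounds_mmhg
        if self.sbp_mmhg.size and (
            np.any(self.sbp_mmhg < lo) or np.any(self.sbp_mmhg > hi)
        ):
            raise ValueError(f"reference SBP outside physiologic bounds [{lo}, {hi}]")

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(v) for i, v in zip(self.window_index, self.sbp_mmhg)}


@dataclass
class Session:
    """One full recording session: three channels, references, annotations."""

    chest_ecg: SignalChannel
    arm_ecg: SignalChannel
    arm_ppg: SignalChannel
    refs: ReferenceSeries
    layout: SessionLayout = field(default_factory=SessionLayout)
    beats: BeatAnnotation | None = None  # reference R-peak annotation
    feet: BeatAnnotation | None = None  # reference PPG-foot annotation
    truth: object | None = None  # synthetic GroundTruth when generated


# ---------------------------------------------------------------------------
# Signal CSV
# ---------------------------------------------------------------------------

def write_channel(channel: SignalChannel, path: str | os.PathLike) -> None:
    """Write a channel as header lines plus one sample per line.

    ``%.17g`` formatting makes the read/write round trip exact for float64.
    """
    if channel.n == 0:
        raise ValueError("refusing to write an empty channel")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# label={channel.label}\n")
        fh.write(f"# rate_hz={channel.sampling_rate_hz!r}\n")
        fh.write(f"# start_s={channel.start_time_s!r}\n")
        np.savetxt(fh, channel.samples, fmt="%.17g")


def read_channel(path: str | os.PathLike, format: str = "csv") -> SignalChannel:
    """Read a signal channel.

    Two CSV dialects are accepted: the canonical headered single-column form
    written by :func:`write_channel`, and a headerless two-column
    ``time_s,value`` form whose rate is inferred (sampling jitter beyond
    1 ppm is rejected).
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                header[key.strip()] = value.strip()
            else:
                data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no samples")
    if "rate_hz" in header:
        samples = np.array([float(v) for v in data_lines])
        if np.any(~np.isfinite(samples)):
            raise ValueError(f"{path}: non-finite samples")
        return SignalChannel(
            samples=samples,
            sampling_rate_hz=float(header["rate_hz"]),
            start_time_s=float(header.get("start_s", 0.0)),
            label=header.get("label", ""),
        )
    # two-column dialect
    rows = [line.replace(",", " ").split() for line in data_lines]
    if any(len(r) != 2 for r in rows):
        raise ValueError(f"{path}: expected rate header or two columns (time_s,value)")
    arr = np.array(rows, dtype=float)
    t, v = arr[:, 0], arr[:, 1]
    if np.any(~np.isfinite(v)) or np.any(~np.isfinite(t)):
        raise ValueError(f"{path}: non-finite values")
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples to infer a rate")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    mean_dt = float(np.mean(dt))
    if np.max(np.abs(dt - mean_dt)) > 1e-6 * mean_dt:
        raise ValueError(f"{path}: non-uniform sampling beyond 1 ppm jitter")
    return SignalChannel(
        samples=v,
        sampling_rate_hz=1.0 / mean_dt,
        start_time_s=float(t[0]),
        label=header.get("label", ""),
    )


# ---------------------------------------------------------------------------
# Annotation / reference CSV
# ---------------------------------------------------------------------------

_LABEL_NAMES = {1: "beat", -1: "artifact"}
_LABEL_VALUES = {v: k for k, v in _LABEL_NAMES.items()}


def write_annotation(ann: BeatAnnotation, path: str | os.PathLike) -> None:
    labels: Iterable[str]
    if ann.labels is None:
        labels = [""] * len(ann)
    else:
        labels = [_LABEL_NAMES.get(int(v), "") for v in ann.labels]
    df = pd.DataFrame(
        {"time_s": ann.times_s, "modality": ann.modality, "label": list(labels)}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_annotation(path: str | os.PathLike) -> BeatAnnotation:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    if df.empty:
        return BeatAnnotation(times_s=np.array([]), modality="ecg_r_peak")
    modality = str(df["modality"].iloc[0])
    label_col = df["label"].astype(str) if "label" in df else pd.Series([""] * len(df))
    labels = None
    if (label_col != "").any():
        labels = np.array([_LABEL_VALUES.get(s, 0) for s in label_col])
    return BeatAnnotation(
        times_s=df["time_s"].to_numpy(float), modality=modality, labels=labels
    )


def write_references(refs: ReferenceSeries, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"trial_index": refs.window_index, "sbp_mmhg": refs.sbp_mmhg}
    ).to_csv(path, index=False, float_format="%.17g")


def read_references(path: str | os.PathLike) -> ReferenceSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    return ReferenceSeries(
        window_index=df["trial_index"].to_numpy(int),
        sbp_mmhg=df["sbp_mmhg"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Session directories
# ---------------------------------------------------------------------------

def save_session(session: Session, directory: str | os.PathLike) -> None:
    """Write a session as a directory of text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_channel(session.chest_ecg, directory / "chest_ecg.csv")
    write_channel(session.arm_ecg, directory / "arm_ecg.csv")
    write_channel(session.arm_ppg, directory / "arm_ppg.csv")
    write_references(session.refs, directory / "sbp_ref.csv")
    if session.beats is not None:
        write_annotation(session.beats, directory / "beats.csv")
    if session.feet is not None:
        write_annotation(session.feet, directory / "feet.csv")
    layout = session.layout
    with open(directory / "layout.json", "w") as fh:
        json.dump(
            {
                "trial_count": layout.trial_count,
                "trial_duration_s": layout.trial_duration_s,
                "window_offset_s": layout.window_offset_s,
                "window_duration_s": layout.window_duration_s,
            },
            fh,
            indent=2,
        )


def load_session(directory: str | os.PathLike) -> Session:
    directory = Path(directory)
    layout = SessionLayout()
    layout_path = directory / "layout.json"
    if layout_path.exists():
        with open(layout_path) as fh:
            layout = SessionLayout(**json.load(fh))
    beats = None
    if (directory / "beats.csv").exists():
        beats = read_annotation(directory / "beats.csv")
    feet = None
    if (directory / "feet.csv").exists():
        feet = read_annotation(directory / "feet.csv")
    return Session(
        chest_ecg=read_channel(directory / "chest_ecg.csv"),
        arm_ecg=read_channel(directory / "arm_ecg.csv"),
        arm_ppg=read_channel(directory / "arm_ppg.csv"),
        refs=read_references(directory / "sbp_ref.csv"),
        layout=layout,
        beats=beats,
        feet=feet,
    )
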