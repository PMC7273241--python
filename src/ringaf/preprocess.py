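"""Recording I/O and the preprocessing chain.

The pipeline order is fixed: band-pass filter (0.2-18 Hz, zero phase) ->
resample to 50 Hz -> segment into overlapping windows (30 s with 20-s
overlap by default, the data-augmentation scheme) -> optionally truncate
each window to a shorter length.  Labels are inherited from the
recording-level ground truth, never recomputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .synth import BeatTrain, Rhythm, SyntheticRecording

TARGET_FS = 50.0
BAND = (0.2, 18.0)
SEGMENT_LENGTHS_S = (30, 25, 20, 15, 10, 5)


class RecordingFormatError(ValueError):
    """CSV/sidecar pair is malformed or inconsistent."""


@dataclass
class Recording:
    """A single-channel PPG recording ready for preprocessing."""

    samples: np.ndarray
    fs: float
    duration: float
    label: Rhythm
    subject_id: str
    recording_id: str = "r000"
    source: str = "synthetic"
    truth: BeatTrain | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.samples) != round(self.duration * self.fs):
            raise RecordingFormatError(
                f"{len(self.samples)} samples inconsistent with duration "
                f"{self.duration} s at fs {self.fs} Hz"
            )


@dataclass
class Segment:
    """One fixed-length labeled window, the unit of classification."""

    samples: np.ndarray
    fs: float
    length_s: float
    label: Rhythm
    subject_id: str
    recording_id: str
    start_s: float
    premature_fraction: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != round(self.length_s * self.fs):
            raise ValueError("segment sample count inconsistent with length_s * fs")

    @property
    def segment_id(self) -> str:
        return f"{self.recording_id}@{self.start_s:g}s/{self.length_s:g}s"


def from_synthetic(rec: SyntheticRecording) -> Recording:
    return Recording(
        samples=rec.samples,
        fs=rec.fs,
        duration=rec.duration,
        label=rec.label,
        subject_id=rec.subject_id,
        recording_id=rec.recording_id,
        source="synthetic",
        truth=rec.truth,
    )


def read_recording(path: str | Path) -> Recording:
    """Read a two-column CSV (time_s, amplitude) with its JSON sidecar."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise RecordingFormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "amplitude"]:
        raise RecordingFormatError(f"unexpected CSV columns {list(df.columns)}")
    try:
        label = Rhythm(meta["label"])
    except (KeyError, ValueError) as exc:
        raise RecordingFormatError(f"unknown or missing label in {sidecar_path}") from exc
    fs = float(meta["fs"])
    duration = float(meta.get("duration", len(df) / fs))
    if len(df) != round(duration * fs):
        raise RecordingFormatError(
            f"{len(df)} rows inconsistent with duration {duration} s at {fs} Hz"
        )
    truth = None
    if meta.get("beat_times"):
        truth = BeatTrain(
            np.asarray(meta["beat_times"], dtype=float),
            np.asarray(meta.get("is_premature", [0] * len(meta["beat_times"])), dtype=bool),
            label,
        )
    return Recording(
        samples=df["amplitude"].to_numpy(),
        fs=fs,
        duration=duration,
        label=label,
        subject_id=str(meta.get("subject_id", path.stem)),
        recording_id=str(meta.get("recording_id", path.stem)),
        source="file",
        truth=truth,
    )


def bandpass(samples: np.ndarray, fs: float, low: float = BAND[0], high: float = BAND[1]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass, applied forward-backward
    so pulse peaks are not shifted.  Output length equals input length."""
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high}-Hz upper corner")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def resample_to_50hz(samples: np.ndarray, fs_in: float) -> np.ndarray:
    """Band-limited polyphase resampling to 50 Hz; identity at 50 Hz."""
    if fs_in < 25:
        raise ValueError("fs_in must be >= 25 Hz")
    if fs_in == TARGET_FS:
        return np.asarray(samples, dtype=float)
    frac = Fraction(TARGET_FS / fs_in).limit_denominator(1000)
    return signal.resample_poly(np.asarray(samples, dtype=float), frac.numerator, frac.denominator)


def preprocess_recording(rec: Recording) -> Recording:
    """Filter then resample; the canonical order before segmentation."""
    x = bandpass(rec.samples, rec.fs)
    x = resample_to_50hz(x, rec.fs)
    duration = len(x) / TARGET_FS
    return replace(rec, samples=x, fs=TARGET_FS, duration=duration)


_EPS_FRACTION = 0.5  # strict-end slack, in sample periods


def segment_windows(rec: Recording, window_s: float = 30.0, overlap_s: float = 20.0) -> list[Segment]:
    """Slice a recording into overlapping windows.

    Stride = window - overlap; starts at 0, stride, 2*stride, ...; a window
    is emitted iff its end lies strictly before the recording end (a 900-s
    recording yields 87 windows at 30/20).  The single exception: a
    recording exactly one window long yields that one window.
    """
    if overlap_s >= window_s:
        raise ValueError("overlap must be shorter than the window")
    if rec.duration < window_s:
        warnings.warn(f"recording shorter than {window_s} s; no segments emitted")
        return []
    stride = window_s - overlap_s
    eps = _EPS_FRACTION / rec.fs
    if abs(rec.duration - window_s) <= eps:
        starts = [0.0]
    else:
        n_windows = int(np.floor((rec.duration - window_s - eps) / stride)) + 1
        starts = [i * stride for i in range(max(n_windows, 0))]
    nwin = round(window_s * rec.fs)
    out: list[Segment] = []
    truth = rec.truth
    for s0 in starts:
        i0 = round(s0 * rec.fs)
        seg_pf = None
        if truth is not None:
            inside = (truth.beat_times >= s0) & (truth.beat_times < s0 + window_s)
            n_in = int(inside.sum())
            seg_pf = float(truth.is_premature[inside].mean()) if n_in else 0.0
        out.append(
            Segment(
                samples=rec.samples[i0 : i0 + nwin],
                fs=rec.fs,
                length_s=window_s,
                label=rec.label,
                subject_id=rec.subject_id,
                recording_id=rec.recording_id,
                start_s=float(s0),
                premature_fraction=seg_pf,
            )
        )
    return out


def truncate_to_length(seg: Segment, length_s: float) -> Segment:
    """Keep the first ``length_s`` seconds of a parent window, so every
    shorter length has exactly as many segments as the 30-s baseline."""
    if length_s >= seg.length_s:
        raise ValueError("truncation length must be shorter than the segment")
    n = round(length_s * seg.fs)
    return replace(seg, samples=seg.samples[:n], length_s=float(length_s))


# -- segment collections -----------------------------------------------------


@dataclass
class SegmentSet:
    """A stack of equal-length segments: samples matrix + manifest."""

    X: np.ndarray                  # (n_segments, n_samples)
    meta: pd.DataFrame             # segment_id, subject_id, recording_id, ...
    fs: float
    length_s: float

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["label"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def subset(self, mask: np.ndarray) -> "SegmentSet":
        mask = np.asarray(mask)
        return SegmentSet(self.X[mask], self.meta.loc[mask].reset_index(drop=True), self.fs, self.length_s)

    def truncate(self, length_s: float) -> "SegmentSet":
        if length_s > self.length_s:
            raise ValueError("truncation length must not exceed the segment length")
        if length_s == self.length_s:
            return self
        n = round(length_s * self.fs)
        meta = self.meta.copy()
        meta["length_s"] = float(length_s)
        return SegmentSet(self.X[:, :n], meta, self.fs, float(length_s))


def stack_segments(segments: Sequence[Segment]) -> SegmentSet:
    if not segments:
        raise ValueError("no segments to stack")
    fs = segments[0].fs
    length_s = segments[0].length_s
    if any(s.fs != fs or s.length_s != length_s for s in segments):
        raise ValueError("segments must share fs and length")
    X = np.stack([s.samples for s in segments])
    meta = pd.DataFrame(
        {
            "segment_id": [s.segment_id for s in segments],
            "subject_id": [s.subject_id for s in segments],
            "recording_id": [s.recording_id for s in segments],
            "start_s": [s.start_s for s in segments],
            "length_s": [s.length_s for s in segments],
            "label": [s.label.value for s in segments],
            "premature_fraction": [s.premature_fraction for s in segments],
        }
    )
    return SegmentSet(X, meta, fs, length_s)


def prepare_segments(
    recordings: Iterable[Recording | SyntheticRecording],
    window_s: float = 30.0,
    overlap_s: float = 20.0,
) -> SegmentSet:
    """Full preprocessing for a cohort: filter -> resample -> segment."""
    segs: list[Segment] = []
    for rec in recordings:
        if isinstance(rec, SyntheticRecording):
            rec = from_synthetic(rec)
        rec = preprocess_recording(rec)
        segs.extend(segment_windows(rec, window_s, overlap_s))
    return stack_segments(segs)


def export_segments(segset: SegmentSet, out_dir: str | Path) -> Path:
    """Write the samples matrix (CSV, one row per segment) and the segment
    manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.savetxt(out_dir / "segments.csv", segset.X, delimiter=",", fmt="%.6g")
    manifest = out_dir / "manifest.csv"
    segset.meta.to_csv(manifest, index=False)
    (out_dir / "segments.json").write_text(
        json.dumps({"fs": segset.fs, "length_s": segset.length_s, "n": len(segset)})
    )
    return manifest


def load_segments(out_dir: str | Path) -> SegmentSet:
    out_dir = Path(out_dir)
    info = json.loads((out_dir / "segments.json").read_text())
    X = np.loadtxt(out_dir / "segments.csv", delimiter=",", ndmin=2)
    meta = pd.read_csv(out_dir / "manifest.csv")
    return SegmentSet(X, meta, float(info["fs"]), float(info["length_s"]))
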