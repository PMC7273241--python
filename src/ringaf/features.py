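"""Pulse-peak detection and hand-crafted rhythm statistics.

The feature-based classification arm works on the peak-to-peak (RR)
intervals of the PPG pulse train: RMSSD, normalized Shannon entropy of the
interval histogram, the coefficient of variation, and the pulse rate; the
autocorrelation arm works on the mean-removed waveform itself (lags
1..150 samples, i.e. 0.02-3.0 s at 50 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .preprocess import Segment, SegmentSet

logger = logging.getLogger(__name__)

N_AUTOCORR_LAGS = 150
SHE_BINS = 16
PEAK_REFRACTORY_S = 0.3
PEAK_EDGE_GUARD_S = 0.2   # ignore candidates this close to a window edge,
                          # where pulses are truncated mid-template
_SMOOTH_S = 0.10          # moving-average width for peak detection
_THRESH_WINDOW_S = 2.0    # rolling window for the adaptive threshold
_THRESH_QUANTILE = 90     # rolling percentile
_THRESH_SCALE = 0.3       # peaks must exceed scale * rolling quantile; low
                          # enough to keep amplitude-modulated (pulse-deficit)
                          # beats, high enough to reject broadband noise


class UndefinedFeatureError(ValueError):
    """Too few pulse peaks to define the requested statistic; the segment
    is excluded from feature-based arms (but kept for the CNN)."""


@dataclass
class PeakSeries:
    """Detected pulse peaks within one segment."""

    peak_times: np.ndarray  # seconds from segment start, strictly increasing

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if self.peak_times.size > 1 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)


def detect_peaks(seg: Segment) -> PeakSeries:
    """Find pulse peaks in a band-passed segment.

    The signal is lightly smoothed; local maxima must exceed an adaptive
    threshold (a rolling upper quantile of the amplitude) and respect a
    0.3-s refractory: among conflicting candidates the larger peak wins.
    Returns an empty series when fewer than two peaks are found.
    """
    x = np.asarray(seg.samples, dtype=float)
    fs = seg.fs
    if x.size == 0 or np.allclose(x, x[0]):
        return PeakSeries(np.empty(0))
    w = max(int(round(_SMOOTH_S * fs)) | 1, 3)
    xs = ndimage.uniform_filter1d(x, w, mode="nearest")
    thr = _THRESH_SCALE * ndimage.percentile_filter(
        xs, _THRESH_QUANTILE, size=int(_THRESH_WINDOW_S * fs), mode="nearest"
    )
    dist = max(int(round(PEAK_REFRACTORY_S * fs)), 1)
    idx, _ = signal.find_peaks(xs, distance=dist)
    idx = idx[xs[idx] > thr[idx]]
    guard = PEAK_EDGE_GUARD_S * fs
    idx = idx[(idx >= guard) & (idx < x.size - guard)]
    if idx.size == 0:
        return PeakSeries(np.empty(0))
    # refine each peak on the unsmoothed signal within +-smoothing window
    refined = []
    for i in idx:
        lo, hi = max(0, i - w), min(x.size, i + w + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # re-apply the refractory after refinement: larger peak wins
    keep: list[int] = []
    for i in refined:
        if keep and i - keep[-1] < dist:
            if x[i] > x[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    return PeakSeries(np.asarray(keep) / fs)


@dataclass
class PeakMatch:
    """Detected-vs-truth beat matching for one segment."""

    n_truth: int
    n_detected: int
    n_matched_truth: int      # truth beats (away from edges) recovered
    n_matched_detected: int   # detected peaks explained by some truth beat
    max_error_s: float

    @property
    def sensitivity(self) -> float:
        return 1.0 if self.n_truth == 0 else self.n_matched_truth / self.n_truth

    @property
    def precision(self) -> float:
        return 1.0 if self.n_detected == 0 else self.n_matched_detected / self.n_detected


def match_peaks(
    peaks: PeakSeries,
    truth_times: np.ndarray,
    length_s: float,
    tol_s: float = 0.04,
    edge_margin_s: float = PEAK_EDGE_GUARD_S + 0.05,
) -> PeakMatch:
    """Score detected peaks against ground-truth beat times.

    ``truth_times`` are in segment-local seconds and may extend slightly
    past the window edges (a pulse whose beat lies just outside still
    leaks its template into the window).  Sensitivity is scored over truth
    beats at least ``edge_margin_s`` inside the window, where the full
    pulse is rendered; precision is scored over every detected peak
    against all nearby truth beats.
    """
    truth_times = np.asarray(truth_times, dtype=float)
    nearby = truth_times[(truth_times >= -0.5) & (truth_times < length_s + 0.5)]
    core = nearby[(nearby >= edge_margin_s) & (nearby < length_s - edge_margin_s)]
    det = peaks.peak_times
    if det.size == 0:
        return PeakMatch(core.size, 0, 0, 0, np.inf if core.size else 0.0)
    d_core = (
        np.abs(det[:, None] - core[None, :]).min(axis=0) if core.size else np.empty(0)
    )
    d_det = (
        np.abs(det[:, None] - nearby[None, :]).min(axis=1) if nearby.size else np.full(det.size, np.inf)
    )
    return PeakMatch(
        n_truth=int(core.size),
        n_detected=int(det.size),
        n_matched_truth=int((d_core <= tol_s).sum()),
        n_matched_detected=int((d_det <= tol_s).sum()),
        max_error_s=float(d_core.max()) if core.size else 0.0,
    )


def rmssd(intervals: np.ndarray) -> float:
    """Root mean square of successive interval differences (seconds)."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise UndefinedFeatureError("RMSSD needs at least 2 intervals")
    d = np.diff(intervals)
    return float(np.sqrt(np.mean(d * d)))


def shannon_entropy(intervals: np.ndarray, n_bins: int = SHE_BINS) -> float:
    """Normalized Shannon entropy of the interval histogram.

    Equal-width bins span the window's own [min, max] interval range;
    entropy uses the natural log and is normalized by ln(n_bins) to [0, 1].
    All-equal intervals give 0 (a single occupied bin).
    """
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 4:
        raise UndefinedFeatureError("ShE needs at least 4 intervals")
    lo, hi = float(intervals.min()), float(intervals.max())
    if (hi - lo) / n_bins <= np.spacing(max(abs(lo), abs(hi))):
        return 0.0  # all intervals in one representable bin
    counts, _ = np.histogram(intervals, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / intervals.size
    return float(-(p * np.log(p)).sum() / np.log(n_bins))


def coefficient_of_variation(intervals: np.ndarray) -> float:
    """Sample standard deviation (n-1) over mean of the intervals."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size < 2:
        raise UndefinedFeatureError("CV needs at least 2 intervals")
    mean = float(intervals.mean())
    if mean <= 0:
        raise UndefinedFeatureError("non-positive mean interval")
    return float(intervals.std(ddof=1) / mean)


def pulse_rate_bpm(peaks: PeakSeries) -> float:
    """Mean pulse rate, 60 / mean interval."""
    if peaks.n_peaks < 2:
        raise UndefinedFeatureError("pulse rate needs at least 2 peaks")
    return float(60.0 / peaks.intervals.mean())


def autocorr_features(seg: Segment, n_lags: int = N_AUTOCORR_LAGS) -> np.ndarray:
    """Normalized sample autocorrelation of the mean-removed waveform,
    r[k] = sum_t x[t] x[t+k] / sum_t x[t]^2, for lags k = 1..n_lags."""
    x = np.asarray(seg.samples, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        logger.warning("zero-variance segment %s: autocorrelation set to 0", seg.segment_id)
        return np.zeros(n_lags)
    full = signal.correlate(x, x, mode="full")
    mid = x.size - 1
    return full[mid + 1 : mid + 1 + n_lags] / denom


@dataclass
class FeatureVector:
    """Rhythm features of one segment."""

    segment_id: str
    rmssd: float
    she: float
    cv: float
    pulse_rate: float
    autocorr: np.ndarray

    @property
    def rmssd_she(self) -> np.ndarray:
        return np.array([self.rmssd, self.she])

    @property
    def ensemble(self) -> np.ndarray:
        """(rmssd, she) concatenated with the autocorrelation vector."""
        return np.concatenate([self.rmssd_she, self.autocorr])


def extract_features(seg: Segment) -> FeatureVector:
    """All rhythm features for one segment; raises
    :class:`UndefinedFeatureError` when too few peaks are found."""
    peaks = detect_peaks(seg)
    iv = peaks.intervals
    return FeatureVector(
        segment_id=seg.segment_id,
        rmssd=rmssd(iv),
        she=shannon_entropy(iv),
        cv=coefficient_of_variation(iv),
        pulse_rate=pulse_rate_bpm(peaks),
        autocorr=autocorr_features(seg),
    )


def feature_table(segset: SegmentSet) -> pd.DataFrame:
    """Feature table for a segment set, one row per segment.

    Columns: rmssd, she, cv, pulse_rate, ac_001..ac_150, plus a boolean
    ``defined`` flag.  Segments with too few peaks get NaN features and
    defined=False; they are excluded from SVM arms but remain available to
    the CNN (the exclusion is logged and counted).
    """
    rows = []
    n_excluded = 0
    for i in range(len(segset)):
        m = segset.meta.iloc[i]
        seg = Segment(
            samples=segset.X[i],
            fs=segset.fs,
            length_s=segset.length_s,
            label=m["label"],
            subject_id=m["subject_id"],
            recording_id=m["recording_id"],
            start_s=m["start_s"],
        )
        base = {"segment_id": m["segment_id"]}
        try:
            fv = extract_features(seg)
            base.update(
                rmssd=fv.rmssd, she=fv.she, cv=fv.cv, pulse_rate=fv.pulse_rate, defined=True
            )
            base.update({f"ac_{k + 1:03d}": fv.autocorr[k] for k in range(fv.autocorr.size)})
        except UndefinedFeatureError as exc:
            n_excluded += 1
            logger.info("segment %s excluded from feature arms: %s", m["segment_id"], exc)
            base.update(rmssd=np.nan, she=np.nan, cv=np.nan, pulse_rate=np.nan, defined=False)
            base.update({f"ac_{k + 1:03d}": np.nan for k in range(N_AUTOCORR_LAGS)})
        rows.append(base)
    if n_excluded:
        logger.warning("%d/%d segments had undefined features", n_excluded, len(segset))
    return pd.DataFrame(rows)


ARM_FEATURES = {
    "svm_rmssd_she": ["rmssd", "she"],
    "svm_autocorr": [f"ac_{k:03d}" for k in range(1, N_AUTOCORR_LAGS + 1)],
    "svm_ensemble": ["rmssd", "she"] + [f"ac_{k:03d}" for k in range(1, N_AUTOCORR_LAGS + 1)],
}
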