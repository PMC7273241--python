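"""Independent brute-force reference implementations used as oracles.

Everything here is written as literal formula evaluation (loops, explicit
pair counting), deliberately independent of the vectorized library code it
checks.
"""

from __future__ import annotations

import math


def rmssd_brute(intervals) -> float:
    diffs = [intervals[i + 1] - intervals[i] for i in range(len(intervals) - 1)]
    return math.sqrt(sum(d * d for d in diffs) / len(diffs))


def shannon_entropy_brute(intervals, n_bins: int = 16) -> float:
    lo, hi = min(intervals), max(intervals)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in intervals:
        k = int((v - lo) / width)
        if k == n_bins:  # right edge belongs to the last bin
            k = n_bins - 1
        counts[k] += 1
    n = len(intervals)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log(p)
    return h / math.log(n_bins)


def cv_brute(intervals) -> float:
    n = len(intervals)
    mean = sum(intervals) / n
    var = sum((v - mean) ** 2 for v in intervals) / (n - 1)
    return math.sqrt(var) / mean


def pulse_rate_brute(peak_times) -> float:
    intervals = [peak_times[i + 1] - peak_times[i] for i in range(len(peak_times) - 1)]
    return 60.0 / (sum(intervals) / len(intervals))


def auc_brute(scores, labels) -> float:
    """Exhaustive pair counting: P(score_AF > score_SR), ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def confusion_brute(predicted, labels, positive="AF"):
    tp = tn = fp = fn = 0
    for p, l in zip(predicted, labels):
        if l == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return tp, tn, fp, fn
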