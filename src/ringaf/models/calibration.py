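"""Temperature scaling and calibration diagnostics.

Temperature scaling divides the logits by a single fitted scalar T > 0
before the softmax; T is chosen to minimize the negative log-likelihood on
a held-out calibration split.  Because division by a positive scalar is a
monotone transform of each logit pair, the predicted class never changes —
only the stated confidence does.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar

from .base import softmax

logger = logging.getLogger(__name__)

MIN_CALIBRATION_SAMPLES = 50


def fit_temperature(logits: np.ndarray, labels: np.ndarray) -> float:
    """Fit the temperature on calibration logits (n, 2) and integer labels.

    Minimizes NLL of softmax(logits / T) over log T (one-dimensional,
    smooth); falls back to T = 1 with a warning if the search fails.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError("logits must have shape (n, 2)")
    if len(labels) < MIN_CALIBRATION_SAMPLES:
        raise ValueError(f"need >= {MIN_CALIBRATION_SAMPLES} calibration samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration split must contain both classes")

    idx = np.arange(len(labels))

    def nll(log_t: float) -> float:
        p = softmax(logits / np.exp(log_t))
        return float(-np.log(np.clip(p[idx, labels], 1e-12, None)).mean())

    res = minimize_scalar(nll, bounds=(np.log(0.05), np.log(20.0)), method="bounded")
    if not res.success or not np.isfinite(res.x):
        logger.warning("temperature search failed; keeping T = 1")
        return 1.0
    return float(np.exp(res.x))


def expected_calibration_error(p_af: np.ndarray, labels: np.ndarray, n_bins: int = 10) -> float:
    """10-bin expected calibration error of binary confidences.

    Confidence = max(p_af, 1 - p_af) is binned over [0.5, 1]; ECE is the
    sample-weighted mean absolute gap between per-bin accuracy and per-bin
    mean confidence.
    """
    p_af = np.asarray(p_af, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (p_af >= 0.5).astype(int)
    conf = np.maximum(p_af, 1.0 - p_af)
    correct = (pred == labels).astype(float)
    edges = np.linspace(0.5, 1.0, n_bins + 1)
    ece = 0.0
    n = len(labels)
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (conf >= lo) & (conf < hi) if hi < 1.0 else (conf >= lo) & (conf <= hi)
        if not mask.any():
            continue
        ece += mask.sum() / n * abs(correct[mask].mean() - conf[mask].mean())
    return float(ece)
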