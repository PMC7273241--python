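"""Linear-kernel SVM arms on hand-crafted rhythm features.

Three feature sets: (RMSSD, ShE); the 150-lag waveform autocorrelation;
and their concatenation (the ensemble).  Features are standardized with
training-set statistics only; class probabilities come from a logistic
link fitted on the training decision scores (Platt scaling), which gives
the continuous score the ROC analysis needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from ..features import ARM_FEATURES
from .base import CalibratedModel


class _SVMBackend:
    def __init__(self, scaler: StandardScaler, svc: LinearSVC, platt: LogisticRegression):
        self.scaler = scaler
        self.svc = svc
        self.platt = platt

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(X))

    def logits(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)[:, None]
        z_af = self.platt.decision_function(s)  # log-odds of AF
        return np.column_stack([np.zeros_like(z_af), z_af])


def arm_matrix(features: pd.DataFrame, arm: str) -> np.ndarray:
    """Feature matrix for one SVM arm (rows must be defined-feature
    segments); the ensemble arm is the 2 + 150 = 152-dim concatenation."""
    cols = ARM_FEATURES[arm]
    return features[cols].to_numpy(dtype=float)


def train_svm(
    features: pd.DataFrame,
    labels: np.ndarray,
    arm: str,
    svm_c: float = 1.0,
    seed: int = 0,
    input_length_s: float = 30.0,
) -> CalibratedModel:
    """Train one linear-SVM arm.

    ``features`` is a defined-feature table (see
    :func:`ringaf.features.feature_table`); ``labels`` are integer
    (0 = SR, 1 = AF).  Raises on a single-class training set.
    """
    if arm not in ARM_FEATURES:
        raise ValueError(f"not an SVM arm: {arm!r}")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = arm_matrix(features, arm)
    scaler = StandardScaler().fit(X)
    svc = LinearSVC(C=svm_c, random_state=seed).fit(scaler.transform(X), y)
    scores = svc.decision_function(scaler.transform(X))[:, None]
    platt = LogisticRegression(C=1e6, random_state=seed).fit(scores, y)
    backend = _SVMBackend(scaler, svc, platt)
    return CalibratedModel(
        backend=backend,
        arm=arm,
        input_length_s=input_length_s,
        temperature=1.0,
        fingerprint={"arm": arm, "svm_c": svm_c, "seed": seed, "n_train": len(y)},
    )
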