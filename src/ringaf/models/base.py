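"""Shared model-layer types: configuration, calibrated models, predictions,
and confidence-threshold filtering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ..synth import Rhythm

ARMS = ("cnn", "svm_rmssd_she", "svm_autocorr", "svm_ensemble")
LABEL_TO_INT = {Rhythm.SR.value: 0, Rhythm.AF.value: 1}


@dataclass(frozen=True)
class ModelConfig:
    """Training configuration for one classification arm.

    CNN defaults: Adam at learning_rate 1e-3 for ``epochs`` epochs, batch
    ``batch_size``, dropout on the fully connected layers, L2 penalty
    ``l2_weight`` on weights.  SVM arms use ``svm_c`` as the margin
    regularization strength.  ``seed`` drives every stochastic choice.
    """

    arm: str
    input_length_s: float = 30.0
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    l2_weight: float = 1e-4
    dropout_rate: float = 0.5
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class CalibratedModel:
    """A trained classifier plus its post-hoc temperature.

    ``backend`` is the opaque trained object; it must expose
    ``logits(X) -> (n, 2)`` (columns ordered SR, AF).  Calibrated
    probabilities are softmax(logits / temperature); dividing by a positive
    scalar never changes the argmax, so calibration leaves every predicted
    label untouched.
    """

    backend: Any
    arm: str
    input_length_s: float
    temperature: float = 1.0
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.backend.logits(np.asarray(X))

    def predict_proba_af(self, X: np.ndarray) -> np.ndarray:
        return softmax(self.logits(X) / self.temperature)[:, 1]


def predictions_frame(
    segment_ids: np.ndarray,
    p_af: np.ndarray,
    arm: str,
    p_af_raw: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble per-segment predictions.  The predicted class is whichever
    has the higher calibrated confidence; an exact tie (p_af = 0.5) is
    called AF, favoring sensitivity in a screening setting.  ``p_af_raw``
    optionally carries the pre-calibration (temperature 1) probability."""
    p_af = np.asarray(p_af, dtype=float)
    predicted = np.where(p_af >= 0.5, Rhythm.AF.value, Rhythm.SR.value)
    confidence = np.maximum(p_af, 1.0 - p_af)
    return pd.DataFrame(
        {
            "segment_id": segment_ids,
            "p_af": p_af,
            "p_af_raw": p_af if p_af_raw is None else np.asarray(p_af_raw, dtype=float),
            "predicted": predicted,
            "confidence": confidence,
            "arm": arm,
        }
    )


def confidence_filter(predictions: pd.DataFrame, threshold: float) -> tuple[pd.DataFrame, float]:
    """Keep predictions whose confidence strictly exceeds ``threshold``;
    returns (kept rows, filtered fraction)."""
    if not (0.5 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0.5, 1]")
    kept = predictions[predictions["confidence"] > threshold]
    frac = 1.0 - len(kept) / len(predictions) if len(predictions) else 0.0
    return kept.reset_index(drop=True), float(frac)


def labels_to_int(labels: np.ndarray) -> np.ndarray:
    return np.asarray([LABEL_TO_INT[str(l)] for l in np.asarray(labels).ravel()])
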