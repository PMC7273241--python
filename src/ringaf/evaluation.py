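"""The diagnostic-evaluation protocol.

Repeated subject-level five-fold cross-validation (5 folds x 10 training
repetitions = 50 validation processes by default), diagnostic metrics
(accuracy, sensitivity, specificity, PPV, NPV with AF as the positive
class), ROC/AUC with a bootstrap CI, the sample-length study, decile
stratifications by interval variability and pulse rate, the
premature-beat-burden study under subject- vs sample-randomized folds,
the confidence-threshold sweep, and repeated external validation on an
all-SR cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import models
from .features import feature_table
from .models import CalibratedModel, ModelConfig, confidence_filter, labels_to_int
from .preprocess import SegmentSet
from .synth import Rhythm, derive_seed

logger = logging.getLogger(__name__)

POSITIVE = Rhythm.AF.value
NEGATIVE = Rhythm.SR.value

BURDEN_BINS = ((0.0, 0.0), (0.0, 0.05), (0.05, 0.10), (0.10, 0.20), (0.20, 1.0))


class LeakageError(RuntimeError):
    """A subject appeared on both sides of a train/test split."""


# -- fold plans --------------------------------------------------------------


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of cross-validation units (subjects or samples) to folds.

    Each fold serves once as the test set; training on the remaining folds
    is repeated ``repeats_per_fold`` times with distinct derived seeds, so
    k x repeats_per_fold validation processes in total.
    """

    unit: str                       # "subject" | "sample"
    k: int
    repeats_per_fold: int
    assignments: Mapping[str, int]  # unit id -> fold index
    seed: int

    @property
    def n_processes(self) -> int:
        return self.k * self.repeats_per_fold

    def fold_units(self, fold: int) -> list[str]:
        return [u for u, f in self.assignments.items() if f == fold]

    def processes(self) -> Iterable[tuple[int, int, int, int]]:
        """Yield (process_index, fold, repeat, train_seed)."""
        i = 0
        for fold in range(self.k):
            for rep in range(self.repeats_per_fold):
                yield i, fold, rep, derive_seed(self.seed, fold, rep)
                i += 1


def make_fold_plan(
    unit_ids: Sequence[str],
    unit: str = "subject",
    k: int = 5,
    repeats_per_fold: int = 10,
    seed: int = 0,
) -> FoldPlan:
    """Shuffle units by seed and deal them into k near-equal folds."""
    if unit not in ("subject", "sample"):
        raise ValueError("unit must be 'subject' or 'sample'")
    unit_ids = list(dict.fromkeys(unit_ids))
    if len(unit_ids) < k:
        raise ValueError(f"need at least {k} units, got {len(unit_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unit_ids))
    assignments = {unit_ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldPlan(unit=unit, k=k, repeats_per_fold=repeats_per_fold, assignments=assignments, seed=seed)


# -- metrics -----------------------------------------------------------------


@dataclass
class MetricsRow:
    """Diagnostic metrics of one prediction set; AF is the positive class.
    Cells that are undefined on the data (e.g. sensitivity with no AF
    samples) are None, never 0 or 1."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None
    n_tested: int = 0
    n_filtered: int = 0
    stratum: str = "overall"
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def as_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
            "auc_lo": self.auc_ci[0] if self.auc_ci else None,
            "auc_hi": self.auc_ci[1] if self.auc_ci else None,
            "n_tested": self.n_tested,
            "n_filtered": self.n_filtered,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
        }
        return d


def _safe_ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(
    predicted: Sequence[str],
    labels: Sequence[str],
    scores: Sequence[float] | None = None,
    stratum: str = "overall",
    n_filtered: int = 0,
) -> MetricsRow:
    """Confusion counts and the five diagnostic ratios; optionally AUC from
    continuous scores (probability of AF)."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.size == 0:
        raise ValueError("empty prediction set")
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must align")
    pos_pred = predicted == POSITIVE
    pos_true = labels == POSITIVE
    tp = int(np.sum(pos_pred & pos_true))
    tn = int(np.sum(~pos_pred & ~pos_true))
    fp = int(np.sum(pos_pred & ~pos_true))
    fn = int(np.sum(~pos_pred & pos_true))
    auc = None
    if scores is not None and 0 < pos_true.sum() < labels.size:
        auc = float(roc_auc_score(pos_true.astype(int), np.asarray(scores, dtype=float)))
    return MetricsRow(
        accuracy=_safe_ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
        auc=auc,
        n_tested=int(predicted.size),
        n_filtered=int(n_filtered),
        stratum=stratum,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
    )


def roc_auc_ci(
    scores: Sequence[float],
    labels: Sequence[str] | Sequence[int],
    ci: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUC (probability a random AF score exceeds a random SR score, ties
    counting one half) with a stratified-bootstrap percentile CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels_to_int(labels) if labels.dtype.kind in "UO" else labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for AUC")
    auc = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        idx = np.concatenate([bp, bn])
        boots[b] = roc_auc_score(y[idx], scores[idx])
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return auc, float(lo), float(hi)


# -- cross-validation --------------------------------------------------------


@dataclass
class StudyReport:
    """Per-process metric rows plus their arithmetic-mean aggregate and
    every per-segment prediction (with process provenance)."""

    rows: pd.DataFrame
    predictions: pd.DataFrame
    experiment: str
    fingerprint: dict = field(default_factory=dict)

    _METRIC_COLS = ("accuracy", "sensitivity", "specificity", "ppv", "npv", "auc")

    @property
    def aggregate(self) -> pd.Series:
        return self.rows[list(self._METRIC_COLS)].mean()


def _calibration_split(
    train_units: list[str], rng: np.random.Generator, fraction: float = 0.2
) -> tuple[list[str], list[str]]:
    units = list(train_units)
    rng.shuffle(units)
    n_cal = max(int(round(fraction * len(units))), 1)
    return units[n_cal:], units[:n_cal]


def _train_and_predict(
    segset: SegmentSet,
    arm: str,
    train_mask: np.ndarray,
    test_mask: np.ndarray,
    config: ModelConfig,
    train_seed: int,
    features: pd.DataFrame | None,
    cal_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    test = segset.subset(test_mask)
    if arm == "cnn":
        cfg = ModelConfig(
            arm="cnn",
            input_length_s=segset.length_s,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            l2_weight=config.l2_weight,
            dropout_rate=config.dropout_rate,
            seed=train_seed,
        )
        fit_mask = train_mask & ~cal_mask if cal_mask is not None else train_mask
        model = models.train_cnn(
            segset.X[fit_mask],
            labels_to_int(segset.labels[fit_mask]),
            cfg,
            segset.X[cal_mask] if cal_mask is not None else segset.X[fit_mask],
            labels_to_int(segset.labels[cal_mask if cal_mask is not None else fit_mask]),
        )
        return models.predict(model, test)
    if features is None:
        raise ValueError("SVM arms require a precomputed feature table")
    feats = features.set_index("segment_id")
    train_ids = segset.meta.loc[train_mask, "segment_id"]
    tr = feats.loc[train_ids].reset_index()
    tr_defined = tr["defined"].to_numpy(bool)
    tr = tr[tr_defined]
    y_tr = labels_to_int(segset.labels[train_mask][tr_defined])
    model = models.train_svm(
        tr, y_tr, arm, svm_c=config.svm_c, seed=train_seed, input_length_s=segset.length_s
    )
    return models.predict(model, test, features=features)


def run_cross_validation(
    segset: SegmentSet,
    arm: str,
    fold_plan: FoldPlan,
    config: ModelConfig | None = None,
    features: pd.DataFrame | None = None,
) -> StudyReport:
    """Run every validation process of the fold plan for one arm.

    Subject-mode plans guarantee that no subject contributes segments to
    both train and test of any process (checked on every process; a
    violation raises :class:`LeakageError`).  For the CNN, a
    subject-disjoint 20% calibration split is carved out of the training
    units of each process for temperature fitting.
    """
    config = config or ModelConfig(arm=arm, input_length_s=segset.length_s)
    if arm in models.ARMS[1:] and features is None:
        features = feature_table(segset)
    meta = segset.meta
    unit_col = meta["subject_id"] if fold_plan.unit == "subject" else meta["segment_id"]
    unit_col = unit_col.to_numpy()
    label_by_id = meta.set_index("segment_id")["label"]

    rows = []
    all_preds = []
    for proc, fold, rep, train_seed in fold_plan.processes():
        test_units = set(fold_plan.fold_units(fold))
        train_units = [u for u in fold_plan.assignments if u not in test_units]
        if set(train_units) & test_units:
            raise LeakageError(f"unit leak in process {proc} (fold {fold}, repeat {rep})")
        test_mask = np.isin(unit_col, list(test_units))
        train_mask = ~test_mask
        if fold_plan.unit == "subject":
            leak = set(meta.loc[train_mask, "subject_id"]) & set(meta.loc[test_mask, "subject_id"])
            if leak:
                raise LeakageError(f"subjects {sorted(leak)} leak across process {proc}")
        cal_mask = None
        if arm == "cnn":
            rng = np.random.default_rng(derive_seed(fold_plan.seed, 7, fold, rep))
            fit_units, cal_units = _calibration_split(train_units, rng)
            cal_mask = np.isin(unit_col, cal_units)
        try:
            preds = _train_and_predict(
                segset, arm, train_mask, test_mask, config, train_seed, features, cal_mask
            )
        except Exception:
            logger.error(
                "process %d failed (fold=%d repeat=%d train_seed=%d)", proc, fold, rep, train_seed
            )
            raise
        preds = preds.assign(
            process=proc,
            fold=fold,
            repeat=rep,
            label=label_by_id.loc[preds["segment_id"]].to_numpy(),
        )
        row = compute_metrics(
            preds["predicted"], preds["label"], scores=preds["p_af"], stratum="overall"
        ).as_dict()
        row.update(process=proc, fold=fold, repeat=rep, train_seed=train_seed, arm=arm)
        rows.append(row)
        all_preds.append(preds)

    return StudyReport(
        rows=pd.DataFrame(rows),
        predictions=pd.concat(all_preds, ignore_index=True),
        experiment=f"cv/{arm}/{fold_plan.unit}",
        fingerprint={
            "arm": arm,
            "unit": fold_plan.unit,
            "k": fold_plan.k,
            "repeats_per_fold": fold_plan.repeats_per_fold,
            "fold_seed": fold_plan.seed,
            "length_s": segset.length_s,
        },
    )


# -- derived studies ---------------------------------------------------------


def length_study(
    segset: SegmentSet,
    arm: str,
    fold_plan: FoldPlan,
    lengths: Sequence[float] = (30, 25, 20, 15, 10, 5),
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Re-run the cross-validation at each sample length (segments derive
    from the same 30-s windows by truncation, so counts match across
    lengths); one model is trained per length and process."""
    out = []
    for L in lengths:
        sub = segset.truncate(float(L))
        feats = feature_table(sub) if arm != "cnn" else None
        rep = run_cross_validation(sub, arm, fold_plan, config, features=feats)
        agg = rep.aggregate
        out.append({"length_s": float(L), "n_segments": len(sub), **agg.to_dict()})
    return pd.DataFrame(out)


def threshold_sweep(
    predictions: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95),
) -> pd.DataFrame:
    """Metrics on the retained set at each confidence threshold; rows where
    every sample is filtered are flagged absent."""
    if "label" not in predictions:
        raise ValueError("predictions must carry true labels")
    out = []
    for thr in thresholds:
        kept, frac = confidence_filter(predictions, float(thr))
        row: dict = {"threshold": float(thr), "filtered_fraction": frac, "absent": False}
        if len(kept) == 0:
            row["absent"] = True
        else:
            m = compute_metrics(
                kept["predicted"],
                kept["label"],
                scores=kept["p_af"],
                stratum=f"threshold={thr}",
                n_filtered=len(predictions) - len(kept),
            )
            row.update(m.as_dict())
        out.append(row)
    df = pd.DataFrame(out)
    return df


def stratify_deciles(
    predictions: pd.DataFrame,
    statistic: str,
    n_bins: int = 10,
) -> dict[str, pd.DataFrame]:
    """Per-decile sensitivity (over AF samples) and specificity (over SR
    samples), with decile boundaries computed from the statistic's
    quantiles *within* each true class."""
    if statistic not in predictions:
        raise ValueError(f"predictions lack a {statistic!r} column")
    out: dict[str, pd.DataFrame] = {}
    for metric, cls in (("sensitivity", POSITIVE), ("specificity", NEGATIVE)):
        sub = predictions[predictions["label"] == cls].copy()
        if sub.empty:
            out[metric] = pd.DataFrame()
            continue
        try:
            sub["decile"] = pd.qcut(sub[statistic], n_bins, labels=False, duplicates="drop")
        except ValueError:
            sub["decile"] = 0
        rows = []
        for d, grp in sub.groupby("decile"):
            if len(grp) < 10:
                logger.warning("decile %s of %s has only %d samples", d, statistic, len(grp))
            correct = (grp["predicted"] == grp["label"]).mean()
            rows.append(
                {
                    "decile": int(d),
                    "n": len(grp),
                    f"{statistic}_lo": grp[statistic].min(),
                    f"{statistic}_hi": grp[statistic].max(),
                    metric: float(correct),
                }
            )
        out[metric] = pd.DataFrame(rows)
    return out


def _burden_bin_label(lo: float, hi: float) -> str:
    if lo == hi == 0.0:
        return "0"
    return f"({lo:g}-{hi:g}]"


def premature_burden_study(
    segset: SegmentSet,
    arms: Sequence[str],
    seed: int,
    k: int = 5,
    repeats_per_fold: int = 1,
    configs: Mapping[str, ModelConfig] | None = None,
) -> pd.DataFrame:
    """Specificity of each arm on SR segments binned by their true
    premature-beat fraction, under subject-randomized and
    sample-randomized fold plans."""
    if segset.meta["premature_fraction"].isna().any():
        raise ValueError("segments must carry ground-truth premature fractions")
    configs = configs or {}
    rows = []
    for unit in ("subject", "sample"):
        ids = segset.subject_ids if unit == "subject" else segset.meta["segment_id"]
        plan = make_fold_plan(list(ids), unit=unit, k=k, repeats_per_fold=repeats_per_fold, seed=seed)
        feats = None
        for arm in arms:
            if arm != "cnn" and feats is None:
                feats = feature_table(segset)
            rep = run_cross_validation(segset, arm, plan, configs.get(arm), features=feats)
            preds = rep.predictions.merge(
                segset.meta[["segment_id", "premature_fraction"]], on="segment_id"
            )
            sr = preds[preds["label"] == NEGATIVE]
            for lo, hi in BURDEN_BINS:
                if lo == hi == 0.0:
                    grp = sr[sr["premature_fraction"] == 0.0]
                else:
                    grp = sr[(sr["premature_fraction"] > lo) & (sr["premature_fraction"] <= hi)]
                if grp.empty:
                    continue
                rows.append(
                    {
                        "unit": unit,
                        "arm": arm,
                        "bin": _burden_bin_label(lo, hi),
                        "bin_lo": lo,
                        "bin_hi": hi,
                        "n": len(grp),
                        "specificity": float((grp["predicted"] == NEGATIVE).mean()),
                    }
                )
    return pd.DataFrame(rows)


def external_validation(
    model: CalibratedModel,
    segset: SegmentSet,
    repeats: int = 10,
    features: pd.DataFrame | None = None,
) -> dict:
    """Repeatedly test an all-SR cohort with a trained model.

    Each segment is evaluated ``repeats`` times; with a deterministic
    model the repeats agree and are still all counted, mirroring a
    repeated-testing protocol (20 x 87 = 1,740 segments tested 10 times
    give 17,400 test cases).
    """
    if not (segset.labels == NEGATIVE).all():
        raise ValueError("external validation cohort must be all SR")
    n_correct = 0
    n_cases = 0
    per_repeat = []
    for _ in range(repeats):
        preds = models.predict(model, segset, features=features)
        ok = int((preds["predicted"] == NEGATIVE).sum())
        n_correct += ok
        n_cases += len(preds)
        per_repeat.append(ok / len(preds))
    return {
        "n_segments": len(segset),
        "repeats": repeats,
        "n_cases": n_cases,
        "n_correct_sr": n_correct,
        "fraction_sr": n_correct / n_cases,
        "per_repeat_fraction": per_repeat,
    }


def embed_features_2d(
    model: CalibratedModel,
    segset: SegmentSet,
    seed: int = 0,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """2-D t-SNE embedding of the CNN's penultimate-layer activations, for
    visualizing how the learned feature space separates the rhythms."""
    if model.arm != "cnn":
        raise ValueError("feature embedding requires the CNN arm")
    from sklearn.manifold import TSNE

    H = model.backend.embed(segset.X)
    n = H.shape[0]
    perplexity = min(30.0, max((n - 1) / 3.0, 2.0))
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    XY = tsne.fit_transform(H)
    p_af = model.predict_proba_af(segset.X)
    out = pd.DataFrame(
        {
            "segment_id": segset.meta["segment_id"],
            "x": XY[:, 0],
            "y": XY[:, 1],
            "label": segset.labels,
            "confidence": np.maximum(p_af, 1 - p_af),
        }
    )
    if extra is not None:
        out = out.merge(extra, on="segment_id", how="left")
    return out
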