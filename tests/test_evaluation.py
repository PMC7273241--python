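"""Evaluation-protocol tests: fold plans, metric formulas vs brute-force
counting, AUC pair counting, leakage guards, derived studies."""

import numpy as np
import pandas as pd
import pytest

from ringaf import evaluation, models
from ringaf.evaluation import (
    LeakageError,
    compute_metrics,
    external_validation,
    make_fold_plan,
    roc_auc_ci,
    run_cross_validation,
    stratify_deciles,
    threshold_sweep,
)
from ringaf.features import feature_table
from ringaf.models import ModelConfig

from _oracles import auc_brute, confusion_brute


class TestFoldPlan:
    def test_equal_division_100_subjects(self):
        plan = make_fold_plan([f"s{i}" for i in range(100)], k=5, seed=1)
        sizes = [len(plan.fold_units(f)) for f in range(5)]
        assert sizes == [20] * 5

    def test_fifty_processes(self):
        plan = make_fold_plan([f"s{i}" for i in range(10)], k=5, repeats_per_fold=10, seed=2)
        procs = list(plan.processes())
        assert len(procs) == 50 and plan.n_processes == 50
        assert len({seed for *_, seed in procs}) == 50  # distinct derived seeds

    def test_folds_partition_units(self):
        ids = [f"s{i}" for i in range(23)]
        plan = make_fold_plan(ids, k=5, seed=3)
        all_units = [u for f in range(5) for u in plan.fold_units(f)]
        assert sorted(all_units) == sorted(ids)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b"], k=5, seed=0)


class TestMetrics:
    def test_all_correct_gives_ones(self):
        m = compute_metrics(["AF", "SR"] * 5, ["AF", "SR"] * 5)
        assert (
            m.accuracy == m.sensitivity == m.specificity == m.ppv == m.npv == 1.0
        )

    def test_worked_confusion_example(self):
        predicted = ["AF"] * 99 + ["SR"] * 1 + ["SR"] * 94 + ["AF"] * 6
        labels = ["AF"] * 100 + ["SR"] * 100
        m = compute_metrics(predicted, labels)
        assert m.sensitivity == pytest.approx(0.99)
        assert m.specificity == pytest.approx(0.94)
        assert m.accuracy == pytest.approx(0.965)

    def test_single_class_cohort_has_absent_sensitivity(self):
        # external-validation bookkeeping: 16529 correct of 17400 SR tests
        predicted = ["SR"] * 16529 + ["AF"] * 871
        labels = ["SR"] * 17400
        m = compute_metrics(predicted, labels)
        assert m.accuracy == pytest.approx(0.9499, abs=1e-4)
        assert m.sensitivity is None  # no AF samples -> undefined, absent
        assert m.ppv == 0.0 and m.npv == 1.0
        assert m.specificity == pytest.approx(0.9499, abs=1e-4)

    def test_agrees_with_brute_force_on_random_sets(self, rng):
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            predicted = rng.choice(["AF", "SR"], n)
            labels = rng.choice(["AF", "SR"], n)
            m = compute_metrics(predicted, labels)
            tp, tn, fp, fn = confusion_brute(predicted, labels)
            assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
            assert m.accuracy == pytest.approx((tp + tn) / n)
            if tp + fn:
                assert m.sensitivity == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m.specificity == pytest.approx(tn / (tn + fp))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [])


class TestAUC:
    def test_perfect_separation(self):
        auc, lo, hi = roc_auc_ci([0.9, 0.8, 0.2, 0.1], ["AF", "AF", "SR", "SR"], seed=1)
        assert auc == 1.0

    def test_worked_pair_counting_example(self):
        auc, *_ = roc_auc_ci([0.9, 0.4, 0.6, 0.2], ["AF", "AF", "SR", "SR"], n_boot=100, seed=1)
        assert auc == pytest.approx(0.75)  # 3 of 4 pairs win

    def test_random_scores_near_half(self, rng):
        scores = rng.uniform(size=2000)
        labels = np.where(np.arange(2000) % 2 == 0, "AF", "SR")
        auc, *_ = roc_auc_ci(scores, labels, n_boot=50, seed=2)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_exhaustive_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 2)  # ties likely
            auc, *_ = roc_auc_ci(scores, y, n_boot=10, seed=0)
            assert auc == pytest.approx(auc_brute(list(scores), list(y)))

    def test_ci_brackets_point_estimate(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 100), rng.normal(0, 1, 100)])
        labels = ["AF"] * 100 + ["SR"] * 100
        auc, lo, hi = roc_auc_ci(scores, labels, n_boot=500, seed=3)
        assert lo <= auc <= hi and 0.5 < auc < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci([0.1, 0.2], ["SR", "SR"])


@pytest.fixture(scope="module")
def svm_report(mini_cohort_segments):
    plan = make_fold_plan(
        sorted(set(mini_cohort_segments.subject_ids)), k=3, repeats_per_fold=2, seed=4
    )
    return run_cross_validation(mini_cohort_segments, "svm_ensemble", plan)


class TestCrossValidation:

    def test_process_count_and_aggregate(self, svm_report):
        assert len(svm_report.rows) == 6
        assert svm_report.aggregate["accuracy"] == pytest.approx(
            svm_report.rows["accuracy"].mean()
        )

    def test_no_subject_leaks_into_test(self, mini_cohort_segments, svm_report):
        """Every process's test subjects are exactly one fold of the plan,
        so no subject can appear on both sides of a split."""
        meta = mini_cohort_segments.meta.set_index("segment_id")
        plan = make_fold_plan(
            sorted(set(mini_cohort_segments.subject_ids)), k=3, repeats_per_fold=2, seed=4
        )
        for proc, grp in svm_report.predictions.groupby("process"):
            fold = int(svm_report.rows.loc[svm_report.rows["process"] == proc, "fold"].iloc[0])
            test_subjects = set(meta.loc[grp["segment_id"], "subject_id"])
            fold_subjects = set(plan.fold_units(fold))
            assert test_subjects == fold_subjects
            train_subjects = set(plan.assignments) - fold_subjects
            assert not (test_subjects & train_subjects)

    def test_deterministic_given_seeds(self, mini_cohort_segments):
        plan = make_fold_plan(
            sorted(set(mini_cohort_segments.subject_ids)), k=3, repeats_per_fold=1, seed=9
        )
        feats = feature_table(mini_cohort_segments)
        r1 = run_cross_validation(mini_cohort_segments, "svm_rmssd_she", plan, features=feats)
        r2 = run_cross_validation(mini_cohort_segments, "svm_rmssd_she", plan, features=feats)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)

    def test_interval_feature_arm_learns_the_contrast(self, mini_cohort_segments):
        """RMSSD+ShE generalizes across subjects even in a tiny cohort;
        the high-dimensional arms need the full-size benchmark."""
        plan = make_fold_plan(
            sorted(set(mini_cohort_segments.subject_ids)), k=3, repeats_per_fold=2, seed=4
        )
        rep = run_cross_validation(mini_cohort_segments, "svm_rmssd_she", plan)
        assert rep.aggregate["accuracy"] >= 0.85

    def test_sample_mode_also_runs(self, mini_cohort_segments):
        plan = make_fold_plan(
            list(mini_cohort_segments.meta["segment_id"]), unit="sample", k=3,
            repeats_per_fold=1, seed=5,
        )
        rep = run_cross_validation(mini_cohort_segments, "svm_rmssd_she", plan)
        assert len(rep.rows) == 3


class TestDerivedStudies:
    def _toy_predictions(self, rng, n=400):
        labels = np.where(rng.random(n) < 0.5, "AF", "SR")
        p_af = np.clip(
            np.where(labels == "AF", 0.8, 0.2) + rng.normal(0, 0.18, n), 0.001, 0.999
        )
        return pd.DataFrame(
            {
                "segment_id": np.arange(n).astype(str),
                "p_af": p_af,
                "predicted": np.where(p_af >= 0.5, "AF", "SR"),
                "confidence": np.maximum(p_af, 1 - p_af),
                "label": labels,
                "cv": rng.uniform(0, 0.4, n),
            }
        )

    def test_threshold_sweep_monotone_filtering(self, rng):
        preds = self._toy_predictions(rng)
        sweep = threshold_sweep(preds, thresholds=np.linspace(0.5, 0.95, 10))
        assert np.all(np.diff(sweep["filtered_fraction"]) >= 0)
        assert sweep.iloc[0]["filtered_fraction"] == 0.0 or preds["confidence"].min() > 0.5

    def test_threshold_sweep_improves_retained_accuracy(self, rng):
        preds = self._toy_predictions(rng, n=3000)
        sweep = threshold_sweep(preds, thresholds=[0.5, 0.9])
        assert sweep.iloc[1]["accuracy"] >= sweep.iloc[0]["accuracy"] - 0.01

    def test_decile_partition_and_homogeneous_rates(self, rng):
        preds = self._toy_predictions(rng, n=5000)
        out = stratify_deciles(preds, "cv")
        for metric, cls in (("sensitivity", "AF"), ("specificity", "SR")):
            df = out[metric]
            n_class = (preds["label"] == cls).sum()
            assert df["n"].sum() == n_class  # partition, each sample once
            assert df["n"].max() - df["n"].min() <= max(2, 0.02 * n_class)
            pooled = preds[preds["label"] == cls]
            pooled_rate = (pooled["predicted"] == pooled["label"]).mean()
            # homogeneous model: each decile close to pooled within binomial error
            se = np.sqrt(pooled_rate * (1 - pooled_rate) / (n_class / 10))
            assert np.all(np.abs(df[metric] - pooled_rate) < 5 * se)

    def test_premature_burden_bins_partition_sr_segments(self, mini_cohort_segments):
        df = evaluation.premature_burden_study(
            mini_cohort_segments, arms=["svm_rmssd_she"], seed=8, k=3
        )
        n_sr = int((mini_cohort_segments.labels == "SR").sum())
        for unit in ("subject", "sample"):
            sub = df[(df["unit"] == unit) & (df["arm"] == "svm_rmssd_she")]
            assert sub["n"].sum() == n_sr  # bins partition the SR segments
            assert sub["specificity"].between(0, 1).all()

    def test_external_validation_counts(self, mini_cohort_segments):
        sr_mask = mini_cohort_segments.labels == "SR"
        sr_set = mini_cohort_segments.subset(sr_mask)
        feats = feature_table(mini_cohort_segments)
        y = models.labels_to_int(mini_cohort_segments.labels)
        ok = feats["defined"].to_numpy(bool)
        model = models.train_svm(feats[ok], y[ok], "svm_rmssd_she")
        res = external_validation(model, sr_set, repeats=10, features=feats)
        assert res["n_cases"] == 10 * res["n_segments"]
        assert 0.0 <= res["fraction_sr"] <= 1.0

    def test_external_validation_rejects_af(self, mini_cohort_segments):
        af_set = mini_cohort_segments.subset(mini_cohort_segments.labels == "AF")
        with pytest.raises(ValueError):
            external_validation(None, af_set)


class TestEmbedding:
    def test_tsne_embedding_separates_classes(self, mini_cohort_segments):
        sub = mini_cohort_segments.subset(np.arange(len(mini_cohort_segments)) % 3 == 0)
        y = models.labels_to_int(sub.labels)
        cfg = ModelConfig(arm="cnn", input_length_s=30.0, epochs=6, batch_size=16,
                          learning_rate=3e-3, seed=3)
        net = models.CNNClassifier(cfg)
        net.fit(sub.X, y)
        model = models.CalibratedModel(backend=net, arm="cnn", input_length_s=30.0)
        emb = evaluation.embed_features_2d(model, sub, seed=0)
        assert len(emb) == len(sub)
        xy = emb[["x", "y"]].to_numpy()
        lab = emb["label"].to_numpy()
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        intra = d[same].mean()
        inter = d[~same & ~np.eye(len(lab), dtype=bool)].mean()
        assert intra < inter

    def test_embedding_deterministic(self, mini_cohort_segments):
        sub = mini_cohort_segments.subset(np.arange(len(mini_cohort_segments)) % 9 == 0)
        y = models.labels_to_int(sub.labels)
        cfg = ModelConfig(arm="cnn", input_length_s=30.0, epochs=2, batch_size=16, seed=3)
        net = models.CNNClassifier(cfg)
        net.fit(sub.X, y)
        model = models.CalibratedModel(backend=net, arm="cnn", input_length_s=30.0)
        e1 = evaluation.embed_features_2d(model, sub, seed=7)
        e2 = evaluation.embed_features_2d(model, sub, seed=7)
        np.testing.assert_allclose(e1[["x", "y"]], e2[["x", "y"]])
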