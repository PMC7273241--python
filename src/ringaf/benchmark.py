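"""The standard synthetic benchmark: study conditions and harness.

The benchmark cohort emulates a paired screening study at desk scale:
40 subjects, one 15-min (900-s) single-channel PPG recording each at
50 Hz — 20 AF subjects with structureless log-normal intervals
(CV 0.25) and interval-dependent pulse amplitude, and 20 SR subjects
with regular intervals (CV 0.05) carrying a premature-beat burden drawn
uniformly in [0, 0.1].  White noise is added at 20 dB SNR plus baseline
wander.  Each recording yields 87 overlapping 30-s segments, 3,480
segments in total.

Evaluation is subject-level five-fold cross-validation with 2 training
repetitions per fold (10 validation processes), a scaled-down version of
the full 5 x 10 protocol that keeps a complete benchmark run on a single
CPU in the tens of minutes.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, preprocess, synth
from .models import ModelConfig

N_AF_SUBJECTS = 20
N_SR_SUBJECTS = 20
RECORDING_S = 900.0
SNR_DB = 20.0
SR_INTERVAL_CV = 0.05
AF_INTERVAL_CV = 0.25
SR_PREMATURE_BURDEN_MAX = 0.1
K_FOLDS = 5
REPEATS_PER_FOLD = 2

# scaled-down CNN training schedule for the benchmark: a third of the
# default epochs at a higher learning rate and smaller batches, which
# converges on the strongly separated synthetic contrast
CNN_EPOCHS = 12
CNN_BATCH = 32
CNN_LR = 3e-3


def benchmark_cohort(seed: int) -> synth.CohortConfig:
    return synth.balanced_cohort(
        n_af=N_AF_SUBJECTS,
        n_sr=N_SR_SUBJECTS,
        seed=seed,
        duration=RECORDING_S,
        sr_interval_cv=SR_INTERVAL_CV,
        af_interval_cv=AF_INTERVAL_CV,
        sr_premature_burden_max=SR_PREMATURE_BURDEN_MAX,
        snr_db=SNR_DB,
    )


def benchmark_segments(seed: int) -> preprocess.SegmentSet:
    """Generate, filter and segment the benchmark cohort."""
    recs = synth.generate_cohort(benchmark_cohort(seed))
    return preprocess.prepare_segments(recs)


def cnn_config(length_s: float = 30.0) -> ModelConfig:
    return ModelConfig(
        arm="cnn",
        input_length_s=length_s,
        epochs=CNN_EPOCHS,
        batch_size=CNN_BATCH,
        learning_rate=CNN_LR,
        seed=0,
    )


def fold_plan(segset: preprocess.SegmentSet, seed: int,
              repeats_per_fold: int = REPEATS_PER_FOLD) -> evaluation.FoldPlan:
    return evaluation.make_fold_plan(
        sorted(np.unique(segset.subject_ids)),
        unit="subject",
        k=K_FOLDS,
        repeats_per_fold=repeats_per_fold,
        seed=synth.derive_seed(seed, 1001),
    )


def run_benchmark_cv(
    segset: preprocess.SegmentSet,
    arm: str,
    seed: int,
    features=None,
    repeats_per_fold: int = REPEATS_PER_FOLD,
) -> evaluation.StudyReport:
    plan = fold_plan(segset, seed, repeats_per_fold)
    config = cnn_config(segset.length_s) if arm == "cnn" else ModelConfig(
        arm=arm, input_length_s=segset.length_s, seed=0
    )
    return evaluation.run_cross_validation(segset, arm, plan, config, features=features)
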