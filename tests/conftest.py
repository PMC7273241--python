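import numpy as np
import pytest

from ringaf import preprocess, synth


@pytest.fixture(scope="session")
def sr_recording():
    """One clean-ish 130-s SR recording with premature beats."""
    spec = synth.RecordingSpec(
        rhythm=synth.Rhythm.SR, duration=130.0, mean_hr=70.0, premature_burden=0.08,
        premature_coupling=0.5, snr_db=30.0,
    )
    return synth.synthesize_recording(spec, seed=101)


@pytest.fixture(scope="session")
def af_recording():
    spec = synth.RecordingSpec(rhythm=synth.Rhythm.AF, duration=130.0, mean_hr=75.0, snr_db=30.0)
    return synth.synthesize_recording(spec, seed=202)


@pytest.fixture(scope="session")
def small_segments(sr_recording, af_recording):
    """Preprocessed 30-s segments from one SR and one AF recording."""
    return preprocess.prepare_segments([sr_recording, af_recording])


@pytest.fixture(scope="session")
def mini_cohort_segments():
    """A small subject-diverse cohort (6 AF + 6 SR, 230 s each) for
    classifier and cross-validation tests."""
    cfg = synth.balanced_cohort(6, 6, seed=5, duration=230.0)
    recs = synth.generate_cohort(cfg)
    return preprocess.prepare_segments(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
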