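"""Generator tests: interval statistics, premature-beat geometry, waveform
periodicity, noise calibration, cohort determinism."""

import numpy as np
import pytest

from ringaf import synth
from ringaf.synth import (
    BeatTrain,
    InfeasibleRhythmError,
    Rhythm,
    RhythmSpec,
    add_noise_and_wander,
    generate_beat_train,
    inject_premature_beats,
    render_waveform,
)


class TestGenerateBeatTrain:
    def test_degenerate_sr_is_perfectly_regular(self):
        spec = RhythmSpec(Rhythm.SR, mean_hr=60, interval_cv=0.0, respiratory_mod_depth=0.0, seed=1)
        train = generate_beat_train(spec, 60.0)
        assert np.allclose(train.intervals, 1.0)
        assert train.beat_times[0] < 1.0 and train.beat_times[-1] < 60.0

    @pytest.mark.parametrize("cv", [0.05, 0.15, 0.3])
    def test_sr_realized_cv_matches_target(self, cv):
        spec = RhythmSpec(Rhythm.SR, mean_hr=70, interval_cv=cv, seed=3)
        iv = generate_beat_train(spec, 900.0).intervals
        assert iv.std(ddof=1) / iv.mean() == pytest.approx(cv, abs=0.01)

    @pytest.mark.parametrize("cv", [0.15, 0.25])
    def test_af_realized_cv_and_mean(self, cv):
        spec = RhythmSpec(Rhythm.AF, mean_hr=70, interval_cv=cv, premature_burden=0, seed=4)
        iv = generate_beat_train(spec, 900.0).intervals
        assert iv.std(ddof=1) / iv.mean() == pytest.approx(cv, abs=0.015)
        assert iv.mean() == pytest.approx(60.0 / 70, rel=0.03)

    def test_af_rmssd_exceeds_sr_rmssd_across_seeds(self):
        from ringaf.features import rmssd

        for seed in range(20):
            af = generate_beat_train(
                RhythmSpec(Rhythm.AF, mean_hr=70, interval_cv=0.25, premature_burden=0, seed=seed),
                300.0,
            )
            sr = generate_beat_train(
                RhythmSpec(Rhythm.SR, mean_hr=70, interval_cv=0.05, seed=seed), 300.0
            )
            assert rmssd(af.intervals) > rmssd(sr.intervals)

    def test_refractory_floor_always_respected(self):
        spec = RhythmSpec(Rhythm.AF, mean_hr=140, interval_cv=0.25, premature_burden=0, seed=9)
        train = generate_beat_train(spec, 300.0)
        assert train.intervals.min() >= synth.REFRACTORY_S

    def test_infeasible_cv_rejected(self):
        spec = RhythmSpec(Rhythm.AF, mean_hr=200, interval_cv=0.8, premature_burden=0, seed=1)
        with pytest.raises(InfeasibleRhythmError):
            generate_beat_train(spec, 60.0)

    def test_determinism(self):
        spec = RhythmSpec(Rhythm.AF, mean_hr=80, interval_cv=0.2, premature_burden=0, seed=7)
        a = generate_beat_train(spec, 120.0)
        b = generate_beat_train(spec, 120.0)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)


class TestPrematureBeats:
    @pytest.fixture()
    def sinus_train(self):
        return generate_beat_train(
            RhythmSpec(Rhythm.SR, mean_hr=70, interval_cv=0.03, seed=11), 900.0
        )

    def test_zero_burden_is_identity(self, sinus_train):
        out = inject_premature_beats(sinus_train, 0.0, 0.5, seed=1)
        np.testing.assert_array_equal(out.beat_times, sinus_train.beat_times)
        assert not out.is_premature.any()

    def test_insertion_count_within_binomial_bound(self, sinus_train):
        burden = 0.1
        log = synth.PrematureInjectionLog()
        out = inject_premature_beats(sinus_train, burden, 0.5, seed=2, log=log)
        n = log.n_attempted
        expect = n * burden
        sd = np.sqrt(n * burden * (1 - burden))
        assert abs(out.is_premature.sum() + log.n_skipped_refractory - expect) < 3 * sd

    def test_coupling_fraction_exact(self, sinus_train):
        coupling = 0.6
        out = inject_premature_beats(sinus_train, 0.2, coupling, seed=3)
        t = out.beat_times
        prem_idx = np.flatnonzero(out.is_premature)
        assert prem_idx.size > 10
        for i in prem_idx:
            # the spawning sinus beat precedes; its own preceding sinus
            # interval sets the coupling distance
            t_sinus = t[i - 1]
            prev_sinus = t[i - 2] if not out.is_premature[i - 2] else t[i - 3]
            ratio = (t[i] - t_sinus) / (t_sinus - prev_sinus)
            assert ratio == pytest.approx(coupling, abs=1e-9)

    def test_sinus_phase_preserved(self, sinus_train):
        out = inject_premature_beats(sinus_train, 0.3, 0.5, seed=4)
        np.testing.assert_allclose(
            out.beat_times[~out.is_premature], sinus_train.beat_times, atol=1e-12
        )

    def test_refractory_and_order_invariants_hold(self, sinus_train):
        out = inject_premature_beats(sinus_train, 0.5, 0.3, seed=5)
        assert np.all(np.diff(out.beat_times) >= synth.REFRACTORY_S - 1e-9)

    def test_rejects_af_train(self):
        af = generate_beat_train(
            RhythmSpec(Rhythm.AF, mean_hr=70, interval_cv=0.2, premature_burden=0, seed=1), 60.0
        )
        with pytest.raises(ValueError):
            inject_premature_beats(af, 0.1, 0.5, seed=0)


class TestRenderWaveform:
    def test_empty_train_renders_flat_zero(self):
        train = BeatTrain(np.empty(0), np.empty(0, dtype=bool), Rhythm.SR)
        rec = render_waveform(train, fs=50, duration=10.0)
        assert np.all(rec.samples == 0)

    def test_periodic_train_has_autocorr_peak_at_one_second(self):
        times = np.arange(0.5, 29.5, 1.0)
        train = BeatTrain(times, np.zeros(times.size, bool), Rhythm.SR)
        rec = render_waveform(train, fs=50, duration=30.0, amplitude_modulation=False)
        x = rec.samples - rec.samples.mean()
        full = np.correlate(x, x, mode="full")
        r = full[x.size:] / full[x.size - 1]  # r[i] is lag i+1
        # largest positive-lag peak sits at one beat period = 50 samples
        assert int(np.argmax(r[10:200])) + 10 + 1 == 50

    def test_amplitude_tracks_preceding_interval_in_af(self):
        train = generate_beat_train(
            RhythmSpec(Rhythm.AF, mean_hr=75, interval_cv=0.25, premature_burden=0, seed=21), 120.0
        )
        rec = render_waveform(train, fs=50, duration=120.0, amplitude_modulation=True)
        # measure rendered peak height at each beat (amplitudes are clamped,
        # so use Spearman-style positivity via Pearson on the raw pair)
        heights = []
        for tb in train.beat_times[1:-1]:
            c = int(round(tb * 50))
            heights.append(rec.samples[max(c - 3, 0) : c + 4].max())
        r = np.corrcoef(train.intervals[: len(heights)], heights)[0, 1]
        assert r > 0.5

    def test_modulation_off_gives_equal_amplitudes(self):
        amps = synth.pulse_amplitudes(
            BeatTrain(np.array([0.5, 1.2, 2.4]), np.zeros(3, bool), Rhythm.AF), False
        )
        assert np.all(amps == 1.0)


class TestNoiseAndWander:
    def test_infinite_snr_zero_wander_is_identity(self, af_recording):
        out = add_noise_and_wander(af_recording, np.inf, wander_amp=0.0, seed=1)
        np.testing.assert_array_equal(out.samples, af_recording.samples)

    def test_realized_snr_within_1db(self):
        train = generate_beat_train(
            RhythmSpec(Rhythm.SR, mean_hr=70, interval_cv=0.05, seed=2), 300.0
        )
        clean = render_waveform(train, fs=50, duration=300.0)
        noisy = add_noise_and_wander(clean, snr_db=20.0, wander_amp=0.0, seed=3)
        noise = noisy.samples - clean.samples
        realized = 10 * np.log10(np.var(clean.samples) / np.var(noise))
        assert realized == pytest.approx(20.0, abs=1.0)

    def test_bandpass_removes_wander_power(self):
        from ringaf.preprocess import bandpass

        train = generate_beat_train(
            RhythmSpec(Rhythm.SR, mean_hr=70, interval_cv=0.05, seed=4), 300.0
        )
        clean = render_waveform(train, fs=50, duration=300.0)
        wandery = add_noise_and_wander(clean, np.inf, wander_freq=0.1, wander_amp=2.0, seed=5)
        wander = wandery.samples - clean.samples
        filtered = bandpass(wandery.samples, 50.0)
        # compare residual power at the wander component
        before = np.var(wander)
        resid = filtered - bandpass(clean.samples, 50.0)
        assert np.var(resid) <= 0.2 * before


class TestCohort:
    def test_external_validation_style_cohort(self):
        cfg = synth.balanced_cohort(0, 20, seed=42, duration=900.0)
        recs = synth.generate_cohort(cfg)
        assert len(recs) == 20
        assert all(r.label is Rhythm.SR for r in recs)

    def test_same_seed_bitwise_identical(self):
        cfg = synth.balanced_cohort(2, 2, seed=9, duration=60.0)
        a = synth.generate_cohort(cfg)
        b = synth.generate_cohort(cfg)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_balanced_class_counts(self):
        cfg = synth.balanced_cohort(20, 20, seed=1, duration=60.0)
        recs = synth.generate_cohort(cfg)
        labels = [r.label for r in recs]
        assert labels.count(Rhythm.AF) == 20 and labels.count(Rhythm.SR) == 20

    def test_duplicate_subject_rejected(self):
        sub = synth.SubjectSpec("x", (synth.RecordingSpec(Rhythm.SR, 60.0),))
        with pytest.raises(ValueError):
            synth.CohortConfig(subjects=(sub, sub), seed=0)

    def test_recording_roundtrip(self, tmp_path, sr_recording):
        from ringaf.preprocess import read_recording

        path = synth.write_recording(sr_recording, tmp_path / "rec.csv")
        back = read_recording(path)
        np.testing.assert_allclose(back.samples, sr_recording.samples, rtol=1e-6)
        assert back.label is Rhythm.SR
        assert back.subject_id == sr_recording.subject_id
        np.testing.assert_allclose(
            back.truth.beat_times, sr_recording.truth.beat_times, atol=1e-7
        )
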