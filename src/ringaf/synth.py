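"""Synthetic photoplethysmography (PPG) cohort generator.

Builds PPG recordings with the statistical structure an atrial-fibrillation
(AF) screen exploits: sinus rhythm (SR) produces regular beat-to-beat
intervals gently modulated by respiration, optionally interrupted by
premature beats with a compensatory pause; AF produces structureless,
right-skewed interval variability with pulse amplitudes that shrink after
short diastolic filling intervals (pulse deficit).  Waveforms are a
superposition of a stereotyped two-lobe pulse template (systolic +
dicrotic), plus white noise at a requested SNR and sinusoidal baseline
wander.

All generators are pure functions of their seeds: the same spec and seed
always reproduce the same recording, bit for bit.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

REFRACTORY_S = 0.25
"""Physiologic floor on the interval between consecutive beats (seconds)."""


class Rhythm(str, enum.Enum):
    SR = "SR"
    AF = "AF"


class InfeasibleRhythmError(ValueError):
    """The requested interval variability cannot be realized above the
    refractory floor without materially distorting the interval law."""


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one generated rhythm.

    mean_hr is in beats/min; interval_cv is the target coefficient of
    variation of the beat-to-beat intervals; premature_burden is the
    per-beat probability of spawning a premature beat (SR only);
    premature_coupling is the fraction of the preceding sinus interval at
    which the premature beat arrives; respiratory modulation applies to SR
    intervals only.
    """

    rhythm: Rhythm
    mean_hr: float = 70.0
    interval_cv: float = 0.05
    premature_burden: float = 0.0
    premature_coupling: float = 0.6
    respiratory_mod_depth: float = 0.02
    respiratory_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rhythm", Rhythm(self.rhythm))
        if not (30.0 <= self.mean_hr <= 220.0):
            raise ValueError(f"mean_hr {self.mean_hr} outside [30, 220] bpm")
        if self.interval_cv < 0:
            raise ValueError("interval_cv must be >= 0")
        if not (0.0 <= self.premature_burden <= 1.0):
            raise ValueError("premature_burden must be in [0, 1]")
        if self.rhythm is Rhythm.AF and self.premature_burden != 0:
            raise ValueError("premature beats are modeled for SR only")
        if not (0.0 < self.premature_coupling < 1.0):
            raise ValueError("premature_coupling must be in (0, 1)")


@dataclass
class BeatTrain:
    """Ground-truth beat times (seconds from recording start)."""

    beat_times: np.ndarray
    is_premature: np.ndarray
    rhythm: Rhythm

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.is_premature = np.asarray(self.is_premature, dtype=bool)
        if self.beat_times.shape != self.is_premature.shape:
            raise ValueError("beat_times and is_premature must be parallel")
        d = np.diff(self.beat_times)
        if d.size and d.min() < REFRACTORY_S - 1e-9:
            raise ValueError("beat intervals violate the refractory floor")
        if self.rhythm is Rhythm.AF and self.is_premature.any():
            raise ValueError("AF trains carry no premature-beat flags")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)


@dataclass
class SyntheticRecording:
    """A rendered PPG trace with its ground truth."""

    samples: np.ndarray
    fs: float
    duration: float
    truth: BeatTrain
    label: Rhythm
    subject_id: str = "s000"
    recording_id: str = "r000"
    noise_snr_db: float = np.inf
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != round(self.duration * self.fs):
            raise ValueError("sample count does not match duration * fs")
        if self.label != self.truth.rhythm:
            raise ValueError("label must equal truth rhythm")


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_beat_train(
    spec: RhythmSpec, duration: float, *, _max_resample: int = 1000
) -> BeatTrain:
    """Generate ground-truth beat times for ``duration`` seconds.

    SR: intervals are the base interval 60/mean_hr, modulated by a sinusoid
    at the respiratory rate with relative depth ``respiratory_mod_depth``,
    plus zero-mean Gaussian jitter scaled so the realized interval CV
    approaches ``interval_cv``.  AF: intervals are i.i.d. log-normal with
    the requested mean and CV (strictly positive, right-skewed).  Intervals
    falling under the refractory floor are resampled.  Premature beats are
    NOT inserted here; see :func:`inject_premature_beats`.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    m = 60.0 / spec.mean_hr
    cv = spec.interval_cv
    rng = np.random.default_rng(spec.seed)

    # Reject specs whose interval law puts appreciable mass under the
    # refractory floor: resampling would then bias mean and CV.
    from scipy.stats import lognorm, norm

    if spec.rhythm is Rhythm.AF and cv > 0:
        mu, sig = _lognormal_params(m, cv)
        p_floor = float(lognorm.cdf(REFRACTORY_S, sig, scale=np.exp(mu)))
    elif spec.rhythm is Rhythm.SR and cv > 0:
        p_floor = float(norm.cdf(REFRACTORY_S, loc=m, scale=cv * m))
    else:
        p_floor = float(m <= REFRACTORY_S)
    if p_floor > 0.1:
        raise InfeasibleRhythmError(
            f"interval_cv={cv} at mean_hr={spec.mean_hr} puts {p_floor:.0%} of "
            f"intervals under the {REFRACTORY_S}-s refractory floor"
        )

    n_max = int(np.ceil(duration / max(m * (1 - 3 * cv), REFRACTORY_S))) + 8

    if spec.rhythm is Rhythm.AF:
        if cv == 0:
            iv = np.full(n_max, m)
        else:
            mu, sig = _lognormal_params(m, cv)
            iv = rng.lognormal(mu, sig, size=n_max)
            for _ in range(_max_resample):
                bad = iv < REFRACTORY_S
                if not bad.any():
                    break
                iv[bad] = rng.lognormal(mu, sig, size=int(bad.sum()))
        times = np.concatenate([[0.0], np.cumsum(iv)])
    else:
        depth = spec.respiratory_mod_depth
        # respiration and jitter partition the interval variance; a
        # sinusoid of relative depth d contributes CV d/sqrt(2)
        jitter_var = max(cv * cv - depth * depth / 2.0, 0.0) * m * m
        jitter_sd = float(np.sqrt(jitter_var))
        if jitter_sd > 0:
            # left-truncation at the refractory floor shrinks the realized
            # spread; inflate the nominal sd so the truncated variance hits
            # the target
            from scipy.optimize import brentq
            from scipy.stats import truncnorm

            def _var_gap(sd_try: float) -> float:
                a = (REFRACTORY_S - m) / sd_try
                return truncnorm.var(a, np.inf) * sd_try**2 - jitter_var

            if _var_gap(jitter_sd) < 0:
                jitter_sd = float(brentq(_var_gap, jitter_sd, 5 * jitter_sd))
        times = [0.0]
        while times[-1] < duration + m:
            t = times[-1]
            base = m * (1.0 + depth * np.sin(2 * np.pi * spec.respiratory_rate * t))
            iv_i = base + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
            tries = 0
            while iv_i < REFRACTORY_S:
                iv_i = base + rng.normal(0.0, jitter_sd)
                tries += 1
                if tries > _max_resample:
                    raise InfeasibleRhythmError("cannot satisfy refractory floor")
            times.append(t + iv_i)
        times = np.asarray(times)

    times = times[times < duration]
    return BeatTrain(times, np.zeros(times.size, dtype=bool), spec.rhythm)


@dataclass
class PrematureInjectionLog:
    n_attempted: int = 0
    n_inserted: int = 0
    n_skipped_refractory: int = 0


def realized_burden(train: BeatTrain) -> float:
    """Fraction of all beats flagged premature."""
    return 0.0 if train.n_beats == 0 else float(train.is_premature.mean())


def inject_premature_beats(
    train: BeatTrain,
    burden: float,
    coupling: float = 0.6,
    seed: int = 0,
    log: PrematureInjectionLog | None = None,
) -> BeatTrain:
    """Insert premature beats into a sinus train.

    Each eligible sinus beat independently, with probability ``burden``,
    spawns a premature beat at ``coupling`` times the preceding sinus
    interval after it.  The following sinus beat is left where it was, so
    the pause after the premature beat is fully compensatory and the
    underlying sinus phase is preserved.  Insertions that would violate the
    refractory floor on either side are skipped and counted in ``log``.
    """
    if train.rhythm is not Rhythm.SR:
        raise ValueError("premature beats can only be injected into SR trains")
    if not (0.0 <= burden <= 0.5):
        raise ValueError("burden must be in [0, 0.5]")
    if log is None:
        log = PrematureInjectionLog()
    if burden == 0.0 or train.n_beats < 3:
        return BeatTrain(train.beat_times.copy(), train.is_premature.copy(), train.rhythm)

    rng = np.random.default_rng(seed)
    t = train.beat_times
    out_times: list[float] = [float(t[0])]
    out_prem: list[bool] = [False]
    for i in range(1, t.size - 1):
        out_times.append(float(t[i]))
        out_prem.append(False)
        log.n_attempted += 1
        if rng.random() >= burden:
            continue
        prev_iv = t[i] - t[i - 1]
        tp = t[i] + coupling * prev_iv
        if (tp - t[i]) < REFRACTORY_S or (t[i + 1] - tp) < REFRACTORY_S:
            log.n_skipped_refractory += 1
            continue
        out_times.append(float(tp))
        out_prem.append(True)
        log.n_inserted += 1
    out_times.append(float(t[-1]))
    out_prem.append(False)
    return BeatTrain(np.asarray(out_times), np.asarray(out_prem), Rhythm.SR)


# -- waveform rendering ------------------------------------------------------

_SYS_WIDTH = 0.055   # Gaussian sigma of the systolic lobe (s); ~0.25 s bump
_DIC_WIDTH = 0.070   # dicrotic lobe sigma (s)
_DIC_DELAY = 0.25    # dicrotic delay after the systolic peak (s)
_DIC_AMP = 0.35      # dicrotic amplitude relative to systolic
_AMP_CLAMP = (0.4, 1.2)  # pulse-deficit clamp, fraction of nominal amplitude
_TEMPLATE_HALF_S = 0.8   # support of one pulse template on either side (s)


def _pulse_template(trel: np.ndarray) -> np.ndarray:
    sys_lobe = np.exp(-0.5 * (trel / _SYS_WIDTH) ** 2)
    dic_lobe = _DIC_AMP * np.exp(-0.5 * ((trel - _DIC_DELAY) / _DIC_WIDTH) ** 2)
    return sys_lobe + dic_lobe


def pulse_amplitudes(train: BeatTrain, amplitude_modulation: bool) -> np.ndarray:
    """Per-beat pulse amplitude; linear in the preceding interval (pulse
    deficit) when modulation is on, clamped to [0.4, 1.2] of nominal."""
    n = train.n_beats
    if not amplitude_modulation or n < 2:
        return np.ones(n)
    iv = train.intervals
    ref = float(np.median(iv)) if iv.size else 1.0
    amps = np.ones(n)
    amps[1:] = np.clip(iv / ref, *_AMP_CLAMP)
    return amps


def render_waveform(
    train: BeatTrain,
    fs: float,
    duration: float,
    amplitude_modulation: bool = True,
    *,
    subject_id: str = "s000",
    recording_id: str = "r000",
) -> SyntheticRecording:
    """Render a noise-free PPG waveform from a beat train.

    Each beat contributes a two-lobe pulse template (systolic + delayed
    dicrotic) centered at the beat time; contributions superpose
    additively.  With ``amplitude_modulation`` on, pulse height scales
    with the preceding interval, emulating the AF pulse deficit.
    """
    if fs < 25:
        raise ValueError("fs must be >= 25 Hz")
    n = round(duration * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    amps = pulse_amplitudes(train, amplitude_modulation)
    half = int(np.ceil(_TEMPLATE_HALF_S * fs))
    for tb, a in zip(train.beat_times, amps):
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if lo >= hi:
            continue
        x[lo:hi] += a * _pulse_template(t[lo:hi] - tb)
    return SyntheticRecording(
        samples=x,
        fs=fs,
        duration=float(duration),
        truth=train,
        label=train.rhythm,
        subject_id=subject_id,
        recording_id=recording_id,
        noise_snr_db=np.inf,
    )


def add_noise_and_wander(
    rec: SyntheticRecording,
    snr_db: float = np.inf,
    wander_freq: float = 0.1,
    wander_amp: float = 0.0,
    seed: int = 0,
) -> SyntheticRecording:
    """Add zero-mean white noise at the requested SNR plus sinusoidal
    baseline wander.  ``snr_db`` is the power ratio of the clean signal
    (about its mean) to the noise; infinite SNR adds no noise."""
    x = rec.samples.copy()
    rng = np.random.default_rng(seed)
    if np.isfinite(snr_db):
        p_sig = float(np.var(x))
        p_noise = p_sig / (10.0 ** (snr_db / 10.0))
        x = x + rng.normal(0.0, np.sqrt(p_noise), size=x.size)
    if wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(x.size) / rec.fs
        x = x + wander_amp * np.sin(2 * np.pi * wander_freq * t + phase)
    out = dataclasses.replace(rec, samples=x, noise_snr_db=float(snr_db))
    return out


# -- cohorts -----------------------------------------------------------------


@dataclass(frozen=True)
class RecordingSpec:
    """One recording to synthesize for a subject."""

    rhythm: Rhythm
    duration: float = 900.0
    fs: float = 50.0
    mean_hr: float | None = None       # None: drawn per subject
    interval_cv: float | None = None   # None: rhythm default (SR .05 / AF .25)
    premature_burden: float = 0.0
    premature_coupling: float = 0.6
    snr_db: float = 20.0
    wander_freq: float = 0.1
    wander_amp: float = 0.1
    amplitude_modulation: bool = True


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    recordings: tuple[RecordingSpec, ...]


@dataclass(frozen=True)
class CohortConfig:
    subjects: tuple[SubjectSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort config")


_DEFAULT_CV = {Rhythm.SR: 0.05, Rhythm.AF: 0.25}


def derive_seed(global_seed: int, *key: int) -> int:
    """Stable per-recording seed from the global seed and index key."""
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def synthesize_recording(
    spec: RecordingSpec,
    seed: int,
    subject_id: str = "s000",
    recording_id: str = "r000",
) -> SyntheticRecording:
    """Full pipeline for one recording: beat train -> premature beats ->
    waveform -> noise + wander; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    mean_hr = spec.mean_hr if spec.mean_hr is not None else float(rng.uniform(55, 95))
    cv = spec.interval_cv if spec.interval_cv is not None else _DEFAULT_CV[Rhythm(spec.rhythm)]
    rspec = RhythmSpec(
        rhythm=Rhythm(spec.rhythm),
        mean_hr=mean_hr,
        interval_cv=cv,
        premature_coupling=spec.premature_coupling,
        seed=derive_seed(seed, 1),
    )
    train = generate_beat_train(rspec, spec.duration)
    if rspec.rhythm is Rhythm.SR and spec.premature_burden > 0:
        train = inject_premature_beats(
            train, spec.premature_burden, spec.premature_coupling, seed=derive_seed(seed, 2)
        )
    rec = render_waveform(
        train,
        spec.fs,
        spec.duration,
        spec.amplitude_modulation,
        subject_id=subject_id,
        recording_id=recording_id,
    )
    rec = add_noise_and_wander(
        rec, spec.snr_db, spec.wander_freq, spec.wander_amp, seed=derive_seed(seed, 3)
    )
    rec.generator_params = {
        "mean_hr": mean_hr,
        "interval_cv": cv,
        "premature_burden": spec.premature_burden,
        "premature_coupling": spec.premature_coupling,
        "snr_db": spec.snr_db,
        "wander_freq": spec.wander_freq,
        "wander_amp": spec.wander_amp,
        "amplitude_modulation": spec.amplitude_modulation,
        "seed": seed,
    }
    return rec


def resolvable_recording(
    spec: RecordingSpec,
    seed: int,
    min_interval_s: float = 0.31,
    max_tries: int = 50,
    subject_id: str = "s000",
    recording_id: str = "r000",
) -> SyntheticRecording:
    """Synthesize a recording whose truth train has no interval below
    ``min_interval_s``, redrawing with derived seeds until it does.

    Peak-recovery studies need this: a detector with a 0.3-s refractory
    cannot, by construction, resolve two beats closer than that, so beat
    trains for such studies must respect the detector's resolution limit.
    Deterministic given ``seed``.
    """
    for k in range(max_tries):
        rec = synthesize_recording(
            spec, derive_seed(seed, k), subject_id=subject_id, recording_id=recording_id
        )
        iv = rec.truth.intervals
        if iv.size == 0 or iv.min() >= min_interval_s:
            return rec
    raise InfeasibleRhythmError(
        f"could not realize min interval {min_interval_s}s in {max_tries} draws"
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticRecording]:
    """Synthesize every recording in the cohort.  Per-recording seeds are
    derived deterministically from the global seed and the (subject,
    recording) index, so the cohort is reproducible as a whole and each
    recording is reproducible in isolation."""
    out: list[SyntheticRecording] = []
    for si, subj in enumerate(config.subjects):
        for ri, rspec in enumerate(subj.recordings):
            seed = derive_seed(config.seed, si, ri)
            out.append(
                synthesize_recording(
                    rspec, seed, subject_id=subj.subject_id, recording_id=f"{subj.subject_id}_r{ri:02d}"
                )
            )
    return out


def balanced_cohort(
    n_af: int,
    n_sr: int,
    seed: int,
    duration: float = 900.0,
    fs: float = 50.0,
    sr_interval_cv: float = 0.05,
    af_interval_cv: float = 0.25,
    sr_premature_burden_max: float = 0.1,
    snr_db: float = 20.0,
) -> CohortConfig:
    """Convenience cohort: ``n_af`` AF subjects and ``n_sr`` SR subjects,
    one recording each; SR subjects get a premature-beat burden drawn
    uniformly in [0, sr_premature_burden_max]."""
    rng = np.random.default_rng(derive_seed(seed, 999))
    subjects = []
    for i in range(n_af):
        subjects.append(
            SubjectSpec(
                f"af{i:03d}",
                (RecordingSpec(Rhythm.AF, duration, fs, interval_cv=af_interval_cv, snr_db=snr_db),),
            )
        )
    for i in range(n_sr):
        burden = float(rng.uniform(0.0, sr_premature_burden_max))
        subjects.append(
            SubjectSpec(
                f"sr{i:03d}",
                (
                    RecordingSpec(
                        Rhythm.SR,
                        duration,
                        fs,
                        interval_cv=sr_interval_cv,
                        premature_burden=burden,
                        snr_db=snr_db,
                    ),
                ),
            )
        )
    return CohortConfig(subjects=tuple(subjects), seed=seed)


# -- disk format -------------------------------------------------------------


def write_recording(rec: SyntheticRecording, path: str | Path) -> Path:
    """Write a recording as two-column CSV (time_s, amplitude) plus a JSON
    sidecar carrying label, ground truth, and generator parameters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.samples.size) / rec.fs
    header = "time_s,amplitude"
    body = np.column_stack([t, rec.samples])
    np.savetxt(path, body, delimiter=",", header=header, comments="", fmt="%.9g")
    sidecar = {
        "subject_id": rec.subject_id,
        "recording_id": rec.recording_id,
        "fs": rec.fs,
        "duration": rec.duration,
        "label": rec.label.value,
        "noise_snr_db": None if np.isinf(rec.noise_snr_db) else rec.noise_snr_db,
        "beat_times": rec.truth.beat_times.tolist(),
        "is_premature": rec.truth.is_premature.astype(int).tolist(),
        "generator_params": rec.generator_params,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


def write_cohort(recs: Sequence[SyntheticRecording], out_dir: str | Path) -> Path:
    """Write every recording plus a cohort manifest JSON; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recs:
        fname = f"{rec.recording_id}.csv"
        write_recording(rec, out_dir / fname)
        entries.append(
            {"subject_id": rec.subject_id, "recording_id": rec.recording_id,
             "label": rec.label.value, "file": fname}
        )
    manifest = out_dir / "cohort.json"
    manifest.write_text(json.dumps({"recordings": entries}))
    return manifest
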