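# Methods

## Problem and scope

`ringaf` implements an end-to-end pipeline for screening atrial
fibrillation (AF) from single-channel photoplethysmography (PPG), the
optical pulse signal a ring- or watch-type wearable records. AF produces
"irregularly irregular" pulse intervals and beat-to-beat amplitude
variation (pulse deficit); sinus rhythm (SR) produces regular intervals
gently modulated by respiration, occasionally interrupted by premature
atrial or ventricular beats that mimic AF irregularity locally. The
package covers: synthetic cohort generation, preprocessing and windowed
segmentation, pulse-peak detection and rhythm statistics, two classifier
families (linear SVM on hand-crafted features; a 1-D CNN on raw
segments) with temperature-calibrated confidence, and a subject-level
diagnostic-evaluation protocol (repeated five-fold cross-validation,
diagnostic ratios, ROC/AUC with bootstrap CI, sample-length and
stratified analyses, confidence-threshold filtering, repeated external
validation).

Because no clinical recordings ship with the package, every claim the
test suite makes is a claim about synthetic data. The generator is
first-class, tested code, and its defaults define the study conditions
under which the pipeline is validated.

## Synthetic PPG model

**Beat trains.** SR intervals are `60/mean_hr` seconds, modulated by a
sinusoid at the respiratory rate (default 0.25 Hz) with relative depth
0.02, plus zero-mean Gaussian jitter. The jitter standard deviation is
chosen so the realized interval coefficient of variation (CV) matches
the requested target; because intervals are resampled when they fall
under the 0.25-s refractory floor, the nominal jitter sd is inflated by
a truncated-normal variance correction so the *post-truncation* CV still
hits the target (verified to ±0.01 at 900 s for CV ≤ 0.3). AF intervals
are i.i.d. log-normal with the requested mean and CV — strictly
positive, right-skewed, and structureless, which is the statistical
signature the classifiers exploit. Specs whose interval law would put
more than 10% of its mass under the refractory floor are rejected as
infeasible rather than silently distorted.

**Premature beats (SR only).** Each eligible sinus beat spawns, with
probability equal to the burden, a premature beat at a fixed coupling
fraction (default 0.5–0.6) of the preceding sinus interval, followed by
a fully compensatory pause (the next sinus beat is not displaced).
Insertions that would violate the refractory floor on either side are
skipped and counted.

**Waveform.** Each beat contributes a stereotyped two-lobe pulse: a
systolic Gaussian lobe (σ = 55 ms, ≈0.25-s bump) plus a dicrotic lobe
at +0.25 s with 0.35 relative amplitude and σ = 70 ms, superposed
additively. With amplitude modulation on, pulse height scales linearly
with the preceding interval relative to the train median, clamped to
[0.4, 1.2] — short diastolic filling gives small pulses, emulating the
AF pulse deficit and giving the CNN a morphology cue beyond timing.
White Gaussian noise is added at a requested SNR (power ratio against
the clean signal), plus a sinusoidal baseline wander (default 0.1 Hz).

**What the generator does not model:** motion artifacts with structured
spectra, optical/hemodynamic coupling, skin-contact dropout, other
atrial tachyarrhythmias, and ectopy patterns beyond single premature
beats with compensatory pauses. Passing tests therefore demonstrate
correctness of the pipeline and separability under these idealized
conditions, not clinical performance.

**Determinism.** Every stochastic step takes a seed; per-recording seeds
derive from the global cohort seed and the (subject, recording) index via
`numpy.random.SeedSequence` spawn keys, so cohorts are bitwise
reproducible as a whole and per recording.

## Preprocessing

The pipeline order is fixed: band-pass filter → resample to 50 Hz →
segment. The filter is a 4th-order Butterworth band-pass (0.2–18 Hz)
applied forward-backward (zero phase), so pulse peaks are not shifted.
Resampling is band-limited polyphase interpolation with an identity
fast-path at 50 Hz. Segmentation slices 30-s windows with 20-s overlap
(stride 10 s); a window is emitted iff its end falls strictly before the
recording end, with a half-sample-period epsilon guarding the strict
inequality against floating rounding. A 900-s recording yields 87
windows; a recording exactly one window long yields that single window.
Shorter samples (25/20/15/10/5 s) are prefixes of each 30-s window, so
every length has identical segment counts and provenance. Labels are
inherited from recording-level ground truth, never recomputed.

## Peak detection and rhythm features

Peaks are local maxima of a lightly smoothed (0.1-s moving average)
band-passed segment that exceed an adaptive threshold — 0.3 times a
rolling 90th percentile of amplitude over 2-s windows — with a 0.3-s
refractory in which the larger peak wins, and a 0.2-s edge guard where
pulses are truncated mid-template. The threshold scale is set low enough
to keep amplitude-modulated (pulse-deficit) beats and high enough to
reject broadband noise bumps. The 0.3-s refractory is the detector's
resolution limit: two true beats closer than that are merged by
construction, so peak-recovery studies generate beat trains whose
intervals stay ≥0.31 s (`resolvable_recording`). Under that condition
recovery is exact (±40 ms) on clean signals and ≥99% at 20 dB SNR.

Features per segment: RMSSD of the peak-to-peak intervals; normalized
Shannon entropy of the interval histogram (16 equal-width bins over the
window's own [min, max], natural log, normalized by ln 16, so the value
lies in [0, 1] and all-equal intervals give 0); interval CV (sample sd,
n−1, over mean); pulse rate (60 / mean interval); and the normalized
autocorrelation of the mean-removed waveform at lags 1–150 samples
(0.02–3.0 s at 50 Hz). Segments with too few peaks raise an
undefined-feature signal and are excluded from the SVM arms (logged and
counted) but remain available to the CNN.

## Classifiers

**SVM arms.** Linear-kernel SVMs on three feature sets: (RMSSD, ShE);
the 150-lag autocorrelation vector; and their 152-dim concatenation
(ensemble). Features are standardized with training-set statistics only;
probabilities come from a logistic link fitted on the training decision
scores (Platt scaling), which also provides the continuous score for ROC
analysis.

**CNN.** Nine weight layers: seven 1-D convolutions (kernel width 7,
channels 8→8→16→16→32→32→64, stride-2 downsampling after every second
convolution, ReLU), global average pooling, and two fully connected
layers (64→32→2) with dropout 0.5 on the hidden layer. Global average
pooling lets one architecture serve every input length from 5-s to 30-s
segments. Training is Adam with softmax cross-entropy, L2 penalty 1e-4
on all weight matrices, in float32, fully deterministic given the seed.
The implementation is pure numpy (per-tap matmul convolutions with
hand-written backpropagation), verified against numerical gradients.
The first epoch warms up at 0.3x the learning rate and the rate steps
down by 0.3x over the final 30% of epochs, which stabilizes early and
late training. Rarely, an unlucky initialization leaves the network
dead (training loss pinned at the chance level ln 2); this is detected
from the training loss alone and training restarts with a
deterministically derived seed (up to three restarts), keeping the
whole procedure a pure function of the original seed. Defaults are 50 epochs, batch 64,
learning rate 1e-3; the benchmark harness uses a scaled schedule
(12 epochs, batch 32, learning rate 3e-3) that converges on the
strongly separated synthetic contrast.

**Calibration.** After training, a single temperature T > 0 is fitted on
a held-out, subject-disjoint calibration split (20% of training
subjects) by minimizing the negative log-likelihood of
softmax(logits/T); the search is a bounded one-dimensional minimization
over log T in [ln 0.05, ln 20], falling back to T = 1 on failure.
Dividing logits by a positive scalar never changes the argmax, so
calibration alters confidence only, never the predicted label. The
predicted class is the one with higher calibrated confidence; an exact
tie (p = 0.5) is called AF, favoring sensitivity in a screening setting.
Confidence filtering keeps predictions whose confidence strictly exceeds
the threshold.

## Evaluation protocol

Units (subjects by default, samples for the leakage-contrast analysis)
are shuffled by seed and dealt into five near-equal folds; each fold
serves once as the test set and training repeats with distinct derived
seeds — 5 × 10 = 50 validation processes at full scale, 5 × 2 = 10 in
the scaled benchmark. Subject mode guarantees no subject contributes
segments to both sides of any split; this is re-checked on every process
and a violation raises an error. Metrics use AF as the positive class:
accuracy, sensitivity, specificity, PPV, NPV from confusion counts, with
undefined cells (e.g. sensitivity on an all-SR cohort) reported as
absent, never as 0 or 1. AUC is the Mann–Whitney probability that a
random AF score exceeds a random SR score (ties half), with a stratified
bootstrap CI (2,000 resamples, seeded). Report aggregates are arithmetic
means over processes.

Derived studies: the sample-length study re-runs the same fold plan on
truncated segments (one model per length); decile stratifications
compute quantile boundaries of interval CV or pulse rate *within* each
true class (sensitivity deciles over AF samples, specificity deciles
over SR samples); the premature-burden study bins SR segments by their
true premature fraction (0, ≤0.05, ≤0.10, ≤0.20, >0.20) and compares
specificity under subject- vs sample-randomized folds; the threshold
sweep reports retained-set metrics and the filtered fraction over a
confidence grid; external validation evaluates an all-SR cohort
repeatedly (10 times), counting every run as a test case; and a t-SNE
embedding of the CNN's penultimate activations supports visualization of
the learned feature space.

## Benchmark conditions and problem sizes

The standard benchmark (`ringaf.benchmark`) is 40 subjects — 20 AF
(interval CV 0.25) and 20 SR (interval CV 0.05, premature burden drawn
uniformly in [0, 0.1]) — one 900-s recording each at 50 Hz and 20 dB
SNR with amplitude modulation on: 3,480 30-s segments. Cross-validation
uses 5 folds × 2 repeats. The peak-recovery study uses 100 30-s
segments from ten 130-s recordings (alternating SR with 8% premature
burden and AF), clean and at 20 dB. The sample-length study uses the
feature-ensemble arm with one repeat per fold. These sizes keep a
complete run on a single CPU in the tens of minutes while leaving
hundreds of segments per test fold.

## Numerical choices and edge cases

- Strict-end segmentation epsilon: half a sample period.
- Histogram right edge: the maximum interval belongs to the last bin.
- Zero-variance segments yield a zero autocorrelation vector with a
  warning; flat segments yield an empty peak series.
- SVM arms require both classes in training and fail loudly otherwise;
  the CNN aborts on non-finite loss with the offending configuration in
  the message.
- Temperature fitting requires ≥50 calibration samples of both classes.
- Bootstrap and t-SNE are seeded; CNN dropout draws from the model's
  own seeded generator, so identical configs reproduce identical
  predictions bit for bit.

## Known limitations

- The synthetic interval laws are stand-ins, not estimates of any
  clinical population; absolute accuracies on the benchmark say nothing
  about accuracy on real patients.
- The premature-beat model uses a fixed coupling fraction and full
  compensatory pause; interpolated (non-compensatory) ectopy and bigeminy
  are not modeled.
- The detector's 0.3-s refractory caps resolvable pulse rates around
  200/min; very short AF intervals merge into single detections, which
  slightly deflates measured variability at extreme rates.
- Sample-mode cross-validation deliberately leaks subjects (that is the
  point of the contrast with subject mode) and must not be used for
  performance claims.
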