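# Methods

This note documents the models, conventions, and design choices behind
`advoice`, in the spirit of the methods documentation of mature scientific
Python packages: what is computed, under which assumptions, with which
defaults, and what the validation on synthetic data does and does not show.

## Analysis unit and preprocessing

The unit of analysis is the **speech block**: a 10-s window of a subject's
concatenated speech, advanced in 5-s steps (`block_length_s`, `block_hop_s`).
Trailing partial windows are dropped rather than zero-padded so every block
carries equal support for its spectral statistics; a signal of duration T
therefore yields `floor((T − 10)/5) + 1` blocks. Overlapping annotation
intervals are merged by interval union before concatenation (manual
segmentation can produce touching or overlapping spans; the union is
order-independent).

Noise handling mirrors a protocol in which each site's background differs:
all noise-only audio in the cohort is cut into 1-s chunks (`noise_chunk_s`),
shuffled under the run seed, concatenated, and added (tiled, default
`noise_gain = 1.0`) to every subject's concatenated speech. The gain and
chunk length are configurable because no canonical values exist for this
remixing step; level-matching per file is deliberately not performed.
Stereo input is averaged to mono; sample rates other than 44.1 kHz are
accepted and logged but never resampled — all analysis is rate-aware, and
silent resampling would alter spectra.

## Frame grid and features

All per-frame measures share one grid: frame 2048 samples, hop 512, Hann
window at 44.1 kHz (≈46.4 ms / 11.6 ms). These are the customary defaults of
the speech-analysis toolkit family for spectral work at this rate, and are
configurable (`FrameGrid`).

**Spectral moments.** The per-frame power spectrum (squared rfft magnitude)
with the DC bin excluded is normalized to a probability mass p_k over bin
frequencies f_k. Center of gravity c = Σ f_k p_k, spectral SD
σ = sqrt(Σ (f_k − c)² p_k), skewness Σ((f_k − c)/σ)³ p_k, and **Pearson
(non-excess) kurtosis** Σ((f_k − c)/σ)⁴ p_k — the established convention for
spectral shape moments, deliberately distinct from the excess convention used
for the distributional summaries below. Power weighting is the default
("center of gravity" is conventionally power-weighted); magnitude weighting
is available (`weighting="magnitude"`). A frame with zero power contributes
nothing; zero spread leaves shape moments undefined. Across the frames of a
block the aggregation is mean and population SD of centroid / skewness /
kurtosis plus the mean spectral SD (7 values); frames with undefined moments
are excluded statistic-by-statistic. Whether such aggregation should run over
frames within a block or blocks within a subject is genuinely ambiguous in
this analysis family; frames-within-block is chosen because the feature
vector is defined per block.

**Intensity** is per-frame RMS amplitude on a linear scale with a
rectangular window (so a constant-amplitude signal measures exactly its
amplitude).

**Fundamental frequency.** A normalized-autocorrelation tracker: for each
frame the mean-removed autocorrelation, normalized by the geometric mean of
head/tail energies, is searched for local maxima over lags in
[1/`fmax`, 1/`fmin`] (default 50–400 Hz, comfortably covering elderly
conversational pitch). Candidates below the voicing threshold 0.45 are
ignored; frames whose RMS falls under the silence floor (1e-4) are unvoiced.
Candidates are scored with an octave cost of 0.05 per octave of lag: the
autocorrelation of a periodic signal is near-unity at every multiple of the
true period, so without a lag penalty, noise decides between the period and
its double; 0.05 is large against that noise yet far below the contrast
between a true period and a spurious candidate. The winning lag is refined
by parabolic interpolation. A final temporal-continuity pass re-marks as
unvoiced any frame deviating more than 30% from the 5-frame running median —
isolated period-doubling slips (typically at segment-concatenation seams,
where the phase is discontinuous) otherwise contaminate extreme-value
statistics such as the block minimum, while genuine pitch trajectories
(jitter ~1%, vibrato) pass untouched.

**Delta series** are consecutive first differences of the per-frame values.
For F0, differences are taken between consecutive *voiced* frames only, so a
silence never manufactures a jump. When fewer than `min_voiced_frames = 10`
frames are voiced, the 18 F0/ΔF0 slots are missing rather than imputed.

**Distributional summary.** Every series is reduced to mean, median,
minimum, maximum, 15th and 85th percentile (linear interpolation),
population SD (divisor n), moment skewness g1, and **excess kurtosis** g2 —
the defaults of the numerical stack this analysis family builds on. Zero SD
leaves the shape statistics missing.

Feature count: 7 + 9 + 9 + 9 + 9 = 43 named slots per block, always present
in the table (missing as empty cells, never dropped columns).

## Screening

Per feature, a **Welch** unequal-variance two-sided t-test (rather than the
pooled-variance test: safer under unequal group spreads, asymptotically
identical otherwise) between patient and healthy rows, at α = 0.05, with no
multiple-testing correction by default — the screening convention is 43 raw
tests; a Benjamini–Hochberg column is available (`bh=True`). The default
unit is block rows, matching the classification stage; `per_subject=True`
aggregates blocks to subject means first. Block-level testing treats
overlapping blocks as independent and therefore inflates effective n; both
modes are provided and reported, and the calibration analysis below uses the
per-subject mode for exactly this reason.

## Classifier evaluation

Each significant feature is evaluated alone: standardized with
training-fold statistics, then fed to L2-regularized logistic regression,
an RBF-kernel soft-margin SVM (library-default regularization), and a
100-tree random forest — all at library defaults, with **no hyperparameter
search** (the point is feature triage, not model building). Folds are
stratified fivefold partitions of the pooled block rows by default;
`group_by_subject=True` keeps all blocks of a subject in one fold,
preventing subject leakage, and is the mode to prefer when blocks per
subject are many. Scores are patient-class probability (LR), signed decision
value (SVM), and the tree-vote fraction (RF; with fully grown trees the
library's averaged leaf probabilities equal the vote fraction). AUC is the
Mann–Whitney statistic with ties counted one-half; ROC curves come from a
full threshold sweep, so the trapezoidal area under the stored points equals
the reported AUC to numerical precision. Fold summaries use the population
SD over the five fold values.

## Synthetic cohort

The generator emulates the *measurement situation*, not speech content: a
subject is a glottal-style pulse train whose period random-walks with an
Ornstein–Uhlenbeck perturbation (jitter, relative SD 0.01, correlation time
0.5 s) and whose per-cycle amplitude is modulated (shimmer, relative SD
0.03), spectrally shaped by a piecewise log-linear envelope — flat below
100 Hz, then `slope_low` dB/octave up to a knee, then `slope_high` beyond —
alternating speech segments (mean 3 s) with pauses (mean 0.8 s), over a
ventilation-like 1/f background at 30 dB SNR, with speech RMS normalized to
0.05 (the amplitude scale typical of distant-microphone conversational
recordings).

The class contrast is carried by the envelope: **patient** −6 dB/octave
throughout (a gentle, featureless roll-off); **healthy** −3 dB/octave up to
6 kHz, then −24 dB/octave (slow roll-off with a sharp high-band knee).
These slopes make the qualitative contrast concrete and configurable; they
are not fitted to any recording. Group sizes default to 83 patients / 75
controls with sex ratios 50/83 and 47/75 female so demographic columns exist
for report parity, though no demographic effects are injected. Between-
subject scatter defaults are small (F0 SD 4 Hz, slope SD 0.25 dB/oct, knee
SD 200 Hz): the generator's purpose is pipeline validation under controlled
ground truth, and large speaker-level heterogeneity would only blur the
known effects (see Limitations).

Because the source is a flat-spectrum pulse train, the power at harmonic k
is the envelope evaluated at k·F0 — so the generator predicts analytically
what the extractor should measure. `envelope_power_moments(params, f0=...)`
computes the centroid/SD/skewness/kurtosis of the harmonic comb; the test
suite requires the measured per-block centroid to agree with this prediction
within 15% (the residual comes from window leakage, jitter broadening, and
the background floor) and, in particular, to order the classes the same way:
the patient centroid sits *below* the healthy one, since the gentle slope
removes more mid-band energy than the healthy slow-then-steep envelope.

Per-subject RNG streams are spawned from (master seed, subject index), so
cohorts are bit-reproducible and any subject can be regenerated alone.

## Calibration protocol

The null configuration (`null_cohort_spec`) gives both groups one identical
profile with **zero** between-subject scatter and a single sex, 120-s
recordings. Group labels are then pure noise: any systematic downstream
signal is a calibration failure. Two checks run on this cohort:

- **Type-I rate.** Subject labels are permuted 200 times and the screening
  rerun in per-subject mode; the fraction of (replicate, feature) pairs
  significant at α = 0.05 must sit near 5%. Per-subject mode is used because
  overlapping blocks violate the independence the block-level t-test
  assumes — block-level testing is anti-conservative by construction, which
  is a property of the design, not an implementation defect.
- **AUC band.** Every feature × classifier mean AUC must stay within
  [0.35, 0.65]. Zero scatter matters here: with subject-level heterogeneity,
  a feature can separate two *particular* 10-subject groups by chance alone
  at block level, which tests the cohort draw rather than the pipeline.

## Numerical choices and degenerate inputs

- WAV I/O is 16-bit PCM; writing scales by 32768 with clipping at the int16
  maximum, so a round-trip errs by at most 2⁻¹⁵ even at +1.0. Out-of-range
  amplitudes are clipped with a warning.
- Missing values are propagated, never imputed: degenerate summaries (zero
  SD), unvoiced blocks, and failed tests yield missing cells with reasons
  where applicable; downstream stages drop missing rows per feature.
- Shuffling, fold assignment, classifier seeding, and synthesis all consume
  explicit seeds; identical inputs and seeds give byte-identical artifacts
  (the run cache relies on this, keyed by input checksum plus extraction
  parameters).
- Validation problem sizes — 10 + 10 subjects at 60 s for parameter
  recovery, 20 subjects at 120 s for calibration, 200 permutations — are
  chosen so the whole suite exercises every stage at full signal fidelity
  while remaining comfortable to run routinely on a single CPU.

## Limitations

- The generator contains no phonetics: no formants, no consonants, no
  lexical or prosodic content, no channel/room variation. Passing its checks
  demonstrates that the pipeline measures what it claims on signals with
  known structure — not that the features discriminate clinical groups, and
  not robustness to reverberation, compression, or microphone diversity.
- Between-subject scatter in the default profiles is deliberately small;
  real cohorts have large speaker-level heterogeneity, under which
  block-level cross-validation optimistically estimates subject-level
  generalization. The subject-grouped fold mode exists precisely for that
  analysis and should be preferred on real data.
- The autocorrelation tracker is adequate for quasi-periodic synthetic
  sources and clean conversational speech in the 50–400 Hz band; creaky or
  diplophonic voices would need a dedicated tracker.
- Voice-activity detection is out of scope: segment annotations are taken
  as given (the supported protocol annotates manually).
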