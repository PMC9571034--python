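# Methods

`epichannel` implements a channel-level pipeline for interictal EEG:
classify individual longitudinal-bipolar (LB) channels as epileptic or
normal with a small BiLSTM sequence network, then diagnose a population's
epilepsy *type* (focal vs generalized) from the across-channel variance of
per-channel detection rates.  This note records the models, conventions
and design choices, and what the synthetic experiments do and do not show.

## Signal model and montage

Input is referential EEG from the 16 lateral electrodes of the 10–20
system (Fp1, Fp2, F3, F4, F7, F8, C3, C4, P3, P4, T3, T4, T5, T6, O1,
O2) sampled at 500 Hz in 10 s windows.  The LB ("double banana") montage
derives 16 bipolar channels along four anterior–posterior chains; each
channel is anode minus cathode with the anterior electrode as anode
(Fp1-F7, F7-T3, …, P4-O2; midline leads Fz/Cz/Pz are excluded).  Because
every channel is a difference of two referential traces, any common
reference signal cancels algebraically; no explicit reference bookkeeping
is needed or attempted.  Useful exact identities, used as test oracles:
the montage is linear in the input, invariant to adding a common signal
to all electrodes, and each chain telescopes (the four channels of a
chain sum to first-minus-last electrode).

## Denoising

Each LB channel is denoised with a 3-level discrete wavelet transform
using `coif3`.  Two strategies are provided because the literature
practice of "removing line noise by three decomposition levels" admits
two readings:

* `approximation_only` — zero all detail coefficients and reconstruct
  from the level-3 approximation.  At 500 Hz this keeps roughly 0–31 Hz,
  which removes 50 Hz mains cleanly but also removes the gamma band.
* `soft_threshold` (default) — soft-shrink detail coefficients at each
  level with the universal threshold σ√(2 ln n), σ estimated per level
  as median(|d|)/0.6745.  This attenuates broadband noise while keeping
  genuine high-frequency content, so gamma-band power computed later
  remains meaningful.  The default is `soft_threshold` precisely because
  the feature set includes gamma power (>30 Hz), which the
  approximation-only reading would annihilate.

Boundary handling defaults to symmetric extension.  One numerical
caveat: with symmetric extension the zero-detail reconstruction is not
an orthogonal projection, so `approximation_only` is only approximately
idempotent near the edges (re-application drift ~1e−3 at boundaries).
Under `extension_mode="periodization"` the transform is orthogonal and
the operation is an exact projection (idempotent to <1e−10, energy
non-increasing); the idempotence property test therefore runs under
periodization, and the mode is recorded in every run config.

## Segmentation and features

Channels are cut into 1 s windows with 50% overlap; with hop =
round(w·(1−overlap)) and trailing partial windows discarded, a 10 s
channel yields exactly 19 segments.  From each segment fifteen features
are computed:

* time domain: mean, standard deviation (n−1), peak-to-peak, min, max,
  skewness, kurtosis, crest factor ("P2RMS": max|x|/RMS), root sum of
  squares, RMS;
* frequency domain: band power in delta (1–4 Hz), theta (4–8), alpha
  (8–14), beta (14–30) and gamma (30–100 Hz).

Conventions, fixed so tests are unambiguous: skewness and kurtosis use
biased central-moment estimators with non-excess kurtosis (Gaussian ≈ 3),
the convention of the common numerical environments in this field; both
are undefined on constant segments and
propagate as NaN, never silently zero.  RMS is included to complete the
named set of fourteen to fifteen (it is needed by the crest factor in
any case).  Band powers integrate a single Hamming-windowed periodogram
(density scaling) over half-open bins [f_lo, f_hi), so contiguous bands
add exactly; 500-sample segments are too short for Welch sub-averaging.
Gamma's upper edge is fixed at 100 Hz since "above 30 Hz" is otherwise
unbounded.  Band powers are computed on denoised segments by default
(configurable), consistent with denoise-then-extract ordering.

## Feature screening

Screening runs on the pooled per-segment table (rows over subjects,
channels and segments).  Two statistics are computed: the full pairwise
Pearson correlation matrix with two-sided p-values from
t = r√((n−2)/(1−r²)), and each feature's point-biserial correlation with
the binary label, tested the same way.  The label association is what
"significant feature" means here — a per-feature p-value is the only
reading under which a specific subset of features can be singled out —
while the pairwise matrix drives redundancy handling.  Absolute |r| is
used against both thresholds.

Group assembly: keep label-significant features (p < 0.05); find the
largest mutually high-correlated cluster among them (all pairwise
|r| ≥ 0.80; exact clique search, trivial at ≤15 features); let the core
be the kept features outside the cluster whose mutual |r| ≤ 0.20; emit
one candidate group per cluster member, core ∪ {member}.  With the
screening structure observed clinically — seven significant features, a
{theta, alpha, beta} power cluster, and a near-uncorrelated core of
{mean, min, skew, kurt} — this yields three 5-feature groups differing
only in the band power they carry.

## Classifier

The channel classifier is the classic five-layer sequence network:
sequence input (19 × 5), bidirectional LSTM, fully connected layer,
softmax, cross-entropy.  It is implemented directly in NumPy (forward
pass, full backpropagation through time, Adam, global gradient-norm
clipping), which keeps training single-threaded and bit-reproducible
from one integer seed.  Defaults mirror the reference architecture:
200 hidden units per direction, 30 epochs, minibatch 150, initial
learning rate 0.01, gradient threshold 1.  Only the terminal hidden
state of each direction feeds the classifier head ("last" output mode).
Weights are Glorot-uniform with forget-gate bias 1.

Because raw features span orders of magnitude (µV² band powers versus
dimensionless kurtosis), each feature is standardized with location and
scale estimated from the training rows only; the statistics travel with
the fitted model.  The positive class is *epileptic*; prediction ties
resolve to *normal* (conservative).

Evaluation uses repeated stratified 80/20 holdout grouped by subject —
overlapping segments and multiple channels of one subject never appear
on both sides of a split — with confusion counts pooled over the test
folds; grouped k-fold is available via `cv="kfold"`.  Performance is
reported as accuracy, sensitivity, specificity, PPV and NPV in percent
from the pooled TP/FN/FP/TN.  One bookkeeping note: in the published
confusion counts for the three candidate groups, the values obtained
from the sensitivity/specificity and PPV/NPV formulas appear with the
two column pairs interchanged relative to the printed summary table;
this package trusts the counts and the formulas, and reports what they
produce.

## Diagnosis statistic

The trained classifier is applied to all 16 LB channels of every subject
in a population; channel *c*'s affected percentage is 100 × (subjects
whose channel c is predicted epileptic)/(population size).  The mean and
sample variance (n−1) of the 16 percentages summarize the profile.
Focal epilepsy concentrates detections on one temporal chain, giving
high variance; generalized epilepsy spreads detections evenly, giving
low variance.  The decision rule is `focal iff variance > threshold`
(strict).  No threshold is published — only the two observed cohort
variances, ≈272 (focal) and ≈51 (generalized) — so the default is 160,
an order-of-midpoint value between them; it is configurable and echoed
in every result.  Each subject contributes one prediction per channel
from its single 10 s window; there is no aggregation choice to make at
that length, and longer recordings can be majority-voted across windows
upstream.

## Synthetic data

Clinical recordings are not redistributable, so a seeded generator
produces stand-in populations carrying the one property the pipeline
exploits: elevated theta power on pathological channels.  Each electrode
is a sum of five band-limited noise components (zero-phase Butterworth
band-pass of white noise, rescaled to target RMS; power therefore scales
with amplitude squared), a 50 Hz sinusoid with electrode-specific random
phase, and a 1/f background.  Baseline RMS amplitudes (µV) are
delta 20, theta 10, alpha 15, beta 5, gamma 2, line 10, pink 5 — typical
resting-state magnitudes with amplitude falling off with frequency.
The line component's phase is per-electrode rather than common-mode so
that it survives bipolar subtraction and the denoiser has real work.

Archetypes: *normal* subjects use baseline amplitudes; *focal* subjects
multiply theta amplitude by 3.0 on one temporal chain's electrodes
(left, right, or both; laterality drawn per subject by default);
*generalized* subjects apply a weaker gain of 1.5 on all 16 electrodes.
Effect sizes are free parameters of the generator — nothing quantitative
about epileptic spectra beyond the theta-band direction is available to
calibrate against — chosen once so that affected channels are clearly
but not trivially separable.  The generator does **not** simulate
epileptiform transients (spikes/sharp waves), ocular or muscle
artifacts, inter-channel correlation from volume conduction, or
non-stationarity.  Passing tests therefore demonstrate that the pipeline
recovers a known spectral contrast through the full montage → DWT →
segmentation → features → BiLSTM chain — not that it attains any
particular accuracy on clinical EEG.

With gain-3 focal channels the classifier typically detects generalized
(gain-1.5) channels at a low, roughly uniform rate, so the generalized
profile variance is dominated by binomial sampling noise,
100²·p(1−p)/n per channel.  Population size therefore matters for the
variance statistic: the desk-scale experiments use 20 subjects per
population (the clinical cohorts had 42–50), the smallest size at which
sampling noise stays well clear of the 160 threshold.

## Desk-scale experiment sizes

The bundled experiments (test suite and `scripts/acceptance.py`) use:
12 focal + 12 normal training subjects (≈56 labelled channels per
class), BiLSTM with 32 hidden units, 10 repeated 80/20 splits for
evaluation, and 20 paired populations of 20 subjects for the diagnosis
study.  These sizes are the package's defaults for synthetic studies
(`RunConfig`); the clinical-scale architecture (200 hidden units)
remains the `NetworkConfig` default.

## Numerical and degenerate-input choices

* Universal-threshold shrinkage skips levels whose estimated σ is 0
  (all-zero details), avoiding 0/0.
* `band_power` uses rectangular integration of half-open bins; a band
  reaching exactly Nyquist excludes the Nyquist bin (negligible at
  these bandwidths).
* Segmentation hop is max(round(w·(1−overlap)), 1); windows longer than
  the signal are an error, not a silent empty list.
* Constant feature columns abort the correlation screen by name rather
  than producing undefined correlations.
* A k-fold test fold that lacks one class (possible for tiny cohorts) is
  skipped and the report says how many splits contributed; repeated
  stratified holdout always holds out both classes.
* All randomness flows from `numpy.random.SeedSequence` spawning, so
  populations, splits and network initialization are reproducible and
  mutually independent.

## Known limitations

* The BiLSTM is CPU-only and unoptimized beyond vectorized BPTT; at 200
  hidden units training is noticeably slower than at desk scale.
* The synthetic generator's realism gap (above) means reported
  synthetic accuracies say nothing about clinical performance.
* The diagnosis threshold (160) is a default between two published
  cohort variances, not an estimated decision boundary; with other
  generators or cohorts it should be re-examined.
* EDF files are read (via `mne`) but not written; the columnar text
  format is the native interchange.
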