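# Methods

`ramanadapt` classifies Raman spectra of tissue measurement sites as cancer
or normal with a one-dimensional residual CNN, and studies how such a
classifier can be moved across acquisition domains: supervised pre-training
on larger source cohorts, parameter-efficient fine-tuning on a small
labelled target cohort, and unsupervised test-time adaptation (TTA) when
target labels are unavailable. Because clinical Raman cohorts are small and
private, the package ships a cohort simulator that reproduces the
statistical structure of such data, so every stage is testable end to end.

## Synthetic cohorts

A measurement site's noise-free spectrum is a sum of Lorentzian vibrational
lines at literature Raman shifts (881, 994, 997, 1007, ~1309, 1334, 1396,
1583, 1602, 1766, 1772 cm^-1; half-width 8 cm^-1 by default, Gaussian shape
available) on top of a broad autofluorescence background modelled as three
Gaussians of characteristic width ~350 cm^-1, i.e. far wider than any line.
Cancer labels are drawn per site (site-specific ground truth, not a
per-patient diagnosis); a cancer site multiplies selected line amplitudes
by a per-line `class_effect`. All intensities of one patient share a
log-normal multiplicative factor (`patient_effect_sd`), the dominant
nuisance structure that makes leave-one-patient-out validation necessary.
Raw data are accumulation matrices: each accumulation adds white Gaussian
noise and Poisson-placed cosmic-ray spikes (20-100x the noise SD, 1-2 grid
points wide). The default grid is 1174 evenly spaced points on
400-2000 cm^-1.

Per-patient measurement counts are drawn from a clipped Poisson whose mean
sits in the lower quarter of the configured range — a right-skewed
distribution matching how clinical per-patient measurement counts behave
(a 10-patient target cohort with range 7-18 averages ~100 spectra, median
~10). Domain presets emulate the transfer-learning setting: an abundant
high-SNR low-fluorescence "bacteria-like" domain, brain / breast /
retrospective-prostate cancer cohorts with class balances of 0.57 / 0.65 /
0.12, and a prospective prostate target with strong autofluorescence and
class balance 0.567. `shift_domain` derives covariate-shifted variants
(baseline amplitude scale, rigid peak translation, SNR rescale).

What the simulator does *not* emulate: instrument response physics,
wavelength calibration error, correlated (non-white) noise, within-patient
spatial correlation, or biochemically realistic spectral shapes. One
consequence worth knowing: the class signal is carried by per-wavenumber
intensities directly, which axis-aligned learners exploit very efficiently
— a random forest on raw grid intensities is close to perfect on the
benchmark, far better than it is on real tissue spectra. Passing benchmarks
therefore demonstrate the *machinery* (training, freezing, adaptation,
validation hygiene), not clinical performance.

## Preprocessing

The chain is: cosmic-ray removal across accumulations, accumulation
averaging, optional dark-frame subtraction, optional instrument-response
division, autofluorescence removal, normalization, linear resampling onto
the 1174-point grid. Each stage is a pure function; the pipeline records
applied/skipped stages in the spectrum's metadata.

*Cosmic rays.* A pixel of one accumulation is replaced by the
across-accumulation median when it deviates by more than 8 robust scales.
The scale is 1.4826 x MAD across accumulations, floored at its
median-over-pixels value — the per-pixel MAD over ~10 accumulations is
itself noisy, and without the floor quiet pixels get over-flagged. Spikes
hitting every accumulation are invisible to the median test; they are
detected (against a running-median of the averaged spectrum, judged at the
detector noise level so genuine sharp Raman lines do not trigger) and
logged, not altered. Single-accumulation inputs fall back to a
within-spectrum median filter test, flagged in metadata.

*Baseline removal.* A bubble-filling lower envelope: in a frame where the
intensity span is scaled to the record length (so bubbles are circles), the
largest circle spanning an interval is grown from below until it touches
the spectrum, the touch point splits the interval, and recursion continues
while intervals are at least `bubble_min_width` (default 50 cm^-1) wide.
Narrower intervals keep their parent's arc — growing tighter bubbles there
would climb into narrow Raman lines. The final envelope is clipped from
above by the spectrum, giving `baseline <= spectrum` and `corrected >= 0`
exactly.

Two documented limitations. First, Lorentzian wings: a lower envelope
cannot distinguish the broad pedestal formed by Lorentzian tails from
fluorescence, so 25-50% of a Lorentzian line's integrated area (over a
+-2..4 HWHM window) is absorbed into the baseline; the line's position and
core survive (height typically reduced ~30% in the worst, on-slope
geometry). Narrow Gaussian-like bands (HWHM ~6 cm^-1) are recovered to
within 5% of their area. This trade-off is intrinsic to envelope methods,
not a tuning issue: pushing the contact points far enough from a Lorentzian
to spare its wings requires bubbles so wide that smooth-background tracking
violates its own 2% contract. Second, on a locally tilted background,
tangent circles contact near their uphill rim, so touch points are denser
on slopes; this tightens background tracking but is why wing absorption is
worst for peaks on steep fluorescence flanks.

*Normalization.* Min-max to [0, 1] by default (the convention of the
processing stacks used with this kind of instrument); unit-area and
unit-norm are available. Min-max anchors the intensity scale to the
strongest band. When the discriminative band is itself (near) the global
maximum — as the 994/997/1007 phenylalanine cluster is here — min-max
suppresses that band's own contrast and relocates the class signal to the
*other* bands' relative heights. Classifiers using the whole spectrum are
indifferent to this; single-band (univariate) analyses are not, which is
why the univariate fixtures in the test-suite use unit-norm preprocessing.

*Resampling* is linear interpolation; extrapolation outside the source
range is refused; no smoothing is applied anywhere.

## The classifier

An initial 1-D convolution (stem), six residual blocks of four
convolutions each, and a two-logit fully connected head trained with
softmax cross-entropy (the two-logit equivalent of binary cross-entropy,
chosen so the TTA objective has an explicit class distribution). All
kernels are width 5 with "same" padding; stride 2 is applied once in the
stem and once in each block's first convolution, so 1174 points contract
through 587-294-147-74-37-19-10. Every convolution is followed by batch
normalization (so conv biases are omitted) and ReLU; shortcuts use a
strided 1x1 projection plus batch norm whenever shape changes. With 100
channels throughout, the model has 1,268,702 parameters (~1.25M); a
64-channel variant is configurable. Parameters are addressable by named
groups (`stem`, `block_1..6`, `head`, plus all batch-norm affine
parameters) — the handle that freezing and TTA need.

The network, its backward pass, and Adam are implemented directly on NumPy
arrays (`ramanadapt.nn`) — a deliberately small, single-threaded CPU core
whose gradients are validated against finite differences in the test suite
and whose runs are bit-reproducible given seeds.

## Training, fine-tuning, test-time adaptation

Supervised training uses Adam (lr 1e-3), at most 25 epochs with early
stopping after 8 epochs without validation-accuracy improvement and
best-weights restoration; batch size 32 (16 in the benchmark, where
training sets are a few hundred spectra and more optimizer steps per epoch
help). Pre-training splits source cohorts 60/20/20 into
train/validation/test with whole patients assigned to one partition; a
partition left without both classes is an error, and every nonzero
partition is guaranteed at least one patient.

Efficient fine-tuning freezes the stem and blocks 1-3 and updates blocks
4-6 plus the head — 50.05% of parameters in the default configuration.
Frozen parameters are never touched by the optimizer (bitwise identity is
asserted in tests), and backpropagation stops below the deepest trainable
group, which roughly halves the per-step cost.

TTA minimizes the Shannon entropy H(p) = -sum_c p_c ln p_c of the model's
own prediction for 5 Adam steps per measurement, updating only the head
and all batch-norm gamma/beta. Two defaults were set empirically (four
seeds, pre-trained model, covariate-shifted target) and differ from the
obvious first choices:

- *Normalization statistics*: when a patient provides at least 8 spectra,
  the stored running batch-norm moments are replaced by that patient
  batch's own moments before adaptation (patients with fewer spectra keep
  running statistics, which keeps single-spectrum adaptation well posed).
  Entropy steps under stale source statistics gave no benefit or mild
  degradation; statistic replacement plus entropy steps gave +0.04..+0.12
  AUC and +0.05..+0.16 accuracy under shift.
- *Within-patient granularity*: each measurement adapts afresh from the
  post-replacement state rather than cumulatively across the patient's
  measurements — cumulative entropy minimization collapses a patient's
  predictions toward a single class (-0.06..-0.12 AUC).

The model is restored to its pre-adaptation checkpoint before the next
patient, so adapting on one patient can never influence another's
predictions; each measurement's entropy trace (6 values: before each of
the 5 steps and after the last) is returned for inspection. TTA after
fine-tuning is supported and reported by the benchmark but no direction is
asserted for it: whether unsupervised sharpening helps a model already
aligned to the target is shift-dependent.

## Baselines and evaluation

The SVM baseline uses a three-step per-fold feature selection over all
1174 grid points: variance > 0.03, |point-biserial r| with the label > 0.9
(with a documented top-k fallback when nothing passes — on normalized
spectra |r| > 0.9 is rarely attainable — and a logged bypass if the
variance gate empties the set), then L1-regularized logistic selection
tightened until at most 10 features survive. Features are z-scored and fed
to an RBF SVM. Two fixed literature band sets are available as
alternatives; band features are the maximum intensity within +-4 cm^-1 (a
printed range such as 1307-1310 uses its full interval). The random forest
uses 100 trees, depth <= 5, all features per split, no class weighting.
Selection, scaling and fitting are refit inside every training fold.

Evaluation is leave-one-patient-out: one fold per patient, fold scores
pooled before computing AUC (Mann-Whitney, ties one half — tested exactly
against exhaustive pair enumeration), accuracy, sensitivity, specificity
and PPV at threshold 0.5. Experiments repeat 5 times; results are
mean (SD) over repetition-level values, compared pairwise by Welch's
t-test with t-based 95% CIs (identical constant samples give p = 1). The
univariate per-band analysis reports Welch p, mean difference with CI,
Cohen's d as the distribution distance, and single-band AUC, reading the
intensity at the listed shift itself by default so that bands 3 cm^-1
apart remain distinguishable.

## Benchmark scale

The benchmark grid runs a 12-channel variant of the architecture (same
depth, stride schedule and group structure; ~19k parameters) with
pre-training capped at 25 epochs (patience 8) and fine-tuning at 6 epochs,
on sources of ~16 patients per domain and the 10-patient shifted target —
sizes chosen so a six-variant, five-repetition grid completes in a few
CPU-minutes while the method ordering (pre-train + fine-tune > scratch;
pre-trained + TTA > pre-trained) is stable across seeds. The target's
covariate shift is baseline x3, peak translation +3 cm^-1, SNR x0.6.

## Numerical notes

- All randomness flows through `numpy.random.default_rng` seeds; repeated
  runs are bit-identical on CPU.
- Batch-norm eps 1e-5, momentum 0.1, unbiased running variance; evaluation
  and TTA gradients use the stored (or replaced) statistics, under which
  the normalization constants are parameter-independent.
- `baseline <= spectrum` is enforced by a final pointwise minimum;
  envelope idempotence (re-correcting a corrected spectrum) changes
  single-band fixtures by < 1% of their maximum, dense multi-line spectra
  by up to ~1.3% (overlapping Lorentzian pedestals are re-absorbed).
- Checkpoints are single `.npz` files holding weights, batch-norm
  buffers, the architecture config and the group-name map, with a format
  version field.
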