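# Methods

This package implements a complete frequency-tagging (FPVS) oddball analysis
chain for MEG/EEG sensor data — stimulus-sequence construction, synthetic
cohort generation, frequency-domain quantification, and nonparametric
cluster-level inference — together with the validation studies that
demonstrate each stage on data with known ground truth.

## The paradigm and its observables

Stimuli are presented at a fast base rate (6 Hz by default) with a deviant
("oddball") stimulus at every fifth position, i.e. at 6/5 = 1.2 Hz. Any
neural process that discriminates oddballs from base items produces a
periodic response component at the oddball frequency and its harmonics,
which concentrates in a handful of known frequency bins. The analysis'
dependent variable is the **oddball response**: the mean signal-to-noise
ratio (SNR) of the amplitude spectrum at the oddball fundamental and its
first three harmonics, per sensor.

## Stimulus construction (`fpvs.stimuli`)

Pseudowords are built by concatenating a 4-letter left constituent (stem or
matched nonstem) with a 3-letter right constituent (suffix or matched
nonsuffix). Each role's items are partitioned into equally sized subsets and
crossed *within* subset, so a subset size of *s* with two subsets yields
2·s² combinations per stimulus class: 72 per class (288 total) for the full
12-item inventory, 18 per class (54 total) for the reduced 6-item inventory.

Sequences are 360 items (60 s × 6 Hz) with oddballs at 1-based positions
5, 10, …, 360. Two repetition policies are supported: `unique` (each oddball
slot gets a distinct item — feasible with a 72-item pool) and `k_repeats`
(an 18-item pool is tiled so every item appears exactly 4 times). Base slots
are sampled uniformly with replacement. A hard constraint forbids identical
texts within an index distance < 5; it is enforced by per-position candidate
filtering plus whole-sequence rejection sampling with a retry cap, and
verified post hoc by exhaustive pairwise scan. Base items are sampled
uniformly with replacement subject to the distance rule — nothing in the
design constrains the base schedule beyond that rule, so no attempt is made
to balance base-item frequencies across the stream.

Item presentation uses sinusoidal contrast modulation,
contrast(t) = (1 − cos 2πt/T)/2 over each cycle of T = 1/6 s, reaching full
contrast at the half cycle (~83.5 ms).

The bundled word and consonant-string pools for the word-in-nonwords
manipulation check are synthetic stand-ins (marked as such in their
filenames): structurally faithful (4-letter words ending in consonants;
unpronounceable 4-consonant strings) but with no claim to the lexical
statistics of any particular study list. Likewise, the split of the reduced
(child) inventory into two subsets of 3 is the package's own choice.

## Synthetic cohorts (`fpvs.simulate`)

The generator emulates what the analysis actually observes, not the
biophysics that produces it:

- **Layout**: a Fibonacci lattice restricted to the upper unit hemisphere
  (160 sensors by default) with an azimuthal-equidistant 2D projection used
  for triangulation and plotting.
- **Signal**: sinusoids at the base frequency and its harmonics (amplitudes
  `base_amplitudes`, broad topography) plus sinusoids at the oddball
  frequency and harmonics (`oddball_amplitudes`), the latter weighted by a
  per-sensor topography in [0, 1] — by default a binary posterior patch,
  emulating the occipito-temporal focus of reading-related responses.
  Response phases are drawn uniformly per subject and shared across trials,
  so trial averaging preserves signal and suppresses noise.
- **Noise**: 1/f-shaped background (spectral shaping of white Gaussian
  noise, default exponent 1.0, unit variance × `noise_scale`) plus white
  sensor noise (`white_scale`). Units are arbitrary: only SNR matters
  downstream.
- **Subjects**: a multiplicative log-normal gain per subject
  (log-sd `subject_sd`, default 0.2) scales the oddball response.

Default amplitudes (0.08, 0.06, 0.04, 0.025 across the four oddball
harmonics, against noise scales 1.0/0.3) were chosen so that the reference
design — five 60-s trials — yields per-sensor oddball responses around
SNR ≈ 2–3 on patch sensors, the order of magnitude typical of word-level
FPVS effects; the base response is much stronger (amplitudes 1.0, 0.4), as
in real recordings. These defaults are for testability and realism of the
*observables*; no claim is made that they reproduce any particular
recording's field amplitudes.

What the generator deliberately omits: stimulus-locked transient waveforms
(responses are pure sinusoids, so ground truth is exact in the frequency
domain), head motion, ocular/cardiac artifacts, and forward modeling from
cortical sources. Simulation runs natively at 250 Hz — the post-decimation
rate of the reference preprocessing — rather than emulating a higher
acquisition rate; a `downsample` hook exists for realism testing. Passing
tests therefore demonstrate correctness of the analysis arithmetic and
calibration of the statistics under this idealized signal model, not
robustness to real-world artifacts.

Every random stream is keyed by `blake2b(global seed / stage / subject /
condition / trial)`, so cohorts are bit-reproducible and adding subjects
never perturbs existing ones.

## Spectral reduction (`fpvs.spectral`)

Trials are cropped to `[head_trim, duration − tail_trim)` and averaged
element-wise. The reference configuration trims 1.667 s (two oddball
cycles) from the head and nothing from the tail of each 60-s trial, giving
a 58.333-s epoch and hence the frequency resolution 1/58.333 = 0.0171 Hz
that all downstream bin arithmetic inherits; a full-trim variant (plus
0.833 s from the tail, 57.5-s epochs) is available through the same two
parameters.

The spectrum is the plain DFT amplitude, sqrt(Re² + Im²)/N per sensor and
bin, with no windowing or detrending (rectangular window; DC retained but
never a target). A sinusoid of amplitude A at an exact bin frequency gives
A/2 at that bin.

SNR normalization divides each bin by the mean of the 20 surrounding bins
(10 per side, skipping the immediately adjacent bin on each side). Edge
bins whose full baseline window would run off the grid are flagged invalid
(NaN) rather than normalized against a truncated window. Baseline windows
are *not* purged of other harmonic bins by default (an exclusion mask can
be built by the caller); at the default spacing the harmonics are ~70 bins
apart, far outside each other's windows.

Target bins: the grid bin nearest the nominal oddball frequency (ties break
to the lower bin) defines the realized fundamental; harmonics are its exact
bin multiples, so realized harmonic frequencies are exact multiples of the
realized fundamental. The module reports realized frequencies for whatever
grid it is given and hard-codes none.

Bad-channel repair replaces a flagged sensor by the inverse-distance-
weighted mean of its good triangulation neighbors (3D distances); a bad
sensor with no good neighbor is an error, not a silent drop.

## Cluster-based permutation test (`fpvs.cluster`)

Because a silent sensor's oddball response sits at SNR ≈ 1, inference is a
one-tailed one-sample test against the constant 1 ("an array of ones"):

1. Per sensor, t(s) = (x̄(s) − 1)/(sd(s)/√n), df = n − 1. A zero-variance
   sensor above the null gives t = +∞, is treated as suprathreshold, and is
   flagged in the report rather than dropped.
2. The cluster-forming threshold is the one-tailed Student t quantile at
   1 − cluster_alpha (default 0.05) for the observed df — computed, never a
   fixed number. (The alternative reading, two-tailed-at-0.05 then
   one-sided, is not used; the choice is recorded in the result's config
   echo.)
3. Sensors at or above threshold are grouped; each marked sensor must have
   at least `min_neighbors = 2` marked neighbors (the FieldTrip-style
   `minnbchan` rule), applied iteratively to a fixed point; connected
   components of the survivors (triangulation adjacency: Delaunay edges of
   the projected layout) are the clusters, scored by summed t.
4. The null distribution sign-flips each subject's deviation from 1 with
   probability ½, independently per subject and permutation (5,000 Monte
   Carlo draws by default) — the exact equivalent of swapping that
   subject's data with the all-ones array in a within-subject design — and
   records the maximum cluster score (0 if none). Cluster
   p = (1 + #{maxima ≥ score})/(1 + n_perm), so p is never exactly 0;
   significance is p ≤ alpha. A relative epsilon (1e-7) guards the ≥
   comparison so the identity sign pattern, which reproduces the observed
   statistic up to floating-point summation order, always counts.

## Pipeline and scenarios (`fpvs.pipeline`)

`run_pipeline` chains simulate → trim/average → spectrum → SNR → oddball
response → cluster test per condition, streaming one trial at a time (the
full 28-subject adult scenario at 60-s trials never holds more than one
sensor × time matrix in memory). Scenario presets mirror the study
dimensions: `adult` = 28 subjects × 5 conditions × 160 sensors with five
trials (22,400 response scalars), `child` = 17 × 3 × 160 with six trials
(8,160 scalars). Preset condition effects seed a strong response in the
manipulation-check condition and one morphological condition (condition 3
for adults, condition 1 for children), with the remaining conditions at
zero — the qualitative pattern the paradigm is designed to resolve. Reports
carry a config hash, the seed, and a content hash; regenerating from the
same config reproduces the report bit for bit.

## Validation studies (`fpvs.validation`) and problem sizes

- **Type-I calibration**: 200 cohorts with the oddball effect multiplier at
  0, each 17 subjects × 160 sensors with one 30-s trial and 2,000
  permutations; the family-wise rejection rate should sit near the nominal
  alpha = 0.05. The scaling keeps the two features the test's operating
  characteristics actually depend on at study scale: the subject count
  (which fixes the df of the cluster-forming t threshold) and a frequency
  grid fine enough that the 21-bin SNR baseline window stays within the
  locally flat part of the 1/f spectrum. Much shorter epochs would widen
  that window into the curved region, bias the null SNR below 1, and make
  the calibration measure the scaling artifact rather than the test. Two
  small opposing biases remain intrinsic to the SNR observable — a ~1%
  upward Jensen bias from the baseline divisor and a downward skew effect
  on the t statistic — and the max-statistic/pruning discreteness leaves
  the test mildly conservative overall.
- **Patch recovery**: 20 runs, 20 subjects, a 10-sensor contiguous patch
  (breadth-first growth on the adjacency graph) with responses elevated to
  mean SNR ≈ 3 against a between-subject sd of 0.7; success = a significant
  cluster with Jaccard overlap ≥ 0.7 against the seeded patch.
- **End-to-end recovery** (test suite): 10-subject, two-condition cohorts
  with 24-s trials and the effect multiplier raised to 2.5 to hold the
  per-sensor SNR near the full-length design's level; the effect condition
  must yield a significant cluster and the null condition none in ≥ 90% of
  runs.
- The dataset-dimension demonstrations run the adult and child scenarios at
  12-s trials, which preserves every count (subjects × conditions ×
  sensors) while keeping the runs under a minute.

## Numerical choices and degenerate inputs

- Nearest-bin ties break to the lower bin, documented and tested.
- SNR of a flat spectrum is exactly 1 on interior bins; edge bins are NaN.
- `simulate` rejects configs whose highest generated harmonic reaches the
  Nyquist frequency, and topographies outside [0, 1].
- Sequence generation failures name the violated constraint instead of
  looping forever (bounded retries).
- Permutation variance terms are clipped at 0 before the square root to
  absorb negative round-off.

## Known limitations

- The synthetic signal model is sinusoidal and artifact-free by design;
  none of the preprocessing robustness questions of real MEG (motion,
  artifacts, filter edge effects) are addressed here.
- Only the one-sample, one-tailed-greater test against a constant is
  implemented; two-condition contrasts, cluster-mass statistics, TFCE, and
  source-space inference are out of scope.
- The base-rate (6 Hz) response is simulated but not quantified; the
  analysis targets the oddball frequencies only.
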