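# Methods

This note documents the models, procedures and design choices behind
`euscv`: a patient-grouped cross-validation framework for differentiating
localized autoimmune pancreatitis (AIP, label 0) from pancreatic ductal
adenocarcinoma (PDAC, label 1) on endoscopic-ultrasound (EUS) video
frames, exercised end-to-end on a synthetic cohort because the clinical
images it is designed for are private patient data.

## The cross-validation framework

**Why group patients, not images.** EUS videos yield hundreds of
near-duplicate frames per patient. Splitting *frames* into training and
test sets leaks patient identity and inflates test performance; the
framework therefore assigns whole patients to k = 5 groups and gives each
group a single role per session. Within any one training session the
test, validation and training patient sets are disjoint by construction,
and `splits.check_leakage` audits this on the actual sampled batches.
Across the four sessions of a test group the validation group rotates —
a group legitimately serves as validation in one session and as training
in another — so the audit is per session, never pooled across sessions.

**Ordered and balanced divisions.** Patients are first totally ordered by
one factor (CHR = session date, AGE, BMI, SAI = g ethanol/day, EDA =
fraction of a reader panel correct on the patient), ties broken by
patient id so divisions are reproducible. The *ordered* manner cuts the
ranked list into k contiguous blocks (the first `n mod k` blocks take the
extra patient); the *balanced* manner assigns rank r to group `r mod k`.
These are the minimal constructions that concentrate, respectively
spread, the factor: with stride assignment each group's ranks form an
arithmetic progression, so group factor-means differ by at most the
within-stride range, whereas contiguous blocks maximize between-group
separation. The variance of the five group factor-means drops by two to
four orders of magnitude from ordered to balanced on simulated cohorts
(`analysis/02_define_splits.py`).

**Role allotments.** With k groups and one test plus one validation group
per session, there are k(k−1) ordered (test, validation) pairs — 20 for
k = 5 — enumerated test-major. The four sessions sharing a test group
form that group's ensemble.

**Quasi-RGB images.** Three distinct grayscale frames of one patient are
stacked as channels, in ascending temporal order, then resized to
224 × 224 (bilinear, per channel). By default the three frames come from
one uniformly chosen video with ≥ 3 frames (`same_video_only = True`),
which preserves the temporal-coherence rationale; patient-wide pooling
across a patient's videos is supported as an option since the design only
requires patient consistency. Because bilinear resizing acts per channel,
the implementation caches per-frame resizes and stacks them — exactly
equivalent to composing first and resizing after (asserted in tests).

**Balanced epoch sampling.** The cohort is imbalanced (61 vs 24), so each
training epoch draws `n_per_epoch` fresh quasi-RGB images split as evenly
as possible between classes — an odd remainder goes to class 1, a fixed
deterministic rule — and, within each class, round-robin over that
class's patients so per-patient counts differ by at most one (the
patients receiving the remainder are chosen by a seeded shuffle).

**Head training and checkpointing.** The feature extractor is frozen;
only the final layer is trained: a single linear layer with a logistic
link, fit by plain minibatch SGD on the logistic loss. After every epoch
the validation AUROC is computed on a *fixed* seeded sample of quasi-RGB
images from the validation patients (drawn once per session, features
extracted once), and the parameters of the best epoch are kept, earliest
epoch on ties. If a validation group happens to contain a single class,
its AUROC is undefined and recorded as 0.5 for every epoch (the
checkpoint then falls back to epoch 1); at the default group sizes this
is a corner case.

**Ensembling and patient scores.** A test patient's images are sampled
once per run (`n_test_per_patient` of them) and scored by all four heads;
the per-image score is the median of the four (for four values, the mean
of the middle pair), and the patient score is the mean of the per-image
medians. Evaluation is at patient level, matching the per-patient
diagnoses of the reader panel; an image-level path is available through
the same metric functions.

## The synthetic cohort generator

The generator produces the statistical structure the framework assumes,
not a physically accurate ultrasound simulation.

Frames are built as: smooth background (fixed vertical intensity
gradient + three random full-period cosines, amplitudes 0.01–0.03 in
[0, 1] intensity units) carrying one elliptical lesion per video
(semi-axes 12–20 % of the frame side, center jittered per video around a
per-patient base), degraded by multiplicative speckle with Rayleigh
amplitude (contrast 30 % of local intensity), quantized to 8-bit.
Consecutive frames share the realized scene, shifted by a ±1 px/frame
random walk (clipped at ±3 px), with fresh speckle per frame. A dark
bottom band (8 % of height, where ultrasound does not reach) and bright
corner marks emulate the overlays a real preprocessing crop must remove;
`default_crop_box` returns the interior window (the full-scale frame
defaults, 576 × 512, accommodate the standard 489 × 465 crop).

**Class signal.** Each patient draws a latent texture coordinate
z ~ N(±effect_size/2, 1), positive shift for PDAC. The lesion interior is
darker by 0.06 + 0.035 z intensity units (PDAC more hypoechoic) with
speckle contrast raised by up to 25 % as z grows. `effect_size` is thus
the standardized between-class separation of the latent; at 0 the classes
are statistically identical. The contrast slope (0.035) was fixed once in
a pilot recoverability analysis so that the sweep {0, 1, 2} spans chance
to strong recovery, and not revisited.

**Diagnosability and the reader panel.** A patient's diagnosability is
`logistic(1.2 · z · (2·label − 1))` — a logistic transform of the realized
class-typical separation, in [0, 1] — so the panel sees the same latent
the images encode rather than an independently dialed difficulty. Each of
the 7 readers (4 experts, slope 0.9; 3 novices, slope 0.5, in
`p_correct = 0.5 + slope·(d − 0.5)`) makes one binary call per patient;
the EDA score is the fraction of readers correct. Mean EDA rises with
effect size, which is what makes EDA a meaningful ordering factor.

**Covariates.** Age ~ N(69.5, 9) years clipped to 40–90; BMI ~ N(22, 2.6)
kg/m² clipped to 15–38; drinker category light/moderate/heavy with
probabilities 56/85, 23/85, 6/85 and g/day uniform within the category
band (<20, 20–60, 60–120); session dates uniform over Feb 2016–Jul 2022.
Covariates are independent of the label by default (matching a cohort
table with no significant covariate differences); a confounding knob can
correlate one factor with the label for split-behavior studies.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: real speckle statistics and attenuation,
needle/Doppler artifacts, operator-dependent views, inter-video
heterogeneity of real lesions, covariates that genuinely influence
texture (age/BMI/alcohol affect real pancreatic echotexture; here they
are label-independent noise unless confounded on purpose), and
laboratory values. Results on this cohort validate the *framework* —
splitting, sampling, training, ensembling, evaluation — not clinical
performance.

## Statistics

* **AUROC**: rank-based (Mann–Whitney) estimator with mid-ranks, equal to
  the trapezoidal area under the empirical ROC; property-tested against
  an exhaustive pairwise oracle and scikit-learn.
* **Threshold metrics** at 0.5; a score exactly at the threshold counts
  as positive (the boundary rule is a package decision). Undefined
  PPV/NPV (empty predicted class) is reported as missing and excluded,
  with a flag, from fold means.
* **Fold aggregation**: unweighted arithmetic mean over the 5 folds.
* **Ordered-vs-balanced comparison**: exact two-sided Wilcoxon rank-sum
  over the 5 + 5 per-fold values, enumerating all C(10, 5) = 252 rank
  assignments with mid-ranks under ties (scipy's exact method does not
  handle ties exactly, so the enumeration is implemented here and
  cross-checked against scipy on tie-free data). With n = 5 + 5 the
  smallest attainable two-sided p is 2/252 ≈ 0.0079.
* **Cohort tables**: continuous covariates as median (range) with the
  Wilcoxon rank-sum test; drinker categories as n (%) with a two-sided
  category-vs-rest test on the 2 × 2 table. Fisher's exact (sum of
  hypergeometric probabilities ≤ the observed table's) is the default.
  A note on the reference values this package recomputes: the study it
  reimplements states Fisher's exact test for categorical variables, but
  its printed drinker-category p-values (0.266, 0.4177, 0.5138 for
  38/61 vs 18/24, 18/61 vs 5/24, 5/61 vs 1/24) are exactly the Pearson
  chi-square values *without* continuity correction (Fisher gives 0.317,
  0.589, 0.671). The chi-square variant is therefore provided
  (`method="chi2"`) and used when reproducing those printed values. The
  printed male-sex p of 0.175 (36/61 vs 19/24) matches neither test —
  nor Yates-corrected chi-square, Barnard, Boschloo, G-test, t-test or
  rank-sum — and is treated as irreproducible from the printed counts;
  the package reports the honestly computed Fisher value 0.1292.

## Occlusion sensitivity

A patch (default 16 × 16, stride 8, chosen as a resolution/runtime
compromise) is replaced — across all channels — by a baseline intensity
(default 0; an array baseline is allowed, and occluding with the image's
own pixels yields an exactly zero map). The patch grid starts at the
top-left corner and appends a final row/column flushed to the image edge
so every pixel is covered. Δ = score(original) − score(occluded) is
defined on the post-link score in [0, 1]; each pixel's value is the mean
Δ over the patches covering it (averaging, not max-pooling, for smoother
maps). Positive values (red in the rendering, diverging colormap
symmetric about 0) mark pixels supporting the prediction. Renders are
written through Pillow without metadata, so they are byte-deterministic.

## Reproducibility and problem sizes

Every stochastic stage derives its seed from the global run seed plus the
stage name via SHA-256 (`euscv._seeding`), so adding a stage never
perturbs earlier stages' randomness, and the full pipeline is a pure
function of its config: repeated runs write byte-identical tables.

One subtlety of small grouped cohorts is worth naming: fold AUROCs are
not independent draws. Each fold's test patients serve as training
patients in other folds' sessions, so any chance association between the
cohort's realized latent textures and its labels pushes *all* folds the
same way — at effect size 0 a single cohort's mean fold AUROC has a
standard deviation near 0.1 across cohort draws, far wider than
naive per-fold binomial noise suggests. Where a stable estimate of the
framework's expected behavior is reported (the signal-recovery sweep in
`scripts/acceptance.py`), each effect size is therefore averaged over
several independent replicate cohorts, and folds whose label-blind test
group happens to hold a single class (undefined AUROC) are excluded, the
same rule `aggregate_folds` applies.

The shipped analyses and the acceptance script run at desk scale, chosen
as this package's own working point: the full 61/24 cohort structure and
all 20 training sessions per division, with short small videos (6–12
frames of 96 × 96 per video), 200 images per epoch, 20 epochs, 30 test
images per patient, and a 128-dimensional random-projection extractor.
At these sizes a complete 20-session cross-validation takes seconds on
one CPU. The full-scale defaults (100–300 frames of 576 × 512, 1000
images/epoch, 300 test images/patient) are retained on the spec objects;
frames are generated lazily per video, so metadata-level work never pays
the imaging cost.

## Known limitations

* The default extractor is a linear projection of block-pooled pixels; a
  logistic head over it can only use linear structure in pooled
  intensities. The class signal is designed to be (mostly) linearly
  recoverable; a deep extractor would be needed for nonlinear texture
  cues, and the `FeatureExtractor` contract accepts one.
* The exact rank-sum enumeration is intended for the 5 + 5 fold
  comparison; it refuses samples beyond ~500k enumerations.
* The generator's lesion is a single ellipse with a global intensity
  shift; it does not model infiltrative margins, ductal dilation or
  calcifications that real readers use.
* `best_val_auroc` is a maximum over epochs and is upward-biased as an
  estimate of validation performance; it is a checkpoint-selection
  criterion, not a performance claim.
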