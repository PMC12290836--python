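# Methods

This note documents the statistical model behind `emodecode`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices a user auditing results should know
about.

## The analysis model

The unit of analysis is one subject's set of trial-wise parameter
estimates ("beta" volumes), one 3-D volume per trial, with a trial
table giving each trial's action modality (execution, observation,
imitation, control), emotion (fear, anger) and acquisition block. The
question asked of the data is binary: can fear and anger trials be told
apart from the multi-voxel pattern — and does a rule learned in one
modality transfer to another? Above-chance transfer is the operational
signature of a representation shared across modalities.

**Classifier.** A linear max-margin classifier (C-SVC with linear
kernel, fixed regularization C = 1, no feature scaling by default).
Features enter as raw beta values of the in-mask voxels, columns in a
fixed lexicographic voxel order. The solver is an in-package SMO
optimizer of the standard equality-constrained C-SVC dual
(maximal-violating-pair selection, (m+M)/2 intercept, tolerance 1e-4);
the test suite asserts agreement of its decision values with
scikit-learn's libsvm-backed `SVC(kernel='linear', C=1)` on random
problems. It exists because the permutation stages refit the
classifier millions of times on problems of ~16 × 20–100 entries, a
regime where per-call overhead, not optimization, is the cost. The fit
is deterministic: no randomness, ties in working-set selection resolved
by lowest index.

**Cross-validation.** Within a modality, leave-one-block-out: one fold
per acquisition block, train on the other blocks. Blocks are balanced
(equal fear/anger), so raw accuracy equals balanced accuracy and the
chance level is exactly 50%. Across modalities there is no CV: train
and test selections are disjoint by design, and each direction
(train → test) is reported separately, never averaged.

**Metrics.** Accuracy = 100 × correct / tested, averaged over folds
(folds are equally sized, so this equals the pooled fraction). AUC is
the rank statistic of the signed decision values pooled across folds
(P(score_fear > score_anger) + ½ P(tie), fear = positive class); with
fewer than two test trials or a single-class test set it is reported as
NaN while accuracy is still returned. A decision value of exactly zero
is classified as the lexicographically first class ("anger") — a
deterministic, documented tie-break that matters only for degenerate
(constant-feature) inputs, where it forces 50% on balanced test sets.

**Searchlight.** Sphere membership uses the strict inequality
`‖offset‖² < radius²`; at the default radius 3 that is 93 voxels. (The
non-strict `≤` convention would give 123, which is not the sphere size
this pipeline is defined to use.) Spheres are truncated at grid edges
and at the brain-mask boundary rather than skipping edge centers, so
the map covers the whole analysis mask; the per-center feature count is
recorded in the map's provenance. Centers are mutually independent and
the map is bit-identical under any execution order.

**Group inference (two-step permutation scheme).** Step 1: per subject,
the emotion labels of the *training* trials are permuted within each
(modality, block) cell — preserving class balance and the fold
structure — and the entire analysis is rerun; default 100 permutations.
One permutation is drawn per iteration and applied before folding (not
re-drawn per fold); whole-block label flips are available as an option.
For cross-modal analyses only training labels move; test labels are
never touched. Step 2: `n_draws` (default 10⁵) bootstrap draws each
select one permutation accuracy per subject uniformly at random and
average them; the observed group mean is ranked right-tailed against
these draw means with add-one smoothing,
`p = (1 + #{mean ≥ observed}) / (n_draws + 1)`, so p is never zero and
the minimum attainable p is 1/(n_draws+1). ROI analyses use this p
uncorrected at α = .05 (two ROI systems; no multiplicity correction at
that level); searchlight maps are corrected voxelwise with
Benjamini–Hochberg FDR at α = .05 over the in-mask voxel family
(statsmodels implementation; a hand-written step-up serves as the
oracle in tests).

**Replication.** A voxel counts as replicated when it reaches a group
mean accuracy of at least 60% *and* FDR significance in both cohorts
(sessions or samples); the significance requirement can be switched off
to obtain a threshold-only overlap. The output is a binary conjunction
map over the common voxel family.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ClassifierSpec.C` | 1.0 | SVM box constraint (beta units are arbitrary; C=1 is the fixed convention of the analysis) |
| `ClassifierSpec.scaling` | none | optional train-fitted z-scoring; recorded in all outputs |
| `SphereIndex.radius` | 3 voxels | searchlight radius; 93 voxels per full sphere |
| `InferenceConfig.n_perm` | 100 | subject-level label permutations |
| `InferenceConfig.n_draws` | 10⁵ | group bootstrap draws; min p = 1/(n_draws+1) |
| `InferenceConfig.alpha` | .05 | right-tailed level, and the FDR level for maps |
| `ReplicationConfig.accuracy_threshold` | 60% | supra-threshold criterion per cohort |

## The synthetic generator

`simulate` produces cohorts with the paradigm's structure: design
`study1` has imitation, observation and execution conditions of 5
blocks × 4 trials each (2 fear + 2 anger per block, order
pseudo-randomized per subject) plus 30 control trials; design `study2`
has imitation and control, 20 trials each. The 30 control trials are
grouped into the five acquisition blocks (6 each, 3 fear-cue / 3
anger-cue) so that leave-one-block-out folds are well defined for the
supplementary imitation-vs-control modality decode.

Each trial's volume is `s(emotion) · A · w_m + ε` with
`s(fear) = +1, s(anger) = −1`, amplitude `A` (default 1.0, beta units),
`w_m` a unit-norm pattern over the ROI voxels, and `ε` i.i.d. Gaussian
noise (default sd 0.5) over voxels and trials. Per modality `w_m` is
the cohort's reference pattern (`shared`), an independent pattern
orthogonalized against the reference and all other distinct patterns
(`distinct` — orthogonality makes cross-decoding of non-shared pairs
exactly chance in expectation, a clean negative control), or zero
(`null`). Subjects perturb the patterns with Gaussian jitter (default
sd 0.2, re-normalized), applied once per subject so shared modalities
stay aligned within subject. The default sharing map — execution and
imitation shared, observation null — encodes the hypothesis structure
the pipeline is meant to recover. Defaults were chosen for test power:
with A/σ = 1.0/0.5 over a 20–27 voxel ROI, within-modality decoding
sits near 90% and null conditions at 50%, so recovery and calibration
are both observable at cohort sizes of 10–20. The per-voxel effect is
`A/√n_ROI`, i.e. patterns spread over larger ROIs are individually
weaker.

Emotion is coded as a sign flip of one pattern — the simplest linearly
separable ground truth; an independent two-pattern variant is available
via `emotion_coding="two_pattern"`. Noise is spatially white by default
(the pipeline consumes unsmoothed betas); optional Gaussian smoothing
of the noise field exists as a config knob. Motion covariates are
generated as a label-independent random walk, so decoding emotion from
them succeeds only at chance — the planted analogue of the
motion-confound control analysis.

**What passing tests do and do not show.** The generator's noise is
i.i.d. Gaussian with no spatial or temporal autocorrelation, no
physiological artifacts, no inter-regional structure, and subjects are
exchangeable draws around one cohort pattern. Recovery and calibration
results on synthetic cohorts therefore validate the *machinery* —
fold hygiene, permutation exchangeability, bootstrap ranking, FDR
bookkeeping, conjunction logic — not the pipeline's behavior under
realistic fMRI noise, and say nothing about effect sizes in real data.

## Numerical and design choices

* **Seeding.** Every randomized stage draws a named substream
  (SeedSequence spawn keys; strings hashed with CRC-32) from one master
  seed: cohort, subject, permutation and bootstrap streams are mutually
  independent, reproducible, and independent of execution order.
  Bootstrap draw indices are generated in one vectorized block per
  inference call and, for maps, shared across voxels — each voxel's
  marginal p is unaffected and the whole map is deterministic.
* **Degenerate inputs.** Constant features yield the zero decision rule
  → tie-break → 50% on balanced sets. Z-scoring guards zero-variance
  columns (sd < 1e-12 treated as 1). Empty masks, empty selections,
  single-block selections and single-class training folds raise typed
  errors rather than returning numbers.
* **Leakage guards.** `cv="none"` requires provably disjoint train/test
  selections (checked against the actual trial table);
  leave-one-block-out requires train and test selections to coincide.
  Both are enforced at the type level and tested.
* **Known limitation — tail behavior of the two-step scheme.** With
  finitely many permutations per subject (e.g. 100), the bootstrap null
  of group means undersamples its extreme tail, and BH-FDR controls the
  false-discovery rate, not family-wise error. In a minority of
  signal-free cohorts the voxelwise procedure can emit a small clump of
  false rejections; the ROI-level rejection rate stays at the nominal
  α (verified by simulation at 400 cohorts). The replication
  conjunction suppresses, but does not formally bound, such events;
  tests therefore assert near-empty (not exactly empty) null overlaps.
* **Problem sizes in the test suite.** Monte-Carlo suites run at
  reduced but statistically meaningful sizes chosen to keep the default
  run around ten minutes on one core: calibration at 400 cohorts of 20
  subjects with 50 permutations and 10⁴ draws; replication at 12³ grids
  with 10 subjects per cohort and 100 permutations. Tolerances are
  derived from the binomial/Monte-Carlo standard errors at those sizes
  (typically 2–3σ bands) and stated in the tests.
* **Open choices resolved.** Whether the original toolbox scaled
  features and how AUC was aggregated across folds is not fixed by the
  analysis convention this package follows; both are exposed as
  recorded options (`scaling`, pooled-AUC default). Grey-matter
  restriction of the searchlight is expressed through the required
  explicit `analysis_mask` argument rather than a hidden default.
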