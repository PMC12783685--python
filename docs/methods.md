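# Methods

This note documents the models, parameter choices and numerical decisions
behind `lcd-pipeline`, and what the synthetic studies do and do not
demonstrate.

## Data model and schema

A profile table has one row per imaged instance with nine reserved
`Metadata_` columns (plate, replica, well, FOV, timepoint, compound, dose,
MoA, role) and D numeric feature columns; every non-`Metadata_` column is a
feature. A *replica* is one complete experimental run (seeding, dosing,
imaging all plates at all timepoints); a *replicate* is each well receiving
the same treatment. Because each replica re-seeds fresh plates, a **physical
plate** is identified by the pair (plate id, replica id); "same plate"
throughout this package means same pair. Wells are "A01".."P24", doses in
µM, timepoints in hours; DMSO vehicle rows carry role `negative_control` and
a null dose.

Tile/FOV records are aggregated to wells with the per-feature **median**
(robust to a single out-of-focus field; mean selectable). Aggregation is
idempotent and never mixes treatments: conflicting metadata within a well is
an error, not a silent overwrite.

## Synthetic plate generator

The generator emulates the study design — several 384-well plates per
replica, each plate holding every compound at every dose (2 technical wells
per compound per plate by default) plus 40 DMSO wells, 4 FOV per well, five
timepoints over 20 h, doses 0.156–10 µM — with a fully specified generative
model:

```
x = e(dose, t) · emax_c · u_c + b_plate + b_replica + b_(replica,fov) + ε
e(dose, t) = dose^h / (dose^h + EC50^h) · t / max(t)
counts ~ Poisson(count_base · (1 − count_inhibition_emax · e(dose, t)))
```

* `u_c` is a unit effect direction: a shared per-MoA direction plus a
  per-compound jitter (`moa_direction_jitter = 0.25`), so mechanism classes
  are linearly recoverable but compounds are not clones.
* Batch offsets are drawn **once per level** from isotropic Gaussians
  (σ_plate = 0.5, σ_replica = 1.0, σ_fov = 0.5 by default, record noise
  σ_noise = 1.0) — the additive model that mixture-model batch integration
  assumes. Replica offsets are deliberately the largest: run-to-run
  variation dominates in live imaging.
* Default `count_base = 120` nuclei per 20× FOV is a typical U2OS seeding
  density; confluency is generated as a noisy linear companion of the count
  rate so the two % Inhibition metrics agree strongly, as coarse viability
  metrics do in practice.
* Ground-truth activity: a condition is truly active when
  `emax_c · e(dose, t) ≥ margin`, with margin = σ_noise/2 by default. The
  margin ties truth to detectability; an unobservable 10⁻³σ effect is not a
  meaningful "active" label.
* Reproducibility: all draws come from PCG64 child streams keyed by
  (seed, purpose, level id), so enlarging one design level never shifts
  unrelated draws and fixtures are bit-stable across platforms.

What the generator does **not** emulate: non-additive (multiplicative or
feature-correlated) batch effects, spatial plate gradients, well-position
effects, heavy-tailed embedding noise, compound aggregation/precipitation at
high dose, or time-varying batch drift. Tests passing on this generator show
the pipeline recovers its own model family faithfully; they do not prove the
additive-batch assumption holds for any particular microscope.

## Normalization

**MAD + Robustize** is applied per measurement — fixed grouping
(plate id, timepoint) — against that group's DMSO wells, with the Gaussian
consistency constant 1.4826. A feature with zero DMSO MAD in a group is
centered and divided by ε = 1.0 instead (logged warning): near-constant
features must not explode. After this step the DMSO per-feature median is
exactly 0 and scaled MAD exactly 1 in every group.

**Harmony-style integration** (in `lcd/_harmony.py`) implements the
soft-k-means + diversity-penalty + per-cluster ridge mixture-of-experts
scheme on the feature matrix directly (no PCA first: the features are
already a learned embedding). Covariates are replica — and FOV for the
`/FOV` variant, treated as categorical with plate-agnostic levels — entering
as stacked indicator blocks. Defaults and their rationale:

* clusters `K = min(30, n/200)`: few, well-populated clusters, so every
  (cluster, batch) cell has enough weight for a stable offset estimate.
  Large K (hundreds of thin clusters) demonstrably under-corrects here.
* diversity penalty θ = 2, assignment softness σ = 0.1 (standard values),
  ridge λ = 0.1 on batch terms only — the cluster intercept (the biology) is
  never penalized or subtracted.
* correction is recomputed from the *original* matrix each round with the
  current soft assignments; rounds refine rather than accumulate.
* stopping: the round-to-round relative correction change decays
  geometrically and then plateaus at a small floor set by assignment jitter;
  iteration stops at `delta < 1e-3` or when the decay flattens (delta >
  0.95 × previous). Exhausting `max_iter = 20` without either raises a
  warning and returns the best iterate.
* order of operations is fixed: MAD per measurement → concatenate →
  integrate once globally.

On DMSO wells of the default batch fixture, a replica-identity logistic
probe reads accuracy 1.0 after MAD alone (3 replicas, chance 1/3) and ~0.29
after MAD + Harmony/FOV; k-NN batch-label agreement never worsens.

## Activity: mAP-ES

Each resample produces **one** average-precision value: a query well of the
condition, 3 positives (same treatment, different plate AND different
replica — the strongest batch contrast), 31 negatives (DMSO from the query's
physical plate — the weakest batch contrast), ranked by cosine similarity to
the query (negative Euclidean selectable). 1000 resamples form the
condition's mAP distribution. Sampling is without replacement within a
resample, independent across resamples, from child streams keyed by
condition, so conditions can be computed in any order or in parallel.

The null distribution repeats this with DMSO queries and DMSO positives, per
**timepoint stratum** (DMSO has no dose; pooling across timepoints would mix
confluency regimes). Exact similarity ties — common in degenerate tests,
measure-zero in real embeddings — are broken by a seeded random shuffle
before a stable sort, making tied orderings uniformly random.

mAP-ES is Cohen's d with the pooled unbiased SD (the standard definition; a
zero pooled SD returns a signed-infinity sentinel with a warning). A
condition is active at mAP-ES ≥ 0.8, the conventional "large effect" cutoff.

A finite-sample caveat discovered during calibration testing: a compound's
mAP distribution is *conditional on its realized wells*. With few wells per
condition (≈12) this conditional distribution is measurably different from
the marginal null even for a true zero effect — not a bias of the method
(mean effect sizes stay near 0 and no false activity calls result), but
two-sample tests against the null at 1000 resamples will reject. At the
study's own dimensions (8 plates × 7 replicas ≈ 112 wells per condition) the
artifact vanishes; calibration checks therefore run at those dimensions.

## Cell-count baseline and % Inhibition

Counts are Z-transformed per (plate id, timepoint) against DMSO mean and
unbiased SD, kept at FOV level. "All replicates without prior aggregation"
is read literally: the activity CI pools every FOV-level normalized count of
the condition across wells, plates and replicas. The CI is a percentile
bootstrap of the median (10,000 resamples by default; the simplest method
consistent with a bare "bootstrap" specification), active iff the upper
bound is below zero. Empirical coverage at n = 40 Gaussian samples is
93–95% over 500 simulations — the familiar mild undercoverage of the
percentile method at moderate n.

% Inhibition is `100·(mean(Metric_DMSO) − Metric_compound)/mean(Metric_DMSO)`,
affine in the compound metric with slope −100/mean(DMSO); a zero DMSO mean
is a domain error.

## MoA classification

Per (dose, timepoint): standardize features on the training split, fit L2
multinomial logistic regression (C = 1) on wells of compounds active at that
condition plus all DMSO wells as an explicit DMSO class — so weak compounds
can honestly be predicted "vehicle-like". Activity filtering applies to
*training only*; at prediction time every compound is scored at every
usable condition. Conditions where filtering leaves only DMSO are skipped;
if no condition in an aggregation window is usable, the fallback prediction
is DMSO.

Per-compound probabilities are softmax averages over wells, reindexed onto
the global class list (a class absent from one probe's training set gets
probability 0 there) and aggregated across conditions by weighted averaging
— uniform weights by default, ascending-dose inclusion with all timepoints
per dose. Aggregation preserves the probability simplex.

Cross-validation assigns **compounds** (never wells) to 5 folds, stratified
by MoA via per-class shuffled round-robin with a rotating start; classes
smaller than k trigger a best-effort warning. McNemar's test uses
`(b − c)²/(b + c)` without continuity correction against χ²₁, switching to
the exact two-sided binomial when b + c < 25; b + c = 0 returns (0, 1).

## SSL objectives

Pure-NumPy contracts for the upstream training losses: DINO cross-entropy
with per-batch EMA teacher centers (τ_student = 0.1, τ_teacher = 0.04,
momentum 0.9 — the standard schedule's defaults; only the learning schedule
itself is out of scope here), Barlow Twins with batch-standardized views
(zero-SD columns get SD + 1e-12 so degenerate toy batches stay finite) and
off-diagonal λ = 0.5, combined 1:1. The crop sampler enforces the
cross-batch constraint (two global crops from two distinct replicas of the
same condition, three local crops per global source) and plane-agnostic
augmentation (every crop's focal plane uniform over the z-stack). Center
updates run per call (per step); no optimizer, scheduler or backbone is
included.

## Problem sizes used in tests

Test fixtures are scaled to the structure that each property needs: recovery
and batch tests use 2 plates × 3 replicas (6–30 compounds, D = 32–64);
calibration uses the full 8 × 7 plate/replica grid with 6 compounds; the
MoA study uses 10 MoA × 3 compounds × 4 doses × 2 timepoints. The full
suite runs in under a minute on one CPU.

## Known limitations

* The Harmony-style correction assumes additive, cluster-wise-constant batch
  offsets; multiplicative or nonlinear batch effects are out of model.
* The generator's effect model is separable in dose and time (Hill × linear
  ramp); real compounds show richer kinetics (delayed onset, washout).
* mAP-ES values for very small well counts are noisy (see the conditional
  caveat above); activity *calls* remain well calibrated but the effect
  sizes themselves should not be compared across very different well counts.
* The MoA probe is linear by design (a representation-quality readout, not a
  production classifier); per-dose learned aggregation weights are exposed
  but default to uniform.
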