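# Methods

This note documents the models, conventions and design choices behind
`cnvpheno`, in the order data flows through the pipeline.

## Coordinate frame and data model

Volumes are arrays indexed `(bscan, ascan, depth)` with 0-based indices and
depth increasing posteriorly. Surfaces assign one float depth (in voxels)
per en-face position; a voxel `k` lies in the slab between surfaces `a` and
`b` iff `a <= k < b` (half-open intervals). All features are computed in
physical units from the voxel spacing `(fast lateral, slow lateral, axial)`
in µm. Three geometry presets share the same 6 × 6 × 2 mm field:

| preset | grid (bscan × ascan × depth) | spacing (µm) |
|---|---|---|
| `full`  | 128 × 512 × 1024 | 11.7 × 47.2 × 2.0 |
| `small` | 64 × 128 × 256   | 46.8 × 94.4 × 8.0 |
| `tiny`  | 32 × 64 × 128    | 93.6 × 188.8 × 16.0 |

`full` matches a Cirrus HD-OCT macular cube; `small` and `tiny` are
proportionally downscaled so cohort-scale experiments run in minutes. The
feature mathematics is resolution-independent (verified by the unit-scaling
audit in the test suite), so the downscaled presets change discretization
noise, not definitions.

The layer stack has 13 surfaces, anterior → posterior: ILM, RNFL-GCL,
GCL-IPL, IPL-INL, INL-OPL, OPL-HFL, ELM, EZ, OS, IZ, IB_RPE, OB_RPE, BM.
Pathology masks are single-label per voxel over {none, IRF, SRF, PED, SHRM};
where lesions overlap during construction the posterior-most compartment
wins (priority PED > SHRM > SRF > IRF, configurable in the contour
rasterizer).

## Bruch's membrane

BM is not segmented; it is constructed as the convex hull of the outer RPE
boundary. The hull is computed **per B-scan** in physically scaled 2-D
coordinates (lateral µm × axial µm) and the posterior (maximal-depth) hull
chain is linearly interpolated back onto the A-scan grid. Per-B-scan rather
than volumetric: the descriptor derivation is B-scan-wise, and a 2-D hull is
well defined under the strongly anisotropic inter-B-scan spacing. The outer
RPE boundary seeds the hull because BM lies posterior to the RPE. The
construction is idempotent, shift-equivariant, and pointwise posterior to
the RPE; over a PED the hull bridges the elevation, recovering the membrane
the RPE would rest on. Degenerate (collinear) profiles are their own hull.

## Synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes, and nothing more:

- **Surfaces**: a smooth posterior baseline (Gaussian-filtered noise, ~1 %
  of the axial range) with all retinal boundaries at fixed fractional
  offsets through a 290–330 µm neurosensory retina, an 18–26 µm RPE band,
  and a foveal pit (90–130 µm, Gaussian profile with 0.35 mm radius) that
  attenuates toward the outer boundaries. The fovea sits at the en-face
  grid centre, which is also where the ETDRS disc is anchored.
- **Lesions**: per-eye total volumes per compartment are drawn from
  log-normal distributions parameterized by class-conditional (mean, sd) in
  mm³ — non-negative and right-skewed, as lesion burdens are. Each total is
  split over 1–3 blobs (Dirichlet weights). SRF/SHRM are half-ellipsoid
  domes that lift the neurosensory retina off the RPE; PED domes lift the
  whole retina + RPE complex off a fixed BM; IRF cysts are ellipsoids
  clipped to the inner retina. Dome aspect ratios (height/lateral radius
  0.2–0.6, lateral anisotropy 0.7–1.4) are jittered per blob, so height and
  width descriptors carry shape noise while volumes track the drawn burden
  directly. Fragments smaller than 3 voxels left where a higher-priority
  lesion carved through a blob are removed as rasterization artifacts.
- **Class structure** (defaults, mean ± sd of volume in mm³): predominantly
  classic SHRM 0.55 ± 0.30 / PED 0.10 ± 0.08; occult SHRM 0.05 ± 0.04 /
  PED 0.60 ± 0.35; minimally classic intermediate in both (SHRM
  0.20 ± 0.14, PED 0.35 ± 0.22); SRF/IRF similar across CNV classes;
  `none` eyes carry zero pathology (cap 10⁻³ mm³). The defaults are chosen
  as clinically plausible burdens that realize the qualitative contrast —
  high SHRM / low PED characterizes predominantly classic CNV, the reverse
  occult — and are validated at construction time. No quantitative per-class
  lesion-size distributions were available to fit, so these are stated
  modelling choices, not estimates.
- **Rendering**: piecewise-constant compartment reflectivities in [0, 1]
  (vitreous 0.05, retina 0.40–0.45, RPE band 0.90, choroid 0.30, fluids
  0.10–0.12, SHRM 0.85) plus additive Gaussian noise (default sd 0.05),
  clipped to [0, 1].

What the generator does **not** emulate: speckle statistics, shadowing and
other scanner artifacts, irregular lesion morphology, segmentation errors in
the layer surfaces, or grader disagreement in the FA labels. Passing tests
therefore demonstrate correctness of the descriptor/classification machinery
and recoverability of a planted effect — not clinical performance on real
scans, which depends on segmentation quality the synthetic rendering cannot
probe.

Seeding: each eye derives its generator streams from
`SeedSequence(cohort_seed, spawn_key=(class, index))`, so cohorts are
byte-reproducible and any single eye can be regenerated in isolation.

## Rule-based segmentation

A deterministic stand-in for a learned fluid segmenter, operating on the
renderer's contrast: voxels are thresholded (dark < 0.25, bright > 0.65)
inside anatomical gates from the layer surfaces — IRF: dark in [ILM, ELM);
SRF: dark in [IZ, IB_RPE); SHRM: bright in [IZ, IB_RPE); PED: dark in
[OB_RPE, BM). Connected components under 3 voxels (26-connectivity) are
discarded to suppress isolated noise flips. On noise-free renderings the
segmentation equals the planted truth exactly; at the default noise level
per-class DICE stays above 0.9 (in practice ≈ 1.0, because the thresholds
sit ≥ 3σ from every compartment intensity).

## ETDRS descriptors

Subfields are **full concentric discs** of radius 0.5 / 1.5 / 3.0 mm (not
annuli): each descriptor name indexes a single radius, and discs keep every
volume/height/width descriptor monotone in radius. An en-face position is
in-disc iff its physical distance from the fovea is ≤ the radius.

Per-B-scan quantities combine across the volume as: **sum** for volumes,
**max** for heights and widths — the C-scan reading of a B-scan-wise
derivation. Height counts labeled voxels per A-scan column (× axial
spacing), tolerating non-contiguity; width is the fast-axis extent
(max − min + 1 columns × fast spacing) of the in-disc footprint, maximized
over B-scans. Slab thickness is (posterior − anterior) depth × axial
spacing; slab volume is thickness summed over in-disc positions × pixel
area.

The default registry enumerates 105 descriptors: {volume, height, width} ×
4 pathology classes × 3 radii (36), plus {mean, min, max thickness,
volume} × 6 slab pairs — (IB_RPE, ILM), (BM, ILM), (BM, OB_RPE),
(BM, IB_RPE), (IB_RPE, OPL-HFL), (OPL-HFL, ILM) — × 3 radii (72), minus the
three `subfield_volume` entries of the (IB_RPE, OPL-HFL) pair, which is
profiled by thickness only (69). The registry is config-driven; names parse
back to their definitions, so alternative enumerations are a one-file
change.

## Classification protocols

- **Plain five-fold CV** (stratified, seeded) for high-signal outcomes
  (CNV vs no CNV): no tuning, no holdout, each eye scored exactly once
  out-of-fold.
- **Holdout tuning** for subtype contrasts: a stratified 15 % holdout is
  split off first and never touched during selection. On the 85 %
  development split, stage 1 runs recursive feature elimination
  (cross-validated curve; the smallest feature set within 0.01 AUROC of the
  best stage is kept), stage 2 grid-searches hyperparameters with the same
  folds ("non-nested": no outer loop). The winner is refit on the full
  development split and scored once on the holdout.
- **External transfer**: the tuned model is applied unchanged to a cohort
  generated on a different scanner geometry; because features live in
  physical units, performance transfers (within 0.05 AUROC in the test
  suite's cross-geometry check).

The learner family is a config choice; the paperless default is a
random-forest ensemble (100 trees, grid over `max_depth` ∈ {None, 4} and
`min_samples_leaf` ∈ {1, 5}) because the pipeline requires internal feature
importances for elimination and ranking; gradient boosting and penalized
logistic regression (importance = |standardized coefficient|) are
alternatives. RFE drops 5 features per round while more than 30 remain,
then 1 — resolution where the curve's elbow lives. The final importance
ranking lists survivors by their last fitted importance, then eliminated
features in reverse elimination order.

## Evaluation conventions

- Dichotomization is `score >= cutoff` everywhere (closed on the positive
  side) — fixed so contingency tables are reproducible.
- AUROC is the mid-rank (tie-corrected concordance) estimator; the ROC
  curve enumerates every distinct score plus a +∞ endpoint, and its
  trapezoidal area equals the rank estimator exactly (asserted
  property-wise in the tests).
- Youden ties are broken toward higher sensitivity (screening context).
- Bootstrap CIs: stratified within class, percentile method, B = 2000 by
  default; stratification guarantees both classes in every resample. Null
  coverage of the 95 % interval is ≥ 93 % over 100 repetitions in the
  acceptance suite.
- DICE with both masks empty is 1.0 (perfect-agreement convention,
  configurable).
- The worked-example contingency tables used in tests and the acceptance
  script (341/41/32/131 development; 102/24/7/32 external) are reported as
  *computed* ratios — 0.8927/0.8037 and 0.8095/0.8205 — i.e. the package
  reports what the counts imply, to four decimals, rather than any rounded
  headline figure.

## Shapley attribution

The estimator is model-agnostic permutation sampling: for each sampled
permutation a random background row is morphed into the explained eye one
feature at a time, and score increments accrue to the switched feature.
The Monte-Carlo residual against the additivity identity
(base + Σ contributions = prediction) is redistributed proportionally to
|contribution|, so local accuracy holds exactly; for a linear model the
estimates converge to the closed form `w_i (x_i − E[background_i])`
(checked within Monte-Carlo tolerance 0.1 at 4000 permutations). The
background defaults to the training split; the default budget is 2048
permutations per eye, and population summaries in the workflow use smaller
budgets (150–256) since variance ranking is far less demanding than
per-eye values. Population impact ranks features by attribution variance;
each feature also carries the sign of the Spearman correlation between its
value and its contribution (direction of effect).

## Problem sizes

Cohort-scale checks use the `tiny` geometry: the fixture cohort is 36 eyes;
the parameter-recovery suite runs 500 eyes (250 occult / 250 predominantly
classic) for each of 3 seeds through the full render → segment → feature →
CV/RFE/attribution path; the acceptance script adds a 240-eye CNV-detection
cohort and 10 eyes for segmentation DICE. These sizes were chosen so the
whole suite completes on a single CPU in minutes while keeping ≥ 100 eyes
per class in the recovery experiments.

## Known limitations

- The rule-based segmenter is tied to the renderer's contrast model; it is
  a pipeline stand-in, not a general OCT fluid segmenter.
- Synthetic lesions are ellipsoidal; real SHRM/PED morphology is far more
  irregular, and real feature distributions will overlap more than the
  defaults do — absolute AUROCs on synthetic cohorts are upper bounds, and
  near-saturated values simply mean the planted effect is clean.
- The minimally classic phenotype is modelled only as intermediate burden;
  the generator makes no attempt to capture its FA-defined lesion-component
  geometry.
- Probabilities are not calibrated; only ranking metrics are reported.
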