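# Methods

`herbgrade` implements a multi-dimensional grading analysis for
*Atractylodis macrocephalae* Rhizoma (AMR, *Baizhu*), a medicinal
rhizome whose commercial grade depends on geographical origin,
cultivation age, and processing. The package reproduces the full
analytical chain on a synthetic cohort whose statistical structure it
also defines: fuzzy-mathematics sensory scoring, OPLS-DA/VIP
differential screening of volatile (HS-GC–MS-style) and non-volatile
(LC–MS-style) compound tables, electronic-nose and electronic-tongue
sensor screening, Spearman correlation mapping, and mid-level PCA
feature fusion into KNN/BPNN/random-forest grade classifiers.

## Study design emulated by the generator

Four specification groups with fixed grade labels: ZJ (grade 1, 10
batches, the genuine-origin material), AH-HN-1 (grade 2, 13), AH-HN-2
(grade 3, 7), HB (grade 4, 9) — 39 batches, five replicate
observations per batch, 195 rows per platform. Replicate-level rows are
used throughout because the classification arithmetic (a 70/30 split of
195 observations giving 135 training and 60 test samples, the
denominators behind accuracies such as 85.19% = 115/135 and
98.33% = 59/60) implies replicate-level data.

Variable panels: 49 volatile compounds (22 flagged as shared peaks),
51 non-volatile compounds annotated with ESI ion mode (30 positive,
21 negative), 18 metal-oxide gas sensors S1–S18, and the 7 taste
sensors AHS, PKS, CTS, NMS, CPS, ANS, SCS. Ten compounds carry real
names because they anchor the planted shared differentials; every
other variable is a placeholder (`V05`…, `N07`…) with a chemical-class
tag — names play no computational role.

## Abundance model

Compound abundances are log-normal:

```
log x[b, r, j] = mu_j + delta[g(b), j] + beta[b, j] + gamma[b] * u_j
               + kappa[r, class(j)] + eps[b, r, j]
```

* `mu_j` — fixed per-compound baseline (deterministic, seed-independent);
* `delta` — the planted group effect, expressed in pooled-SD units
  (pooled SD = within-group replicate-level SD,
  `sqrt(batch^2 + class^2 + replicate^2)` ≈ 0.0176 on the log scale);
* `beta` — per-variable batch-level biological noise (sigma 0.004).
  The tables represent internal-standard-normalised relative contents,
  which is why no large shared concentration factor appears: it cancels
  in the ratio to the internal standard;
* `gamma * u` — a batch-level *analytical confound* (sample-preparation
  variation) that slides each batch along the platform's middle-grade
  axis `u` (the signed direction separating AH-HN-1 from AH-HN-2 over
  the shared differentials); sigma 0.037 for the volatile platform,
  0.011 for the non-volatile one, independent between platforms;
* `kappa` — per-acquisition response drift shared by the compounds of
  one chemical class (sigma 0.016), the part of instrument drift a
  single internal standard cannot cancel;
* `eps` — per-variable technical noise (sigma 0.005).

Planted effects: the four shared volatiles (caryophyllene, γ-elemene,
aromadendrene, atractylone) are shifted (AH-HN-1 +9.6, AH-HN-2 +7.0,
HB −7.0 pooled SDs), producing the mean ordering
AH-HN-1 > AH-HN-2 > ZJ > HB. Nine volatiles shift identically in both
middle grades, twelve only in HB; the per-contrast differential sets
therefore have a union of 25 and a three-way intersection of exactly
the four named compounds. The non-volatile panel mirrors this with six
shared differentials (lactones higher in ZJ, sugars higher in HB,
middle-grade separation 0.5 SD), eight both-middle-grade and eleven
HB-only differentials — union 25, split 17 positive / 8 negative mode.
All single-contrast effects are ±5 pooled SDs; magnitudes this large
(and the small biological noise) describe a tightly controlled,
normalised assay, chosen so the screening criteria below are met with
wide margins. Real cohorts have far larger batch-to-batch coefficients
of variation, so passing these tests demonstrates correctness of the
pipeline, not its power on noisy field data.

## Sensor model

Sensor responses are non-negative linear combinations of latent
channel abundances through fixed loading matrices, times multiplicative
acquisition noise (a per-run gain shared by the array, sigma 0.008,
plus per-sensor noise, sigma 0.009 — together giving a repeated-
acquisition RSD of ≈1.5%, under the 3% repeatability bound). The gas
array's channels are a baseline matrix response, an aroma index
(derived from the realized shared-volatile profile of each batch, so
sensor–compound correlations arise by construction), ZJ and HB process
markers (smoke-drying and seedling cultivation leave end-grade odor
signatures), and a weak growth-age marker for the older middle grade.
The nine informative sensors S17, S11, S1, S18, S13, S12, S14, S5, S7
load on grade-varying channels; the other nine load only on the
baseline. The taste array's single grade-varying channel follows
atractylenolide I (highest in ZJ, lowest in HB) and loads on PKS and
ANS only. Each grade-varying channel carries its own batch-level blur,
independent of the chromatographic confounds — so every platform sees
the middle-grade boundary through different noise, which is what makes
mid-level fusion genuinely better than the best single platform.

Acquisition protocols are modelled at feature level: the gas array
performs consecutive injections and discards the first; the taste
array takes nine readings, discards the first four and averages the
last five.

## Sensory evaluation

Ten evaluators rate each batch on four criteria (sectional color,
chrysanthemum pattern, oil spots, number per kilogram) over four
quality levels. Criterion weights come from the binary-comparison
method with a diagonal-1 convention, so a strict importance ranking
yields weights 4:3:2:1 (0.4, 0.3, 0.2, 0.1); importance ties are
rejected rather than split, matching the 1-point/0-point rule. Level
values default to 90/70/50/30 — the centres of 20-point bands
consistent with the reported grade bands — and the score is
`B = w · M · V` with `M` the membership (evaluator-fraction) matrix.
Bands are lower-closed, upper-open (topmost closed): [60, 80] Grade I,
[40, 60) Grade II; scores outside every band get an explicit
out-of-range label.

The generator draws evaluator counts from a multinomial whose
expectation places the score at a per-batch target: a group base
(ZJ 72, AH-HN-1 70.5, AH-HN-2 52, HB 46) plus 1.5 points per z-unit of
the batch's caryophyllene, γ-elemene, aromadendrene and atractylenolide
I levels. The two top targets deliberately interleave: ZJ scores
highest overall while the middle grades carry more of the shared
volatiles, and without interleaving the score–terpene Spearman
correlation would sit exactly at the significance boundary.

## Chemometrics

OPLS-DA is implemented from first principles. Predictors are
mean-centred and unit-variance scaled (the default of the software
ecosystem this models; preprocessing parameters are refit inside every
cross-validation training fold). Y-orthogonal components (default one)
are deflated before a NIPALS PLS2 predictive fit; the orthogonal
weight is projected out of the column space of `X'Y`, which makes the
orthogonal scores exactly uncorrelated with every class column. Class
coding is a single centred 0/1 column for two classes, a centred
one-hot block with `K − 1` predictive components otherwise. Predictive
scores are oriented so the first class's mean score is negative.

VIP is computed over the predictive components,
`VIP_j = sqrt(p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a)`, so
`mean(VIP^2) = 1` exactly; screening keeps variables strictly above 1.
`Q^2 = 1 − PRESS/SS` uses seeded stratified 7-fold cross-validation
(leave-one-out when the fold count equals the sample count). The
permutation test (default 200 permutations) refits the model and `Q^2`
under shuffled labels and reports the add-one empirical p-value;
models are called valid at p ≤ 0.05, with the SIMCA-style intercept
diagnostics reported but not used as the gate. When rows are
replicates, labels are permuted across batches (block permutation) —
replicates of one batch share their label by design, and row-level
shuffling would overstate the observed model's advantage. An optional
validity gate empties the differential set of any model that fails the
permutation test; with the gate on, null data yields almost no flags.

Pairwise screening contrasts each lower grade against ZJ on
replicate-level rows (a batch-mean option exists; at 17–23 batches the
sampling noise of variable–class correlations makes exact set recovery
unattainable). The non-volatile platform is screened as one panel with
per-mode counting via the ion-mode annotation; a per-mode modelling
option mirrors the two ESI acquisitions. Sensor arrays are screened
with a single four-class model. Spearman correlation uses tie-corrected
average ranks with two-sided t-approximation p-values (α = 0.05, no
multiplicity correction by default; Benjamini–Hochberg can be applied
downstream); constant columns give missing values, never zero.

## Fusion and classification

Each platform is autoscaled and reduced to the smallest number of PCA
components reaching 95% cumulative explained variance (deterministic
component signs; the rotation is fitted on the full matrix before
splitting, matching a features-first-then-split workflow, with a
leakage-free fit-on-train variant behind a flag). Score blocks are
concatenated with per-column provenance. The seeded stratified 70/30
split takes floor(0.7 n) training rows (136/59 for 195); the
`study_size` flag keeps the pure per-class floors (135/60), the sizes
the study arithmetic back-calculates to. Classifiers use the stated
fixed hyperparameters: KNN with K = 2 (Euclidean, the even-K vote tie
resolved toward the nearest neighbour via distance weighting), a
single-hidden-layer network with 5 sigmoidal units, softmax output,
cross-entropy loss and at most 1000 iterations, and a 500-tree random
forest with 3 candidate variables per split. Reports carry train/test
accuracy and the 4×4 confusion matrix; replicate-level splits inflate
absolute accuracies (replicates of one batch can cross the split), and
the batch-grouped split exists for honest generalisation estimates —
the no-signal calibration test uses it.

## Numerical choices and limitations

* All randomness flows from named `SeedSequence` substreams of one
  master seed; equal inputs give byte-identical tables, and adding a
  pipeline stage never perturbs earlier stages' draws.
* NIPALS runs to a 1e-12 relative score tolerance; degenerate fits
  (constant labels, classes with one member, orthogonal components
  beyond the structured rank, zero explained Y-variance for VIP) raise
  errors rather than returning silently.
* Zero-variance columns are dropped with a record by default
  (configurable to an error).
* The generator validates its inputs (unknown compound ids and sensors
  are named; non-positive sigmas rejected); the standalone acquisition
  simulators accept zero sigmas so noiseless protocols can be tested.
* What the cohort does **not** emulate: chromatograms or sensor
  response curves (only the feature values the analysis consumes),
  missing values, batch-effect drift over acquisition order, realistic
  biological variance, or any deviation from log-normality. Results on
  this cohort validate the implementation, not field performance.
* Problem sizes in the test suite (e.g. 20-seed recovery and
  classification sweeps, 50-run permutation-null calibration at
  24×8) were chosen to estimate the relevant rates with comfortable
  margins at interactive runtimes.
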