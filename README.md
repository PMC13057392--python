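# herbgrade

Multi-platform chemometric grading of *Atractylodis macrocephalae*
Rhizoma (AMR, *Baizhu*), a medicinal rhizome whose commercial grade
reflects origin, cultivation age, and processing. The package is aimed
at analysts who combine chromatographic compound tables with
electronic-nose/-tongue sensor arrays and sensory panels to build and
validate grading models — and at anyone who wants a fully synthetic,
seeded test bed for that kind of multi-platform workflow.

It implements, as a tested library plus CLI:

* **Fuzzy comprehensive sensory evaluation** — binary-comparison
  criterion weights `w` (a strict ranking of four criteria gives
  4:3:2:1), membership-degree matrix `M` of evaluator fractions, level
  values `V`, score `B = w·M·V`, and grade banding (60–80 Grade I,
  40–60 Grade II).
* **OPLS-DA from first principles** — UV scaling, Y-orthogonal
  component deflation, NIPALS PLS2, `R²X`/`R²Y`, stratified
  cross-validated `Q² = 1 − PRESS/SS`, label-permutation validation
  (block permutation over batches), and VIP scores normalised so
  `mean(VIP²) = 1`. Differential compounds and sensors are the
  variables with VIP > 1; "shared" differentials are those flagged in
  every pairwise contrast against the reference grade.
* **Sensor-array screening and correlation maps** — four-grade
  multiclass OPLS-DA on the 18-sensor gas array and 7-sensor taste
  array; tie-corrected Spearman maps between sensors, compounds, and
  sensory scores.
* **Mid-level data fusion** — per-platform PCA scores at 95%
  cumulative explained variance, concatenated and fed (70/30 seeded
  stratified split) to KNN (K = 2), a 1×5-unit backpropagation network
  (≤1000 iterations), and a 500-tree random forest (mtry = 3).
* **A synthetic cohort generator** — 39 batches in four grade groups
  (10/13/7/9) with five replicates each, log-normal compound tables
  with planted grade effects, latent-channel sensor responses, and
  evaluator counts coupled to four named compounds. Every downstream
  stage is testable offline and byte-reproducible from one seed.

See `docs/methods.md` for the model details and their rationale.

## Worked example

```python
import herbgrade as hg
from herbgrade.sensory import PairwiseComparison, binary_comparison_weights, batch_scores
from herbgrade.synthetic import CRITERIA

ds = hg.generate_dataset()            # default design, seed 42

w = binary_comparison_weights(PairwiseComparison.from_ranking(CRITERIA))
print(batch_scores(ds.evaluator_counts, w).head(3))
#  batch_id  score grade_band
#     ZJ-01   72.2    Grade I
#     ZJ-02   71.8    Grade I
#     ZJ-03   70.4    Grade I

vol = hg.screen_compounds(ds, "volatile")
print(len(vol.union), sorted(vol.shared))
# 25 ['aromadendrene', 'atractylone', 'caryophyllene', 'γ-elemene']

print(hg.screen_sensor_array(ds, "etongue").variables)
# ['ANS', 'PKS']

table, reports = hg.compare_sources(ds)
print(table.pivot(index="source", columns="classifier", values="test_accuracy").round(3))
# classifier    bpnn    knn     rf
# enose        0.780  0.746  0.780
# etongue      0.746  0.678  0.729
# fused        0.763  0.881  0.881
# nonvolatile  0.797  0.695  0.881
# volatile     0.864  0.780  0.864

print(hg.modal_confusion(reports))
# ('AH-HN-1', 'AH-HN-2')
```

Reading the output: the genuine-origin ZJ batches score in the 70–80
band; pairwise VIP > 1 screening of the three lower grades against ZJ
flags 25 volatile differentials whose intersection is the four named
terpenoid markers; the taste array's discriminating sensors are PKS
and ANS; and across every data source the classifiers' residual
confusion concentrates on the two middle grades, whose chemical
profiles are planted closest together — the fused feature block is
where the random forest matches or beats the single platforms.

The same stages are available from the shell:

```
herbgrade simulate --seed 42 --out-dir results
herbgrade grade --counts results/data/evaluator_counts.csv
herbgrade screen --platform volatile
herbgrade classify --seed 42
herbgrade run-all --seed 42 --out-dir results    # full pipeline + manifest
```

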