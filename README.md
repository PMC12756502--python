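# docrefine

Identifying *representative* patients in disorders-of-consciousness (DOC)
cohorts from resting-state functional connectivity.

## The problem

Distinguishing unresponsive wakefulness syndrome (UWS, also called the
vegetative state) from the minimally conscious state (MCS) is one of the
hardest calls in clinical neurology: behavioral misdiagnosis rates run as
high as ~40%. Any supervised classifier trained on such labels inherits the
label noise. `docrefine` implements a data-driven procedure that combines
the behavioral assessment (Coma Recovery Scale-Revised, CRS-R, total score
0–23) with whole-brain functional connectivity to select the patients whose
neural features are *consistent* with their clinical label — a clean
training subset — and to flag the rest as excluded (likely mislabeled or
atypical).

## The method

For each subject with ROI time series over *n* = 116 anatomical regions,
functional connectivity is the Pearson correlation of every region pair
(6,670 = 116·115/2 edges), Fisher transformed, z = atanh *r*. Comparing two
groups edge-by-edge with two-sample *t*-tests (*p* < 0.05) yields a
*decreased* and an *increased* significant-edge set, and each subject's

- **DCI** (decreased connectivity index) = mean z over the decreased edges,
- **ICI** (increased connectivity index) = mean z over the increased edges,

define a 2-D feature space into which any subject can be projected.

The refinement is EM-like. Seed with UWS patients scoring CRS-R ≤ 5
(misdiagnosis is unlikely at very low scores); contrast seed vs. healthy
controls (HC); fit bivariate-Gaussian group models (μ, Σ) and their 90%
confidence ellipses, (x−μ)ᵀΣ⁻¹(x−μ) ≤ χ²₀.₉(df=2) = 4.605. The E-step
re-selects exactly the UWS patients inside the UWS ellipse; the M-step
recomputes contrast, features and models; iterate until label or centroid
(‖Δμ‖ < 10⁻⁴) stability, at most 3 iterations, with optional greedy
boundary fine-tuning that only accepts moves lowering

L = Σᵢ∈UWS d²(xᵢ, μ_UWS) + Σᵢ∈HC d²(xᵢ, μ_HC) − λ·d²(μ_UWS, μ_HC).

At convergence, UWS patients inside the final ellipse are representative;
MCS patients *outside* it are representative. Partitions are validated by
500 random half-split linear-SVM classifications in the [DCI, ICI] plane.

A fully synthetic cohort generator (`synthetic_cohort`) with planted
representative/mislabeled structure makes the pipeline testable end to end;
the packaged clinical table provides the real cohort's demographics, labels
and CRS-R scores.

## Worked example

```python
import docrefine as dr

# a synthetic study-scale cohort: 20 HC, 58 UWS (31 planted representative),
# 30 MCS (23 planted representative), 116 regions, 206 volumes
cohort, timeseries, truth = dr.simulate_cohort(dr.CohortBlueprint(rng_seed=1))
edge_vectors = dr.compute_edge_vectors(timeseries)

result = dr.refine(cohort, edge_vectors, dr.RefinementConfig())
print(len(result.representative_uws), len(result.representative_mcs),
      result.converged_by, result.final_state.iteration)

scheme = dr.SplitScheme(n_group1=len(result.representative_uws),
                        n_group2=len(result.representative_mcs),
                        n_repetitions=500, rng_seed=11)
dist = dr.classify_repeated(sorted(result.representative_uws),
                            sorted(result.representative_mcs),
                            scheme, edge_vectors=edge_vectors)
print(dist.summary())
```

prints

```
27 25 label_stability 2
95.9%
```

— 27 of the 58 UWS and 25 of the 30 MCS patients are retained as
representative, with membership stable after two iterations, and the two
representative groups separate at 95.9% mean test accuracy over 500 random
half-splits. The same cohort classified with its raw labels reaches only
70.0%, and excluded-UWS versus representative-MCS 59.0% — the ordering
that motivates cleaning the labels before training a classifier.

The same steps are available from a shell:

```
docrefine simulate --out cohort/ --rng-seed 1
docrefine refine --manifest cohort/manifest.csv --out refined/ --plot
docrefine classify --manifest cohort/manifest.csv --group1 ... --group2 ... --out clf/
```

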