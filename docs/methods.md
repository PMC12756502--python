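# Methods

## Model and procedure

`docrefine` operates entirely on preprocessed ROI time series (rows = time
points, columns = regions); acquisition, realignment, nuisance regression
and filtering are upstream concerns and out of scope. For a subject with
*n* regions, the connectivity matrix is the Pearson correlation of region
pairs; the strictly-upper-triangular edges, in the canonical (i < j)
row-major 0-based order shared by every module, are Fisher transformed
(z = atanh *r*; variance-stabilizing, approximately normal with variance
1/(T−3) for T time points). Perfectly collinear pairs (|r| = 1) are
rejected rather than clamped because atanh diverges there and a silent ±∞
would poison every group mean downstream.

An edgewise contrast between groups 1 and 2 applies a two-sided pooled-
variance Student's t-test per edge (Welch available via `equal_var=False`)
at level α = 0.05, strict inequality, with no multiplicity correction by
default — the edge mask is a feature-selection device, not an inference;
Bonferroni/Benjamini-Hochberg hooks exist but default off. Edges
significant with group 2 below group 1 form the *decreased* set, the
others the *increased* set. DCI and ICI are means of a subject's edge
values over those sets; both are taken on the Fisher-z scale by default
(`mean_on="z"`), keeping tests and indices on one scale, with `mean_on="r"`
available for averaging back-transformed correlations instead.

The refinement alternates:

* **M-step** — given a selected-UWS set, recompute the HC-vs-selected
  contrast, re-project every subject (selected, excluded, MCS, HC) into
  the resulting [DCI, ICI] space, refit both group models (centroid =
  mean; covariance = sample covariance, divisor n−1), and evaluate the
  monitoring objective L (below).
* **E-step** — re-select exactly the UWS patients whose feature vector
  lies inside the UWS group's 90% ellipse, d² ≤ χ²₀.₉(df=2) = 4.605,
  boundary inclusive. HC membership is never updated; only its model is
  refit as the feature space moves.

Stopping: membership unchanged (label stability), or the concatenated
(μ_UWS, μ_HC) centroid shift dropping below 10⁻⁴, or 3 iterations — the
procedure empirically stabilizes in 2–3 and the cap guarantees
termination. The final assignment reads containment off the final ellipse
for both patient groups: UWS inside are representative, MCS inside are
UWS-like and therefore excluded. We read the final membership from the
ellipse rather than from the last E-step because the two can disagree at
the iteration cap, and the containment reading is the one the assignment
rule itself defines; it also makes the UWS and MCS rules symmetric.

The objective
L = Σ_selected d²(xᵢ, μ_UWS) + Σ_HC d²(xᵢ, μ_HC) − λ·d²(μ_UWS, μ_HC),
with λ = 1 by default, is used for monitoring and fine-tuning only — the
E/M updates are the ellipse rules, which the operational procedure
actually executes. Each within-group distance uses that group's own
covariance; the between-centroid term uses the pooled within-group
covariance (symmetric, standard, reduces to Euclidean for identity
covariances — a choice we make because a two-group distance needs a single
metric). Optional fine-tuning considers UWS patients with d² within
(1 ± 0.1)·χ² of the boundary ("near" the ellipse is otherwise
unquantified) and greedily toggles membership, keeping only toggles that
strictly decrease L, so L is non-increasing and the sweep terminates.

Numerical safeguards: group models need ≥ 3 members (a 2-D covariance is
otherwise degenerate); a ridge ε·I with ε = 10⁻⁸·tr(Σ)/2 is added only
when the covariance's condition number exceeds 10⁸ (13-point seed clouds
can be nearly collinear); matrices asymmetric beyond 10⁻¹⁰ are rejected;
a selected set shrinking below 3 aborts with the full trace attached.

## Validation harness

Two groups are compared by repeatedly (500×) splitting each group into a
training half (⌈n/2⌉, a deterministic convention recorded in the scheme)
and a test half, fitting a linear-kernel SVM (C = 1, no class weights) on
the training [DCI, ICI] points, and scoring test accuracy. Features are
standardized using training-half statistics only: the raw feature scale
depends on the contrast that defined it, and an unstandardized unit-C
margin underfits badly when that scale is small (we observed chance-level
training accuracy on 4σ-separated clusters) — standardization makes the
harness scale-invariant without touching the C = 1, linear-kernel choice.

Under the default `train_only_mask` policy the contrast — and hence the
feature space — is recomputed from the training subjects of each
repetition and test subjects are only projected, so no test information
enters feature construction. `whole_sample_mask` reuses one contrast over
all subjects, mirroring protocols that select the mask on the full sample;
for overlapping groups it is optimistically biased (the mask has seen the
test subjects), and the package documents this direction with a test. A
repetition whose training contrast yields an empty edge set is recorded as
NaN and counted, never silently dropped.

## Synthetic cohort generator

The generator emulates what the method assumes about DOC cohorts, with
defaults matching the study scale: 116 regions, 206 time points, 20 HC,
58 UWS (31 representative + 27 MCS-like mislabeled), 30 MCS (23
representative + 7 UWS-like mislabeled); 5% of edges decreased by −0.3 and
2% increased by +0.2 (correlation scale) in the fully altered profile,
half shifts in the intermediate profile shared by the mislabeled-UWS and
representative-MCS groups; 13 representative-UWS patients with CRS-R ≤ 5
(scores 3–5), other UWS 6–7, MCS 6–18, HC none.

Structure, and why each piece exists:

* **Base connectome** — a 6-factor loading model normalized to a
  correlation matrix (moderate positive and negative couplings, strictly
  positive definite). Optional per-subject loading jitter exists but
  defaults off.
* **Planted edge shifts with compensated PD projection** — shifting
  hundreds of random edges by ±0.3 makes the matrix indefinite (smallest
  eigenvalue ≈ −1.1 at default density), and any positive-definite
  projection necessarily shrinks the realized shifts by ~30% while
  spreading small "spillover" differences over unplanted edges. We
  project by eigenvalue clipping with diagonal renormalization and then
  rescale the requested deltas twice so the realized mean shift on each
  planted set lands within ~10% of target. The spillover that remains is
  treated as genuine diffuse signal — real group differences are not
  confined to a sparse edge list either.
* **Bounded severity disk** — each patient draws a pair of multipliers on
  the decrease/increase deltas, uniform on a disk of radius 0.3 around
  the class center (1 full, ½ intermediate, 0 HC). Severity within a
  diagnostic class is bounded, so the clusters are compact: a uniform
  elliptical cloud has maximal squared Mahalanobis distance 4 < 4.605,
  which is what lets a 90% ellipse fitted on ~13–30 points actually
  contain its class. With Gaussian severity tails the out-of-sample
  containment of a fitted 90% ellipse caps near 85% regardless of scale,
  and the refinement cannot reach high membership recovery — a property
  of the ellipse rule, not of the implementation.
* **Severity-graded global coupling** — every off-diagonal correlation is
  scaled by 1 − 0.25·severity, emulating the diffuse global
  hypoconnectivity of low-consciousness states. Beyond realism this
  matters statistically: it fills the significant-edge mask with genuine
  graded differences, diluting the pure false-positive edges whose
  selection noise otherwise biases the mask-defining subjects' own
  features relative to equally affected non-members (a circularity
  inherent to recomputing the mask from the current selection).
* **Observation noise** — i.i.d. Gaussian with SD 0.3 added to unit-
  variance signals; it keeps empirical |r| < 1 and mildly shrinks
  correlations (factor ≈ 0.92).
* **Sampling** — time points i.i.d. from the subject's covariance. Real
  BOLD has autocorrelation, motion and physiological structure; none of
  that is modeled because the pipeline consumes only Pearson
  correlations, for which i.i.d. sampling is sufficient. Passing tests
  therefore demonstrate correctness of the method's statistics and
  geometry, not robustness to fMRI artifacts.

`null_blueprint()` zeroes all class effects (both deltas and the coupling
slope — the slope is a class effect of this generator, so "no planted
effects" must include it). Calibration checks of the edgewise test run the
null with an identity base (`base_loading_sd=0`): under the factor-model
base, t-statistics are correlated across edges and the significant-edge
fraction fluctuates far beyond the binomial band that an
independent-edges calculation predicts.

Under the default blueprint the full pipeline recovers planted
representative/excluded membership at ≈ 91–92% agreement averaged over 20
generator seeds, within the 3-iteration cap; the residual disagreement is
dominated by the finite-sample geometry of small-n ellipse fits at the
cluster boundaries and the mask-recomputation circularity described above.

## Problem sizes and determinism

Default test and acceptance runs use the full 116-region, 108-subject
cohort for end-to-end checks (one simulate-plus-refine cycle takes a few
seconds), a 20-region preset for unit-level pipeline tests, 500-repetition
split schemes for accuracy distributions, and 10⁵ draws for ellipse
coverage. Every stochastic component is driven by an explicit seed:
generator outputs are bytewise reproducible, split schemes derive each
repetition's permutation from (seed, repetition), and the refinement loop
itself is deterministic given its inputs.

## Known limitations

* The generator's inter-subject variability is trait-driven (severity,
  coupling); it does not reproduce the broad idiosyncratic connectome
  differences of real cohorts, which would loosen the clusters.
* DCI/ICI average on the z scale by default; the alternative r-scale
  averaging is implemented but changes numbers slightly.
* Fine-tuning's stopping rule ("strict decrease of L over a fixed
  candidate band") is this package's formalization of an otherwise
  qualitative step.
* The MCS assignment uses the UWS ellipse only; the HC ellipse is
  visualization.
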