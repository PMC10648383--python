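# Methods

## Shape model and superimposition

A specimen is an ordered configuration of k = 18 landmarks in 2D (wing-vein
intersections, digitized in a consistent order). Size is measured by centroid
size, CS = √Σᵢ‖xᵢ − x̄‖²; shape is what remains after similarity nuisances
are removed by generalized Procrustes analysis:

1. center each configuration and record CS;
2. scale to unit centroid size (preshape);
3. initialize the consensus as the first preshape;
4. rotate every preshape onto the consensus by the proper-rotation Kabsch
   solution (SVD of the 2×2 cross-covariance with determinant sign
   correction — reflections are never absorbed);
5. re-estimate the consensus as the coordinate-wise mean, re-centered and
   rescaled to unit CS;
6. iterate 4–5 until the decrease of Q = Σ_specimens ‖alignedᵢ − consensus‖²
   falls below `tol` (default 1e-10, far below any biological signal;
   `max_iter` 100, non-convergence is recorded, not fatal).

GPA output is defined only up to a global rotation. The gauge is fixed by
rotating the converged consensus — and all aligned configurations with it —
to best match the first specimen's original orientation. This makes outputs
byte-stable; the cost is that the absolute output orientation follows
specimen 1, so coordinate-level comparisons across differently-oriented
copies of a dataset must be made modulo one common rotation (gauge-invariant
quantities — distances, variances, accuracies — are unaffected, and the test
suite checks both).

Tangent projection (on by default) maps each aligned shape vector v to
v + (1 − v_c·v) v_c, with v_c the flattened consensus; this orthogonal
projection flattens the shape sphere at the consensus so the downstream
linear statistics operate in a Euclidean space. At this study's shape
variances (Procrustes deviations ~0.04) the projection moves coordinates by
< 1e-3 and no conclusion depends on it; both paths are exposed and the
difference is quantified in the tests.

Reflection handling is a data contract, not a transform: all wings must be
digitized with one chirality (e.g. all left wings). `validate_dataset` warns
when the signed area of the landmark polygon changes sign across records.

## Inferential statistics

All tests run per sex; mosquito wings are sexually dimorphic in size and
shape, and pooling sexes confounds species contrasts. A pooled mode exists
for exploration and warns loudly.

**Size ANOVA.** Classical one-way F on centroid size with the parametric
F-distribution p; optional permutation p by label shuffling. The pipeline
default reports the parametric p (no permutations), matching how a plain
size ANOVA is conventionally reported; permutations are a config switch.

**Allometry.** Shape-on-size Procrustes regression: each of the 2k
coordinate columns is regressed on CS (raw CS by default; log CS via
config — the choice is a documented ambiguity, and at CV ≈ 5% the two are
nearly affine so R² barely moves). Column-wise explained and residual sums
of squares are summed into Procrustes sums of squares; R² = SS_model/SS_total
and F = (SS_model/1)/(SS_resid/(n−2)). Significance comes from fully
randomizing the specimen-to-size assignment — for a single-predictor model
this coincides with residual randomization under the intercept-only reduced
model. p = (c+1)/(N+1) with the observed statistic counted among the
permutations; Z = (F_obs − mean F_perm)/sd F_perm on the untransformed F
(the simplest standardized effect size; labeled as such in reports).

**Disparity.** Morphological disparity is the mean squared Procrustes
distance from the group mean with denominator n (a *mean*, not an unbiased
variance; users comparing against n−1 conventions should rescale by
n/(n−1)). Pairwise group contrasts |PV_a − PV_b| get permutation p-values by
label shuffling.

**Observer analyses.** On the replicated-digitization subset (each selected
wing measured once by each observer): (a) one-way permutation ANOVA of CS on
observer — note that on a fully crossed design this test is structurally
conservative under free permutation, because every observer measures the
same wings and the observed F is forced toward zero (visible as negative Z
scores); specimen identity is deliberately *not* modeled as a block, since
the single-factor design is what the standard toolchain runs; (b)
within-specimen Procrustes variance (mean over wings of the PV of that
wing's replicates) against within-species PV computed on one measurement per
wing — their ratio is the repeatability proxy; (c) LOOCV-LDA on the
replicate set, to express observer noise on the accuracy scale. With r
replicates the denominator-n PV estimator has expectation
((r−1)/r)·(2k−4)σ²_obs — the finite-sample factor matters at r = 3 and is
used wherever an expectation is quoted.

## Classification

Superimposition removes 4 of the 2k degrees of freedom, so raw superimposed
coordinates have a singular pooled covariance. LDA therefore runs on
full-rank PCA scores (all components above 1e-12 of the leading eigenvalue,
capped at n − 3 so every leave-one-out fold keeps an invertible pooled
covariance). This is an orthogonal rotation of the data: results are
identical to any generalized-inverse treatment of the raw coordinates, and a
raw-coordinate mode exists for well-conditioned feature sets.

The discriminant is the two-Gaussian equal-covariance rule: pooled
within-class covariance W (divisor n − 2), direction w = W⁻¹(μ₁ − μ₂),
threshold midway between projected class means shifted by ln(π₁/π₂); priors
proportional to class frequencies by default (equal priors via config);
posteriors from the logistic form of the model. Decision ties (score exactly
0) go to class 1 deterministically and are counted.

Cross-validation leaves one specimen out and refits the LDA per fold, but
the GPA and the PCA basis are computed once on the full sample — matching
how discriminant toolchains cross-validate precomputed coordinates. This is
mildly optimistic (the held-out specimen influenced the consensus and the
basis); the effect is small at n > 100 and the report records the setting.
A strict per-fold mode was considered and deferred: it changes the question
from "how well does this coordinate system discriminate" to "how well does
the whole pipeline transfer", which the replicate-observer analysis probes
more directly.

`landmark_differences` ranks landmarks by the magnitude of the group
mean-shape displacement and scores each landmark alone with a two-feature
LOOCV-LDA — quantifying that no single landmark suffices.

## Synthetic study generator

`SyntheticSpec` defines a forward model of everything the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| group sizes | 77/70/67/57 | (species × sex) specimens |
| `species_effect_d` | 0.02 | Procrustes distance between species mean shapes |
| `focal_landmark`, `focal_share` | 18, 0.5 | half the species field's norm on the medial-fork landmark, remainder even across the rest |
| `sex_effect_d` | 0.025 | female–male mean-shape distance |
| `cs_means` | 1000/1020/920/920 | lognormal CS means (arbitrary image units; ~2% female species contrast, equal males) |
| `cs_sigma` | 0.05 | sd of log CS (CV ≈ 5%) |
| `allometry_slope` | 0.135 | shape units per unit log CS, giving R² ≈ 0.03 |
| `individual_noise` | 0.0068 | per-coordinate sd ⇒ within-group PV ≈ 1.5e-3 |
| `observer_noise` | 0.0042 | per-coordinate sd ⇒ within-specimen PV ≈ 3.8e-4 |
| replicate design | 20 wings/group × 3 observers | replicated digitization subset |

Shape perturbations (effect fields, noise) are applied in shape space —
centered, unit-size, with the four similarity directions projected out —
*before* the nuisance size/rotation/translation, so σ values are in
Procrustes units and within-group PV calibrates to (2k−4)σ² plus the
allometric variance (βσ_CS)², up to the (n−1)/n estimator factor. Effect
field directions are fixed generator constants (internal seeds independent
of the user seed); the species field's magnitude profile is enforced jointly
with similarity-orthogonality by alternating projection to a fixed point.
Observer noise is i.i.d. across observers by default; an optional
per-observer constant bias field exercises the detection path.

Defaults were chosen once to land at the magnitudes a wing-morphometrics
study of this design reports — within-species PV ~1e-3, observer PV ~4e-4,
allometric R² ~0.03, a ~2% female size contrast, LOOCV accuracy in the high
80s to low 90s — and are documented here rather than re-derived per run.

What the generator does *not* emulate: correlated biological shape variation.
Real wing samples concentrate ~40–50% of shape variance in the first two
principal components; the generator's isotropic noise spreads variance
evenly, so its PC1+PC2 share is ~15% and — for a fixed total PV — more noise
falls along the discriminant direction than in real data. Passing tests
therefore demonstrate the pipeline's correctness and calibration, not the
accuracy attainable on real wings (which is higher at the same total
variance). Likewise the template geometry and per-landmark displacement
fields are generator constants with no claim of biological realism.

## Numerical choices

- Convergence: `tol` 1e-10 on the decrease of Q; typical datasets converge
  in 3–5 iterations.
- PCA sign gauge: the largest-magnitude element of each loading is positive.
- Rank decisions: singular values below 1e-12 of the largest are treated as
  zero; an ill-conditioned pooled covariance (cond > 1e12) raises an error
  instructing PCA reduction rather than returning garbage.
- Permutation p-values use the (c+1)/(N+1) estimator and are bit-reproducible
  under a fixed seed; Z is NaN when the permutation distribution is
  degenerate.
- Degenerate inputs (all-coincident landmarks, constant size covariate,
  empty groups, unreplicated specimens) raise typed errors or warn-and-
  exclude, as documented per function.
- Reports serialize at full precision with display rounding only in the
  human-readable summary (F to 2 dp, R² to 3 dp, PV to 6 dp); JSON reports
  are byte-stable functions of (input, config, seed), which is why report
  provenance carries a config hash and seed but no timestamp.

## Known limitations

- 2D, complete configurations only: no missing-landmark estimation, no
  semilandmarks, no 3D, no bilateral-symmetry decomposition.
- Reflection is a validation concern, not a correction; mixed-chirality
  datasets must be fixed upstream.
- Centroid sizes are in input units; cross-dataset size comparisons assume a
  shared image calibration, which the package cannot verify.
- The observer size ANOVA ignores the specimen blocking of the crossed
  design (see above); its p-values are conservative on such data.
- Two-class LDA only; no quadratic/regularized discriminants, no multi-class
  problems, no probability calibration.
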