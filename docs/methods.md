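# Methods

This note documents the models, numerical conventions, and design choices
behind `limbmorph`, and what the synthetic-data tests do and do not
establish about real CT-derived data.

## Cross-sectional geometry from voxels

A bone is a binary occupancy grid with isotropic spacing *h* (mm).  Before
slicing, the grid is rotated so that the dominant principal axis of the
occupied-voxel cloud becomes array axis 0; if that axis already coincides
with a grid axis (within ~0.5°), the volume is only transposed, avoiding
interpolation.  The proximal end is placed at the lower index by a
center-of-mass rule (the heavier half goes distal), which is deterministic
but arbitrary; none of the derived traits depend on it.

Per slice, with material pixels at centers (xᵢ, yᵢ):

- CSA = n·h²; total area = hole-filled mask area (2-D morphological fill,
  which also closes nutrient-foramen-like openings); compactness =
  CSA / total area.
- Second moments about the material centroid:
  Ixx = Σ(yᵢ−ȳ)²h² + n·h⁴/12, Iyy likewise, Ixy = Σ(xᵢ−x̄)(yᵢ−ȳ)h².
  The h⁴/12 term is each pixel's own moment about its center; with it,
  axis-aligned rectangles are **exact** (the 2×2-pixel slice gives
  I = 16/12 mm⁴ identically), and convergence for smooth sections is
  first-order in *h*.  Tools that omit the term will read slightly lower I
  on coarse grids.
- I_major/I_minor are the larger/smaller eigenvalues of
  [[Ixx, −Ixy], [−Ixy, Iyy]], so CSS = I_major/I_minor ≥ 1 by construction
  regardless of how the section is oriented in the grid.

Functional length is operationalized as the occupied extent along the
slicing axis, (last − first occupied slice + 1)·h.  The anatomical
definition (greatest distance between articular surfaces) needs landmarks
the voxel model does not carry; for shaft-dominated long bones the two
agree to within the cap geometry.  The trait window is the middle 40% of
functional length (slices whose centers fall within [0.3 L, 0.7 L] measured
from the first occupied slice); the midshaft is the slice nearest 0.5 L,
ties broken proximally.  Cg averages compactness over the window; DE and
CSS are read at the midshaft slice.  Voxel indices are 0-based, slice
ranges inclusive, physical positions are voxel centers.

Accuracy at the spacings used in tests (h ≤ b/25 for oracle sections):
ellipse CSS within 2% of (a/b)², annulus compactness within 1% of
1 − (r/R)², in-plane rotations change the traits by < 2%.

## Superimposition and shape statistics

GPA: configurations are centered, scaled to unit centroid size
(CS = √Σ‖pⱼ − centroid‖², recorded before scaling), then iteratively
rotated to the running consensus with proper rotations only (det +1);
reflections are handled upstream by the explicit side-mirroring step, so
chirality is never silently absorbed.  Iteration stops when the consensus
moves < 1e-10 (max 100 rounds); at convergence the consensus equals the
mean of the aligned configurations.

Linear models on multivariate responses use sequential (type-I) sums of
squares measured as traces of residual cross-product differences between
nested fits.  Every term's null distribution comes from RRPP: permute the
residuals of that term's reduced model, add them back to the reduced fitted
values, recompute F.  p = (1 + #{F* ≥ F_obs}) / (1 + n_perm), which cannot
be zero; the effect size Z is the z-score of F_obs in the raw permutation
distribution (no log transform — signs are interpretable directly).  With a
univariate response and no phylogenetic transform the F statistic equals
classical ANOVA F exactly.  For small n the full permutation set can be
enumerated (`all_perms=True`), which the tests use as a brute-force oracle.

The phylogenetic variant premultiplies response and design by C^(−1/2), the
inverse symmetric square root (eigendecomposition) of the Brownian or
λ-scaled covariance.  Pairwise group tests use Euclidean distances between
group least-squares means (covariates at their means) with the null built
from the reduced model that drops *all* terms involving the group factor;
which reduced model anchors pairwise nulls is a genuine free choice in this
framework, and this is the most conservative standard option.

Pillai's trace is tr(H(H+E)⁻¹) per sequential term with E from the full
model; it requires more residual degrees of freedom than response columns,
so shape data are first reduced to leading principal components (the
pipeline caps PCs well below n − rank).  Two-block PLS takes the SVD of the
cross-covariance of centered blocks; r-PLS is |corr| of the first paired
scores and the null permutes specimen order of one block.  CVA operates on
PC scores retaining ≥ 95% variance (configurable), capped below n − g so
the pooled within-group covariance stays invertible; leave-one-out
classification recomputes group means and pooled covariance without the
held-out specimen and assigns by smallest Mahalanobis distance, exact ties
to the smallest group index.

## Phylogenetic linear models

C(λ) multiplies the off-diagonal entries of the Brownian covariance C(1)
(C₁ᵢⱼ = shared root-to-MRCA branch length) by λ ∈ [0, 1], leaving the
diagonal untouched.  For an ultrametric tree, diag C(1) = T·I, so C(λ)
shares C(1)'s eigenvectors; the implementation exploits this to profile the
likelihood over λ with one eigendecomposition per tree instead of one
Cholesky per candidate λ, making thousand-replicate bootstraps cheap.

Fitting is ML: given λ, β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y, σ̂² = êᵀC⁻¹ê/n,
log L = −½(n log 2πσ̂² + log|C| + n).  λ̂ maximizes the profile likelihood
via an 11-point grid scan followed by bounded 1-D search around the best
grid point (profiles can be flat or bimodal; exact ties break toward
smaller λ).  On a star tree the profile is flat and the fit is flagged.
Model competition uses AICc with k = #β + 2 (σ² and λ both count); weights
are exp(−Δ/2) normalized, and ΔAIC < 2 is flagged "supported".  R² is the
GLS R² against the intercept-only GLS fit at the same λ̂.  Equivalences
verified in tests: λ = 0 reproduces OLS to 1e-10; λ = 1 reproduces the
independent-contrasts regression-through-origin slope to 1e-6; the whole
fit was cross-checked against an independent GLS implementation on one
dataset (λ̂, log-likelihood, and all coefficients agree to printed
precision).

**Bootstrap.** Coefficient uncertainty uses a parametric bootstrap:
y* = Xβ̂ + ε*, ε* ~ N(0, σ²C(λ)), refit (λ re-estimated) per replicate,
95% CIs from the 2.5/97.5 percentiles of replicate quantities.  Tips are
not exchangeable under phylogenetic covariance, so case-resampling is
deliberately avoided.  Two numerical choices matter here:

1. *Noise parameters are REML-estimated.*  The ML σ̂² = RSS/n is biased low
   by p/n, and λ̂ is biased toward 0 when group factors align with clades
   (see below); simulating bootstrap noise at the ML values shrinks every
   CI.  The restricted likelihood removes the fixed-effect degrees of
   freedom, restoring near-nominal CI coverage (measured ~94% pooled at
   study scale).  Fitting, AICc, and the replicate refits remain ML so that
   model comparison is unaffected.
2. *Replicate λ refits use a two-stage grid* (coarse 0.1, fine 0.01,
   batched across replicates); at that resolution the coefficient
   distributions are indistinguishable from scalar-optimized refits.

Group means for pairwise contrasts are least-squares means at the
grand-mean ln size whenever size is in the model, removing size confounding
from mean comparisons.  Allometry verdicts are a pure function of the slope
CI: entirely above zero → positive, below → negative, else isometric
(dimensionless traits make zero the isometric expectation).

The phylogenetic paired t-test fits an intercept-only PGLS to the per-tip
difference d = a − b with a single λ estimated for d (a deliberate
simplification of a joint two-trait model); t = intercept / SE with the
n/(n−1) bias-corrected GLS variance and n − 1 degrees of freedom.

**λ identifiability caveat.**  When ecotypes are unions of clades — as in
the target system and the synthetic generator — the ecotype factor absorbs
much of the phylogenetic signal, and the residual λ of models containing
ecotype is only weakly identified: at a generating λ of 0.5 under the
size×ecotype design, roughly 40% of ML fits collapse to λ̂ = 0 (median
absolute error ≈ 0.29), whereas intercept-only fits on the same tree
recover λ with median absolute error ≤ 0.15 across λ ∈ {0, 0.5, 1}.  This
mirrors the empirical pattern that fitted λ drops to ~0 once ecotype enters
the model, and it slightly degrades bootstrap CI coverage at intermediate λ
(~92.6% versus ~94% at λ = 0).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analyses assume:

- **Bones**: hollow elliptical frustum, constant cortical thickness, flare
  g(s) = 1 + flare·s⁴ toward solid caps (|s| ≥ 0.75 of the half-length),
  plus Gaussian radial bumps at fixed surface sites.  Midshaft CSA and
  second moments have closed forms — the oracle for the voxel code.
  Landmarks sit on a fixed (θ, s) parametric grid of the outer surface, so
  landmark j corresponds across specimens *by construction*, replacing the
  template-transfer registration step used on real scans.  Tests default to
  60 landmarks to keep p < n for MANOVA/CVA; the counts are configurable.
- **Tree**: pure-birth with exponential waiting times, rescaled to unit
  crown depth; exactly ultrametric.
- **Ecotypes**: whole clades painted from randomly chosen internal nodes
  (clade sizes constrained to ~8–45% of tips, matching the target clade's
  ecotype sizes), background tips forming the final ecotype.  A
  permutation-tested clustering index confirms painted labels are more
  phylogenetically clustered than chance.
- **Traits**: ln size is Brownian (root 4.0 ln mm, rate 0.15 per unit
  depth); each structure trait follows y = β₀(eco) + β₁(eco)·ln size + ε,
  ε ~ N(0, σ²C(λ)).  Default β₀/β₁/λ per trait are sized like squirrel
  long-bone values (Cg ≈ 0.55–0.65 with shallow positive slopes and
  λ = 0.4; DE ≈ 15–25 with slopes of order 1 and λ = 0; CSS ≈ 1.26–1.71
  with fraction-scale slopes and λ = 0).  Effect sizes are chosen for
  testability — the source system does not pin them down.
- **Shapes**: ecotype mean (smooth deterministic deformations of the
  template) + (ln size − root)·allometry vector + Brownian deviations
  independent across landmark coordinates with tree-structured covariance
  across tips.

All randomness flows through one seeded generator (`numpy` PCG64);
identical seeds give bit-identical datasets.  The pipeline derives each
stage's seed from the master seed through a stable hash of the stage label,
so adding or removing a stage never perturbs the others.

Not emulated: trabecular architecture, scanner noise and segmentation
error, registration/landmark-transfer error, within-species variation
(one specimen per species), measurement error in the tree.  Passing tests
therefore establish the correctness of the *estimators and their
calibration* under the assumed generating models, not the biological
conclusions one would draw from real scans.

## Problem sizes used in the test suite

Simulation-based checks run at the study scale of 76 tips with 4
clade-clustered ecotypes.  Calibration tests use 300 simulated datasets
with 500 bootstrap replicates each (CI coverage and allometry verdicts),
100 datasets per generating design for model-selection recovery, 500 null
datasets × 499 permutations per permutation test, and 100 runs for CVA
chance level; the full-pipeline determinism check runs the complete
synthetic pipeline twice at 99 permutations / 100 bootstrap replicates.
These sizes keep the whole suite under a few minutes while leaving binomial
noise well inside the asserted bands.

## Known limitations

- Functional length is a grid-extent proxy; on real bones with prominent
  processes it can exceed the articular-surface definition.
- The λ profile under clade-aligned designs is weakly identified (above);
  percentile bootstrap CIs undercover by 1–2 points at intermediate λ.
- NRRD volumes are not read; volumes are TIFF stacks with a JSON sidecar
  carrying the spacing.
- CVA accuracy is reported on jackknifed Mahalanobis classification in PC
  space; with p ≥ n the retained dimension cap makes accuracies depend
  mildly on the variance threshold chosen.
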