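# Methods

This note records the statistical model, the design decisions behind it,
and what the bundled synthetic cohort does and does not demonstrate.

## Compositional preprocessing

Sequencing counts and MS peak areas carry no absolute scale: only
within-sample ratios are interpretable, and both tables are very sparse.
All modeling therefore happens after the robust centered log-ratio
transform (rclr): each positive entry becomes `ln x` minus the mean of
`ln x` over that sample's *positive* entries; zeros are marked missing.
No pseudocounts are used anywhere by default (a pseudocount flag exists
on `rclr` for comparison work, off by default).  Consequences worth
keeping in mind:

- every statistic downstream is invariant to per-sample scaling (library
  size, injection volume);
- a zero is "not observed", not "absent" — completion, not imputation,
  fills the structure;
- the per-sample centering subtracts the mean over an *observed subset*
  that differs per sample, which injects a small shared shift into every
  feature of a table.  Two places compensate for this: the factorization
  centers columns on their observed-entry means first, and cross-omic
  correlations re-center reconstructed profiles across features within a
  table before correlating (a feature profile in clr space is only
  defined relative to the table average).

Rarefaction (for count tables only) subsamples each sample to a common
depth without replacement via the multivariate hypergeometric
distribution; samples below depth are dropped and reported, never
padded.  The default depth is 10,200 reads; depth, seed, and the number
of draws are configurable.

## Masked low-rank completion

`optspace.complete` approximates a NaN-masked matrix by `U S Vᵀ` at rank
*r*, minimizing squared error over observed entries only:

1. spectral initialization — SVD of the zero-filled matrix rescaled by
   the inverse observed fraction (optional degree trimming for very
   uneven masks, off by default at this scale);
2. gradient steps on `(U, V)` with a backtracking line search (halve the
   step until the loss does not increase, at most 20 halvings; grow the
   step 1.5x after an accepted move), re-solving the small `r x r` core
   `S` exactly by least squares after every trial step;
3. after convergence, a QR + small-SVD reparametrization leaves `U`, `V`
   orthonormal and `S` diagonal, nonnegative, nonincreasing — without
   changing the reconstruction.

The per-iteration loss is monotone by construction.  On fully observed
input the spectral initialization *is* the truncated SVD, so the
solution matches the SVD oracle to machine precision; on half-observed
noiseless rank-2 data (60 x 40) the held-out entries are recovered to
relative error ~1e-15.  Defaults: rank 3 (ordinations are read on 2-3
axes), `max_iter` 200, `tol` 1e-6 on the relative loss change.  The
solver is deterministic; the `seed` argument is recorded for provenance.

## Joint factorization

For tables `X_1 … X_M` over identical samples the model is
`X_m ≈ U S V_mᵀ` with one orthonormal sample-score matrix `U` and one
singular-value vector shared across tables; the objective averages the
per-table mean squared error over observed entries (equal table weights
by default; a weight vector is exposed).  Each sweep:

1. solves every table's feature loadings exactly, column by column,
   given `U` (closed-form least squares on observed entries, batched via
   normal equations);
2. takes an SVD of the vertically concatenated loadings — this
   re-orthogonalizes the shared scores and recomputes the shared
   singular values each iteration, keeping the per-table factors in one
   consistent rotation;
3. solves the sample scores row by row given the loadings, followed by a
   QR re-orthonormalization.

Every block update is an exact minimizer and the rotations preserve the
reconstruction, so the joint objective is monotone nonincreasing; the
sweep converges in a few dozen iterations at this scale.  Exact block
solves were chosen over plain gradient steps for the multi-table solver
precisely because they make the monotonicity contract structural and
converge fast; a single table degrades to `optspace.complete`, which
makes single-table joint factorization and RPCA *identical*, not merely
equivalent up to rotation.

**Cross-validation.**  Whole samples are assigned to train/test (80/20
by default, 5 seeded random splits).  The model is fit on training
samples only; each test sample is projected by least squares of a random
half of its observed rclr entries onto the trained `V_m S`, and the
reconstruction is scored on the *other* half.  Scoring the same entries
used for the projection would reward any extra rank (it fits r free
parameters per sample); with held-out-entry scoring the CV error has a
real minimum, and on synthetic paired data a rank sweep recovers the
planted rank in 20/20 replicates.  The returned factors are fit on all
samples; the CV splits only produce the error estimates.

**Cross-omic correlations** are Pearson correlations (Spearman by flag)
between reconstructed sample-space profiles `U S v_j` of features in
different tables, after the per-table re-centering described above.
Features with all-zero loadings get zero rows.  Since reconstructions
are rank-limited, these correlations are saturated relative to raw-data
correlations and should be ranked, not interpreted as effect sizes.

## Group statistics

- **PERMANOVA**: Anderson's pseudo-F from squared distances,
  `F = (SS_between/(k−1)) / (SS_within/(n−k))` with the Gower partition;
  p by seeded label permutation `(#{F* ≥ F}+1)/(B+1)` (default B = 999),
  or by full enumeration of the distinct label assignments for small
  designs (exact mode).  Free permutation assumes exchangeable units:
  with repeated measures per animal, test at one timepoint per animal or
  expect inflated rejection.
- **Pairwise Mann-Whitney** with Bonferroni correction across all group
  pairs; the exact null distribution when both groups have n ≤ 8 and no
  ties, else the normal approximation with tie correction.
- **Log-ratio regression**: Pearson r, two-sided p and the least-squares
  line between two log-ratio series matched on the samples both retain.
- **Random-intercept trend** `log_ratio ~ host_age * group +
  (1 | animal)` is a declared delegation to statsmodels `MixedLM`;
  singular or non-converged fits are flagged, not raised.

## PLS-DA

Two-class PLS-DA on the rclr matrix with unobserved entries set to 0 —
the row-centered neutral value.  This 0-fill is a deliberate divergence
from the completion-based unsupervised path: the supervised model needs
a dense design and the neutral fill does not leak class information.
The PLS core is NIPALS (scikit-learn `PLSRegression`, no column
scaling); on top of it: VIP scores
`VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)` (so
`mean(VIP²) = 1` identically), selection at VIP > 1 (configurable), and
a classification error rate from stratified k-fold CV (default 5) with
nearest-class-centroid prediction in score space and held-out
predictions pooled across folds.  `auto_ncomp` picks the component count
in {1,2,3} with the smallest CV CER.  The fit is deterministic given the
data; the seed moves only fold assignment.

## Synthetic cohort generator

The generator emulates a three-arm repeated-measures design — regular
chow + air (RC-Air), high-fat/high-cholesterol + air (HFHC-Air), and
HFHC + intermittent hypoxia/hypercapnia (HFHC-IHC) — with both omics
layers driven by the same latent factors:

- *Design*: 3 arms x 8 mice x 20 timepoints (host age 10 → 19.5 weeks),
  150 microbial features, 250 metabolite features, expected library size
  12,000 reads (so rarefying at 10,200 drops a realistic fraction),
  count dropout 0.3, metabolite dropout 0.2, latent rank 2.
- *Factors*: axis 1 = `effect_size · g · τ` + N(0, 0.35) where τ is the
  time fraction and g the arm multiplier (RC-Air 0, HFHC-Air 0.6,
  HFHC-IHC 1.0) — exposure differences that grow over the study; axis 2
  = per-mouse level N(0, 0.5) + sample noise N(0, 0.5); any further axes
  are iid sample noise.  `effect_size` defaults to 1.2 on the natural-log
  scale, i.e. the strongly affected features change ~3-fold between the
  extreme arms by study end — the size of effect these designs are
  powered for.
- *Microbes*: multinomial counts from softmax(factors x loadings +
  feature baseline + per-mouse intercept), then Bernoulli dropout.  A
  Dirichlet-multinomial flag adds extra overdispersion.
- *Metabolites*: log-normal intensities on the same factors with feature
  noise N(0, 0.3) and dropout.
- *Planted structure*: an Akkermansiaceae-like family (8 features, axis-1
  loading +0.6…+1.4) opposing a Muribaculaceae-like family (12 features,
  −0.6…−1.4); RC- vs HFHC-IHC-associated metabolite panels (15 each,
  mirrored signs); and 5 microbe–metabolite pairs whose loading vectors
  are *equal* and whose metabolite carries no feature noise — the ground
  truth for correlation-detection tests.

Generator design points that matter for recovery tests, fixed once when
the generator was designed:

- loading matrices are centered to zero column mean (the clr only
  identifies loadings up to a shared shift; centering makes the planted
  pair relation survive the transform);
- planted-pair microbes get a high abundance baseline (log-offset 3),
  because a marker whose counts collapse to zero over half the design
  has no estimable profile;
- family/panel features get extra spread on the non-exposure axes so the
  planted "crowd" does not collapse onto a single direction.

What the generator does **not** emulate: taxon phylogeny, chemical
structure or MS peak shape, batch effects, time-autocorrelated noise
within mice beyond a constant intercept, or compositional interactions
between taxa.  Passing tests show the pipeline recovers the *kind* of
structure it models, at desk scale, not that real data behave this way.

### A geometric limit on pair detection

With a rank-2 latent space, feature profiles are directions in a plane:
about 1% of random cross-table pairs lie within ~0.8° of collinearity,
exactly the accuracy limit of any estimator.  Detecting planted pairs in
the top 1% of |correlation| is therefore ill-posed at rank 2 however
strong the signal: truly collinear pairs and chance alignments are
inside each other's estimation error.  At latent rank 3 the coincidence
probability falls quadratically (the top-1% cutoff widens to ~8°) and
detection is clean (20/20 replicates, all pairs, in the test suite).  The correlation-detection test accordingly runs the generator
at rank 3; subspace-recovery tests keep the rank-2 default.

## Pipeline and provenance

`run_pipeline` chains: read → rarefy → align → RPCA per table (+
ordinations, distances) → PERMANOVA → PLS-DA on the metabolome (two
configured arms, VIP table) → loading/VIP-based feature filtering →
joint factorization (+ CV) → cross-omic correlations → family and
VIP-panel log ratios (+ dropped-sample sidecars) → pairwise tests at the
last timepoints, log-ratio regression and the LME trend.  Any stage
error aborts with the stage name.  All seeds and parameters echo into
`provenance.json`; reruns with the same config are bit-identical (the
provenance file itself differs only if the output path does).

## Problem sizes in the test suite

Unit tests run a reduced cohort (3 mice/arm, 5 timepoints, 50 + 60
features); recovery and detection tests run the full default design
(480 samples) for 20 seeds each; the PERMANOVA calibration uses 1000
null datasets of 20 samples with 99 permutations; PLS-DA null behavior
uses 100 permuted-label fits of 60 x 30.  The committed fixture
(`tests/data/cohort_small`, 54 samples, 60 + 80 features, expected depth
3,000) is small enough to ship as plain TSV while still exercising the
rarefaction-drop path and the planted cross-omic correlation.

## Known limitations

- The joint objective is nonconvex; the spectral initialization is good
  at these sizes but there is no global-optimality guarantee.
- CV rank selection is a solver-level property: on rclr-transformed
  tables the transform itself adds weak extra predictable components
  (the observed-subset centering shift, column-mean estimation error),
  which can pull the selected rank one above the planted one.
- PERMANOVA's free permutation is anticonservative under repeated
  measures (see above); restricted permutation is not implemented.
- PLS-DA is two-class only; multiclass contrasts are run pairwise.
- Cross-omic correlations from rank-limited reconstructions are for
  ranking, not effect-size estimation.
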