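# Methods

This note documents the statistical model behind each stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs
reproducible.

## Cohort model

A cohort couples one subject record (sex M/F, decimal age in years,
standing height in cm, five optional spreading-caliper distances in mm)
with an optional configuration of 24 named facial soft-tissue landmarks
(x, y, z in mm, arbitrary device frame).  Age-group membership uses
completed years: `floor(age)` located in the inclusive ranges 3–6, 7–12,
13–15, 16–18, 19–21, 22–25, which partition ages 3–25.  Fractional-age
boundary cases (e.g. 6.9 years) therefore stay in the younger group;
this is a package convention, chosen because "age in completed years" is
the usual demographic reading.  Sex tokens other than `M`/`F` are
errors — nothing is inferred.  The five caliper distances are input-only:
their defining landmarks (euryon, frontotemporale, zygion, gonion,
glabella, opisthocranion) are not among the 24 digitized landmarks, so
they can never be derived.  Subjects without a landmark row are kept for
caliper-only analyses and flagged.

## The 29 measurements

24 measurements are Euclidean interlandmark distances; 5 come from the
calipers.  Bilateral distance measurements use the left side only
(palpebral fissure length, nasal ala length, and the three facial
depths), the convention being that left and right convey the same
information; cranial base width (tragion to tragion) spans both sides by
definition.  Regions: cranium (4 measurements), face (8), eye (3), nose
(6), mouth (8).  Rigid motion of a configuration leaves every derived
measurement unchanged; uniform scaling scales them linearly (tested
properties).

## ANCOVA and the modified Cohen's d

Within each age group and measurement, `value ~ sex + height + age` is
fit by ordinary least squares (statsmodels).  With a single two-level
factor and no interaction, the partial F for sex equals the squared t on
the sex coefficient, so the reported p is the coefficient's two-sided t
probability on n − 4 df.  Least-squares means are evaluated at the
included subjects' covariate means — the conventional ANCOVA choice; the
evaluation point only shifts both adjusted means equally, so the
difference, p, and d are invariant to it (and to any affine rescaling of
the covariates, e.g. cm → m; tested).  The effect size divides the
adjusted mean difference by the root of the residual (covariate-adjusted
within-groups) mean square.  Magnitude labels: |d| < 0.20 very small,
< 0.50 small, ≤ 0.80 moderate, > 0.80 large; exactly 0.80 is classified
moderate because "large" is read strictly.  No multiple-testing
correction is applied by default — effect sizes carry the interpretive
weight; `fdr=True` appends Benjamini–Hochberg adjusted p values as an
extra column.  Subjects missing a measurement are dropped from that cell
only (pairwise deletion).  Cells with fewer than two subjects of either
sex are reported as skipped with a reason rather than fit.

Regional summaries are unweighted means of signed d over each region's
measurements; a region with no estimable measurement in a group is
absent, never imputed as zero.  Growth attainment is
100 × (group mean / same-sex adult mean) per measurement, averaged per
region; the adult group is its own reference, so its per-measurement
attainment is 100 by construction but regional values are reported for
all six groups for symmetry.

## Superimposition and shape coordinates

Generalized Procrustes analysis: each configuration is centered, scaled
to unit centroid size, and rotated onto the current consensus by the
Kabsch solution constrained to proper rotations (the smallest singular
vector's sign is flipped when the cross-covariance determinant is
negative, which also breaks degenerate-singular-value ties); the
consensus is the coordinate-wise mean re-normalized to unit centroid
size, initialized from the first configuration in input order, iterated
until its root-summed-squared change falls below 1e-10 (cap 100
iterations; non-convergence is flagged, not fatal).  Reflections are
never admitted, so chirality is preserved.  No tangent-space projection
is applied: at facial levels of shape variation the difference between
superimposed and tangent-projected coordinates is negligible, and
keeping raw superimposed coordinates makes the discriminant field
directly interpretable in landmark space.  The Procrustes distance
between two normalized shapes is the root summed squared coordinate
difference after optimal proper rotation.

The common frame inherits the (arbitrary) orientation of the first
input configuration.  Any comparison of a result field against an
external reference (e.g. the generator's injected displacement field)
must first rotate the consensus onto that reference by ordinary
Procrustes alignment; the tests and the acceptance script do this.

Allometry/age adjustment regresses each of the 72 shape coordinates on
centroid size and age by least squares, pooled across sexes within the
age group, keeping residuals.  Pooling preserves the sex mean difference
for testing (a sex-specific regression would absorb it).  Residuals are
exactly orthogonal to both covariates (tested to 1e-9).

## Inference

**Permutation test.**  The observed statistic is the Procrustes distance
between the male and female mean adjusted configurations (each
re-normalized to unit size).  The null permutes sex labels over the
already-superimposed, already-adjusted coordinates — re-running GPA per
permutation is unnecessary because the superimposition does not use the
labels.  p = (1 + #{perm ≥ obs}) / (1 + B), so p is never 0 and has
resolution 1/(B + 1); distances within 1e-12 of the observed value count
as ties, so duplicated groups yield p = 1 exactly.  Default B = 5000.

An operating characteristic worth knowing: permuting raw labels over
covariate-adjusted residuals is exactly calibrated only when the group
label is uncorrelated with the covariates.  When sex is strongly
correlated with size (as in post-pubertal groups, where males are much
taller), the adjustment shrinks the observed between-sex difference but
not the permuted ones, making the test conservative — measured rejection
rates under the null generator were ≈0.05 in the height-matched
late-childhood cell but ≈0.02 at puberty and near 0 in adults.  The
Monte-Carlo calibration, power, and monotonicity checks therefore run on
the late-childhood cell, which isolates the injected-effect dial from
this confounding.  The same mechanism also means the covariate
adjustment both attenuates a true sex signal (by 1 − ρ², ρ the sex–size
correlation) and injects sex-difference variance into the residuals in
proportion to the squared effect, so discriminant accuracy in
sex-size-confounded groups saturates and can decline at extreme injected
effects.  This is a property of the adjust-then-test scheme itself, not
of the implementation.

**Centroid size.**  Welch's two-sided t on per-subject centroid sizes —
chosen over the pooled-variance t because group variances and sizes are
unequal by design.

**Discriminant analysis.**  After superimposition the pooled within-sex
covariance W of the 72 coordinates is rank-deficient (7 similarity
degrees of freedom are removed, and rank is further capped at n − 2),
so the discriminant weights use the Moore–Penrose inverse, with singular
values below 1e-10 × the largest treated as zero.  PCA pre-reduction was
rejected to keep weights in landmark space.  Scores are projections onto
the weights; classification uses the unweighted midpoint of the two
group mean scores (no prior-probability weighting, since per-sex
accuracies are reported separately with unequal n).  Hotelling's
T² = (n₁n₂/n)·δ'W⁻δ with δ the mean difference; the p value uses the F
approximation with the retained rank r as dimensionality,
F = T²(n − r − 1)/((n − 2)r) on (r, n − r − 1) df.  Jackknife
classification refits the full discriminant on each leave-one-out sample
(exact refits, no downdating approximations).

The exported per-landmark **shape-change field** is the male-minus-female
mean difference of the adjusted coordinates — this is what the male and
female wireframes display (consensus ± magnification/2 × field, default
magnification ×5).  The raw W⁻-weighted discriminant vector is kept in
`DfaResult.weights`, but it is not used for the wireframes: when W has
genuinely small (not zero) trailing singular values, 1/s amplification
makes the weight vector's direction unstable from sample to sample,
whereas the mean-difference field recovers an injected displacement
field at cosine ≈ 0.9 under the default noise conditions.

## Synthetic cohort generator

Each subject's configuration is built as

    scale · (template + effect_scale · (±½) · sex_effect)
      + allometry_slope · (CS − CS_template) · A + ε,

then randomly rotated (uniform over proper rotations) and translated —
the device frame that superimposition must undo.  The template is a
bilaterally symmetric idealized adult face with interlandmark distances
in the normal adult range.  The ±½ split keeps the mid-sex average on
the template, so the injected male-minus-female difference is exactly
`effect_scale · sex_effect`.  `scale` is the group's growth factor
(0.80, 0.89, 0.95, 0.99, 1.00, 1.00 relative to adult — typical
craniofacial attainment) times a height coupling
`1 + 0.5·(height − h̄_group)/h̄_group`, with the reference height pooled
across sexes so that size carries no sex information beyond height
itself (this is what makes `effect_scale = 0` a clean null for the
covariate-adjusted analyses).  Heights are Gaussian per (group, sex)
cell with the default means/SDs of the emulated study population (e.g.
adult males 182.2 ± 7.1 cm, adult females 165.7 ± 6.9 cm); ages are
uniform within each group's year range — uniform rather than matched to
empirical age SDs because only the covariate-adjustment machinery needs
age variation.  ε is i.i.d. isotropic Gaussian per coordinate, default
0.5 mm, on the order of careful landmark digitizing error.  A is a
fixed unit-norm allometric field (mandible drops, nose projects with
size), slope default 0.02 mm per mm of centroid size.  Caliper distances
are template-proportional constants scaled by growth and by
`1 + effect_scale · 0.04 · (±½)`, plus 5 mm Gaussian between-subject
scatter (anthropometric scale); no landmark model exists for them.
The default cell sizes reproduce the emulated study population
(98/95 … 222/360 per group, 1553 subjects).

What the generator does **not** emulate: real between-subject covariance
structure of facial shape (individuals differ from the template only by
i.i.d. landmark noise), fluctuating or directional asymmetry,
non-Gaussian digitizing error, and age trends within a group beyond the
allometric field.  Consequences: effect sizes on derived distances run
larger than in real cohorts (true biological shape variance is
underrepresented), and classification accuracies are not comparable to
real-data values.  Passing tests demonstrate correctness and calibration
of the machinery under a known model, not real-world effect magnitudes.

## Numerical conventions

Determinism: every stochastic stage takes an integer seed
(`numpy.random.default_rng`); the pipeline derives per-group permutation
seeds from the run seed via `SeedSequence`, records them in
`manifest.json`, and fixed output formatting (p to 4 decimals with
`<0.0001` below resolution, d to 2 decimals, coordinates to 6–9
decimals) pins byte-identical reruns.  Degenerate inputs error early
with the offending quantity named: coincident landmarks (zero centroid
size), coplanar configurations, rank-deficient ANCOVA designs, constant
covariates, sexes below the minimum cell sizes (2 for the tests, 3 for
the discriminant, 4 for the jackknife).

Monte-Carlo problem sizes used by the test suite and acceptance script:
null calibration with 12–15 subjects/sex and 199 permutations over 1000
replicates; power and recovery at 200 subjects/sex over 100 seeds;
monotonicity over effect scales {0, 0.5, 1, 2} with 20 seeds per level;
one full study-sized run at 5000 permutations per group.  These sizes
give Monte-Carlo standard errors comfortably inside the asserted bands
while keeping a full run in minutes on one core.
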