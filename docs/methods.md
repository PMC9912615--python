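# Methods

This note records the statistical conventions the package implements,
the defaults it ships with and why, what the synthetic-data generator
does and does not emulate, and the design choices made where more than
one defensible option existed.

## Superimposition and object symmetry

Full generalized Procrustes analysis: every configuration is centered,
scaled to unit centroid size, and iteratively rotated to the running
consensus until the RMS consensus displacement falls below 1e-10
(maximum 200 iterations; non-convergence is an error, not a warning).
Rotations are solved by SVD with a determinant guard, so improper
rotations can never enter through the fitting step; reflection exists
only in the explicit mirroring operation (negate the first axis, then
relabel rows by the scheme's mirror pairing — any other reflection
plane is equivalent after relabeling, one is fixed for
reproducibility). Procrustes coordinates are used directly, with no
tangent-space projection.

With `include_mirrors=True` the relabeled mirror copies join the fit
and the consensus is symmetrized every iteration, which makes
`mirror(consensus) == consensus` exact rather than approximate. After
convergence the whole fit is rotated to a canonical orientation
(principal axes with deterministic sign rules; when mirrors are
included only the in-plane orientation is canonicalized so the symmetry
plane stays at x = 0). This is what makes aligned coordinates invariant
to arbitrary similarity transforms of the input to ~1e-8, which the
test suite asserts.

The asymmetric component is stored as ½(original − mirror), so
symmetric + asymmetric reconstructs the aligned original exactly. The
½ convention only rescales asymmetry sums of squares; it is applied
consistently everywhere (DA, FA, ANOVA).

The pairwise shape distance m² is the full-Procrustes residual
1 − c², with c the sign-corrected nuclear norm of the cross-product
matrix of two unit-size configurations; this form is symmetric in its
arguments, which the paper-style "compare any two mice" permutation
test relies on.

## Procrustes ANOVA

Sums of squares are pooled over the doubled (original + mirror) sample:
Individual from symmetric deviations of specimen means around the grand
mean, Side from the DA vector, Individual×Side from FA, Error from
replicate scatter. These strata are orthogonal, so they add exactly to
the total Procrustes SS, and the suite asserts the identity at 1e-9.

Degrees of freedom follow the standard object-symmetry bookkeeping for
3D data with p bilateral pairs and q midline landmarks: the shape space
(3k − 7) splits into a symmetric subspace of 3p + 2q − 4 and an
asymmetric subspace of 3p + q − 3; Individual gets (n−1)·dim_sym, Side
dim_asym, the interaction (n−1)·dim_asym, Error n(r−1)(3k−7). Published
tables sometimes print df from other conventions; `anova_table_from_ss`
therefore accepts SS and df as given and reproduces the MS = SS/df and
mixed-model F arithmetic (Individual and Side over the interaction, the
interaction over measurement error) without re-deriving df. Under
pure-noise simulation every F ratio has mean ≈ 1 with this bookkeeping,
which the suite checks over 200 replicates.

Parametric F p-values are the default. Because Procrustes data violate
the usual F assumptions, an optional sign-flip randomization of the
per-specimen asymmetric components (sides are exchangeable within an
individual under the null) provides permutation p-values for Side and
the interaction.

## Allometry

Multivariate OLS of the flattened shape component on log CS; the
summary is 100·SS_predicted/SS_total, reported to two decimals only at
print time. The permutation test shuffles CS against shapes, uses
predicted SS as the statistic, and applies the add-one rule
p = (1 + #{perm ≥ obs})/(n_perm + 1) so p = 0 is impossible. The fit is
run separately for symmetric and asymmetric components; the symmetric
residuals (re-centered on the mean shape) feed PCA and the PS-route
RDs. Residuals are exactly uncorrelated with log CS coordinate-wise;
under the null the expected percent predicted is 100/(n−1), and the
suite confirms the Monte-Carlo mean against that value.

One consequence worth knowing: when a mutant group happens to draw
sizes correlated with its genotype (easy at n = 6), the size-adjustment
step absorbs part of the genuine group effect. This is a property of
the method, not of the implementation; the recovery tests quantify it
and the generator's validation conditions keep size variation modest so
the attenuation stays within ~2 percentage points of an implanted 10%
effect.

## PCA and PC distances

Eigendecomposition of the specimen covariance of flattened size-adjusted
symmetric coordinates, computed by SVD of the centered data matrix.
Percent variance is taken over all non-null eigenvalues so shares sum
to 100. Component signs are fixed by making each component's
largest-magnitude loading positive, so score plots reproduce across
runs and specimen orderings. The distance-to-grand-mean summary is the
Euclidean norm of each specimen's score vector restricted to the PCs
explaining more than 5% of variance — the set is recomputed from the
data, never hard-coded to five. (Where a text description "average of
the sum of scores" conflicts with a figure's "Euclidean distance", the
Euclidean distance is implemented.)

## Relative linear dimensions

The catalog contains, per module, all pairs within {left ∪ midline},
all pairs within {right ∪ midline} (midline–midline pairs once), plus
each bilateral mirror pair once: 2·C(b+m,2) − C(m,2) + b entries for a
module with b pairs and m midline landmarks. Midline landmarks belong
to both side sets — required so dimensions like a side-to-midline nasal
height exist on both sides. For the package's default 105-landmark
scheme — facial 14 pairs + 12 midline, vault 16 + 3, base 11 + 8 — the
catalog has exactly 1278 entries. Cross-module distances are excluded
because compensatory change between modules is expected.

Classification thresholds default to the strict regime (|Δ| > 5% of the
control mean, p < 0.001 pooled two-tailed t, every mutant individual
consistent in direction); a milder regime (2%, p < 0.01, no consistency
requirement) is a configuration change, not a code change. No
multiple-testing correction is applied by default, matching the raw
thresholds practice; a Bonferroni flag exists and defaults off. EDMA
group comparisons use per-distance arithmetic means of CS-scaled
distances; the form-difference ratio (mutant mean / control mean) is
reported alongside the percent difference.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the analysis assumes: 105
landmarks (41 bilateral pairs + 23 midline in three modules), 21
specimens in groups of 6 mutant / 6 Cre-driver / 8 floxed / 1 wild
type, two digitization replicates. Defaults, all in template
coordinate units (template spans roughly ±3 per axis, CS ≈ 45):

| parameter | default | rationale |
| --- | --- | --- |
| `effect_pct` | +8% on 4 facial pairs | mirrors the reported ~8–9% structure-length changes; deliberately borderline against the 5% rule |
| `cs_cv` | 0.05 | ~5% centroid-size CV among newborn littermates |
| `allometry_scale` | 0.06 | puts the size-predicted share of symmetric variation near the reported ~15% |
| `individual_sd` | 0.010 | symmetric inter-individual variation, ~1% of a process-length dimension |
| `da_scale` | 0.0012 | sets the Side-vs-interaction F ratio in the low single digits, as reported |
| `fa_sd` | 0.005 | fluctuating asymmetry below individual variation |
| `digit_sd` | 0.0015 | replicate error ≈ 0.003–0.01% of CS, under the 0.02% QC threshold |
| `replicates` | 2 | the two-digitization design |

Effects are implanted as distance-percent changes — the unit the
classifier tests — by moving both endpoints of a pair (and of its
mirror-image pair) apart along the pair axis, which makes the implanted
raw distance ratio exact. The template is not a homogeneous point
cloud: each module carries a few *process* landmark pairs, isolated
dumbbells standing clear of their surroundings the way real bony
processes do. Effect pairs are chosen among them so that implanting a
change perturbs every off-target catalog RD by less than 3.5%,
comfortably under the 5% rule; without such isolation, any landmark
displacement bleeds >5% changes into short neighboring distances and no
clean ground truth exists. The allometric and DA fields are
symmetric/antisymmetric respectively and are projected orthogonal to
the template's seven similarity directions, so superimposition does not
absorb them.

What the generator does **not** emulate: anatomical geometry,
structured (low-rank) covariance of individual variation — real
specimens concentrate variance in a few biological modes, giving
steeper PCA spectra than the isotropic noise here — spatially
correlated digitization error, or outliers. Passing recovery tests
therefore demonstrate that the pipeline's bookkeeping and
classification logic are correct under the assumed error model, not
that real-data preprocessing problems (landmarking drift, missing
landmarks, asymmetric digitization bias) are handled.

The ground truth for the allometric fraction is defined as the same OLS
estimator applied to the exact implanted symmetric fields, so the
recovery comparison isolates distortion introduced by superimposition
and size-adjustment rather than re-measuring the estimator's known
finite-sample inflation.

## Numerical choices and degenerate inputs

* GPA convergence 1e-10 (RMS), 200 iterations; degenerate (zero-CS)
  configurations are refused everywhere.
* Zero within-group variance in a t-test (noise-free synthetic input)
  yields p = 0 when means differ and p = 1 when they do not, rather
  than NaN.
* Permutation p-values always use the add-one rule; the default seed
  (20230209) is a documented constant, and every simulation or test
  accepts an explicit seed.
* CSV round-trips are bit-exact (`float_precision="round_trip"` on
  read).
* Replicates are retained for the ANOVA error stratum and averaged
  before regression, PCA and RDs; the QC threshold (0.02% of CS) warns
  and never fails the run.

## Known limitations

* Parametric ANOVA p-values inherit the usual Procrustes-data caveats;
  use the sign-flip option for the asymmetry effects when it matters.
* The canonical-orientation rules can flip under near-degenerate
  principal axes of the consensus (e.g. a perfectly spherical shape);
  generic biological shapes are unaffected.
* Group–size confounding at small n attenuates size-adjusted group
  effects (see Allometry above); with 6 mutants, a ~3σ adverse size
  draw can demote a 10% implanted effect below the per-individual
  consistency rule.
* The TPS reader covers LM3 blocks with optional ID lines only.
* 2D data are out of scope throughout.
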