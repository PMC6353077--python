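# Methods

## Problem and scope

`cremsex` implements univariate osteometric sex estimation for cremated
(calcined) human skeletal series. The setting: a collection of burned adult
individuals, each with an archaeologically assigned gender label (M/F, inferred
from grave goods) used as the truth proxy for biological sex, and a sparse
matrix of caliper measurements (mm) on heat-resistant skeletal landmarks —
epiphyses of long bones, carpals, tarsals, patella, mandibular condyle, axis.
Preservation is highly uneven, so every analysis is complete-case per trait.

The pipeline has four stages, each usable on its own:

1. **Observer-error screen** — traits whose inter-observer relative technical
   error of measurement reaches 5% are dropped.
2. **Dimorphism statistics** — per trait: per-sex (n, mean, sd), Welch t,
   variance-homogeneity tests, the two-normal non-overlap index D with a
   bootstrap SD, and the density-intersection cut-off x₀.
3. **Cut-off classification with stratified cross-validation** — accuracy and
   per-sex precision of the x₀ classifier estimated by 1000 resampled 70/30
   splits.
4. **Cross-application of external standards** — cut-offs derived from other
   (e.g. modern cremated) reference series applied to the series at hand.

## Technical error of measurement

For two observers measuring the same N individuals,

    TEM = sqrt( Σᵢ dᵢ² / 2N ),   dᵢ = first − second reading (mm),
    RTEM = 100 · TEM / MEAN  (percent),

where MEAN is the mean of the two observers' means over the same individuals.
A trait is **excluded when RTEM ≥ 5%** — the published error table marks 5.1,
5.5 and 11.8 as unacceptable while everything strictly below 5 passes, so the
boundary case is excluded. Applied to the bundled published MEAN/TEM values
this retains 21 of 24 traits (dropping axis dens height, humeral head
transverse diameter, mandibular condyle thickness). Only the two-observer form
is implemented; generalized k-observer TEM and intra-observer designs are out
of scope.

## The non-overlap index D and the cut-off x₀

Each sex's trait distribution is modelled as a normal fitted by moments from
the complete-case summaries: X_M ~ N(μ_M, σ_M²), X_F ~ N(μ_F, σ_F²), with
sample SDs (n−1 denominator). Sexual dimorphism is quantified as the area in
which the two densities do **not** overlap:

    D = 1 − ∫ min(φ_M(x), φ_F(x)) dx ,

computed analytically: the crossing points of the two densities solve a
quadratic in x (one root when σ_M = σ_F, two otherwise), and the overlap is a
sum of normal CDF differences over the intervals they delimit, with the
smaller density on each interval identified by its log-density at an interior
probe point (log densities keep the comparison exact under tail underflow).
D = 0 for identical distributions, D → 1 under complete separation, and D is
symmetric in the two labels. Equivalently, 1 − D is the total misclassification
mass of the equal-prior Bayes classifier on the two fitted normals.

The **cut-off point x₀** is the crossing located in the bulk of the two
distributions — the root at which the common density value is largest. With
equal SDs this is exactly the midpoint of the means; with unequal SDs it
coincides with the between-means root whenever one exists. For weakly
dimorphic traits with markedly unequal SDs the bulk crossing can fall slightly
*outside* the closed interval between the means (it does for the axis dens
transverse diameter and the talus head-neck length); the bulk-crossing rule
reproduces all 21 published cut-offs within ±0.02 mm, which the strictly
between-means reading cannot. When the two crossings' densities tie (equal
means, unequal SDs), the lower root is taken so the choice is deterministic
and label-symmetric; such traits have no usable classifier anyway (D counts
only the sub-σ sliver between crossings).

For every practically dimorphic trait the second crossing carries negligible
mass and D equals the misclassification complement of the single threshold
x₀; they differ visibly only when the SD ratio is large relative to the mean
gap (talus head-neck length: 0.200 vs 0.187). Classification always uses the
single threshold x₀, since that is what a practitioner applies to a bone.

### Sampling SD of D

The published tables report a standard deviation for D without stating its
estimator. Here `bootstrap_D_sd` is a **parametric bootstrap**: redraw n_M and
n_F values from the fitted normals, refit moments, recompute D; report the
sample SD over replicates (default 1000; seed-reproducible). For the radius
reference row this gives 0.068, and a delta-method cross-check gives 0.071,
whereas the source table prints 0.09 (and is uniformly ~1.3× our values across
traits). We therefore treat the printed D-sd column as produced by a different,
unreported estimator and claim only order-of-magnitude agreement with it. None
of the downstream classification results depend on D_sd.

## Inference

- **Welch t** from summaries: t = (mean_F − mean_M)/√(s_M²/n_M + s_F²/n_F)
  with Welch–Satterthwaite df and two-sided p. The female-minus-male sign
  convention makes dimorphic traits (larger male means) come out negative,
  matching the published tables. Verified in tests against
  `scipy.stats.ttest_ind_from_stats(equal_var=False)`.
- **Variance homogeneity**: two-sided variance-ratio (F) test and Bartlett's
  test on the raw per-sex samples.
- No multiple-testing correction is applied across the 21 traits; p-values are
  reported raw, and the tables should be read accordingly.

## Cross-validation

Per trait, each of 1000 replicates: (1) stratified training draw of
⌈0.70·n⌉ individuals *per sex*, uniformly without replacement — ceiling
rounding per sex is the only reading that reproduces the published train/test
sizes (radius 43/17, patella max width 16/5, lunate max length 13/4); (2) x₀
fitted on the training moments; (3) test individuals classified (male side =
the side of the larger training mean; ties at the cut-off classify male — a
measure-zero event for continuous data, but file-based inputs need a
deterministic rule); (4) confusion matrix CA/CB/CC/CD with gender as truth;
(5–7) accuracy = (CA+CD)/N, precision_F = CA/(CA+CB), precision_M =
CD/(CC+CD) — i.e. per-class recall, following the field's usage of
"precision"; (8) means and SDs over replicates. A replicate whose test set
lacks one sex contributes to every defined quantity; the undefined precision
is excluded from its own mean/SD rather than imputed as 0. Replicates draw
from independent substreams spawned from the master seed, so results are
independent of evaluation order.

External standards are applied by recomputing x₀ from the standard's per-sex
summaries (or optionally using its published cut-off) and classifying the
entire input series with it.

## Synthetic data generator

The generator emulates the reference collection's statistical structure so the
whole pipeline is testable without the original individual-level data:

- per-sex trait values drawn independently from the reference standard's
  normals (values floored at 0.1 mm — irrelevant at skeletal scales but keeps
  the positivity invariant under extreme configurations);
- **exact** per-trait, per-sex missingness: which individuals carry a trait is
  a uniform draw without replacement hitting the target counts exactly (the
  default study fixture reproduces the reference layout: 124 adults, 50 M /
  74 F, per-trait counts equal to the published Ns, e.g. radius 26/34, lunate
  max length 6/11);
- optional dual-observer replicates: truth + iid N(0, σ_err²) noise per
  observer, so TEM converges to σ_err (verified by simulation);
- optional gender-label flips at a configurable rate, emulating sex–gender
  mismatch;
- one master seed spawns a substream per (stage, trait), keyed by CRC of the
  trait code: adding a trait never perturbs the others, and identical
  configurations are byte-identical.

What the generator deliberately does **not** model: inter-trait correlation
within an individual (the analyses are strictly univariate; any joint
structure would be invented), left/right side effects, age structure, and
heat-induced shrinkage as a physical process (population differences enter
only through alternative standards' means). Passing tests therefore validate
the statistical machinery under the stated two-normal model, not the
anthropological adequacy of that model for real assemblages.

## Numerical and design choices

- Crossing roots via the numerically stable quadratic formula (no companion
  matrix); density equality at x₀ holds to 1e-9 relative, property-tested.
- Degenerate inputs: identical distributions give D = 0 directly but no
  cut-off (explicit error; in table form, a D = 0 row with NaN cut-off);
  zero-variance groups raise for t and variance tests.
- Seeds: every stochastic path (generator, bootstrap, cross-validation) takes
  an explicit integer seed; equal seeds give equal results to the last digit.
- Reports round as the field prints (2 dp for mm and D, 1 dp for percents)
  while keeping full-precision columns alongside.
- Measurement CSVs serialize floats with shortest round-trip repr and are
  parsed with correctly-rounded conversion, so read∘write is the identity.
- Recomputation tolerances versus the published tables: reference summaries
  are printed at 2 decimals, so recomputed D is compared at ±0.01 (±0.002 on
  the four values printed at 3 decimals), x₀ at ±0.02 mm, and t at ±0.05. One
  trait (first metatarsal medio-lateral head width) sits at the edge of the D
  budget (recomputed 0.576 vs printed 0.57), consistent with input rounding.
- Problem sizes in the test suite are chosen to keep the full run under a
  minute: bootstrap cross-checks at 500–2000 replicates, Monte-Carlo oracles
  at 10⁶ draws, cross-validation claims at the study's own 1000 replicates.

## Known limitations

- Side (left/right) is not modelled; measurements are assumed side-agnostic.
- Units are fixed to millimetres; no conversion layer.
- Only univariate classification; no multivariate/discriminant or posterior
  probability sexing, no ROC analysis, and no rule for combining conflicting
  per-trait calls within an individual.
- The gender label is taken at face value as the truth proxy; the flip-rate
  machinery exists to study robustness, but no latent-class correction is
  attempted.
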