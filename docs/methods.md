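# Methods

`aromadrivers` implements a vinegar flavoromics workflow that links a GC-MS
volatile profile of six commercial Chinese vinegars (B1-B6) to consumer
liking: quantification through internal-standard calibration curves, odor
activity value (OAV) scoring, aroma-category profiling, group statistics,
consumer segmentation, and per-cluster preference-driver ranking by partial
least squares regression (PLSR). This note records the models, the defaults
and why, the numerical choices, and what the packaged synthetic data can and
cannot demonstrate.

## Quantification

Calibration lines are read as `response = slope * concentration + intercept`
with concentration in µg/L. The direction is not stated with the printed
curves, but the large negative intercepts (e.g. ethyl acetate,
y = 30.114x − 191,619) only make physical sense with the detector response
on the left-hand side. The response may be either a raw peak area or an
analyte/internal-standard area ratio; both are supported because the curves
are linear either way and the package never needs to know which convention
produced them.

Only 9 of the 52 volatiles have their own standard curve. The remaining
compounds are semi-quantified by a surrogate curve chosen as: same chemical
class, nearest retention index; ties broken by lowest compound id; if a
class has no curve at all, the globally nearest retention index is used
(this fallback can be disabled, in which case orphaned compounds raise an
error). The assignment is deterministic and total: every compound maps to
exactly one curve.

Replicate responses are inverted individually and then averaged; the cell sd
is the sample sd (ddof = 1) of the inverted replicates. Negative inverted
concentrations (responses below the intercept crossing) are clamped to 0 and
flagged rather than raised, because calibration intercepts are negative and
small responses would otherwise crash batch runs. Cells below the curve's
LOD are flagged `BELOW_LOD` and carry no value; cells between LOD and LOQ
are flagged `BELOW_LOQ` and keep their value by default (`loq_policy=
"censor"` suppresses it). "Trace" observations are a distinct state with no
numeric value; they are excluded from every downstream computation and enter
driver matrices as 0 (below-threshold presence is treated as negligible
signal, not as missing data).

The printed "Linear Range(μg/L)LOQ/LOD" column conflates a range with the
two limits; the two numbers are parsed as a LOQ/LOD pair and the linear
range itself is not modeled.

## OAV and aroma profiles

`OAV = concentration / odor threshold`, undefined when the catalog records
no threshold (stored as absent, never 0 or infinity) or when the
concentration cell is trace/censored. A compound is aroma-active in a sample
when its OAV is strictly greater than 1 (strict inequality, matching the
"higher than 1" convention).

A sample's aroma profile assigns each aroma category the **sum** of OAVs of
active compounds whose descriptor set intersects the category's term set.
Sum is the standard OAV-profile aggregator; mean and max are available. The
default descriptor → category map ships as an editable YAML derived from the
catalog's descriptor strings: the nine classic aroma elements (fruity,
floral, herbaceous, nutty, caramel, earthy, chemical, fatty, roasted)
extended with sour, green, sweet and fragrant, which the per-product aroma
summaries also use.

### Inconsistencies in the reference tables

Three internal inconsistencies exist between the printed concentration,
threshold and OAV tables; the package stores the tables as printed and keeps
the discrepancies visible instead of silently fixing them:

1. 2-methylbutyric acid: printed threshold 20 µg/L, but every printed OAV
   implies 70 µg/L (e.g. 13,432.09 / 191.887 = 70.0).
2. 2,3,5-trimethylpyrazine: printed threshold 400 µg/L, implied 1800 µg/L.
3. 2,3-dimethylpyrazine in B2: 3190.07 / 2500 = 1.276 > 1, yet the OAV table
   has no row for it and the text says it never reached threshold.

The packaged catalog therefore carries both a printed and an implied
threshold column (identical except for items 1-2). Cross-checks against the
printed OAV table use the implied thresholds and reproduce all 100 printed
cells to relative error ≤ 4.1e-4; active-set comparisons are scoped to
compounds that have a printed OAV row because of item 3.

## Group statistics

One-way ANOVA accepts raw replicates or summary statistics (mean, sd, n per
group); the summary route reconstructs SS_between from means and SS_within
from sds and is algebraically exact for any design.

Duncan's multiple range test is implemented from its definition: means are
sorted ascending and a pair spanning p positions is significant when the
difference exceeds `R_p = q(p, df_error) * sqrt(MS_error / n)`, where `q` is
the studentized-range quantile at the protected level `1 − (1 − α)^(p−1)`
(scipy's `studentized_range` supplies the quantile function; values at
α = 0.05, df = 12 match the published Duncan tables). Letters are assembled
with the insert-and-absorb compact-letter-display algorithm, with "a"
assigned to the smallest mean — the convention of the reference
concentration table, where "a" marks the lowest concentrations. The
critical-range formula assumes a balanced design; unbalanced groups raise an
error pointing at an explicit harmonic-mean workaround rather than silently
approximating. With k = 2 the procedure reduces to Fisher's LSD decision.

Consumer liking is compared across products with the tie-corrected
Kruskal-Wallis test, treating each rating as an independent observation
grouped by product — the phrasing of the original analysis implies this
reading even though every consumer rated all six products. A Friedman
variant that honors the repeated-measures structure is provided but off by
default. An exact-enumeration mode exists for tiny samples (≤ 10
observations) and is used to validate the p-value against a full
permutation distribution.

## Segmentation

PCA is computed by SVD of the centered (optionally autoscaled) matrix;
component signs are fixed by making the largest-magnitude loading entry of
each component positive, so results are bit-reproducible. Zero-variance
columns under scaling raise an error naming the column. Undefined OAV cells
impute to 0 (absence of aroma activity) before a samples × compounds PCA.

Consumers are clustered on their raw liking rows (not PCA scores; a flag
enables score-space clustering) with Lloyd's k-means: Euclidean distance,
`n_init = 50` random restarts, best within-cluster sum of squares kept,
empty clusters re-seeded at the farthest point. k defaults to 3 to match
the three-segment structure of the study; silhouette-based selection is
deliberately not automated. Labels are canonicalized by decreasing cluster
size, then by first-consumer position, so reports are stable. The
implementation tracks per-iteration inertia (monotonically non-increasing)
and agrees with scikit-learn's KMeans on fixtures; scikit-learn is used only
as a cross-check.

## Preference drivers (PLSR)

Per cluster, X is the products × compounds concentration matrix (not OAVs:
the stated analysis correlates *concentrations* with liking; an OAV switch
exists for exploration) and y is the cluster's mean liking per product.
"Scaled and centered" is read as column autoscaling of X plus centering of
y — the only standard reading for PLSR on heterogeneous volatile scales.

PLS1 is fit by NIPALS: `w = X'y / ||X'y||`, `t = Xw`, `p = X't / t't`,
`q = y't / t't`, deflate `X ← X − tp'`, `y ← y − qt`; coefficients
`B = W (P'W)^{-1} q`. Successive score vectors are mutually orthogonal
(checked to 1e-8), and with all `min(n−1, m)` components the coefficients
equal the least-squares solution. `n_components` defaults to 2 — six
products cap the usable rank at 5 and two components is the conventional
preference-mapping choice — configurable 1..4. Zero-variance predictors are
dropped (coefficient and importance 0); a constant y raises "no signal".

Relative importance of predictor j is `100 · |b_j| / Σ|b_k|`; importances
are non-negative and sum to 100. Rankings break ties by compound id. VIP
scores, jackknife uncertainty and cross-validated component selection are
documented extensions, not defaults.

## Synthetic data

The generators reproduce the *structure* of the study, because its raw
consumer-level data were never deposited.

* **Panel**: 86 consumers, 76 completers in three latent clusters of
  30/18/28. Each completer's row is their cluster archetype plus iid
  Gaussian noise (sd 1.0), rounded and clipped to the 1-7 scale; the ten
  non-completers lose one product score at random. The default archetypes
  encode the reported qualitative pattern — cluster 1 low overall but
  favoring B4/B6, cluster 2 favoring B2/B3, cluster 3 favoring B1/B3/B6 —
  with pairwise Euclidean separations of 4.2-4.8 scale units, chosen from a
  power analysis (misassignment probability ≈ Φ(−d/2σ) per boundary, i.e.
  ~2% per consumer) so that planted clusters are recoverable but not
  trivially separated. Demographics are sampled from a region table in
  which Beijing carries ~48% of consumers. Ordinal scores come from a
  round-and-clip Gaussian latent; a threshold-ordinal scheme was considered
  and rejected as adding parameters without changing what the recovery
  tests demonstrate.
* **Concentrations**: true sample × compound means are log-normal with
  class-specific parameters spanning the observed magnitudes (major
  esters/acids 1e5-1e7 µg/L, minor volatiles 1e1-1e3 µg/L); triplicate
  responses go through the forward calibration line with multiplicative
  noise at CV 0.05 (the accepted repeatability of the triplicate SPME
  design); trace cells are injected at probability 0.02.
* **Comments**: consumer × product mentions are drawn per polarity with
  probability proportional to how far the score sits from the scale
  midpoint, with terms multinomial over the 18 + 18 controlled vocabulary.
  Only nine vocabulary terms are known from the published consumer
  comments; the rest are synthetic placeholders and are marked as such in
  the YAML.

What passing these tests does *not* show: real consumers are not Gaussian
perturbations of three archetypes (segment structure in real panels is
fuzzier and cluster sizes are an outcome, not a parameter), real replicate
noise is not exactly multiplicative, and comment elicitation is richer than
a two-parameter multinomial. The synthetic results validate the
algorithms, not the original study's effect sizes.

## Quantities that are not reproducible at desk scale

The following printed values depend on the raw 76 × 6 consumer liking
matrix (and, for the PCA figure, on an unspecified input set and
preprocessing), none of which are deposited. They are therefore **not
reproducible** from this package and are deliberately not asserted
numerically anywhere:

* the 86.9% two-component variance figure of the volatile PCA (the compound
  subset, value type and scaling behind it are unstated; the packaged OAV
  matrix with undefined → 0 and no scaling yields 83.5% and reproduces the
  qualitative quadrant pattern — B3/B5 opposite B2/B6 on the first
  component — which is checked instead);
* the empirical cluster sizes 30/18/28 (they parameterize the synthetic
  generator; recovering them from regenerated data is a property of the
  generator, not a reproduction);
* the mean likings 3.60 (B6) and 3.18 (B1) and the 0.43 range of product
  means;
* the printed per-cluster importance percentages (e.g. 4.342935 for
  1-methylpyrrole-2-carboxaldehyde in cluster 1).

These are covered instead by the calibration, recovery and correctness
properties above (Kruskal-Wallis size, ARI-based segment recovery, PLSR
oracle equivalence and planted-driver recovery).

## Problem sizes and tolerances

The test suite and the acceptance script run at the study's own scale: 52
compounds × 6 products, 86-consumer panels, 2000 Monte-Carlo replicates for
test calibration, 20 seeds for segmentation recovery, 10 seeds for driver
recovery, 50 random 6-group toys for the Duncan oracle. Numerical
tolerances: OAV reproduction ≤ 1e-3 relative (printed tables carry 3
decimals); PLSR vs oracle 1e-8; PCA reconstruction 1e-10; score
orthogonality 1e-8.
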