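# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `poolgp`.

## Data model

The analysis unit is a *population* (a genebank accession of a wild,
outcrossing species), genotyped as a pool: one alternative-allele
frequency per population and marker, in [0, 1], with missing values
allowed. Phenotypes are plot-level records from balanced complete-block
trials in one or more environments. All downstream machinery —
kinship, GWAS, prediction — operates on the n × p frequency matrix, not on
individual genotypes; individual-level quantities (LD, inbreeding,
dominance) are not observable and not modelled.

## Trait means and heritability (phenostats)

Two fixed-effect ANOVA models are fitted by direct sums of squares, which
is exact for balanced data:

* model 1, one environment: `Y_ij = mu + g_i + b_j + E_ij`
* model 2, several environments:
  `Y_ijr = mu + g_i + env_j + (g x env)_ij + b/env_jr + E_ijr`

Unbalanced layouts are rejected with an explicit error rather than
approximated: the expected-mean-squares (EMS) estimators used for the
variance components are exact only under balance, the supported trial
designs are balanced, and a silent fall-back to an approximate analysis
would change the meaning of H². Negative EMS component estimates are
truncated at zero (standard practice). For the population F test in
model 2 the denominator is the g × env mean square, consistent with
environments and interaction treated as random. Under balance the EMS
estimates coincide with REML when the REML solution is interior, which
the test suite verifies against a brute-force restricted-likelihood
optimizer.

Adjusted (least-squares) means are `mu + g_i`; under balance they equal
raw population means, and the test suite checks them against a generic
OLS-prediction oracle. Across-environment means carry an `_avg` trait
suffix. Heritability indicators on a population-mean basis:

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / R)                  (model 1)
    H2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2/J + sigma_e^2/(J R)) (model 2)

with R blocks per environment and J environments; H² is defined as 0 when
the genetic component estimate is 0.

## Kinship and marker QC (grm)

Markers pass QC when the per-population minor allele frequency
min(x, 1−x) strictly exceeds `maf_min` (default 0.05) in at least
`min_pops` (default 10) populations, counting only non-missing values
(the filter precedes imputation). Missing entries are then replaced by
the marker mean. The relationship matrix is

    G = M M' / K,   K = 0.5 * sum_j xbar_j (1 - xbar_j)

with M column-centered. G is symmetrized and validated to be PSD up to a
small eigenvalue tolerance. Because LD cannot be computed from pools, the
correlation decay of frequency columns of same-scaffold marker pairs,
binned by bp distance, serves as its population-level proxy; both r² and
|r| are reported.

## Spatial statistics (spatialstats)

Distances between origin coordinates are great-circle (haversine, mean
Earth radius 6 371 008.8 m); the discrepancy against ellipsoidal geodesics
is below 0.5% and immaterial for the rank-based uses here. Moran's I is
computed with the raw-weight textbook formula; the default weights are
inverse distance with zero diagonal. The customary R implementation
row-normalizes the weight matrix first — `row_normalize=True` reproduces
that convention exactly (verified against reference values), and the
two-population identity I = −1 holds under both. The variance and p-value
use the randomization (permutation-moment) normal approximation; the raw
statistic is reported unclamped since some weight schemes push I outside
the nominal [−1, 1]. The Mantel correlation is the Pearson correlation of
strictly-lower-triangle entries, with a one-tailed (greater) permutation
p-value using the add-one correction `p = (1 + #{r* >= r}) / (n_perm + 1)`
and 500 permutations by default.

## Mixed-model GWAS (gwas)

The null model y = Xβ + u + e with u ~ N(0, σ²g G) is fitted by REML
through one spectral decomposition: eigendecompose S G S (S the projector
off col(X)), keep the n − rank(X) leading eigenpairs, and profile the
restricted likelihood over δ = σ²e/σ²g on a 100-point log grid spanning
10⁻⁵–10⁵ followed by bounded scalar refinement (tolerance 10⁻⁸ on log δ).
One subtlety: when G is rank-deficient the null space of S G S mixes
col(X) with null(G), so the projected response S y (not y) must be used
when forming the spectrum coordinates — otherwise fixed-effect signal
leaks into zero-eigenvalue directions and δ is badly overestimated.

Per-marker tests use the P3D shortcut: variance components frozen at the
null estimates, data whitened by H^{-1/2} (H = σ̂²g G + σ̂²e I), then a
vectorized per-marker regression with two-sided t tests on
n − rank(X) − 1 degrees of freedom. Exact per-marker REML (`p3d=False`)
is available for validation; P3D and exact p-values agree in rank above
0.99 in the test suite. With σ̂²g = 0 the scan reduces exactly to OLS.
Constant markers are flagged (β = 0, p = 1). Multiple testing uses
Benjamini–Hochberg adjusted p-values ("q-values" here, threshold 10%);
Storey-type estimation of the null proportion is not implemented.

Variance explained is reported two ways: R²_ols, the squared Pearson
correlation of the trait with the frequency column; and R²_kinship, the
partial R² of the marker after whitening both by the null H^{-1/2}. The
latter is this package's operational definition of "variance explained
with kinship taken into account" — a defensible but not uniquely
determined choice; it reduces to R²_ols as the genetic variance vanishes.
Redundancy pruning declares a marker "unlinked at threshold t" when its
maximum absolute correlation with every other listed marker is below t.
The forward stepwise model visits significant markers in p-value order
and admits one iff it lowers AIC, with candidates capped at n − 2.

## RR-BLUP genomic prediction (gpredict)

y = 1µ + Zu + e with Z the column-centered frequency matrix and
u ~ N(0, σ²u I). REML profiles δ = σ²e/σ²u through the spectrum of ZZ′
(shared machinery with the GWAS null model); the intercept is the GLS
estimate and BLUPs are û = Z′(ZZ′ + δI)⁻¹(y − 1µ̂). New data are centered
by the *training* column means so cross-validation never leaks holdout
information. The predictor is affine, so a synthetic cultivar assembled
as the mean of parent rows predicts exactly as the mean of its parents'
predictions — a property the test suite asserts. Equivalence with the
GBLUP route (G = ZZ′/K at matched shrinkage λ = δ/K) holds to 10⁻⁸.

Predictive ability is the Pearson correlation of observed and predicted
values on held-out populations; cross-validation repeats random
holdout-50 subsampling (default 100 repeats) with per-repeat seeds
spawned from one master seed. A genome-wide RR-BLUP dilutes a monogenic
signal across all markers — single-QTL traits are only predicted
near-perfectly when the QTL is in the fitted marker subset, which is
precisely the motivation for GWAS-informed marker selection.

Geographic-origin prediction treats longitude and latitude as traits in a
leave-one-out loop. The intercept of each fold's model is fixed at the
panel-wide coordinate mean rather than re-estimated: a per-fold GLS
intercept tracks −y_i/(n−1), and when the genotype carries no geographic
signal the predictions are near-constant, so that mechanical term drives
the fold correlation to −1. Fixing the intercept leaves a negligible 1/n
contribution of the held-out value and restores the expected behaviour
(correlation ≈ 0 without isolation by distance, strongly positive with
it). Prediction error is reported as the great-circle distance between
predicted and true coordinates.

## Calibration-set optimization (calibopt)

Procedures 1–2 cluster a distance matrix (genetic Euclidean or geographic
great-circle) with Ward linkage into k groups and select the member of
each group with the lowest mean within-group distance (ties break on the
lexicographically smallest id). Ward is used because the linkage of the
constrained variant is Ward-like and it yields compact strata; it is a
parameter, not a claim of fidelity. Procedure 3 max-normalizes both
dissimilarities and blends their squares, (1−α)D²_gen + αD²_geo (default
α = 0.5) — Ward pseudo-inertia is linear in squared dissimilarities, so
this blends the two criteria exactly, and α = 0 or 1 degenerates to the
single-matrix procedures. Procedure 4 maximizes CDmean by randomized
exchange: from a seeded random k-subset, 1000 iterations each propose
swapping one selected with one unselected population, keeping only
improvements. The CD of an unphenotyped population i is

    CD_i = [G - lambda (Z'PZ + lambda G_r^-)^{-1}]_ii / G_ii

with Z the calibration incidence, P the projector off the calibration
intercept, λ the residual-to-genetic variance ratio (default 1,
i.e. an assumed h² of 0.5 — the ratio actually used is logged in the
selection metadata), and G_r^- a ridge-stabilized inverse
(ridge 10⁻⁶ × mean diagonal) because a pooled-frequency G is often
near-singular.

A calibration set is scored by training on it, predicting all remaining
populations, and locating the resulting predictive ability within the
envelope of 100 random same-size sets:
score = (OptPA − MinPA)/(MaxPA − MinPA). Scores outside [0, 1] are
legitimate (an optimized set can beat every random set). Degenerate
(constant) predictions give NaN abilities and are excluded from the
envelope.

GWAS-informed marker selection runs a kinship-only GWAS on the
calibration populations, then visits markers by ascending p-value and
admits each as a fixed effect iff the nested-model F test improves at 5%,
capped at the calibration size; the selection never touches validation
data. Marker-number curves fit RR-BLUP models with growing marker sets —
GWAS-set markers first, then random markers one at a time (and, for the
contrast, random markers from the start) — and report the smallest count
reaching 95% of the raw curve maximum (no smoothing; first count
attaining the threshold).

## Synthetic data (simdata)

The generator emulates the summary statistics of a spatially structured
wild collection; it is a stand-in constrained by those statistics, not a
population-genetic simulation.

* **Frequencies.** For each scaffold, a matrix-normal draw with separable
  covariance: across populations, a unit-diagonal kernel
  `w·exp(−d_km/ibd_range_km) + (1−w)·I` (exponential isolation-by-distance
  decay mixed with a white nugget); across markers within the scaffold,
  `exp(−Δbp/within_scaffold_corr)`. The field, scaled by `logit_sd`, is
  added to the logit of an ancestral frequency drawn from Beta(maf_shape,
  1) folded to the minor allele (rare-allele skew) and inverse-logit
  transformed, guaranteeing frequencies in (0, 1). A shared latent factor
  with position-dependent loadings was considered and rejected: loadings
  depending only on position cannot make between-marker correlation a
  function of bp *distance*, which the separable kernel gives exactly.
* **Defaults.** `ibd_range_km = 550`, `spatial_weight = 0.3`,
  `logit_sd = 1.2` were calibrated once by bisection so that the Mantel
  correlation between genetic and geographic distances on the reference
  configuration (200 populations in a Europe-like bounding box, 2000
  markers) is ≈ 0.44 — the degree of spatial genetic structure typical of
  such collections — and frozen; across seeds the realized correlation
  spans ≈ 0.42–0.50. `maf_shape = 0.4` puts the median minor-allele
  frequency below 0.25; `within_scaffold_corr = 10 kb` against 50 kb
  scaffolds gives visible correlation decay within the sampled range.
* **Phenotypes.** Genetic values g = Σ a_q x_q over QTL sampled uniformly
  (Gaussian effects by default, signed-exponential for few-large-effect
  architectures), standardized; plot values add environment, nested
  block, G×E interaction and residual noise, all balanced. Interaction
  and residual variances are solved from the target heritability
  indicator (σ²ge/J + σ²e/(JR) = σ²g(1−h²)/h²), with `gxe_share`
  splitting the non-genetic budget; the model-2 H² estimator therefore
  recovers `h2_pop` in expectation, which the tests verify on a
  0.2/0.5/0.9 grid. h2_pop = 0 or n_qtl = 0 produce pure-noise traits.
* **Missingness.** Independent Bernoulli masking at the requested rate
  with per-marker missingness capped at 33%, the plausible upper range
  for pooled genotyping; the cap also guarantees every marker stays
  imputable.

What passing tests on these data do **not** show: robustness to
unbalanced designs, genotyping error, non-Gaussian trait noise, discrete
subpopulation structure (the generator's structure is continuous
isolation by distance), allele-frequency estimation noise from finite
read depth, or selection. Real pooled data also couple missingness with
coverage; here it is independent.

## Problem sizes and numerical choices

The validation suite runs at desk scale — 30–300 populations and
300–5000 markers, chosen so the full suite completes in a few minutes
while still exercising every code path at the sizes where the asymptotic
approximations (normal Moran p, P3D, BH) behave. Spectral REML is exact
and O(n³) per fit, comfortably fast for n ≤ 10³. Tolerances: kinship PSD
to −10⁻⁸ (relative), GLS-oracle agreement to 10⁻⁸, BH-oracle to 10⁻¹²,
REML grid optimality to 10⁻⁴, RR-BLUP/GBLUP identity to 10⁻⁸. Tie-breaks
are deterministic everywhere (lexicographic ids in cluster
representatives, stable sorts in p-value orderings), so every function is
bit-reproducible given its seed.

## Known limitations

* Balanced designs only for ANOVA; no Satterthwaite/REML path for
  unbalanced trials.
* The "variance explained with kinship" definition (whitened partial R²)
  is one reasonable operationalization among several.
* BH is the only FDR procedure; Storey's π₀ estimation is not included.
* CDmean's λ is a user parameter, not estimated per trait.
* The pipeline treats traits independently; no multi-trait models.
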