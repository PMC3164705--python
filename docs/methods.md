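# Methods

This note documents the models, conventions and numerical choices behind
`utilidiv`, and what the synthetic-data tests do and do not demonstrate
about real survey data.

## Trait space

Species are described by six utilitarian properties: `construction` and
`firewood` as preference ranks on {0,1,2,3} (0 = not used, 1 = least,
2 = moderate, 3 = high preference), and `medicinal`, `food`, `tools`,
`furniture` as 0/1 use indicators. The 0 level encodes non-use alongside
the three preference categories used for ranked properties.

**Gower dissimilarity.** d(i,j) = Σₖ wₖ δₖ / Σₖ wₖ, with
δₖ = |xᵢₖ − xⱼₖ| / rangeₖ for ordinal properties (ranks treated as
interval-scaled after range normalization; δₖ = 0 when the pool range is
0) and δₖ = 1[xᵢₖ ≠ xⱼₖ] for binary ones. Two deliberate choices:

* *Symmetric binary treatment.* Shared absence of a use (e.g. neither
  species is medicinal) counts as similarity, unlike Gower's asymmetric
  presence coefficient. For utilitarian similarity, "not used for X" is
  informative, not missing.
* *Zero-range properties* contribute 0 but stay in the denominator, so
  distances remain in [0,1] and comparable across property subsets.

Weights default to 1 per property and are exposed per property.

**Dendrogram.** Agglomerative clustering via scipy; candidates are UPGMA,
single, complete and WPGMA (centroid/median/Ward are excluded: non-monotone
or variance-based). The retained tree maximizes the Pearson correlation
between cophenetic and input distances; exact ties go to the earliest
candidate, UPGMA first. Non-monotone height sequences are refused at
construction because edge lengths would go negative.

Edge lengths follow the hclust convention — tips at height 0, internal
nodes at merge height, edge = height difference. FD values depend on this
convention, so it is stamped into every run's metadata. Discrete trait
profiles duplicate freely, so tied merge distances are common; merge order
under ties follows scipy's deterministic nearest-neighbor-chain algorithm,
which makes runs reproducible but means tie resolution is an implementation
detail, not a scientific claim.

## Functional diversity

FD of a plot is the summed edge length of the minimal connected subtree of
the *pool* dendrogram spanning the plot's species: an edge above node v
counts exactly when v's subtree contains a nonempty proper subset of the
members. Consequences: a singleton plot has FD = 0 (continuity, standard
for monocultures); the stem from the members' MRCA to the root is *not*
counted (the alternative inflates every FD equally; the choice is recorded
in metadata); the full pool's FD is the total tree length. The dendrogram
is built once from the full pool — per-plot re-clustering would destroy
cross-plot comparability and invalidate the null model.

The implementation accumulates per-node member counts bottom-up in merge
order (vectorized across thousands of membership vectors at once). An
independent brute-force oracle — remove each edge, test whether two members
are separated — is kept in the package for cross-checks and used
exhaustively in the tests.

## Null model and Index of Variance

Null communities hold richness S fixed and draw S species uniformly
without replacement from the pool (no abundance weighting — nothing in the
sampling design justifies weights). Default 5000 draws per plot; each plot
gets independent draws even at equal S, so significance flags are
independent across plots. Two-sided assessment at α = 0.05: flag `higher`
above the null 97.5th percentile, `lower` below the 2.5th (percentiles by
linear interpolation); tail p-values use the add-one convention
p = (1 + #extreme)/(1 + n_iter).

IV = (Obs − Exp)/Exp, the relative deviation of observed FD from the null
mean: 0 when observed matches expectation, positive for low redundancy.
An `iv_form="ratio"` switch reports plain Obs/Exp for sensitivity checks.
Exp ≤ 0 (only possible for degenerate pools) is an error, not a value.

**Property importance** removes one property at a time and rebuilds the
Gower matrix and dendrogram from scratch — Gower renormalizes over the
remaining properties, so pruning the six-property tree would be wrong.
The linkage method is held fixed at the full-table winner so that removals
are compared on one clustering rule. Mean observed FD across plots with
and without the property gives the drop; rank 1 = largest drop. A removal
that leaves an all-constant table is reported as NaN and ranked last. Note
that removing even a *constant* property changes FD by the denominator
renormalization (×6/5); the drop is a relative, not absolute, measure.

## Drivers (GLM stage)

IV is regressed on up to six covariates with Gaussian errors and identity
link (ordinary least squares, via statsmodels). All 2⁶ = 64 predictor
subsets are fitted; AIC = −2ℓ + 2k with k = p + 2 (intercept, slopes,
error variance — ΔAIC and Akaike weights are invariant to the constant),
weights exp(−Δᵢ/2) normalized over the candidate set, supported set
ΔAIC < 2. Predictors enter raw (unstandardized), so coefficients are on
field scales (m²/ha, meters, counts); reported df is n − (p + 1). Plots
lacking either covariates or IV are dropped with a logged count.
Rank-deficient designs raise a collinearity error naming the predictors.
AICc is not applied by default; at n ≈ 56 and p ≤ 6 the correction does
not change orderings materially, and the package reports plain AIC.

## Regression trees (CART stage)

One tree per village-distance band (the transect design's
0/100/200/400/800/1600/3200 m), pooled across sites, predicting per-stem
DBH from the six properties. Splits minimize within-node sum of squares
(sklearn's squared-error criterion); `min_leaf` = 5 stems per leaf.
Ordinal splits are rendered as "property ≥ level", binary as
"property = 1" (right branch = the rated/used side).

Size selection: cost-complexity pruning path from the full tree, 10-fold
cross-validated mean squared prediction error per complexity, and the
**1-SE rule** — the smallest tree within one standard error of the minimum
CV error. The plain minimum-CV rule (`se_rule=0`) is available but not the
default: on pure-noise responses it retains a spurious split in roughly a
third of replicates, whereas the 1-SE rule prunes to the root essentially
always while still recovering noise-free planted splits exactly. Ties in
CV error go to the smaller tree.

Fit is the Pearson correlation of leaf-mean predictions with observed DBH;
a single-leaf model predicts a constant and is reported as r = 0 with an
explicit flag rather than NaN. A per-species-mean response mode is
available behind a flag (`per_species_mean`); per-stem is the default.

## Synthetic data

The generator emulates the survey design end-to-end: 8 sites × 7 plots on
edge-to-interior transects (56 plots), an 80-species pool, richness 8–30
per plot. Per-property marginals (ordinal multinomial 0.4/0.2/0.2/0.2,
binary rate 0.3) are uniform-ish placeholders — no depositable field data
exists to calibrate them, and they are labelled synthetic throughout.

Planted structure, one knob per pipeline stage:

* **Assembly** — `random` (uniform S-subsets; IV centers on 0),
  `clustered` (neighbors sampled with weight ∝ exp(−d/τ), τ = 0.08 Gower
  units; low FD, negative IV), `dispersed` (greedy max–min distance
  selection with 5% random picks; high FD, positive IV). Redundancy is
  planted through assembly rules on the trait dendrogram rather than by
  fixing IV directly — mirroring the causal chain harvest → composition →
  redundancy.
* **Covariates** — field-plausible ranges (basal area 10–80 m²/ha, canopy
  ~N(18,4) m, elevation 600–1200 m, human-pressure counts decaying with
  distance); `planted_iv` adds a linear covariate effect
  (default basal-area slope −6×10⁻⁴, noise sd 0.05, Table-1-scale
  magnitudes) so GLM recovery is checkable against known slopes.
* **Stems** — 1 + Poisson(2) stems per member species; DBH lognormal with
  a log-mean shift for species with firewood ≥ 2 (means 30 vs 110 cm,
  log-sd 0.35), truncated at the 10 cm survey floor; log-sd 0 gives exact
  noise-free means for split-recovery tests.

Everything is determined by one master seed, and every generated table
passes the same validation as read CSVs.

**What passing tests show — and don't.** The generator matches the
pipeline's assumptions by construction (linear covariate effects with
Gaussian noise, equiprobable null sampling, a single threshold DBH rule).
Passing therefore demonstrates correctness and calibration of the
*implementation* — type-I error ≈ α, unbiased expected FD, planted-effect
recovery at stated power — not robustness to real-data features it does
not emulate: spatial autocorrelation among plots, abundance-biased
detection, preference drift between villages, correlated properties, or
misspecified covariate relationships. Misspecification scenarios are
config options, not defaults.

## Problem sizes and tolerances

Statistical checks run at sizes where their Monte-Carlo error is small
relative to the asserted bands: 1000 plots / 999 null draws for type-I
calibration (two-sided band 0.035–0.065 around α = 0.05), 200 plots per
assembly mode for power, 200 replicates at n = 500 for GLM selection,
100 replicates for CART noise control, exhaustive enumeration (255 and
C(6,3) = 20 subsets) for the FD and null-expectation oracles. Oracle
agreement is asserted to 10⁻¹² relative (two summation orders of the same
edge lengths); Newick export carries 12 significant digits, round-trip
faithful to well below 10⁻⁹.

## Known limitations

* Tie resolution among equal Gower distances follows scipy's agglomeration
  order; topologies (not FD calibration) can differ across scipy versions.
* The null model is richness-constrained only; occurrence-frequency-
  preserving (independent-swap) nulls are out of scope by design.
* Missing trait values are a validation error, not an imputation problem.
* Coefficient model-averaging and spatial random effects are deliberately
  absent from the GLM stage.
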