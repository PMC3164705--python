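# utilidiv

Utilitarian (functional) diversity and redundancy analysis for forest plot
surveys.

Subsistence communities rely on forest plants for construction wood,
firewood, medicine, food, tools and furniture. `utilidiv` quantifies how
diverse — and how redundant — those *utilitarian properties* are within
tree assemblages, and what drives their variation, using the machinery of
community-ecology functional diversity:

1. **Trait space.** Species are scored on six utilitarian properties
   (construction and firewood as preference ranks 0–3; medicinal, food,
   tools, furniture as 0/1). Pairwise dissimilarity is the Gower
   coefficient for mixed data, d(i,j) = Σₖ wₖ δₖ(i,j) / Σₖ wₖ with
   range-normalized differences for ordinal properties and mismatch
   indicators for binary ones. Agglomerative clustering (UPGMA, single,
   complete, WPGMA) builds candidate dendrograms; the tree with the highest
   cophenetic correlation to the input distances is kept (UPGMA wins ties).
2. **Functional diversity.** Per plot, FD is the total branch length of the
   smallest subtree of the pool dendrogram connecting the plot's species
   (the dendrogram-based FD of Petchey & Gaston; tips at height 0, edge
   length = merge-height difference, no root stem).
3. **Null model and redundancy.** For each plot of richness S, 5000 null
   communities are drawn uniformly from the species pool at the same S.
   The Index of Variance IV = (Obs − Exp)/Exp compares observed FD to the
   null mean; plots outside the null 2.5–97.5 percentiles are flagged
   (two-sided α = 0.05). Positive IV = species more utilitarianly distinct
   than chance = **low redundancy**. Removing one property at a time and
   recomputing everything ranks properties by the FD drop their loss causes.
4. **Drivers.** IV is regressed on six plot covariates (basal area, felled
   trees, canopy height, distance from village, trails, elevation) with
   Gaussian-identity GLMs over all 64 predictor subsets, ranked by AIC with
   Akaike weights wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2); ΔAIC < 2 marks the
   supported set.
5. **Tree size.** CART regression trees predict stem DBH from the six
   properties, one tree per village-distance band (0–3200 m), grown on
   within-node sum of squares and pruned by 10-fold cross-validated
   cost-complexity (1-SE rule), evaluated by the Pearson correlation of
   predicted to observed DBH.

A synthetic-data generator emulates the full survey (8 sites × 7 plots on
edge-to-interior transects) with planted assembly structure, covariate
effects and DBH rules, so every stage can be validated against a known
truth.

## Worked example

```bash
utilidiv run --synthetic --seed 1 --out results/demo
```

runs the whole pipeline on the default synthetic survey (80 species, 56
plots) and prints, among other lines:

```
plots: 56
flagged higher (low redundancy): 0
flagged lower (high redundancy): 0
not significant: 56
mean IV: 0.0106

property importance (rank: drop in mean FD on removal):
  1. tools: FD_all=5.289 FD_without=4.662 drop=0.628
  2. construction: FD_all=5.289 FD_without=4.686 drop=0.604
  ...

supported GLMs (delta AIC < 2):
  intercept-only: AIC=-153.3 dAIC=0.00 weight=0.121 R2=0.000
  ...
```

Read this as: under random community assembly (the generator's default) no
plot has significantly more or less utilitarian diversity than richness
alone predicts, the mean Index of Variance is near zero, every property's
removal costs a comparable amount of trait-space structure (none was
planted as dominant), and the intercept-only GLM wins — there is no
covariate effect to find, exactly as generated. The same
analysis runs on real CSVs via `--traits/--communities/--covariates/--stems`
(schemas in `utilidiv.data`); `utilidiv simulate` writes a synthetic
four-table survey plus its planted truth, and `utilidiv summarize` digests
a completed results directory.

Library use mirrors the CLI:

```python
from utilidiv import RunConfig, SyntheticConfig, run_pipeline, summarize

result = run_pipeline(RunConfig(synthetic=SyntheticConfig(), seed=1, outdir="results/demo"))
print(summarize(result))
```

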