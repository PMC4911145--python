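# flankfda

Functional-data analysis of genomic landscapes flanking element
integration sites.

Given two groups of genomic regions (e.g. transposable-element flanks vs
matched controls), the package quantifies feature tracks over ordered
1-kb windows around each integration site and asks *which* features
separate the groups, at *which* locations and *scales*, and *how they act
jointly*:

1. **Window quantification** (`flankfda.windows`) — ±32-kb flanks split
   into 64 windows (configurable), with per-window **content** (covered
   fraction), **count**, or bp-weighted **average** of BED/bedGraph
   tracks; element filtering (length bounds, assembly-gap overlap,
   mutual flank overlap) and seeded control-region placement.
2. **Feature screening** (`flankfda.screen`) — complete-linkage
   clustering on 1 − |Spearman ρ|, one representative per cluster above
   a 0.8 correlation threshold.
3. **Interval-wise testing** (`flankfda.itp`) — synchronized two-sample
   permutation tests per window (mean difference, median difference,
   variance ratio), nonparametric combination over every contiguous
   window interval, and adjusted p-values `A(L, k)` controlling the
   family-wise error rate over intervals at every maximum length
   `L = 1..K`. Features are classified as invariant (IDL: shifted
   everywhere), localized (LDL: shifted at specific windows/scales) or
   not significant.
4. **Logistic modeling** (`flankfda.flr`) — single fits per predictor
   with deviance explained (DE); shifted-log regularization of skewed
   predictors; set-aside of dominant predictors (DE > 20%); LASSO subset
   selection of scalar predictors by 10-fold CV misclassification;
   forward addition of functional (interval-mean) predictors with a
   ΔDE > 1% + AIC-decrease rule; backward pruning of non-significant
   scalars; per-predictor relative contribution to DE (RCDE).
5. **Pipeline** (`flankfda.pipeline`) — the whole comparison from one
   YAML config, with TSV reports and a JSON manifest; deterministic
   given the seed.
6. **Synthetic data** (`flankfda.synthetic`) — seeded generators for
   curves with known IDL/LDL/null structure (AR(1) window noise,
   gaussian/lognormal/bounded marginals), scalar features, and toy
   BED/bedGraph fixtures that quantify back to the generator's intent
   exactly.

## CLI

```sh
# synthetic curves from a YAML spec
flankfda simulate --spec sim.yaml --out simdir/

# quantify tracks over element flanks
flankfda quantify --elements elems.bed --chrom-sizes genome.sizes \
    --track gene_content=genes.bed:content \
    --track methylation=meth.bedgraph:weighted_average \
    --flank-kb 32 --window-kb 1 --out curves/

# interval-wise testing of every curve feature
flankfda itp --curves curves/ --groups labels.tsv \
    --stats mean_diff,median_diff,var_ratio --n-perm 10000 \
    --basis 65 --alpha 0.05 --seed 1 --out itp_out/

# single + multiple logistic modeling from the classification summary
flankfda flr --curves curves/ --groups labels.tsv \
    --classifications itp_out/itp_summary.tsv --out flr_out/

# or everything from one config
flankfda run --config comparison.yaml --out run_out/
```

Element BED files carry the class label in column 5:
`chrom  start  end  id  class_label  strand` with
`class_label ∈ {fixed, polymorphic, in_vitro, control}`. Curve matrices
are TSV with a `region_id` column and one column per window
(`-32 … -1, +1 … +32`). Group labels are a TSV with `region_id` and a
binary `label` column (1 = group 1).

A comparison config (see `flankfda.pipeline.run_from_config`) lists the
curve TSVs, the label file, optional low-resolution scalar tables, and
any threshold overrides (`alpha`, `n_perm`, `statistics`, `basis_nodes`,
`screen_threshold`, `de_threshold`, …).

## Notes on statistical conventions

- Permutation p-values count ties as extreme and include the identity
  assignment, so `p ≥ 1/n_perm`; samples with `n1+n2 ≤ 10` use
  exhaustive enumeration.
- All tests are two-sided; signs of the observed statistics are
  reported separately for enrichment/depletion calls.
- Interval tests combine synchronized component tests with Fisher's
  rule by default (Tippett min-p available).
- `A(L, k)` is non-decreasing in `L`; `A(1, ·)` are raw component
  p-values and `A(K, ·)` is the classical max-over-all-intervals
  adjustment with strong FWER control. Classification ignores
  significance confined to scales below `K/4` (configurable), where the
  sub-maximal correction admits nominal-rate false component hits.
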