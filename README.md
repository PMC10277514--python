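# seromics

Analysis toolkit for multiplex serum inflammatory proteomics on the NPX
(log2-like) scale, built around a case/case/control liver-disease cohort
design (healthy controls, NAFL, NASH):

- **QC filtering** — proteins detected in more than 10% of samples below the
  limit of detection are excluded from analysis (strictly-greater rule).
- **Differential abundance** — per-protein two-sided Mann–Whitney tests with
  median-difference effects (and their linear-scale 2^Δ ratios), corrected
  jointly by the two-stage Benjamini–Krieger–Yekutieli linear step-up FDR at
  Q = 5%; confounder-stratified re-testing (fibrosis stage 0–1 vs 2–4, BMI,
  T2D, hypertension, sex, age median split) and reference-group median
  heat-map normalization.
- **Biomarker panels** — empirical ROC per protein, thresholding at a target
  specificity (default 0.76 and 0.90), k-of-n combination rules with their
  full (k, sensitivity, specificity) continuum, exact McNemar comparison of
  paired rules, and marker-subset selection by exhaustive AIC search over
  maximum-likelihood logistic fits.
- **Differential co-expression** — group-wise Spearman matrices, residual
  (difference) matrices, Ward/Euclidean clustering of residual profiles, and
  per-cluster enrichment summaries.
- **Subgroup discovery** — Ward clustering of samples in marker-gene space,
  pairwise differentially-expressed-gene counts between clusters (Welch test
  + two-stage FDR), and a random-cluster permutation null for calibration.
- **Synthetic data** — a cohort generator with planted mean shifts,
  group-specific correlation blocks, left-censoring at a per-protein LOD and
  comorbidity covariates, plus a subgrouped transcriptome generator; both
  return the ground truth used by the recovery tests.

All statistical primitives (Mann–Whitney with exact enumeration, chi-square,
Spearman, two-stage FDR, exact McNemar, deterministic Ward linkage with
lexicographic tie-breaks) live in `seromics.stats` and are validated against
independent brute-force oracles in the test suite.

## CLI

```sh
seromics simulate --seed 1 --out sim/              # synthetic cohort + truth
seromics filter --npx sim/npx_wide.tsv --lod sim/npx_below_lod.tsv --out filt/
seromics diff --npx filt/filtered_npx.tsv --metadata sim/metadata.tsv \
    --group-a NASH --group-b NAFL --out diff.tsv --plot volcano.png
seromics diff ... --stratify fibrosis --out strat.tsv
seromics panel --npx filt/filtered_npx.tsv --metadata sim/metadata.tsv \
    --target-spec 0.76 --target-spec 0.90 --max-size 6 --out panel/
seromics coexpr --npx filt/filtered_npx.tsv --metadata sim/metadata.tsv \
    --contrast NASH,NAFL --out coexpr/
seromics subgroups --expr expr.tsv --markers g1,g2,g3,g4,g5,g6 --k 8 \
    --null-perms 1000 --seed 1 --out subgroups/
seromics run --npx sim/npx_wide.tsv --lod sim/npx_below_lod.tsv \
    --metadata sim/metadata.tsv --seed 1 --out run/
```

`run` executes filter → differential → stratified → panel → co-expression
(→ subgroups, when a transcriptome and markers are configured) and writes
per-stage TSV/JSON plus a `manifest.json` with parameters, derived seeds and
SHA-256 hashes of every output; reruns with the same config and seed are
byte-identical.

### File formats

- wide TSV: samples × proteins with a header row; optional companion TSV of
  below-LOD flags (0/1) of the same shape
- long CSV: `sample_id,protein_id,npx,below_lod`
- metadata TSV: `sample_id`, `group` (HC/NAFL/NASH) plus optional histology
  (`nas` must equal steatosis + lobular inflammation + ballooning),
  comorbidity and demographic columns

All files are UTF-8 with `NA` as the missing-value token.

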