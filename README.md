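# pairsig

Rank-based immune lncRNA **pair** prognostic signatures for survival cohorts.

Instead of modeling raw expression, the pipeline works on binary pair
indicators — for an ordered pair of lncRNAs (X, Y) a sample scores 1 iff
`expr(X) >= expr(Y)` — which makes every downstream quantity invariant to
per-sample normalization. The stages:

1. **Screen** (`pairsig.screen`): retain lncRNAs co-expressed with an
   immune gene list (Pearson |r| > 0.4, p < 0.001), then call
   differential expression tumor-vs-normal (|log2FC| > 1, BH-FDR < 0.05,
   Welch t on log2(x+eps)).
2. **Pair** (`pairsig.pairs`): build the 0/1 pair matrix over all C(n,2)
   pairs and drop pairs whose rarer value occurs in <20% of samples.
3. **Select** (`pairsig.signature`): univariate Cox screen (p < 0.05) →
   repeated cross-validated LASSO-Cox, counting how often each pair is
   selected at lambda_min over many random fold reassignments → pairs above
   the frequency threshold → multivariate Cox with backward-AIC reduction.
   Risk score = Σ coef(i) × E(i).
4. **Evaluate** (`pairsig.evaluation`): time-dependent ROC/AUC at 1/2/3
   years (cumulative-case / dynamic-control with Kaplan–Meier censoring
   correction), Youden-index cutoff, risk-group assignment, KM + log-rank,
   independence analysis against clinical covariates, chi-square and
   rank-sum association tests.
5. **Microenvironment** (`pairsig.microenv`): single-sample rank-enrichment
   (ssGSEA-style) stromal/immune scores with their exact sum, Spearman
   correlation of risk scores with immune-cell abundance tables, and
   checkpoint-gene group comparisons.

Survival statistics (`pairsig.survival`) are first-principles: Newton–Raphson
Cox partial-likelihood fitting with the Efron tie correction and explicit
monotone-likelihood (separation) flagging, product-limit Kaplan–Meier, and
the two-group log-rank test.

A synthetic-cohort generator (`pairsig.synthetic`) emits tumor/normal
expression with immune co-expression structure, planted differentially
expressed lncRNAs, Weibull survival driven by planted pair indicators,
calibrated censoring, and a ground-truth record — so the whole pipeline is
verifiable end to end without external data.

## CLI

```sh
# simulate a cohort (config is a YAML mapping of CohortSpec fields)
pairsig simulate --config cohort.yaml --outdir data --seed 7

# stage by stage
pairsig screen  --expr data/expression.tsv --gtf data/annotation.gtf \
                --immune-genes data/immune_genes.txt \
                --clinical data/clinical.tsv --outdir out
pairsig pair    --expr data/expression.tsv --de-lnc out/deirlncRNAs.tsv \
                --clinical data/clinical.tsv --outdir out
pairsig select  --pairs out/pairs.tsv --clinical data/clinical.tsv \
                --cycles 1000 --folds 10 --freq-thresh 100 --seed 7 --outdir out
pairsig fit     --pairs out/pairs.tsv --clinical data/clinical.tsv \
                --selected out/selected_pairs.txt --outdir out
pairsig score   --model out/model.json --pairs out/pairs.tsv --outdir out
pairsig evaluate --scores out/risk_scores.tsv --clinical data/clinical.tsv \
                --horizons 365,730,1095 --outdir out
pairsig microenv --expr data/expression.tsv --gene-sets sets.gmt \
                --scores out/risk_scores.tsv --outdir out

# or everything at once on a simulated cohort
pairsig run --config cohort.yaml --outdir out --seed 7 --cycles 100
```

Every subcommand accepts `--log-level {debug,info,warning,error}`.

Samples present in the clinical table are treated as tumors; matrix samples
absent from it are treated as normals.

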