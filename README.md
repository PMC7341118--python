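# stagepath

Stage-stratified co-expression and pathway-imbalance analysis of tumor
expression cohorts, with an SVM classifier separating early (stage I/II)
from advanced (stage III/IV) disease.

Tumor staging studies often ask which genes and pathways change as disease
progresses, and whether those changes can classify a new sample. Single
genes are noisy, platform-dependent markers; pathway-level summaries are
more stable. `stagepath` implements that idea end to end for a four-stage
cohort (e.g. lung adenocarcinoma stages I–IV): from a gene × sample
expression matrix and stage labels it derives per-stage feature genes,
co-expression networks, pathway enrichment, a per-sample pathway imbalance
score, and a cross-validated early/advanced classifier. A synthetic-cohort
generator with planted ground truth makes the whole chain testable without
access to a real cohort.

## The method

1. **Preprocess** — drop genes/samples with >10% missing values, impute
   per-gene means, z-score every sample against the stage-I (control)
   mean and sample SD, so control expression is standard normal per gene.
2. **Feature genes** — keep genes whose signed coefficient of variation
   (CV = mean/SD on the z scale) falls outside the empirical quartiles;
   screen by four-group one-way ANOVA (P < 0.05); assign significant genes
   to stage feature sets via TukeyHSD pairwise contrasts (Tukey–Kramer for
   unbalanced groups).
3. **Co-expression** — connect gene pairs with |Pearson r| > 0.5 (sign
   recorded), per stage and globally; summarize topology (average shortest
   path, closeness, clustering, degree) and convert degree into gene
   weights ω = 1/(1+e^(−degree)) ∈ [0.5, 1).
4. **Enrichment** — one-sided Fisher exact test of each stage's feature
   set against a GMT pathway collection over the CV-candidate background.
5. **Pathway imbalance** — per sample and enriched pathway,

       A(P) = log2( Σ_up ω_i (X_i − μ_i)² / Σ_down ω_j (X_j − μ_j)² )

   with μ the control baseline: 0 is balance, >0 up-dominant, <0
   down-dominant. Pathways whose scores differ across stages (ANOVA
   P < 0.05) become classifier features.
6. **Classifier** — stages I/II vs III/IV, RBF-kernel SVM on the pathway
   scores with recursive feature elimination (one-standard-error rule) and
   (C, γ) grid search nested inside stratified five-fold cross-validation;
   reports per-fold ROC, AUC, accuracy and precision.

See `docs/methods.md` for conventions, defaults and design rationale.

## Worked example

The numbered scripts under `analysis/` run the reference synthetic study
(1,000 genes, 50 samples per stage, 20 pathways, 4 planted with a
stage-drifting imbalance at effect 1.5 SD) and write their tables under
`results/`:

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_feature_genes.py
python analysis/04_coexpression.py
python analysis/05_enrichment_and_scores.py
python analysis/06_classifier.py
```

Output of the run (seed 1):

```
CV filter kept 500/1000 genes (50%)
ANOVA (P<0.05): 109 genes; per-stage sizes I=100, II=93, III=86, IV=93; shared by all four stages: 81
planted-gene recall in the union of stage sets: 80/80
...
stage I: 100 nodes, 517 edges (517 positive / 0 negative), ASP = 1.295
global: 102 nodes, 1010 edges (597 positive / 413 negative) — supplies the gene weights
...
screened (score-ANOVA P<0.05): ['PW000', 'PW001', 'PW002', 'PW003'] — 4/4 planted recovered
  mean A(P) in stage I:  PW000=-0.04, PW001=-0.18, PW002=-0.01, PW003=+0.00
  mean A(P) in stage IV: PW000=+2.69, PW001=-2.69, PW002=+3.43, PW003=-2.63
...
five-fold CV (RFE nested per fold): mean AUC = 0.880, accuracy = 0.810, precision = 0.800
```

Reading: half the genes pass the CV filter (the quartile rule by
construction), all 80 planted differential genes land in the stage feature
sets, the four planted pathways are enriched and screened, their mean
imbalance score drifts from ≈0 in the control stage to ±2.7 log2 units in
stage IV with the planted sign, and the SVM separates early from advanced
samples with cross-validated AUC 0.88.

The same pipeline is available as a CLI (`stagepath simulate | validate |
preprocess | select-features | network | enrich | score | classify | run`)
for file-based use; `stagepath run` writes every intermediate plus a
deterministic `manifest.json`.

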