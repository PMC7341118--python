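# Methods

`stagepath` implements a stage-stratified analysis of bulk tumor expression
cohorts: it extracts stage-specific feature genes, builds co-expression
networks per stage, quantifies pathway-level up/down imbalance per sample,
and classifies early (stage I/II) versus advanced (stage III/IV) tumors from
those pathway scores. This note records the model, the conventions, and the
design decisions that were genuinely open.

## Preprocessing

Input is a genes × samples matrix on whatever scale the user considers
analysis-ready (the package applies no log transform), plus stage labels
I–IV with stage I as the default control group. The chain is fixed:

1. **Missing filter.** Genes, then samples, whose missing fraction
   *strictly exceeds* `missing_fraction_max` (default 0.10) are dropped.
   Gene-first ordering preserves more samples; every drop is logged with
   the triggering fraction.
2. **Mean imputation.** Remaining missing cells are replaced by the gene's
   mean over observed samples.
3. **Control-anchored z-score.** Each gene is transformed as
   (x − μ_g)/σ_g with μ_g, σ_g the mean and *sample* SD (n−1 denominator)
   over control-stage samples. After this step the control group of every
   retained gene has mean 0 and sample SD 1 exactly; genes with zero
   control variance cannot be scaled and are dropped. The transform is
   affine per gene, so gene–gene Pearson correlations are unchanged.

Normalization precedes the CV filter because the signed CV (below) is only
meaningful on a centered scale.

## Feature genes

The **signed coefficient of variation** of a gene is CV = mean/SD over all
samples of the z-scored matrix. On this scale CV ≈ 0 marks genes that
hover around the control baseline; large |CV| marks consistent departure
from it, with the sign giving the direction. Genes with CV strictly outside
the empirical `cv_quantile_low`/`cv_quantile_high` quantiles (default
quartiles, keeping ~50%) form the candidate universe. Quantiles use linear
interpolation between order statistics (numpy's default, the classical
"type 7" rule), so kept-gene counts are reproducible.

Candidates are screened by one-way fixed-effects ANOVA across the four
stage groups at raw p < α (default 0.05; no multiple-testing correction —
the screen is a filter, not an inference). F statistics are computed
vectorized from between/within sums of squares and agree with
`scipy.stats.f_oneway` to 1e-10 (tested). ANOVA-significant genes are then
assigned to stages through TukeyHSD pairwise contrasts: adjusted p-values
come from the studentized-range distribution with the Tukey–Kramer standard
error, which handles the unbalanced group sizes typical of staged cohorts;
they agree with `scipy.stats.tukey_hsd` to 1e-8 (tested). A gene joins
stage k's feature set iff at least one Tukey-significant pair involves
stage k — the simplest rule that yields overlapping per-stage sets — and
the *shared* set is the four-way intersection. The rule is isolated in one
function so alternatives can be swapped in.

## Co-expression networks

Edges connect gene pairs with Pearson r > `corr_threshold` (positive) or
r < −threshold (negative) — strict inequalities, so |r| exactly at the
threshold draws no edge. Per-stage networks use that stage's feature genes
and that stage's samples; a **global** network (union of feature genes, all
samples) is built as well, and it is the one that supplies gene weights for
pathway scoring, because scoring an unlabeled sample at classification time
must not depend on its unknown stage.

Topology conventions for disconnected graphs:

- **ASP** is the mean shortest-path length over *connected* ordered pairs
  (0.0 when no pair is connected). Disconnected pairs are excluded rather
  than treated as infinite, since thresholded co-expression graphs are
  routinely fragmented.
- **Closeness** of node v is (number of reachable nodes)/(sum of distances
  to them); isolated nodes get 0.
- **Clustering** is the usual closed/possible-triplet ratio.

Deleting an edge whose removal preserves components can only lengthen
paths: ASP never decreases and no closeness ever increases. The caveat is
deliberate: deleting a *bridge* removes pairs from the connected-pair
average, and under the finite-ASP convention that can shrink ASP (a 3-node
path has ASP 4/3; removing one edge leaves a single pair at distance 1).
The monotonicity test therefore draws random non-bridge deletions.

Node degree maps to an importance weight through the logistic function
ω = 1/(1+e^(−degree)), so ω ∈ [0.5, 1): hubs approach 1, genes absent from
the network (or isolated) default to the minimum 0.5. In floating point
ω saturates to exactly 1.0 beyond degree ≈ 37; the strict upper bound is
mathematical, not numerical.

## Enrichment

Per-stage feature sets are tested for over-representation in each pathway
by the one-sided Fisher exact test (hypergeometric upper tail, via
`scipy.stats.hypergeom`), flagging raw p < α. The background universe is
the CV-candidate set — the pool the feature genes were actually drawn
from — because a genome-wide background would overstate enrichment;
it is configurable. Pathways are intersected with the background before
testing.

## Pathway imbalance score

For pathway P with up-regulated member genes i = 1..m and down-regulated
genes j = 1..n, a sample scores

    A(P) = log2( Σ_i ω_i (X_i − μ_i)²  /  Σ_j ω_j (X_j − μ_j)² )

with ω the global-network degree weight and μ the control-stage baseline
(identically 0 after z-scoring, but carried symbolically so unnormalized
inputs also work). A(P) = 0 is balance; positive values mean the
up-regulated side dominates the departure from baseline, negative the
down-regulated side. Both sides of the ratio are floored at ε = 1e-8,
keeping the score finite when one side's deviations vanish; a sample
sitting exactly at baseline scores log2(ε/ε) = 0. The score is exactly
antisymmetric under swapping the up/down sets, and scaling one side's
deviations by c shifts A(P) by 2·log2 c.

**Direction assignment** is done once, cohort-wide: a pathway member gene
(pathway ∩ union of stage feature sets) is "up" if its mean z-score over
non-control samples is positive, "down" if negative, excluded in the
measure-zero case of exactly 0. A per-stage assignment would be slightly
more sensitive but would make the direction table depend on the very label
the classifier must predict; label-free scoring won.

Pathways whose A(P) distributions differ across the four stages by one-way
ANOVA (raw p < α) are "screened" and become classifier features.

## Classifier

Stages I/II are regrouped as *early*, III/IV as *advanced*. The model is an
RBF-kernel SVM on standardized pathway scores. A gamma of exactly 0 would
make the kernel constant, so the grid explores γ ∈ {0.01, 0.1, 1/d, 1}
(d = number of features) with C ∈ {0.1, 1, 10, 100}, chosen by inner
3-fold stratified CV accuracy inside each outer training fold. The outer
loop is stratified 5-fold CV (stratification matters: the advanced class is
typically the small one); held-out decision scores give per-fold ROC
curves, AUC, accuracy and precision. Because the corresponding figure-of-
merit in staging studies is variously called "precision" or "accuracy", the
report emits all three metrics.

**RFE.** Each elimination round scores the current feature subset by
repeated stratified CV accuracy (5 folds × 3 repeats), ranks features by
the absolute weight of a linear SVM refit on the subset, and drops the
lowest `rfe_step`. The returned subset is the *smallest one within one
standard error of the best mean accuracy*. The one-SE parsimony rule is
used instead of plain argmax because an RBF SVM is nearly indifferent to a
handful of noise features: the accuracy profile is flat within fold noise,
and argmax then lands on arbitrary noisy peaks that retain uninformative
features. Under the one-SE rule, planted-signal simulations recover the
informative features with at most one spurious one in ≥ 90% of cohorts.

**Leakage.** By default the evaluation re-runs RFE inside every outer
training fold (`features=None`), so no held-out sample influences feature
selection; grid search is always nested. Passing a pre-selected feature
list reproduces the simpler select-then-evaluate protocol for comparison.
The direction table is cohort-wide by construction (it uses only the
control/non-control split, not the early/advanced labels), which is the
one data-dependent step not re-fit per fold; its orientation signal comes
from all non-control stages and is deliberately label-free.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not RNA-seq count noise, batch effects, or library-size artifacts.
Control-stage expression is Normal(0, noise_sd²) i.i.d. across samples.
Each planted pathway's genes share an equicorrelated latent factor
(pairwise r = `coexpr_block_rho`, default 0.6) and carry per-stage mean
shifts linear in stage index: dominant-direction genes shift by
±effect_size·(stage−1), opposite-direction genes by `minor_shift_ratio`
(default 0.3) of that. The asymmetry is essential: A(P) squares deviations,
so a symmetric ±shift is *balanced* and undetectable by design; the minor
ratio keeps both directions recoverable from data while planting a real
imbalance. Dominance alternates up/down across planted pathways.
Non-planted pathways contain pure null genes (negative controls for
enrichment and the score screen); leftover genes are null and pathway-free.
Missing values are placed uniformly at `missing_rate` (default 2%).
`plant_balance_profile` overrides a pathway's per-stage shifts to follow an
arbitrary dominance profile (zero = balance at that stage).

Reference conditions, used by the tests and the acceptance script: 1,000
genes, 50 samples per stage, 20 pathways of 20 genes, 4 planted, effect
1.5 SD. At this size the full pipeline runs in seconds; the recovery tests
(10 cohorts) stay under two minutes. Passing tests show the chain recovers
planted structure under its own model assumptions — they say nothing about
normalization adequacy, count noise, or confounding in real cohorts.

## Determinism

All randomness derives from one root seed fanned out per step via
`numpy.random.SeedSequence`; a rerun with identical seed and inputs
reproduces every output file byte for byte. Wall-clock timings go to the
logger, never into the manifest, to keep manifests comparable.

## Known limitations

- The feature-gene → stage assignment rule ("any significant Tukey pair
  involving stage k") is one of several defensible mappings; it is isolated
  behind `tukey_assign`.
- Raw p-value screens at α = 0.05 inherit the multiplicity behavior of the
  original procedure; expect ~α false positives among null genes/pathways.
- Direction assignment can be unstable for genes hovering near baseline
  (mean non-control z ≈ 0); such genes contribute little to A(P) either
  way.
- The generator's Gaussian model makes the ANOVA/Tukey calibration exact;
  heavy-tailed real data would be less well calibrated.
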