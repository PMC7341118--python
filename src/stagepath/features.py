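"""Stage feature-gene extraction.

Pipeline: signed coefficient of variation (CV = mean/SD on the z-scored
scale) → two-tail quantile filter → one-way four-group ANOVA → TukeyHSD
pairwise comparison (Tukey–Kramer for the unbalanced groups) → per-stage
feature sets and their four-way intersection.

A gene belongs to stage k's feature set iff at least one Tukey-significant
stage pair involves k; the shared set is the intersection over the four
stages.  Because the CV is computed on the control-anchored z scale its
sign is informative: positive CV marks genes drifting above the control
baseline, negative CV below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import STAGES, StageCohort, ValidationError, logger

#: the 6 unordered stage pairs, in canonical order
STAGE_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(STAGES, 2))


@dataclass
class GeneVariationStats:
    """Per-gene mean, sample SD and signed CV over all samples."""

    mean: pd.Series
    sd: pd.Series
    cv: pd.Series  # only genes with sd > 0
    zero_sd_genes: list[str]


@dataclass
class AnovaResult:
    fstat: pd.Series
    pvalue: pd.Series
    selected: set[str]
    alpha: float


@dataclass
class StageFeatureSets:
    """Per-stage feature-gene sets with the Tukey evidence behind them."""

    anova_genes: set[str]
    per_stage: dict[str, set[str]]
    shared: set[str]
    tukey_pvalues: pd.DataFrame  # genes x 6 stage pairs ("I-II", ...)
    alpha: float


def compute_cv(matrix: pd.DataFrame) -> GeneVariationStats:
    """Signed CV = mean / sample SD per gene over all samples."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    zero = matrix.index[sd == 0].tolist()
    if zero:
        logger.info("CV undefined for %d zero-variance genes", len(zero))
    cv = (mean[sd > 0] / sd[sd > 0]).rename("cv")
    return GeneVariationStats(mean=mean, sd=sd, cv=cv, zero_sd_genes=zero)


def two_tail_filter(
    stats_: GeneVariationStats, q_low: float = 0.25, q_high: float = 0.75
) -> set[str]:
    """Keep genes whose CV lies strictly outside the [q_low, q_high] empirical quantiles.

    Quantiles use linear interpolation between order statistics (numpy's
    default, the classical "type 7" rule).
    """
    if not (0 <= q_low < q_high <= 1):
        raise ValidationError(f"require 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    cv = stats_.cv
    if len(cv) < 4:
        raise ValidationError(f"need >=4 genes with defined CV, have {len(cv)}")
    lo = float(np.quantile(cv.to_numpy(), q_low))
    hi = float(np.quantile(cv.to_numpy(), q_high))
    kept = cv.index[(cv < lo) | (cv > hi)]
    return set(kept)


def _group_columns(matrix: pd.DataFrame, cohort: StageCohort) -> dict[str, list[str]]:
    groups = {
        stage: [s for s in samples if s in matrix.columns]
        for stage, samples in cohort.groups().items()
    }
    if set(groups) != set(STAGES):
        raise ValidationError(f"need samples in all four stages, have {sorted(groups)}")
    for stage, cols in groups.items():
        if len(cols) < 2:
            raise ValidationError(f"stage {stage} has {len(cols)} sample(s) in the matrix; need >=2")
    return groups


def _anova_components(
    X: np.ndarray, col_groups: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int]:
    """Between/within sums of squares and group means for each row of X."""
    N = sum(len(g) for g in col_groups)
    k = len(col_groups)
    grand = X.mean(axis=1)
    group_means = np.stack([X[:, g].mean(axis=1) for g in col_groups], axis=1)
    ns = np.array([len(g) for g in col_groups], dtype=float)
    ssb = ((group_means - grand[:, None]) ** 2 * ns[None, :]).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for j, g in enumerate(col_groups):
        ssw += ((X[:, g] - group_means[:, j][:, None]) ** 2).sum(axis=1)
    return ssb, ssw, group_means, N, k


def anova_screen(
    matrix: pd.DataFrame,
    cohort: StageCohort,
    genes: set[str] | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way fixed-effects F-test per gene across the four stage groups.

    Genes with no within-group variance and no between-group spread get
    p = 1 (never selected); zero within-group variance with distinct group
    means gives p = 0.
    """
    rows = matrix.index if genes is None else [g for g in matrix.index if g in genes]
    sub = matrix.loc[rows]
    groups = _group_columns(sub, cohort)
    col_pos = {c: i for i, c in enumerate(sub.columns)}
    col_groups = [np.array([col_pos[c] for c in groups[s]]) for s in STAGES]

    X = sub.to_numpy()
    ssb, ssw, _, N, k = _anova_components(X, col_groups)
    df_between, df_within = k - 1, N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_between) / (ssw / df_within)
    p = np.where(
        ssw > 0,
        stats.f.sf(F, df_between, df_within),
        np.where(ssb > 0, 0.0, 1.0),
    )
    F = np.where(ssw > 0, F, np.where(ssb > 0, np.inf, 0.0))
    fstat = pd.Series(F, index=sub.index, name="F")
    pvalue = pd.Series(p, index=sub.index, name="p")
    selected = set(sub.index[pvalue < alpha])
    return AnovaResult(fstat=fstat, pvalue=pvalue, selected=selected, alpha=alpha)


def tukey_pvalues(
    matrix: pd.DataFrame, cohort: StageCohort, genes: set[str]
) -> pd.DataFrame:
    """TukeyHSD adjusted p-values for all 6 stage pairs, per gene.

    Uses the studentized-range distribution with the Tukey–Kramer standard
    error for unequal group sizes: q = |m_a − m_b| / sqrt(MSE/2·(1/n_a+1/n_b)).
    """
    rows = [g for g in matrix.index if g in genes]
    if not rows:
        raise ValidationError("tukey_pvalues: empty gene set")
    sub = matrix.loc[rows]
    groups = _group_columns(sub, cohort)
    col_pos = {c: i for i, c in enumerate(sub.columns)}
    col_groups = [np.array([col_pos[c] for c in groups[s]]) for s in STAGES]
    ns = np.array([len(g) for g in col_groups], dtype=float)

    X = sub.to_numpy()
    _, ssw, group_means, N, k = _anova_components(X, col_groups)
    df_within = N - k
    mse = ssw / df_within

    cols = {}
    for a, b in combinations(range(k), 2):
        diff = np.abs(group_means[:, a] - group_means[:, b])
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = diff / se
        p = np.where(
            mse > 0,
            stats.studentized_range.sf(np.where(mse > 0, q, 0.0), k, df_within),
            np.where(diff > 0, 0.0, 1.0),
        )
        cols[f"{STAGES[a]}-{STAGES[b]}"] = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(cols, index=sub.index)


def tukey_assign(
    matrix: pd.DataFrame,
    cohort: StageCohort,
    anova_genes: set[str],
    alpha: float = 0.05,
) -> StageFeatureSets:
    """Assign ANOVA-significant genes to stage feature sets via Tukey pairs.

    Rule: gene ∈ stage k's set iff some pair (k, j) has adjusted p < alpha.
    """
    if not anova_genes:
        raise ValidationError("tukey_assign: no ANOVA-significant genes")
    pvals = tukey_pvalues(matrix, cohort, anova_genes)
    per_stage: dict[str, set[str]] = {s: set() for s in STAGES}
    sig = pvals < alpha
    for a, b in STAGE_PAIRS:
        hit = set(pvals.index[sig[f"{a}-{b}"]])
        per_stage[a] |= hit
        per_stage[b] |= hit
    shared = set.intersection(*(per_stage[s] for s in STAGES))
    return StageFeatureSets(
        anova_genes=set(anova_genes),
        per_stage=per_stage,
        shared=shared,
        tukey_pvalues=pvals,
        alpha=alpha,
    )


def select_features(
    matrix: pd.DataFrame,
    cohort: StageCohort,
    q_low: float = 0.25,
    q_high: float = 0.75,
    alpha: float = 0.05,
) -> tuple[GeneVariationStats, set[str], AnovaResult, StageFeatureSets]:
    """CV filter → ANOVA screen → Tukey stage assignment, in one call."""
    stats_ = compute_cv(matrix)
    candidates = two_tail_filter(stats_, q_low, q_high)
    anova = anova_screen(matrix, cohort, genes=candidates, alpha=alpha)
    if not anova.selected:
        raise ValidationError("no gene passed the four-group ANOVA screen")
    sets = tukey_assign(matrix, cohort, anova.selected, alpha=alpha)
    return stats_, candidates, anova, sets
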