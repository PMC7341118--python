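"""Missing-value filtering, mean imputation and control-anchored z-scoring.

The order is fixed: missing filter (genes first, then samples) → per-gene
mean imputation → z-score against the control stage.  After normalization
the control-stage samples of every retained gene have mean 0 and sample
SD 1, so the control group sits on a standard-normal scale and downstream
deviations are in control-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StageCohort, ValidationError, logger


@dataclass(frozen=True)
class DropRecord:
    """One discarded gene or sample, with the statistic that triggered it."""

    item: str
    axis: str  # "gene" | "sample"
    reason: str
    statistic: float


@dataclass
class NormalizationParams:
    """Per-gene control-group mean and sample SD used for z-scoring."""

    mean: pd.Series
    sd: pd.Series
    control_stage: str = "I"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"control_mean": self.mean, "control_sd": self.sd})


def _log_drops(drops: list[DropRecord]) -> None:
    for d in drops:
        logger.info("dropped %s %s: %s (statistic=%.6g)", d.axis, d.item, d.reason, d.statistic)


def filter_missing(
    matrix: pd.DataFrame, max_fraction: float = 0.10
) -> tuple[pd.DataFrame, list[DropRecord]]:
    """Drop genes, then samples, whose missing fraction strictly exceeds the threshold."""
    drops: list[DropRecord] = []
    gene_frac = matrix.isna().mean(axis=1)
    keep_genes = gene_frac <= max_fraction
    for gene in matrix.index[~keep_genes]:
        drops.append(DropRecord(gene, "gene", f"missing fraction > {max_fraction}", float(gene_frac[gene])))
    out = matrix.loc[keep_genes]
    if out.shape[0] == 0:
        raise ValidationError("missing-value filter removed every gene")

    sample_frac = out.isna().mean(axis=0)
    keep_samples = sample_frac <= max_fraction
    for sample in out.columns[~keep_samples]:
        drops.append(
            DropRecord(sample, "sample", f"missing fraction > {max_fraction}", float(sample_frac[sample]))
        )
    out = out.loc[:, keep_samples]
    if out.shape[1] == 0:
        raise ValidationError("missing-value filter removed every sample")
    _log_drops(drops)
    return out, drops


def impute_mean(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell with the mean of its gene's observed values."""
    if not matrix.isna().any().any():
        return matrix
    observed_counts = matrix.notna().sum(axis=1)
    dead = matrix.index[observed_counts == 0].tolist()
    if dead:
        raise ValidationError(f"genes with no observed values cannot be imputed: {dead[:5]}")
    row_means = matrix.mean(axis=1, skipna=True)
    out = matrix.T.fillna(row_means).T
    return out


def zscore_to_control(
    matrix: pd.DataFrame, cohort: StageCohort
) -> tuple[pd.DataFrame, NormalizationParams, list[DropRecord]]:
    """Z-score every sample against the control stage's per-gene mean and SD.

    SD uses the n−1 denominator.  Genes whose control SD is 0 cannot be
    scaled and are dropped (logged).  Returns the transformed matrix, the
    normalization parameters for the retained genes, and the drop log.
    """
    controls = [s for s in cohort.control_samples() if s in matrix.columns]
    if len(controls) < 2:
        raise ValidationError(
            f"need >=2 control-stage ({cohort.control_stage}) samples, found {len(controls)}"
        )
    if matrix.isna().any().any():
        raise ValidationError("z-scoring requires an imputed (complete) matrix")
    mu = matrix[controls].mean(axis=1)
    sd = matrix[controls].std(axis=1, ddof=1)

    drops = [
        DropRecord(gene, "gene", "zero variance in control group", 0.0)
        for gene in matrix.index[sd == 0]
    ]
    keep = sd > 0
    if not keep.any():
        raise ValidationError("every gene has zero control-group variance")
    _log_drops(drops)
    out = matrix.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    params = NormalizationParams(mean=mu[keep], sd=sd[keep], control_stage=cohort.control_stage)
    return out, params, drops


def preprocess(
    matrix: pd.DataFrame, cohort: StageCohort, max_missing_fraction: float = 0.10
) -> tuple[pd.DataFrame, NormalizationParams, list[DropRecord]]:
    """Full preprocessing chain: missing filter → imputation → control z-score."""
    filtered, drops = filter_missing(matrix, max_missing_fraction)
    imputed = impute_mean(filtered)
    normalized, params, zdrops = zscore_to_control(imputed, cohort)
    return normalized, params, drops + zdrops
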