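"""Per-sample pathway imbalance score and the pathway-level ANOVA screen.

For a pathway P with up-regulated member genes i = 1..m and down-regulated
member genes j = 1..n, a sample's imbalance score is

    A(P) = log2( Σ_i ω_i (X_i − μ_i)²  /  Σ_j ω_j (X_j − μ_j)² )

where ω is the gene's co-expression degree weight and μ its control-stage
(stage I) baseline mean — identically 0 on the z-scored scale, but carried
symbolically so unnormalized inputs also work.  A(P) = 0 marks balance
between the two directions, A(P) > 0 up-dominance, A(P) < 0 down-dominance.
Each side of the ratio is floored at a small ε (default 1e-8) so the score
stays finite when one side's deviations vanish.

Gene direction is assigned once, cohort-wide: a pathway member gene is "up"
when its mean z-score over all non-control-stage samples is positive,
"down" when negative (exactly zero → excluded).  A label-free direction
table lets an unlabeled sample be scored at classification time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import anova_screen
from .io import GeneSetCollection, StageCohort, ValidationError, logger

#: floor applied to each side of the A(P) ratio
EPSILON = 1e-8


@dataclass
class DirectionEntry:
    """Up/down pathway member genes with their network weights."""

    pathway: str
    up: dict[str, float]  # gene -> weight ω
    down: dict[str, float]

    @property
    def scorable(self) -> bool:
        return bool(self.up) or bool(self.down)


@dataclass
class PathwayDirectionTable:
    entries: dict[str, DirectionEntry]
    mu: pd.Series  # per-gene baseline (0 on the z scale)
    unscorable: list[str] = field(default_factory=list)

    def scorable_pathways(self) -> list[str]:
        return [p for p, e in self.entries.items() if e.scorable]


@dataclass
class PathwayScoreMatrix:
    """Pathways × samples matrix of A(P) with the screening ANOVA attached."""

    scores: pd.DataFrame
    screen: pd.DataFrame | None = None  # pathway, F, p, selected

    @property
    def selected(self) -> list[str]:
        if self.screen is None:
            return []
        return self.screen.loc[self.screen["selected"], "pathway"].tolist()


def assign_directions(
    matrix: pd.DataFrame,
    cohort: StageCohort,
    collection: GeneSetCollection,
    pathways: list[str],
    feature_genes: set[str],
    weights: dict[str, float],
    mu: pd.Series | None = None,
) -> PathwayDirectionTable:
    """Build the up/down direction table for the given pathways.

    Member genes of a pathway are its intersection with ``feature_genes``
    (the union of the stage feature sets).  Direction comes from the sign of
    the gene's mean z-score over non-control samples; genes missing a
    network weight default to ω = 0.5.
    """
    if mu is None:
        mu = pd.Series(0.0, index=matrix.index)
    non_control = [
        s for s in matrix.columns if cohort.labels.get(s) not in (None, cohort.control_stage)
    ]
    if not non_control:
        raise ValidationError("no non-control samples to orient gene directions")
    mean_dev = matrix[non_control].sub(mu, axis=0).mean(axis=1)

    sets = collection.as_sets()
    entries: dict[str, DirectionEntry] = {}
    unscorable: list[str] = []
    for pathway in pathways:
        members = sorted(sets.get(pathway, set()) & feature_genes & set(matrix.index))
        up: dict[str, float] = {}
        down: dict[str, float] = {}
        for g in members:
            dev = mean_dev[g]
            if dev > 0:
                up[g] = weights.get(g, 0.5)
            elif dev < 0:
                down[g] = weights.get(g, 0.5)
            else:
                logger.info("gene %s has exactly zero mean deviation; excluded from %s", g, pathway)
        entry = DirectionEntry(pathway=pathway, up=up, down=down)
        if entry.scorable:
            entries[pathway] = entry
        else:
            unscorable.append(pathway)
            logger.info("pathway %s has no oriented member genes; unscorable", pathway)
    return PathwayDirectionTable(entries=entries, mu=mu, unscorable=unscorable)


def imbalance_score(
    sample_values: pd.Series,
    entry: DirectionEntry,
    mu: pd.Series | None = None,
    epsilon: float = EPSILON,
) -> float:
    """A(P) for one sample; see the module docstring for the formula."""
    if not entry.scorable:
        raise ValidationError(f"pathway {entry.pathway} is unscorable")
    if mu is None:
        mu = pd.Series(0.0, index=sample_values.index)
    num = sum(w * (sample_values[g] - mu.get(g, 0.0)) ** 2 for g, w in entry.up.items())
    den = sum(w * (sample_values[g] - mu.get(g, 0.0)) ** 2 for g, w in entry.down.items())
    return float(np.log2(max(num, epsilon) / max(den, epsilon)))


def score_matrix(
    matrix: pd.DataFrame, table: PathwayDirectionTable, epsilon: float = EPSILON
) -> PathwayScoreMatrix:
    """A(P) for every scorable pathway × every sample (vectorized)."""
    pathways = table.scorable_pathways()
    dev = matrix.sub(table.mu.reindex(matrix.index).fillna(0.0), axis=0)
    sq = dev.to_numpy() ** 2
    pos = {g: i for i, g in enumerate(matrix.index)}
    out = np.empty((len(pathways), matrix.shape[1]))
    for r, pathway in enumerate(pathways):
        entry = table.entries[pathway]
        num = np.zeros(matrix.shape[1])
        den = np.zeros(matrix.shape[1])
        for g, w in entry.up.items():
            num += w * sq[pos[g]]
        for g, w in entry.down.items():
            den += w * sq[pos[g]]
        out[r] = np.log2(np.maximum(num, epsilon) / np.maximum(den, epsilon))
    scores = pd.DataFrame(out, index=pd.Index(pathways, name="pathway"), columns=matrix.columns)
    return PathwayScoreMatrix(scores=scores)


def screen_pathways(
    score_mat: PathwayScoreMatrix, cohort: StageCohort, alpha: float = 0.05
) -> PathwayScoreMatrix:
    """Four-group ANOVA of A(P) across stages; select pathways with p < α."""
    anova = anova_screen(score_mat.scores, cohort, alpha=alpha)
    screen = pd.DataFrame(
        {
            "pathway": score_mat.scores.index,
            "F": anova.fstat.to_numpy(),
            "p": anova.pvalue.to_numpy(),
            "selected": (anova.pvalue < alpha).to_numpy(),
        }
    )
    return PathwayScoreMatrix(scores=score_mat.scores, screen=screen)
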