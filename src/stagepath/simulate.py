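"""Synthetic four-stage expression cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: an unbalanced four-group cohort, stage-specific differentially
expressed gene blocks, equicorrelated co-expression blocks, and pathways
whose up/down balance drifts with stage.

Model
-----
Control-stage (stage I) expression of every gene is Normal(0, noise_sd²),
i.i.d. across samples, with planted-pathway genes sharing an equicorrelated
latent factor (pairwise correlation ``coexpr_block_rho``).  A planted
pathway has a dominant direction (up or down, alternating across planted
pathways): dominant-direction genes shift their mean by
``±effect_size × (stage_index − 1)`` while the opposite-direction genes
shift by ``minor_shift_ratio`` of that.  The asymmetry is what plants a
detectable pathway imbalance — a squared-deviation score is blind to a
symmetric ±shift — while keeping both directions recoverable from the data.
Non-planted pathways and leftover genes are pure nulls, serving as negative
controls for enrichment and the pathway-score screen.

Missing entries are placed uniformly at ``missing_rate`` and everything is
reproducible from ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import STAGES, GeneSetCollection, StageCohort, ValidationError


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator knobs; defaults are the cohort used throughout the tests."""

    n_genes: int = 1000
    n_samples_per_stage: tuple[int, int, int, int] = (50, 50, 50, 50)
    n_pathways: int = 20
    genes_per_pathway: int = 20
    n_planted_pathways: int = 4
    effect_size: float = 1.5
    coexpr_block_rho: float = 0.6
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    minor_shift_ratio: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_pathways > self.n_pathways:
            raise ValidationError("n_planted_pathways exceeds n_pathways")
        if self.genes_per_pathway * self.n_pathways > self.n_genes:
            raise ValidationError("genes_per_pathway * n_pathways exceeds n_genes")
        if self.n_planted_pathways and self.genes_per_pathway < 2:
            raise ValidationError("planted pathways need >=2 genes (both directions)")
        if not (0 <= self.coexpr_block_rho < 1):
            raise ValidationError("coexpr_block_rho must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must be in [0, 1)")
        if len(self.n_samples_per_stage) != 4 or any(n < 2 for n in self.n_samples_per_stage):
            raise ValidationError("need 4 stage sizes, each >= 2")


@dataclass
class SyntheticTruth:
    """Planted structure: what a successful analysis should recover.

    ``shifts`` is a genes × 4 frame of per-stage mean shifts (stage order
    I–IV); ``directions`` maps planted genes to ±1; ``blocks`` maps genes to
    the co-expression block (= planted pathway) they belong to.
    """

    planted_pathways: list[str]
    dominance: dict[str, str]  # pathway -> "up" | "down"
    directions: dict[str, int]  # gene -> +1 / -1
    shifts: pd.DataFrame  # genes x stages
    blocks: dict[str, str] = field(default_factory=dict)

    def expected_stage_gap(self, gene: str) -> float:
        """Planted stage-IV minus stage-I mean for a gene (0 if null)."""
        if gene not in self.shifts.index:
            return 0.0
        row = self.shifts.loc[gene]
        return float(row["IV"] - row["I"])


def build_truth(spec: SyntheticSpec) -> SyntheticTruth:
    """Lay out pathways, directions and per-stage mean shifts for a spec."""
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    pathways = [f"PW{p:03d}" for p in range(spec.n_pathways)]
    planted = pathways[: spec.n_planted_pathways]

    shifts = pd.DataFrame(0.0, index=genes, columns=list(STAGES))
    directions: dict[str, int] = {}
    dominance: dict[str, str] = {}
    blocks: dict[str, str] = {}

    stage_steps = np.arange(4, dtype=float)  # 0,1,2,3 for stages I..IV
    for p_idx, pathway in enumerate(pathways):
        members = genes[p_idx * spec.genes_per_pathway : (p_idx + 1) * spec.genes_per_pathway]
        if pathway not in planted:
            continue
        dom = "up" if p_idx % 2 == 0 else "down"
        dominance[pathway] = dom
        half = len(members) // 2
        up_genes, down_genes = members[:half], members[half:]
        for g in up_genes:
            directions[g] = +1
            blocks[g] = pathway
        for g in down_genes:
            directions[g] = -1
            blocks[g] = pathway
        for g in members:
            scale = 1.0 if (dom == "up") == (directions[g] > 0) else spec.minor_shift_ratio
            shifts.loc[g] = directions[g] * scale * spec.effect_size * stage_steps
    return SyntheticTruth(
        planted_pathways=planted,
        dominance=dominance,
        directions=directions,
        shifts=shifts,
        blocks=blocks,
    )


def plant_balance_profile(
    truth: SyntheticTruth, pathway: str, profile: tuple[float, float, float, float]
) -> SyntheticTruth:
    """Override a planted pathway's per-stage shifts to follow a dominance profile.

    ``profile[s] > 0`` makes up-regulated genes of the pathway dominate at
    stage ``s`` (expected imbalance score > 0), ``< 0`` makes down-regulated
    genes dominate, ``0`` plants balance.  Returns ``truth`` mutated in place
    (also returned for chaining); realize the cohort afterwards.
    """
    if len(profile) != 4:
        raise ValidationError(f"profile needs 4 per-stage values, got {len(profile)}")
    if pathway not in truth.planted_pathways:
        raise ValidationError(f"{pathway!r} is not a planted pathway")
    members = [g for g, pw in truth.blocks.items() if pw == pathway]
    for g in members:
        d = truth.directions[g]
        for s_idx, stage in enumerate(STAGES):
            c = profile[s_idx]
            if d > 0:
                truth.shifts.loc[g, stage] = max(c, 0.0)
            else:
                truth.shifts.loc[g, stage] = min(c, 0.0)
    return truth


def _gene_set_collection(spec: SyntheticSpec) -> GeneSetCollection:
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    sets = {
        f"PW{p:03d}": genes[p * spec.genes_per_pathway : (p + 1) * spec.genes_per_pathway]
        for p in range(spec.n_pathways)
    }
    desc = {name: "synthetic pathway" for name in sets}
    return GeneSetCollection(sets=sets, descriptions=desc)


def realize_cohort(
    spec: SyntheticSpec, truth: SyntheticTruth
) -> tuple[pd.DataFrame, StageCohort, GeneSetCollection]:
    """Draw an expression matrix consistent with ``truth`` under ``spec``."""
    rng = np.random.default_rng(spec.rng_seed)
    genes = list(truth.shifts.index)
    gene_pos = {g: i for i, g in enumerate(genes)}

    sample_ids: list[str] = []
    sample_stage: dict[str, str] = {}
    for stage, n in zip(STAGES, spec.n_samples_per_stage):
        for i in range(n):
            sid = f"S_{stage}_{i:03d}"
            sample_ids.append(sid)
            sample_stage[sid] = stage
    n_samples = len(sample_ids)

    noise = rng.standard_normal((len(genes), n_samples))
    values = noise.copy()

    # equicorrelated blocks: x = sqrt(rho)*f + sqrt(1-rho)*e, unit variance
    rho = spec.coexpr_block_rho
    for pathway in truth.planted_pathways:
        members = [g for g, pw in truth.blocks.items() if pw == pathway]
        if not members or rho == 0:
            continue
        factor = rng.standard_normal(n_samples)
        rows = [gene_pos[g] for g in members]
        values[rows, :] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise[rows, :]

    values *= spec.noise_sd

    stage_of_col = np.array([STAGES.index(sample_stage[s]) for s in sample_ids])
    shift_arr = truth.shifts.to_numpy()  # genes x 4
    values += shift_arr[:, stage_of_col]

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    cohort = StageCohort(labels=sample_stage, control_stage="I")
    return matrix, cohort, _gene_set_collection(spec)


def generate_cohort(
    spec: SyntheticSpec, truth: SyntheticTruth | None = None
) -> tuple[pd.DataFrame, StageCohort, GeneSetCollection, SyntheticTruth]:
    """Generate a full synthetic cohort; see the module docstring for the model."""
    if truth is None:
        truth = build_truth(spec)
    matrix, cohort, collection = realize_cohort(spec, truth)
    return matrix, cohort, collection, truth
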