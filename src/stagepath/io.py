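"""Readers/writers for the three input formats and the run configuration.

Formats
-------
* expression matrix: TSV, header row of sample IDs, first column gene IDs,
  optional missing-value tokens;
* stage labels: two-column TSV ``sample_id<TAB>stage`` with stages I–IV
  (roman, case-insensitive, or arabic 1–4);
* gene sets: standard GMT (``name<TAB>description<TAB>gene...``).

Expression matrices are held as :class:`pandas.DataFrame` (genes as rows,
samples as columns, ``NaN`` marking missing values before preprocessing).
Gene and sample identifiers are opaque strings; no symbol mapping is done.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("stagepath")

#: canonical ordered tumor stages
STAGES: tuple[str, ...] = ("I", "II", "III", "IV")

DEFAULT_MISSING_TOKENS = frozenset({"NA", "NaN", ""})

_STAGE_ALIASES = {
    **{s.upper(): s for s in STAGES},
    "1": "I",
    "2": "II",
    "3": "III",
    "4": "IV",
}


class ParseError(ValueError):
    """Malformed input file (the message names the offending line)."""


class ValidationError(ValueError):
    """Structurally valid input violating a domain invariant."""


def normalize_stage(token: str) -> str:
    """Map a stage token ('iii', '3', 'IV', ...) onto the canonical I–IV."""
    key = token.strip().upper()
    if key not in _STAGE_ALIASES:
        raise ValidationError(f"unknown stage label {token!r} (expected I-IV or 1-4)")
    return _STAGE_ALIASES[key]


@dataclass(frozen=True)
class StageCohort:
    """Sample → stage assignment with a designated control stage.

    The control stage (default I, the lowest-malignancy group) anchors the
    z-score normalization and the baseline mean of the pathway imbalance
    score.
    """

    labels: Mapping[str, str]
    control_stage: str = "I"

    def __post_init__(self) -> None:
        bad = {s for s in self.labels.values() if s not in STAGES}
        if bad:
            raise ValidationError(f"stage labels outside I-IV: {sorted(bad)}")
        if self.control_stage not in STAGES:
            raise ValidationError(f"control stage {self.control_stage!r} not in I-IV")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def samples_of(self, stage: str) -> list[str]:
        return [s for s, g in self.labels.items() if g == stage]

    def control_samples(self) -> list[str]:
        return self.samples_of(self.control_stage)

    def stage_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STAGES}
        for g in self.labels.values():
            counts[g] += 1
        return counts

    def groups(self) -> dict[str, list[str]]:
        """Sample lists per represented stage, in canonical stage order."""
        return {s: self.samples_of(s) for s in STAGES if any(g == s for g in self.labels.values())}

    def validate_against(self, matrix: pd.DataFrame, min_per_stage: int = 2) -> None:
        missing = [s for s in self.labels if s not in matrix.columns]
        if missing:
            raise ValidationError(
                f"{len(missing)} labeled samples absent from the matrix, e.g. {missing[:3]}"
            )
        for stage, n in self.stage_counts().items():
            if 0 < n < min_per_stage:
                raise ValidationError(
                    f"stage {stage} has {n} sample(s); need at least {min_per_stage} "
                    "for within-group variance"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways) from a GMT file.

    ``sets`` preserves file order; genes are deduplicated within each set.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def as_sets(self) -> dict[str, set[str]]:
        return {name: set(genes) for name, genes in self.sets.items()}


@dataclass
class RunConfig:
    """Tunable thresholds of the pipeline, with the defaults used throughout.

    cv_quantile_low / cv_quantile_high
        empirical quantiles of the signed CV distribution bounding the
        two-tail keep region (default quartiles, keeping ~50% of genes).
    corr_threshold
        |Pearson r| above which a co-expression edge is drawn (strict).
    alpha
        significance level shared by the ANOVA screen, TukeyHSD pairs,
        Fisher enrichment and the pathway-score ANOVA.
    missing_fraction_max
        genes/samples whose missing fraction strictly exceeds this are
        dropped.
    """

    cv_quantile_low: float = 0.25
    cv_quantile_high: float = 0.75
    corr_threshold: float = 0.5
    alpha: float = 0.05
    missing_fraction_max: float = 0.10
    cv_folds: int = 5
    rfe_step: int = 1
    rng_seed: int = 0
    control_stage: str = "I"
    nested_rfe: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.cv_quantile_low < self.cv_quantile_high < 1):
            raise ValidationError(
                "require 0 < cv_quantile_low < cv_quantile_high < 1, got "
                f"({self.cv_quantile_low}, {self.cv_quantile_high})"
            )
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rfe_step < 1:
            raise ValidationError("rfe_step must be >= 1")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(
    path: str | Path, missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS
) -> pd.DataFrame:
    """Read a genes × samples TSV into a float DataFrame (NaN = missing).

    Raises :class:`ParseError` on ragged rows (pandas names the line) and
    :class:`ValidationError` on duplicate gene or sample identifiers.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=list(missing_tokens),
            keep_default_na=False,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:  # pragma: no cover - message pass-through
        raise ParseError(f"malformed expression matrix {path}: {exc}") from exc
    dup_genes = df.index[df.index.duplicated()].unique().tolist()
    if dup_genes:
        raise ValidationError(f"duplicate gene IDs in {path}: {dup_genes[:5]}")
    dup_samples = df.columns[df.columns.duplicated()].unique().tolist()
    if dup_samples:
        raise ValidationError(f"duplicate sample IDs in {path}: {dup_samples[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix as TSV; float formatting round-trips bit-exactly.

    Cells are written with ``repr(float)`` — the shortest decimal string
    that parses back to the identical IEEE-754 double — so a write/read
    cycle reproduces the matrix exactly.
    """
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(gene) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# stage labels


def read_stage_labels(path: str | Path, control_stage: str = "I") -> StageCohort:
    """Read a two-column sample/stage TSV into a :class:`StageCohort`."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            sample, stage = fields
            if sample in labels:
                raise ValidationError(f"{path}:{lineno}: duplicate sample ID {sample!r}")
            labels[sample] = normalize_stage(stage)
    return StageCohort(labels=labels, control_stage=control_stage)


def write_stage_labels(cohort: StageCohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, stage in cohort.labels.items():
            fh.write(f"{sample}\t{stage}\n")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file; one set per line, genes deduplicated preserving order."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, desc, *genes = fields
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if not deduped:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
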