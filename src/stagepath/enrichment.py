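"""Fisher-exact over-representation of feature genes in pathway sets.

For each pathway the 2×2 table partitions the background universe by
feature-set membership and pathway membership; the one-sided (enrichment)
exact p-value is the hypergeometric upper tail P[X ≥ k].  The background
defaults to the CV-filter candidate universe the feature genes were drawn
from, and pathways are intersected with it before testing.  No
multiple-testing correction is applied; selection is raw p < α.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import GeneSetCollection, ValidationError


@dataclass
class EnrichmentResult:
    """Per-pathway enrichment table for one feature-gene set."""

    table: pd.DataFrame  # pathway, overlap, feature_size, pathway_size, background_size, p, selected
    alpha: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "pathway"].tolist()


def fisher_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P[X >= k].

    N background genes of which K in the pathway; n feature genes drawn;
    k the observed overlap.
    """
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    feature_genes: set[str],
    collection: GeneSetCollection,
    background: set[str],
    alpha: float = 0.05,
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of a feature set against every pathway."""
    if not background:
        raise ValidationError("empty background universe")
    if not feature_genes <= background:
        raise ValidationError("feature genes must be a subset of the background")
    N = len(background)
    n = len(feature_genes)
    rows = []
    for pathway, genes in collection.as_sets().items():
        members = genes & background
        K = len(members)
        k = len(members & feature_genes)
        p = fisher_pvalue(k, K, n, N) if K else 1.0
        rows.append(
            {
                "pathway": pathway,
                "overlap": k,
                "feature_size": n,
                "pathway_size": K,
                "background_size": N,
                "p": p,
                "selected": p < alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["pathway", "overlap", "feature_size", "pathway_size", "background_size", "p", "selected"],
    )
    return EnrichmentResult(table=table, alpha=alpha)
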