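#!/usr/bin/env python
"""Per-stage and global co-expression networks with topology summaries.

For each stage, correlates that stage's feature genes over that stage's
samples and draws edges at |Pearson r| > 0.5; a global network (all feature
genes, all samples) supplies the logistic degree weights used by the
pathway imbalance score.  Writes edge lists, a topology summary and the
gene weights to results/network/.
"""

import json
from pathlib import Path

from stagepath.io import STAGES, read_expression_matrix, read_stage_labels
from stagepath.network import build_network, count_edge_signs, degree_weights, topology

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    norm = read_expression_matrix(ROOT / "preprocess" / "normalized_matrix.tsv")
    cohort = read_stage_labels(ROOT / "data" / "stages.tsv")
    out = ROOT / "network"
    out.mkdir(parents=True, exist_ok=True)

    summary = {}
    union = set()
    for stage in STAGES:
        genes = {
            g for g in (ROOT / "features" / f"stage_{stage}.txt").read_text().splitlines() if g
        }
        union |= genes
        net = build_network(norm, genes, cohort.samples_of(stage), threshold=0.5)
        net.edges().to_csv(out / f"edges_stage_{stage}.tsv", sep="\t", index=False)
        pos, neg, tot = count_edge_signs(net)
        topo = topology(net)
        summary[stage] = {
            "nodes": len(net.nodes), "positive": pos, "negative": neg, "total": tot,
            "asp": topo.average_shortest_path,
        }
        print(f"stage {stage}: {len(net.nodes)} nodes, {tot} edges "
              f"({pos} positive / {neg} negative), ASP = {topo.average_shortest_path:.3f}")

    global_net = build_network(norm, union, list(norm.columns), threshold=0.5)
    global_net.edges().to_csv(out / "edges_global.tsv", sep="\t", index=False)
    pos, neg, tot = count_edge_signs(global_net)
    summary["global"] = {"nodes": len(global_net.nodes), "positive": pos,
                         "negative": neg, "total": tot}
    print(f"global: {len(global_net.nodes)} nodes, {tot} edges "
          f"({pos} positive / {neg} negative) — supplies the gene weights")

    weights = degree_weights(global_net, union)
    with open(out / "gene_weights.json", "w") as fh:
        json.dump(weights, fh, indent=2, sort_keys=True)
    with open(out / "topology.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
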