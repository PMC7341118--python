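"""End-to-end orchestration: preprocess → features → networks → enrichment →
pathway scores → classifier, with a deterministic manifest.

All randomness derives from ``RunConfig.rng_seed`` through a
``numpy.random.SeedSequence`` fan-out, so any step can be replayed
independently and a rerun with the same seed and inputs reproduces every
output byte for byte.  Wall-clock timings go to the logger only; the
manifest holds the deterministic content (config snapshot, input hashes,
per-step counts, output paths).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, enrichment, features, network, preprocess, scoring
from .io import (
    STAGES,
    GeneSetCollection,
    RunConfig,
    StageCohort,
    logger,
    read_expression_matrix,
    read_gmt,
    read_stage_labels,
    write_expression_matrix,
)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _step_seeds(root_seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline_frames(
    config: RunConfig,
    matrix: pd.DataFrame,
    cohort: StageCohort,
    collection: GeneSetCollection,
    outdir: str | Path | None = None,
) -> dict:
    """Run the full analysis on in-memory inputs; returns the manifest dict.

    When ``outdir`` is given every intermediate is written there as
    TSV/JSON.
    """
    t0 = time.monotonic()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seeds = _step_seeds(config.rng_seed)

    manifest: dict = {"config": config.to_dict(), "steps": {}, "outputs": {}}

    # 1. preprocessing
    cohort = StageCohort(labels=dict(cohort.labels), control_stage=config.control_stage)
    norm, params, drops = preprocess.preprocess(matrix, cohort, config.missing_fraction_max)
    cohort = StageCohort(
        labels={s: g for s, g in cohort.labels.items() if s in norm.columns},
        control_stage=config.control_stage,
    )
    manifest["steps"]["preprocess"] = {
        "genes_in": int(matrix.shape[0]),
        "samples_in": int(matrix.shape[1]),
        "genes_kept": int(norm.shape[0]),
        "samples_kept": int(norm.shape[1]),
        "dropped": len(drops),
    }

    # 2. feature selection
    stats_, candidates, anova, sets = features.select_features(
        norm, cohort, config.cv_quantile_low, config.cv_quantile_high, config.alpha
    )
    union_features = set().union(*sets.per_stage.values())
    manifest["steps"]["feature_selection"] = {
        "cv_candidates": len(candidates),
        "anova_genes": len(anova.selected),
        "per_stage": {s: len(sets.per_stage[s]) for s in STAGES},
        "shared": len(sets.shared),
        "union": len(union_features),
    }

    # 3. co-expression networks (per stage + global; global supplies ω)
    stage_networks = {}
    net_summary = {}
    for stage in STAGES:
        net = network.build_network(
            norm, sets.per_stage[stage], cohort.samples_of(stage), config.corr_threshold
        )
        stage_networks[stage] = net
        pos, neg, tot = network.count_edge_signs(net)
        topo = network.topology(net)
        net_summary[stage] = {
            "nodes": len(net.nodes),
            "positive": pos,
            "negative": neg,
            "total": tot,
            "asp": topo.average_shortest_path,
            "mean_closeness": float(np.mean(list(topo.closeness.values()))) if topo.closeness else 0.0,
            "mean_clustering": float(np.mean(list(topo.clustering.values()))) if topo.clustering else 0.0,
        }
    global_net = network.build_network(norm, union_features, list(norm.columns), config.corr_threshold)
    pos, neg, tot = network.count_edge_signs(global_net)
    net_summary["global"] = {"nodes": len(global_net.nodes), "positive": pos, "negative": neg, "total": tot}
    weights = network.degree_weights(global_net, union_features)
    manifest["steps"]["coexpression"] = net_summary

    # 4. enrichment per stage against the CV-candidate background
    enriched_union: list[str] = []
    enrich_tables = {}
    for stage in STAGES:
        res = enrichment.fisher_enrich(sets.per_stage[stage], collection, candidates, config.alpha)
        enrich_tables[stage] = res
        for p in res.selected:
            if p not in enriched_union:
                enriched_union.append(p)
    manifest["steps"]["enrichment"] = {
        s: {"selected": len(enrich_tables[s].selected)} for s in STAGES
    } | {"union_selected": len(enriched_union)}

    # 5. pathway imbalance scores + ANOVA screen
    table = scoring.assign_directions(
        norm, cohort, collection, enriched_union, union_features, weights
    )
    screened: list[str] = []
    score_mat = None
    if table.scorable_pathways():
        score_mat = scoring.score_matrix(norm, table)
        score_mat = scoring.screen_pathways(score_mat, cohort, config.alpha)
        screened = score_mat.selected
    manifest["steps"]["pathway_score"] = {
        "scorable": len(table.scorable_pathways()),
        "unscorable": len(table.unscorable),
        "screened": len(screened),
        "screened_pathways": screened,
    }

    # 6. classifier on the screened pathway scores
    report = None
    if score_mat is not None and len(screened) >= 1:
        classes = classify.make_binary(cohort)
        sub = score_mat.scores.loc[screened]
        rfe_features = classify.rfe_select(
            sub, classes, step_k=config.rfe_step, folds=config.cv_folds, seed=seeds[5]
        )
        report = classify.train_and_evaluate(
            sub,
            classes,
            features=None if config.nested_rfe else rfe_features,
            folds=config.cv_folds,
            seed=seeds[6],
            rfe_step=config.rfe_step,
        )
        manifest["steps"]["classifier"] = {
            "rfe_selected": rfe_features,
            "consensus_features": report.selected_features,
            "mean_auc": report.mean_auc,
            "mean_accuracy": report.mean_accuracy,
            "mean_precision": report.mean_precision,
            "initial_accuracy": report.initial_accuracy,
        }
    else:
        manifest["steps"]["classifier"] = {"skipped": "no screened pathways to classify"}

    # write artifacts
    if out is not None:
        write_expression_matrix(norm, out / "normalized_matrix.tsv")
        params.to_frame().to_csv(out / "normalization_params.tsv", sep="\t")
        pd.DataFrame(
            {"gene_id": stats_.cv.index, "cv": stats_.cv.to_numpy()}
        ).to_csv(out / "cv_values.tsv", sep="\t", index=False)
        for stage in STAGES:
            with open(out / f"feature_genes_stage_{stage}.txt", "w") as fh:
                fh.write("\n".join(sorted(sets.per_stage[stage])) + "\n")
            enrich_tables[stage].table.to_csv(
                out / f"enrichment_stage_{stage}.tsv", sep="\t", index=False
            )
            stage_networks[stage].edges().to_csv(
                out / f"network_stage_{stage}.tsv", sep="\t", index=False
            )
        global_net.edges().to_csv(out / "network_global.tsv", sep="\t", index=False)
        with open(out / "topology.json", "w") as fh:
            json.dump(net_summary, fh, indent=2, sort_keys=True)
        if score_mat is not None:
            score_mat.scores.to_csv(out / "pathway_scores.tsv", sep="\t")
            score_mat.screen.to_csv(out / "pathway_screen.tsv", sep="\t", index=False)
        if report is not None:
            with open(out / "classifier_report.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        manifest["outputs"] = {p.name: p.name for p in sorted(out.glob("*")) if p.name != "manifest.json"}

    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return manifest


def run_pipeline(
    config: RunConfig,
    expression: str | Path,
    labels: str | Path,
    gmt: str | Path,
    outdir: str | Path,
) -> dict:
    """File-based entry point; writes ``manifest.json`` under ``outdir``."""
    matrix = read_expression_matrix(expression)
    cohort = read_stage_labels(labels, control_stage=config.control_stage)
    cohort.validate_against(matrix)
    collection = read_gmt(gmt)
    manifest = run_pipeline_frames(config, matrix, cohort, collection, outdir)
    manifest["inputs"] = {
        "expression": {"path": str(expression), "sha256": _sha256(expression)},
        "labels": {"path": str(labels), "sha256": _sha256(labels)},
        "gmt": {"path": str(gmt), "sha256": _sha256(gmt)},
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
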