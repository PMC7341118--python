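#!/usr/bin/env python
"""Generate the reference synthetic cohort used by the downstream steps.

Writes a 1,000-gene x 200-sample four-stage cohort (50 samples per stage)
with 20 pathways, 4 of them planted with a stage-drifting up/down imbalance
at effect 1.5 SD, ~2% missing values, and the planted truth for later
comparison.  Outputs land in results/data/.
"""

import json
from pathlib import Path

from stagepath.io import write_expression_matrix, write_gmt, write_stage_labels
from stagepath.simulate import SyntheticSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    spec = SyntheticSpec(rng_seed=SEED)
    matrix, cohort, collection, truth = generate_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, OUT / "expression.tsv")
    write_stage_labels(cohort, OUT / "stages.tsv")
    write_gmt(collection, OUT / "pathways.gmt")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(
            {
                "planted_pathways": truth.planted_pathways,
                "dominance": truth.dominance,
                "directions": truth.directions,
                "seed": SEED,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    n_missing = int(matrix.isna().sum().sum())
    print(f"cohort: {matrix.shape[0]} genes x {matrix.shape[1]} samples "
          f"({n_missing} missing cells, {100*n_missing/matrix.size:.1f}%)")
    print(f"stages: {cohort.stage_counts()}")
    print(f"planted pathways: {truth.planted_pathways} with dominance {truth.dominance}")
    print(f"wrote {OUT}/expression.tsv, stages.tsv, pathways.gmt, truth.json")


if __name__ == "__main__":
    main()
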