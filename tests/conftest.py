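import numpy as np
import pandas as pd
import pytest

from stagepath import RunConfig, StageCohort
from stagepath.preprocess import preprocess
from stagepath.simulate import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Small planted cohort reused by several module tests."""
    return SyntheticSpec(
        n_genes=300,
        n_samples_per_stage=(20, 20, 20, 20),
        n_pathways=6,
        genes_per_pathway=10,
        n_planted_pathways=2,
        effect_size=1.5,
        missing_rate=0.02,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def normalized_small(small_cohort):
    matrix, cohort, collection, truth = small_cohort
    norm, params, _ = preprocess(matrix, cohort)
    return norm, cohort, collection, truth, params


@pytest.fixture()
def four_group_frame():
    """80-sample frame with 20 samples per stage and easy group structure."""
    rng = np.random.default_rng(5)
    samples = [f"s{g}_{i}" for g in "ABCD" for i in range(20)]
    labels = {
        s: stage for s, stage in zip(samples, ["I"] * 20 + ["II"] * 20 + ["III"] * 20 + ["IV"] * 20)
    }
    values = rng.standard_normal((30, 80))
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(30)], columns=samples)
    return frame, StageCohort(labels=labels)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
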