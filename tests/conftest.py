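import numpy as np
import pandas as pd
import pytest

import modulepivot as mp

REFERENCE_SEED = 0


@pytest.fixture(scope="session")
def reference_config() -> mp.SimulationConfig:
    """The reference synthetic study: 5 planted 100-gene modules at
    within-module r = 0.7 plus 100 background genes, 4 groups x 5 samples."""
    return mp.SimulationConfig(seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def reference_study(reference_config):
    return mp.simulate_expression(reference_config)


@pytest.fixture(scope="session")
def reference_detection(reference_study):
    study, _ = reference_study
    return mp.detect_modules(study)


@pytest.fixture(scope="session")
def true_partition(reference_study) -> mp.ModulePartition:
    _, truth = reference_study
    return mp.ModulePartition(module_of=dict(truth.true_module_of))


@pytest.fixture()
def tiny_study() -> mp.ExpressionStudy:
    values = pd.DataFrame(
        {
            "s1": [1.0, 1.0, 4.0],
            "s2": [2.0, 2.0, 2.0],
            "s3": [3.0, 4.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    return mp.ExpressionStudy(
        values=values, group_of={"s1": "a", "s2": "a", "s3": "b"}
    )


def make_study(matrix: np.ndarray, groups: list[str]) -> mp.ExpressionStudy:
    genes = [f"g{i + 1}" for i in range(matrix.shape[0])]
    samples = [f"s{i + 1}" for i in range(matrix.shape[1])]
    return mp.ExpressionStudy(
        values=pd.DataFrame(matrix, index=genes, columns=samples),
        group_of=dict(zip(samples, groups)),
    )
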