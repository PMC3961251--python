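import numpy as np
import pytest

import bicbench as bb


@pytest.fixture
def tiny_matrix() -> bb.ExpressionMatrix:
    rng = np.random.default_rng(11)
    return bb.ExpressionMatrix.from_arrays(
        [f"g{i}" for i in range(5)],
        [f"s{j}" for j in range(4)],
        rng.normal(size=(5, 4)),
    )


@pytest.fixture(scope="session")
def desk_dataset():
    """Small planted multi-tissue dataset shared across tests (read-only)."""
    cfg = bb.desk_config(seed=42)
    matrix, labels, truth = bb.generate_multitissue_dataset(cfg)
    return cfg, matrix, labels, truth


@pytest.fixture(scope="session")
def desk_annotations(desk_dataset):
    cfg, _, _, truth = desk_dataset
    tiger, go = bb.generate_annotation_sets(truth, cfg)
    return tiger, go
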