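import numpy as np
import pytest

from mrshift.config import PipelineConfig
from mrshift.synthetic import SimDesign, generate_grn, make_study


def small_design(seed: int = 0, **overrides) -> SimDesign:
    """A scaled-down study: 600 genes, 800 cells, 6 TFs."""
    defaults = dict(
        n_genes=600,
        n_cells={
            ("shAPC", "d3"): 200,
            ("shAPC", "d7"): 200,
            ("shScr", "d3"): 200,
            ("shScr", "d7"): 200,
        },
        seed=seed,
    )
    defaults.update(overrides)
    return SimDesign(**defaults)


def small_config(seed: int = 0, **overrides) -> PipelineConfig:
    data = dict(
        seed=seed,
        sim_n_tfs=6,
        sim_targets_per_tf=15,
        sim_n_mrs=3,
        sim_design={
            "n_genes": 600,
            "n_cells": {
                ("shAPC", "d3"): 200,
                ("shAPC", "d7"): 200,
                ("shScr", "d3"): 200,
                ("shScr", "d7"): 200,
            },
        },
        mindy_perm=100,
    )
    data.update(overrides)
    return PipelineConfig(**data)


@pytest.fixture(scope="session")
def small_study():
    """Simulated small study shared across read-only tests."""
    design = small_design(seed=11)
    network, design, adata, truth = make_study(
        seed=11, design=design, n_tfs=6, targets_per_tf=15, n_mrs=3
    )
    return network, design, adata, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_grn():
    return generate_grn(n_tfs=5, targets_per_tf=20, n_mrs=2, seed=1, n_genes=600)
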