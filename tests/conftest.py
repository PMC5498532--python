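import numpy as np
import pandas as pd
import pytest

from emtscreen import ExpressionMatrix, ScreenConfig, SimulationParams


@pytest.fixture
def small_params():
    """Scaled-down simulation for fast unit tests."""
    return SimulationParams(
        n_entities=3,
        n_tumor_entities=2,
        lines_per_state_per_entity=10,
        n_tumors_per_entity=80,
        n_epi_markers=10,
        n_mes_markers=10,
        n_entity_specific=4,
        n_null=60,
        seed=7,
    )


@pytest.fixture
def config():
    return ScreenConfig(seed=0)


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples, log2 scale, two entities."""
    values = pd.DataFrame(
        [[8.0, 9.0, 2.0, 3.0], [2.0, 3.0, 8.0, 9.0], [5.0, 5.0, 5.0, 5.0]],
        index=["CDH1", "VIM", "G1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(
        values=values,
        scale="log2",
        entity_of={"s1": "colon", "s2": "colon", "s3": "colon", "s4": "colon"},
    )


def rng(seed=0):
    return np.random.default_rng(seed)
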