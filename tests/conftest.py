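import numpy as np
import pandas as pd
import pytest

from mindnet import (
    ParcellationScheme,
    SyntheticCortexSpec,
    VertexFeatureTable,
    generate_subject,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Mirrored 10-region (5/hemisphere), 3-feature synthetic cortex."""
    return SyntheticCortexSpec.create(
        R_per_hemisphere=5, d=3, n_r=150, separation=1.0, mirror=True, seed=3
    )


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return generate_subject(small_spec)


@pytest.fixture
def toy_table():
    """Hand-sized vertex table: 6 vertices, 2 regions, 5 named features."""
    df = pd.DataFrame(
        {
            "vertex_id": [0, 1, 2, 0, 1, 2],
            "hemisphere": ["left"] * 3 + ["right"] * 3,
            "region": ["A", "A", "B", "B", "B", "B"],
            "CT": [2.0, 4.0, 3.0, 2.5, 3.5, 3.0],
            "SA": [2.0, 2.0, 1.0, 1.5, 2.5, 2.0],
            "Vol": [1.0, 2.0, 3.0, 1.5, 2.0, 2.5],
            "MC": [-0.5, 0.5, 0.1, -0.2, 0.3, 0.0],
            "SD": [0.1, 0.3, -0.2, 0.0, 0.2, -0.1],
        }
    )
    return VertexFeatureTable(df, ["CT", "SA", "Vol", "MC", "SD"])


@pytest.fixture
def toy_parcellation():
    return ParcellationScheme(
        pd.DataFrame(
            {
                "region_id": ["A", "B"],
                "hemisphere": ["left", "right"],
            }
        )
    )
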