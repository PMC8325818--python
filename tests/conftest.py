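import numpy as np
import pandas as pd
import pytest

from spotmap import ClassReference, SpotTable
from spotmap import simulate as sim


@pytest.fixture
def small_spots():
    """Nine hand-placed reads, three genes, one sample."""
    return SpotTable(pd.DataFrame({
        "gene": ["A", "A", "A", "B", "B", "B", "C", "C", "C"],
        "x": [0.0, 1.0, 2.0, 10.0, 11.0, 12.0, 5.0, 5.5, 6.0],
        "y": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 8.0, 8.0, 8.0],
    }))


@pytest.fixture
def uniform_spots():
    """600 uniform reads of 3 equally abundant genes (spatial randomness)."""
    rng = np.random.default_rng(42)
    n = 600
    return SpotTable(pd.DataFrame({
        "gene": rng.choice(["A", "B", "C"], n),
        "x": rng.uniform(0, 1000, n),
        "y": rng.uniform(0, 1000, n),
    }))


@pytest.fixture
def five_class_ref():
    """5 classes × 8 genes, each class with a strong marker."""
    rng = np.random.default_rng(7)
    means = rng.uniform(0.5, 2.0, (5, 8))
    for i in range(5):
        means[i, i] = 25.0
    return ClassReference(pd.DataFrame(
        means,
        index=[f"class_{i}" for i in range(5)],
        columns=[f"g{i}" for i in range(8)],
    ))


@pytest.fixture
def layered_spec():
    return sim.TissueSpec(
        field_size=(1000.0, 1000.0),
        layers=[
            sim.LayerBand(0, 100, {"L1": 1.0}),
            sim.LayerBand(100, 200, {"L2": 1.0}),
        ],
        reads_per_layer=400,
        background_genes=["Bg"],
        reads_per_background_gene=200,
    )
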