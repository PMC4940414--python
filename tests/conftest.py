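import numpy as np
import pandas as pd
import pytest

from traitnet import (
    CorrelationBlock,
    SimulationConfig,
    annotation_frame,
    generate_panel,
)
from traitnet.containers import NormalizedMatrix


@pytest.fixture
def two_block_config():
    """Two planted blocks of 10 features each, latent correlation 0.7."""
    cfg = SimulationConfig(
        n_lines=100,
        n_replicates=5,
        n_metabolites=20,
        n_enzymes=0,
        missing_rate=0.0,
        h2=0.6,
        seed=7,
    )
    mets = cfg.metabolite_ids
    cfg.blocks = [
        CorrelationBlock("A", mets[:10], 0.7),
        CorrelationBlock("B", mets[10:], 0.7),
    ]
    return cfg


@pytest.fixture
def small_panel():
    cfg = SimulationConfig(
        n_lines=30,
        n_replicates=4,
        n_metabolites=8,
        n_enzymes=3,
        missing_rate=0.05,
        h2=0.5,
        n_plates=2,
        seed=11,
    )
    table, truth = generate_panel(cfg)
    return cfg, table, truth


def make_normalized(values: np.ndarray, n_lines: int, n_reps: int,
                    features=None) -> NormalizedMatrix:
    """Wrap an array (samples x features) as a NormalizedMatrix."""
    values = np.asarray(values, dtype=float)
    if features is None:
        features = [f"f{j}" for j in range(values.shape[1])]
    index = pd.MultiIndex.from_product(
        [[f"L{i}" for i in range(n_lines)], [f"r{k}" for k in range(n_reps)]],
        names=["line_id", "replicate_id"],
    )
    frame = pd.DataFrame(values, index=index, columns=features)
    return NormalizedMatrix(frame)


@pytest.fixture
def simple_annotations():
    return annotation_frame(["m1", "m2"], ["e1"])
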