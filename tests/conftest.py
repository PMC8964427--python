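import numpy as np
import pandas as pd
import pytest

from cernaforge import ExpressionMatrix, SimConfig
from cernaforge.simulate import simulate_all


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One full simulation shared across tests (read-only)."""
    return simulate_all(default_config)


def make_matrix(values, feature_ids, stages, n_reps, layer="mRNA") -> ExpressionMatrix:
    """Small helper: matrix with ``<stage>_<rep>`` sample IDs."""
    samples = [f"{s}_{r + 1}" for s in stages for r in range(n_reps)]
    df = pd.DataFrame(np.asarray(values, dtype=float), index=feature_ids, columns=samples)
    return ExpressionMatrix(values=df, layer=layer)
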