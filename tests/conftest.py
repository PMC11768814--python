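import numpy as np
import pandas as pd
import pytest

from opswatch import SyntheticConfig, ToxicityMatrix, load_paper_fixtures
from opswatch.data import INDICATOR_NAMES


@pytest.fixture(scope="session")
def paper_fixtures():
    return load_paper_fixtures()


@pytest.fixture
def default_cfg():
    return SyntheticConfig(seed=0)


def random_toxicity(n_entities: int, seed: int) -> ToxicityMatrix:
    """A small valid 24-indicator matrix with random but in-range values."""
    rng = np.random.default_rng(seed)
    cols = {}
    for name in INDICATOR_NAMES:
        if name in ("BCF", "IGC50", "LC50DM", "LC50FM"):
            cols[name] = np.exp(rng.normal(1.0, 0.8, n_entities))
        else:
            cols[name] = rng.uniform(0, 1, n_entities)
    frame = pd.DataFrame(
        cols, index=pd.Index([f"E{i:02d}" for i in range(n_entities)], name="name")
    )
    return ToxicityMatrix(frame)
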