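import numpy as np
import pandas as pd
import pytest

from peelfusion import GeneratorConfig, generate_replicate_blocks
from peelfusion.blocks import FeatureBlock

#: worked 3x3 example used across the texture tests
EXAMPLE_IMG = np.array([[0, 0, 1], [0, 0, 1], [0, 2, 2]], dtype=np.uint8)


@pytest.fixture(scope="session")
def citrus_blocks():
    """One seeded draw of the default study design (6 classes x 10)."""
    return generate_replicate_blocks(cfg=GeneratorConfig(n_per_class=10, seed=7))


@pytest.fixture
def toy_block():
    rng = np.random.default_rng(0)
    index = pd.Index([f"s{i}" for i in range(12)], name="sample_id")
    data = pd.DataFrame(rng.normal(size=(12, 3)), index=index, columns=["a", "b", "c"])
    labels = pd.Series(["x"] * 6 + ["y"] * 6, index=index, name="class")
    return FeatureBlock("physico", data, labels)
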