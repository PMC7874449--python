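import numpy as np
import pandas as pd
import pytest

from guildflow.containers import FeatureTable


@pytest.fixture
def tiny_ft() -> FeatureTable:
    """3 features x 2 samples, counts."""
    df = pd.DataFrame(
        [[1.0, 0.0], [2.0, 3.0], [0.0, 5.0]],
        index=["fA", "fB", "fC"],
        columns=["s1", "s2"],
    )
    return FeatureTable(df, unit="counts")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return str(path)
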