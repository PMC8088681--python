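import numpy as np
import pandas as pd
import pytest

from trisomap import ExpressionSample


def make_sample(values: dict[str, float], sample_id="s1", condition="A") -> ExpressionSample:
    return ExpressionSample(sample_id, condition, pd.Series(values, dtype=float))


@pytest.fixture
def small_catalog() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": ["GENE1", "GENE2", "GENE3", "GENE4", "MTG1"],
            "chromosome": ["1", "1", "2", "21", "MT"],
            "start": [100, 600_000, 1_000, 50_000, 1_000],
            "end": [10_100, 610_000, 11_000, 60_000, 2_000],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
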