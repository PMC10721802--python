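import numpy as np
import pandas as pd
import pytest

from mcifmri import BoldSeries, FeatureTable


def make_table(
    n_per_class: int = 20,
    n_features: int = 10,
    planted: dict[int, float] | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Small labelled feature table; ``planted`` maps column -> Cohen's d."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.repeat([0, 1], n_per_class)
    x = rng.standard_normal((n, n_features))
    for col, d in (planted or {}).items():
        x[y == 1, col] += d
    frame = pd.DataFrame(
        x,
        index=[f"sub-{i:03d}" for i in range(n)],
        columns=[f"fALFF__{j + 1:03d}__region_{j + 1:03d}" for j in range(n_features)],
    )
    return FeatureTable(data=frame, labels=pd.Series(y, index=frame.index))


def make_series(data: np.ndarray, **kwargs) -> BoldSeries:
    return BoldSeries(data=np.asarray(data, dtype=float), **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
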