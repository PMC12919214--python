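import numpy as np
import pandas as pd
import pytest

from mitosel import GroupData, ObservationSet


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def small_obs():
    """Five hand-written records across two clones, with one exact zero."""
    df = pd.DataFrame(
        {
            "cell": ["c1", "c1", "c2", "c2", "c3"],
            "clone": ["A", "A", "A", "B", "B"],
            "mutation": ["m1", "m2", "m1", "m1", "m2"],
            "vaf": [0.2, 0.8, 0.5, 0.1, 0.9],
            "score": [0.4, 0.0, 0.35, -0.1, 0.6],
        }
    )
    return ObservationSet.from_dataframe(df)


def random_group(rng, n=10, pi=0.3, a=0.4, b=0.1, sigma=0.3):
    """A small group drawn from the generative process itself."""
    v = rng.uniform(0, 1, n)
    z = rng.random(n) >= pi
    score = np.where(z, a * v + b + sigma * rng.standard_normal(n), 0.0)
    return GroupData.from_records(v, score)
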