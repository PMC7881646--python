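import numpy as np
import pytest

from mwsl.datatypes import FeatureMatrix, Outcome


def make_features(n: int, M: int, seed: int = 0) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    return FeatureMatrix(
        rng.standard_normal((n, M)),
        [f"f{j}" for j in range(M)],
        [f"s{i}" for i in range(n)],
    )


@pytest.fixture
def iid_features() -> FeatureMatrix:
    """200 x 20 iid standard-normal feature matrix."""
    return make_features(200, 20, seed=42)


@pytest.fixture
def null_outcome(iid_features) -> Outcome:
    rng = np.random.default_rng(7)
    return Outcome("continuous", rng.standard_normal(iid_features.n))
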