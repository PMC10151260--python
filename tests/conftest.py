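import numpy as np
import pytest

from homovar.samples import GroupedSample


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_normal_groups(rng):
    """Two normal groups with unequal sizes and a genuine scale difference."""
    x = rng.normal(0.0, 1.0, 17)
    y = rng.normal(0.3, 2.0, 23)
    return x, y


@pytest.fixture
def three_group_sample(rng):
    """Three normal groups of unequal sizes."""
    return GroupedSample.from_arrays(
        [
            rng.normal(0.0, 1.0, 12),
            rng.normal(0.5, 1.5, 15),
            rng.normal(1.0, 1.0, 11),
        ],
        labels=["S", "H", "B"],
    )
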