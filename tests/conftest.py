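import numpy as np
import pytest

from wormtwitch.segmentation import AreaSeries
from wormtwitch.contraction import deviation_series


@pytest.fixture
def worked_series():
    """The five-frame hand-worked body-area series at 0.07 s/frame."""
    return AreaSeries([10.0, 8.0, 10.0, 8.0, 10.0], 0.07)


@pytest.fixture
def worked_deviation(worked_series):
    return deviation_series(worked_series)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
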