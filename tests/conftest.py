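import numpy as np
import pytest

from codstress.respirometry import RespirometerSpec
from codstress.synthetic import FishRecord


@pytest.fixture
def spec():
    return RespirometerSpec()


@pytest.fixture
def fast_spec():
    """Low-rate spec for schedule tests where per-sample detail is irrelevant."""
    return RespirometerSpec(sampling_hz=0.2)


@pytest.fixture
def fish():
    return FishRecord(
        fish_id="f1", treatment="control", tank_id="t1", ecotype="coastal",
        mass_g=159.4, length_cm=24.3, alive=True, true_smr=60.0,
        response_class="none",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
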