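import numpy as np
import pytest

from zfswim import FishRecord, TunnelSpec
from zfswim.synthetic import SyntheticTruth


@pytest.fixture
def tunnel() -> TunnelSpec:
    """The small individual respirometer: 1.8 L, fresh water at 28 °C."""
    return TunnelSpec(volume_l=1.8, temperature_c=28.0)


@pytest.fixture
def fish() -> FishRecord:
    """A fish at the mean morphometrics of the economy experiment."""
    return FishRecord(
        fish_id="f01",
        standard_bl_cm=3.05,
        total_tl_cm=3.60,
        body_weight_g=0.43,
        group="individual",
    )


@pytest.fixture
def noiseless_truth() -> SyntheticTruth:
    return SyntheticTruth(trace_noise_sd_pct_as=0.0, ct_noise_sd=0.0, seed=7)


@pytest.fixture
def truth() -> SyntheticTruth:
    return SyntheticTruth(seed=7)
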