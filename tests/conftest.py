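import numpy as np
import pytest

from saibr import (
    ChannelStack,
    SceneParams,
    build_pixel_pool,
    fit_two_channel,
    make_cohort,
)


def stack_from(primary, af, rfp=None, roi=None, sample_id="s", meta=None):
    """Build a ChannelStack from plain arrays (test helper)."""
    return ChannelStack(
        primary=np.asarray(primary, dtype=float),
        predictor_af=np.asarray(af, dtype=float),
        predictor_rfp=None if rfp is None else np.asarray(rfp, dtype=float),
        roi=roi,
        sample_id=sample_id,
        meta=meta or {},
    )


@pytest.fixture(scope="session")
def unlabeled_params():
    """Study-condition generator defaults for unlabeled calibration scenes."""
    return SceneParams(seed=10)


@pytest.fixture(scope="session")
def calibration_scenes(unlabeled_params):
    return make_cohort(unlabeled_params, 10)


@pytest.fixture(scope="session")
def fitted_model(calibration_scenes):
    """Two-channel model fitted on the pooled unlabeled calibration scenes."""
    pool = build_pixel_pool([s.stack for s in calibration_scenes], 2.0)
    return fit_two_channel(pool)
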