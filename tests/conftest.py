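import numpy as np
import pytest

from tonguegloss import CalibrationModel
from tonguegloss.synthetic import TongueSceneParams, make_pair, tongue_mask_from_params


@pytest.fixture
def identity_model() -> CalibrationModel:
    """RGB passed through as XYZ, white at (255, 255, 255)."""
    return CalibrationModel.identity()


@pytest.fixture
def default_scene() -> TongueSceneParams:
    return TongueSceneParams(seed=0)


def scene_with_fraction(fraction_pct: float, seed: int) -> TongueSceneParams:
    """Scene whose ground-truth glossy fraction of the tongue is ``fraction_pct``."""
    params = TongueSceneParams(seed=seed)
    area = int(np.count_nonzero(tongue_mask_from_params(params)))
    params.speckle_px = int(round(area * fraction_pct / 100.0))
    return params


@pytest.fixture
def five_pct_pair():
    """A pair with exactly 5% of the tongue glossy, plus its ground truth."""
    params = scene_with_fraction(5.0, seed=11)
    pair, speckle = make_pair(params)
    return pair, speckle, params
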