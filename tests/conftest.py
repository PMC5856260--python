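import numpy as np
import pytest

from fibroquant.evaluation import train_quantification_models
from fibroquant.synthetic import StainProfile, SyntheticSlideParams, generate_slide


@pytest.fixture(scope="session")
def quant_models():
    """Compact low/high-magnification model pair shared across the suite."""
    return train_quantification_models(seed=5)


@pytest.fixture(scope="session")
def probe_slide():
    """A fresh (non-training) slide with ground truth for agreement checks."""
    params = SyntheticSlideParams(
        width_px=384, height_px=384, fibrotic_mass_fraction=0.35,
        alveolar_collagen_fraction=0.10, n_bronchi=2, seed=999,
        stain_profile=StainProfile(hue_shift_deg=5.0, intensity_scale=1.1),
    )
    pyramid, gt = generate_slide(params)
    return pyramid, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
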