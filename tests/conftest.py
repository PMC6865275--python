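import numpy as np
import pytest

from gridattn.attention import AttentionConfig, AttentionModel
from gridattn.backbone import make_backbone
from gridattn.classes import ADENOCARCINOMA
from gridattn.synthetic import Lesion, SyntheticSpec, generate_tissue_image


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model():
    """Small attention model (k=8, 3 heads, no dropout) for numeric tests."""
    model = AttentionModel(backbone=make_backbone("tiny", feature_dim=8, seed=0),
                           config=AttentionConfig(n_filters=3, dropout_p=0.0), seed=0)
    return model


@pytest.fixture(scope="session")
def small_tissue():
    """One rendered 492x984 tissue (1x2 grid) with an adenocarcinoma lesion."""
    spec = SyntheticSpec(image_width=984, image_height=492, seed=7,
                         lesions=[Lesion(ADENOCARCINOMA, (500, 120, 900, 360))])
    return generate_tissue_image(spec)


@pytest.fixture(scope="session")
def normal_tissue():
    spec = SyntheticSpec(image_width=984, image_height=492, seed=8)
    return generate_tissue_image(spec)


def structured_cells(n, size=32, seed=0):
    """Cells with distinct mean levels so backbone features differ per cell."""
    rng = np.random.default_rng(seed)
    levels = np.linspace(-2.0, 2.0, n, dtype=np.float32)
    base = np.stack([np.full((size, size, 3), v, np.float32) for v in levels])
    return base + 0.2 * rng.standard_normal(base.shape).astype(np.float32)
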