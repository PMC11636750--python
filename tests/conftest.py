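import numpy as np
import pytest

import lungct as lc


@pytest.fixture(scope="session")
def small_phantom_cfg():
    return lc.PhantomConfig(height=64, width=64, tumor_radius_range=(4, 9))


N_SUITE, N_TRAIN = 60, 45


@pytest.fixture(scope="session")
def phantom_suite(small_phantom_cfg):
    """60 preprocessed phantoms (alternating cancer / non-cancer); the
    first 45 are the training portion used by ``fitted_segmenter``."""
    cfg = small_phantom_cfg
    samples = [lc.generate_phantom(cfg.replace(tumor_count=1 if i % 2 else 0),
                                   seed=i) for i in range(N_SUITE)]
    images = [lc.preprocess_image(s.image) for s in samples]
    masks = [s.mask for s in samples]
    labels = [s.label for s in samples]
    return images, masks, labels


@pytest.fixture(scope="session")
def fitted_segmenter(phantom_suite):
    images, masks, _ = phantom_suite
    return lc.DBNSegmenter(random_state=0).fit(images[:N_TRAIN],
                                               masks[:N_TRAIN])
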