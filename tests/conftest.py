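import numpy as np
import pytest

from drenet.backbones import calibrate_batchnorm
from drenet.ensemble import DRENet
from drenet.synthetic import (CLASS_LABELS, SyntheticDatasetSpec,
                              generate_dataset)
from drenet.interface import load_images


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """24 easy-mode phantoms (6 per class) downsampled to 56x56."""
    out = tmp_path_factory.mktemp("phantoms56")
    spec = SyntheticDatasetSpec({c: 6 for c in CLASS_LABELS},
                                master_seed=42, image_size=56)
    manifest = generate_dataset(spec, out)
    images = load_images(manifest, out)
    return manifest, images


@pytest.fixture(scope="session")
def frozen_model(small_dataset):
    """A frozen random-init ensemble at 56px input with calibrated BN."""
    _, images = small_dataset
    model = DRENet.build(seed=1, input_size=56)
    pick = np.linspace(0, len(images) - 1, 8).astype(int)
    calib = [images[i] for i in pick]
    calibrate_batchnorm(model.extractor_resnet, calib)
    calibrate_batchnorm(model.extractor_densenet, calib)
    return model
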