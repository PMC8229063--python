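"""Reduced-scale study protocol used by the acceptance checks and the
reproduction script.

The full published protocol (597 radiographs, ImageNet-pretrained
backbones, GPU-scale fine-tuning) is out of reach on a laptop-class CPU,
so the recovery study runs the complete pipeline at reduced scale:

* 120 easy-mode phantoms (30 per class) rendered by the bundled generator
  and downsampled to 56x56 network inputs;
* frozen random-initialized extractors whose batch-norm statistics are
  calibrated on 16 images (the transfer-learning initialization cannot be
  shipped, and fine-tuning 170 M parameters on one CPU is not feasible);
* full 36-angle RIA on every training portion;
* two-fold closed-world cross-validation (about 60 training and 60 test
  images per fold, the published protocol's fold structure at k = 2) and
  the standard four class-disjoint open-world runs;
* SCN training exactly per the published recipe (9 epochs, batch 10,
  lr 0.001, momentum 0.9, L2 0.0001).

One call runs both configurations on a single seed and shares the
concat-feature cache between them.
"""

from __future__ import annotations

import tempfile

from .augment import RotationPolicy
from .closed_world import ClosedWorldResult, prepare_frozen_model, \
    run_closed_world
from .interface import load_images
from .open_world import OpenWorldResult, run_open_world
from .synthetic import CLASS_LABELS, SyntheticDatasetSpec, generate_dataset
from .training import TrainConfig

__all__ = ["REDUCED_INPUT_SIZE", "REDUCED_COUNTS", "reduced_scale_study"]

REDUCED_INPUT_SIZE = 56
REDUCED_COUNTS = {c: 30 for c in CLASS_LABELS}
BN_CALIBRATION_IMAGES = 16


def reduced_scale_study(seed: int, counts: dict[str, int] | None = None,
                        k: int = 2) -> tuple[ClosedWorldResult, OpenWorldResult]:
    """Generate a phantom dataset and run both evaluation configurations.

    ``seed`` drives the dataset, the extractor initialization, the fold
    assignment, and SCN training.  Returns (closed-world result,
    open-world result).
    """
    counts = counts or REDUCED_COUNTS
    policy = RotationPolicy()  # the full 36-angle grid
    with tempfile.TemporaryDirectory() as tmp:
        manifest = generate_dataset(
            SyntheticDatasetSpec(counts, master_seed=seed,
                                 image_size=REDUCED_INPUT_SIZE), tmp)
        images = load_images(manifest, tmp)
    labels = manifest["label"].tolist()
    config = TrainConfig(seed=seed, epochs_backbone=0)
    cache = prepare_frozen_model(images, seed, REDUCED_INPUT_SIZE,
                                 BN_CALIBRATION_IMAGES, policy)
    closed = run_closed_world(images, labels, config, k=k, seed=seed,
                              policy=policy, input_size=REDUCED_INPUT_SIZE,
                              cache=cache)
    opened = run_open_world(images, labels, config, seed=seed, policy=policy,
                            input_size=REDUCED_INPUT_SIZE, cache=cache)
    return closed, opened
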