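"""Independent template-matching oracle for the phantom generator.

Classifies a phantom by maximum normalized cross-correlation against
noiseless mid-range class templates rendered at a small set of candidate
pose angles.  Everything runs at half resolution for speed.  This oracle
is deliberately independent of the package's CNN pipeline: it only uses
the generator's published geometry ranges and plain NCC matching.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from skimage.feature import match_template

from drenet.synthetic import (CLASS_LABELS, ImplantPhantomSpec,
                              class_template, render_phantom)

_SCALE = 2  # downsample factor for matching
_POSE_CANDIDATES = (-24.0, -16.0, -8.0, 0.0, 8.0, 16.0, 24.0)


def _template_image(class_id: str, angle: float, difficulty: str) -> np.ndarray:
    tpl = class_template(class_id, difficulty)
    spec = ImplantPhantomSpec(
        class_id=class_id,
        stem_length_px=sum(tpl.stem_length) // 2,
        stem_width_px=sum(tpl.stem_width) // 2,
        head_radius_px=sum(tpl.head_radius) // 2,
        head_shape=tpl.head_shape,
        collar=tpl.collar,
        foreground_intensity=255,
        background_gradient=(0, 0),
        noise_sd=0.0,
        pose_angle_deg=angle,
        pose_offset_px=(0, 0),
        seed=0,
    )
    img = render_phantom(spec)[:, :, 0].astype(np.float64)
    small = np.asarray(Image.fromarray(img.astype(np.uint8)).resize(
        (224 // _SCALE, 224 // _SCALE), Image.Resampling.BILINEAR), np.float64)
    # crop to the implant bounding box plus margin
    ys, xs = np.nonzero(small > 16)
    m = 2
    y0, y1 = max(ys.min() - m, 0), min(ys.max() + m + 1, small.shape[0])
    x0, x1 = max(xs.min() - m, 0), min(xs.max() + m + 1, small.shape[1])
    return small[y0:y1, x0:x1]


class TemplateOracle:
    def __init__(self, difficulty: str = "easy") -> None:
        self.templates = {
            c: [_template_image(c, a, difficulty) for a in _POSE_CANDIDATES]
            for c in CLASS_LABELS
        }

    def classify(self, image: np.ndarray) -> str:
        if image.ndim == 3:
            image = image[:, :, 0]
        small = np.asarray(Image.fromarray(image.astype(np.uint8)).resize(
            (224 // _SCALE, 224 // _SCALE), Image.Resampling.BILINEAR), np.float64)
        best, best_score = None, -np.inf
        for label, templates in self.templates.items():
            for tpl in templates:
                score = match_template(small, tpl, pad_input=False).max()
                if score > best_score:
                    best, best_score = label, score
        return best
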