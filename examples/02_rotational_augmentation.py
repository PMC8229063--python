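"""Rotational invariant augmentation (RIA).

Each training image is expanded into 36 in-plane poses (0..350 degrees in
10-degree steps, the original included).  Test images are never augmented.
"""
import numpy as np

from drenet import RotationPolicy, ria_expand, render_phantom
from drenet.synthetic import sample_phantom_spec

image = render_phantom(sample_phantom_spec("C1", seed=3))
policy = RotationPolicy()

augmented = ria_expand([image], policy)
print(f"1 input image -> {len(augmented)} poses "
      f"(first pose identical to the input: "
      f"{np.array_equal(augmented[0], image)})")
print(f"538 training images would become {538 * policy.n_angles} "
      "augmented images.")
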