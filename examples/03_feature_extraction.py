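"""The two truncated backbones and their feature vectors.

The modified ResNet-50 maps an image to f1 (2048-d), the modified
DenseNet-201 to f2 (1920-d); their concatenation f = [f1 | f2] (3968-d)
is what the shallow concatenation network classifies.
"""
import numpy as np

from drenet import FeatureExtractorSpec, build_extractor, stage_shapes
from drenet.ensemble import concat_features
from drenet.synthetic import render_phantom, sample_phantom_spec

image = render_phantom(sample_phantom_spec("C2", seed=1))
resnet = build_extractor(FeatureExtractorSpec("resnet50_modified", seed=0))
densenet = build_extractor(FeatureExtractorSpec("densenet201_modified", seed=0))

f1 = resnet.features([image])[0]
f2 = densenet.features([image])[0]
f = concat_features(f1, f2)
print(f"f1: {f1.shape}, f2: {f2.shape}, concatenated f: {f.shape}")

print("\nResNet stage shapes (224x224 input):")
for name, h, w, c in stage_shapes(resnet, input_size=224):
    print(f"  {name:18s} {h}x{w}x{c}")
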