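"""Published benchmark averages for DRE-Net on the real shoulder-implant
X-ray dataset (597 images, four manufacturers, 10-fold cross-validation).

These numbers are comparison constants only: reproducing them requires
the external dataset, ImageNet-pretrained weights, and GPU-scale
training, none of which this package performs.  They are used to recompute
the headline deltas (the RIA gain over generic rotation+translation
augmentation, and the gain over the human visual-comparison baseline) and
as context in reports.  All values are percentages.
"""

from __future__ import annotations

__all__ = ["CLOSED_WORLD_BENCHMARKS", "SUBJECTIVE_BENCHMARK",
           "OPEN_WORLD_BENCHMARKS", "PCA_KNN_BENCHMARK"]


def _r(accuracy, f1, precision, recall):
    return {"accuracy": accuracy, "f1": f1,
            "precision": precision, "recall": recall}


#: 10-fold closed-world averages by augmentation regime
CLOSED_WORLD_BENCHMARKS = {
    "no_augmentation": {
        "ResNet-50": _r(66.70, 62.02, 64.67, 59.83),
        "DenseNet-201": _r(55.76, 47.55, 49.73, 45.73),
        "DRE-Net (sequential)": _r(58.10, 50.82, 51.78, 49.96),
    },
    "with_random_rotation_translation": {
        "ResNet-50": _r(80.56, 77.66, 79.49, 76.02),
        "DenseNet-201": _r(80.57, 77.60, 79.05, 76.32),
        "DRE-Net (sequential)": _r(77.05, 74.80, 76.93, 73.07),
    },
    "with_ria": {
        "ResNet-50": _r(80.57, 78.02, 79.21, 76.95),
        "DenseNet-201": _r(84.75, 83.76, 85.21, 82.42),
        "DRE-Net (end-to-end)": _r(81.55, 79.12, 80.77, 77.66),
        "DRE-Net (sequential)": _r(85.92, 84.69, 85.33, 84.11),
    },
}

#: average human visual-comparison performance over the same 10 folds
SUBJECTIVE_BENCHMARK = {
    "Subjective Method": _r(52.25, 49.54, 48.86, 50.28),
}

#: two-fold class-disjoint (open-world) averages
OPEN_WORLD_BENCHMARKS = {
    "ResNet-50": _r(74.96, 67.14, 67.78, 66.51),
    "DenseNet-201": _r(76.64, 71.31, 70.64, 72.05),
    "DRE-Net": _r(77.36, 70.85, 71.22, 70.49),
}

#: the PCA(lambda=10)+KNN ablation versus the SCN head
PCA_KNN_BENCHMARK = {
    "SCN": _r(85.92, 84.69, 85.33, 84.11),
    "PCA+KNN": _r(57.94, 48.04, 60.17, 40.60),
}
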