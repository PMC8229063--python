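"""Manifest and configuration I/O shared by the pipeline and the CLI.

A dataset manifest is a CSV with header ``path,label,split`` (plus any
extra columns such as ``seed`` or RIA provenance).  Labels are the class
ids C1..C4 or the manufacturer names they stand for (Cofield, Depuy,
Tornier, Zimmer), which are normalized to class ids on load.  The class
order is fixed globally as (Cofield, Depuy, Tornier, Zimmer) = (C1..C4);
tie-breaking and confusion-matrix layout depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .synthetic import CLASS_LABELS, MANUFACTURERS
from .training import TrainConfig

logger = logging.getLogger(__name__)

__all__ = ["LABEL_ALIASES", "load_manifest", "load_images", "RunConfig",
           "setup_logging"]

LABEL_ALIASES = {name: cid for name, cid in zip(MANUFACTURERS, CLASS_LABELS)}
VALID_SPLITS = ("train", "test")


def load_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a manifest CSV; returns a normalized frame.

    Paths are interpreted relative to the manifest's directory.  Errors
    name the offending row (1-based, excluding the header).
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    required = {"path", "label", "split"}
    if not required.issubset(manifest.columns):
        raise ValueError(
            f"manifest must have columns {sorted(required)}, got "
            f"{list(manifest.columns)}")
    base = path.parent
    labels = []
    for row_no, row in enumerate(manifest.itertuples(index=False), start=1):
        label = LABEL_ALIASES.get(row.label, row.label)
        if label not in CLASS_LABELS:
            raise ValueError(
                f"row {row_no}: unknown label {row.label!r} (expected one of "
                f"{CLASS_LABELS} or {MANUFACTURERS})")
        if row.split not in VALID_SPLITS:
            raise ValueError(
                f"row {row_no}: split must be one of {VALID_SPLITS}, "
                f"got {row.split!r}")
        if check_files and not (base / row.path).exists():
            raise FileNotFoundError(
                f"row {row_no}: image file not found: {base / row.path}")
        labels.append(label)
    manifest = manifest.copy()
    manifest["label"] = labels
    return manifest


def load_images(manifest: pd.DataFrame, images_dir: str | Path) -> list[np.ndarray]:
    """Load manifest images as uint8 arrays, in manifest order."""
    images_dir = Path(images_dir)
    return [np.asarray(Image.open(images_dir / p)) for p in manifest["path"]]


@dataclass
class RunConfig:
    """One file describing a full run; round-trips losslessly through YAML.

    Every stochastic component derives its seed from ``root_seed``.
    """

    root_seed: int = 0
    out_dir: str = "runs/default"
    synthesis: dict = field(default_factory=lambda: {
        "counts_per_class": {"C1": 8, "C2": 30, "C3": 7, "C4": 15},
        "difficulty": "easy",
    })
    augmentation: dict = field(default_factory=lambda: {
        "angle_step_deg": 10, "interpolation": "bilinear", "fill_value": 0,
    })
    backbones: dict = field(default_factory=lambda: {
        "pretrained": False, "input_size": 224, "bn_calibration": 0,
    })
    training: dict = field(default_factory=lambda: {
        k: v for k, v in TrainConfig().to_dict().items() if k != "seed"})
    evaluation: dict = field(default_factory=lambda: {"k": 10})

    def train_config(self) -> TrainConfig:
        cfg = dict(self.training)
        cfg.setdefault("seed", self.root_seed)
        return TrainConfig.from_dict(cfg)

    def rotation_policy(self):
        from .augment import RotationPolicy
        step = self.augmentation.get("angle_step_deg", 10)
        return RotationPolicy(
            angles_deg=tuple(float(a) for a in np.arange(0, 360, step)),
            interpolation=self.augmentation.get("interpolation", "bilinear"),
            fill_value=self.augmentation.get("fill_value", 0))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
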