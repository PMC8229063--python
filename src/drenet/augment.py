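"""Rotational invariant augmentation (RIA).

Training images are expanded into in-plane rotations about the image
centre on a 10-degree grid, 36 poses per image *including* the unrotated
original (0, 10, ..., 350 degrees).  Rotation preserves the canvas size:
content rotated outside the frame is discarded and exposed corners take a
constant fill value.  Multiples of 90 degrees are exact array
re-indexings; other angles interpolate.  Test-split images are never
augmented.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = ["RotationPolicy", "DEFAULT_ANGLES", "rotate_image", "ria_expand",
           "ria_expand_manifest", "RandomRotationTranslationPolicy"]

DEFAULT_ANGLES: tuple[float, ...] = tuple(float(a) for a in range(0, 360, 10))


@dataclass(frozen=True)
class RotationPolicy:
    """Angle grid and resampling conventions for RIA."""

    angles_deg: tuple[float, ...] = DEFAULT_ANGLES
    interpolation: str = "bilinear"
    fill_value: int = 0

    def __post_init__(self) -> None:
        if self.interpolation not in ("bilinear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        mod = [a % 360.0 for a in self.angles_deg]
        if len(set(mod)) != len(mod):
            raise ValueError("rotation angles must be unique modulo 360")
        if not (0 <= self.fill_value <= 255):
            raise ValueError("fill_value must be an intensity in [0, 255]")

    @property
    def n_angles(self) -> int:
        return len(self.angles_deg)


@dataclass(frozen=True)
class RandomRotationTranslationPolicy:
    """Labelled alternative augmentation used only to benchmark against
    RIA: each training image receives ``copies`` random in-plane
    rotations combined with random translations.  Not part of RIA.
    """

    copies: int = 36
    max_angle_deg: float = 360.0
    max_shift_px: int = 10
    interpolation: str = "bilinear"
    fill_value: int = 0
    name: str = "random_rotation_translation"

    def expand(self, images: list[np.ndarray], seed: int) -> list[np.ndarray]:
        rng = np.random.default_rng(seed)
        rot_policy = RotationPolicy(angles_deg=(0.0,),
                                    interpolation=self.interpolation,
                                    fill_value=self.fill_value)
        out = []
        for img in images:
            for _ in range(self.copies):
                angle = float(rng.uniform(0.0, self.max_angle_deg))
                rotated = rotate_image(img, angle, rot_policy)
                dy, dx = rng.integers(-self.max_shift_px,
                                      self.max_shift_px + 1, size=2)
                shifted = np.full_like(rotated, self.fill_value)
                h, w = rotated.shape[:2]
                ys = slice(max(dy, 0), min(h + dy, h))
                xs = slice(max(dx, 0), min(w + dx, w))
                ys_src = slice(max(-dy, 0), max(-dy, 0) + (ys.stop - ys.start))
                xs_src = slice(max(-dx, 0), max(-dx, 0) + (xs.stop - xs.start))
                shifted[ys, xs] = rotated[ys_src, xs_src]
                out.append(shifted)
        return out


def rotate_image(image: np.ndarray, angle_deg: float,
                 policy: RotationPolicy | None = None) -> np.ndarray:
    """Rotate about the geometric centre ((H-1)/2, (W-1)/2), same-size output.

    Positive angles follow the ``np.rot90`` orientation so that quarter
    turns on square images are bit-exact re-indexings.
    """
    policy = policy or RotationPolicy()
    if not math.isfinite(angle_deg):
        raise ValueError(f"rotation angle must be finite, got {angle_deg!r}")
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D (H, W[, C]) image array")
    a = angle_deg % 360.0
    square = image.shape[0] == image.shape[1]
    if a == 0.0:
        return image.copy()
    if a == 180.0:
        return image[::-1, ::-1].copy()
    if square and a in (90.0, 270.0):
        k = int(a // 90)
        return np.rot90(image, k=k).copy()
    order = 1 if policy.interpolation == "bilinear" else 0
    rotated = ndimage.rotate(
        image.astype(np.float64), a, axes=(1, 0), reshape=False, order=order,
        mode="constant", cval=float(policy.fill_value), prefilter=False)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(rotated), info.min, info.max).astype(image.dtype)
    return rotated.astype(image.dtype)


def ria_expand(images: list[np.ndarray],
               policy: RotationPolicy | None = None) -> list[np.ndarray]:
    """Expand each image into one copy per policy angle (input-major order)."""
    policy = policy or RotationPolicy()
    if len(images) == 0:
        warnings.warn("ria_expand called with an empty image list")
        return []
    out: list[np.ndarray] = []
    for img in images:
        for angle in policy.angles_deg:
            out.append(rotate_image(img, angle, policy))
    return out


def ria_expand_manifest(manifest: pd.DataFrame, policy: RotationPolicy | None,
                        images_dir: str | Path, out_dir: str | Path) -> pd.DataFrame:
    """Expand the train split of a manifest on disk; test rows pass through.

    Augmented rows record ``source_path`` and ``angle_deg``; file names get
    a ``_rot{angle}`` suffix.  Test-split images are copied unmodified so
    the output directory is self-contained.
    """
    policy = policy or RotationPolicy()
    if "split" not in manifest.columns:
        raise ValueError("manifest must carry a 'split' column")
    images_dir, out_dir = Path(images_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        src = images_dir / row["path"]
        if not src.exists():
            raise FileNotFoundError(f"manifest references a missing image: {src}")
        if row["split"] != "train":
            img = Image.open(src)
            img.save(out_dir / src.name)
            out_row = dict(row)
            out_row.update(path=src.name, source_path=row["path"], angle_deg=0.0)
            rows.append(out_row)
            continue
        arr = np.asarray(Image.open(src))
        for angle in policy.angles_deg:
            rot = rotate_image(arr, angle, policy)
            name = f"{src.stem}_rot{int(angle) if float(angle).is_integer() else angle}{src.suffix}"
            Image.fromarray(rot).save(out_dir / name)
            out_row = dict(row)
            out_row.update(path=name, source_path=row["path"], angle_deg=float(angle))
            rows.append(out_row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.to_csv(out_dir / "manifest.csv", index=False)
    n_train = int((manifest["split"] == "train").sum())
    logger.info("RIA: %d train rows -> %d augmented rows (%d angles)",
                n_train, n_train * policy.n_angles, policy.n_angles)
    return out
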