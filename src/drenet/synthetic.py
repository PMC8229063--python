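"""Synthetic shoulder-implant radiograph phantoms.

Real post-operative shoulder radiographs show a bright metallic prosthesis
(a rod-like humeral stem topped by a head component) over a soft-tissue
background.  The four manufacturer classes used here (C1..C4) differ in
stem length/width and head geometry; C4 is deliberately drawn close to C2
(both hemispherical heads, similar stem) so the generated data reproduce
the confusable class pair seen in the real dataset.

Images are 224x224, 8-bit, three identical channels, and byte-reproducible
from their spec: the per-sample seed drives parameter jitter, pose, and
noise.  ``difficulty='hard'`` narrows the C2/C4 geometric gap.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

logger = logging.getLogger(__name__)

CANVAS = 224
CLASS_LABELS = ("C1", "C2", "C3", "C4")
#: manufacturer names in the fixed global class order
MANUFACTURERS = ("Cofield", "Depuy", "Tornier", "Zimmer")

__all__ = [
    "CANVAS", "CLASS_LABELS", "MANUFACTURERS",
    "ImplantPhantomSpec", "SyntheticDatasetSpec", "ClassTemplate",
    "CLASS_TEMPLATES", "HARD_C4_OVERRIDES", "class_template",
    "sample_phantom_spec", "render_phantom", "generate_dataset",
]


@dataclass(frozen=True)
class ClassTemplate:
    """Closed geometry ranges (inclusive) for one manufacturer class."""

    stem_length: tuple[int, int]
    stem_width: tuple[int, int]
    head_radius: tuple[int, int]
    head_shape: str           # rounded | hemispherical | angled
    collar: bool


# Easy-mode templates: every geometric range is disjoint across classes so a
# template-matching oracle can audit the generator.  C1: short stem, rounded
# head, collar.  C2: long wide stem, large hemispherical head.  C3: small
# angled head on a short stem.  C4: hemispherical head near C2's but on a
# narrower stem (the confusable pair).
CLASS_TEMPLATES: dict[str, ClassTemplate] = {
    "C1": ClassTemplate((68, 84), (16, 19), (23, 27), "rounded", True),
    "C2": ClassTemplate((118, 138), (26, 30), (34, 38), "hemispherical", False),
    "C3": ClassTemplate((48, 62), (12, 15), (16, 20), "angled", False),
    "C4": ClassTemplate((92, 110), (20, 23), (28, 32), "hemispherical", False),
}

# Hard mode pulls C4 into C2's ranges (overlapping stems and heads).
HARD_C4_OVERRIDES = ClassTemplate((110, 130), (24, 28), (32, 36), "hemispherical", False)


def class_template(class_id: str, difficulty: str = "easy") -> ClassTemplate:
    if class_id not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_id!r}; expected one of {CLASS_LABELS}")
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"difficulty must be 'easy' or 'hard', got {difficulty!r}")
    if difficulty == "hard" and class_id == "C4":
        return HARD_C4_OVERRIDES
    return CLASS_TEMPLATES[class_id]


@dataclass
class ImplantPhantomSpec:
    """Full deterministic description of one phantom image."""

    class_id: str
    stem_length_px: int
    stem_width_px: int
    head_radius_px: int
    head_shape: str
    collar: bool
    foreground_intensity: int
    background_gradient: tuple[int, int]
    noise_sd: float
    pose_angle_deg: float
    pose_offset_px: tuple[int, int]
    seed: int

    def validate(self) -> None:
        if self.class_id not in CLASS_LABELS:
            raise ValueError(f"unknown class {self.class_id!r}")
        if self.head_shape not in ("rounded", "hemispherical", "angled"):
            raise ValueError(f"unknown head shape {self.head_shape!r}")
        for name in ("stem_length_px", "stem_width_px", "head_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # the implant (stem + head + pose offset) must fit the canvas;
        # a rounded head is a full disc above the stem, the others extend
        # at most one radius beyond the stem shoulder
        head_extent = 2 * self.head_radius_px if self.head_shape == "rounded" \
            else self.head_radius_px
        extent = self.stem_length_px + head_extent
        off = max(abs(self.pose_offset_px[0]), abs(self.pose_offset_px[1]))
        if extent + 2 * off > CANVAS:
            raise ValueError(
                f"implant geometry (extent {extent}px + offset {off}px) exceeds "
                f"the {CANVAS}px canvas")
        if not (0 <= self.foreground_intensity <= 255):
            raise ValueError("foreground_intensity must be in [0, 255]")
        for g in self.background_gradient:
            if not (0 <= g <= 255):
                raise ValueError("background_gradient values must be in [0, 255]")


@dataclass
class SyntheticDatasetSpec:
    """Recipe for a reproducible synthetic dataset."""

    counts_per_class: dict[str, int]
    image_size: int = CANVAS
    master_seed: int = 0
    difficulty: str = "easy"
    train_fraction: float = 0.5

    @property
    def total(self) -> int:
        return sum(self.counts_per_class.values())


def _sample_seed(master_seed: int, index: int) -> int:
    """Order-independent per-sample seed via a stable hash."""
    h = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big")


def sample_phantom_spec(class_id: str, seed: int,
                        difficulty: str = "easy") -> ImplantPhantomSpec:
    """Draw one phantom spec from the class-conditional parameter ranges."""
    tpl = class_template(class_id, difficulty)
    rng = np.random.default_rng(seed)
    spec = ImplantPhantomSpec(
        class_id=class_id,
        stem_length_px=int(rng.integers(tpl.stem_length[0], tpl.stem_length[1] + 1)),
        stem_width_px=int(rng.integers(tpl.stem_width[0], tpl.stem_width[1] + 1)),
        head_radius_px=int(rng.integers(tpl.head_radius[0], tpl.head_radius[1] + 1)),
        head_shape=tpl.head_shape,
        collar=tpl.collar,
        foreground_intensity=int(rng.integers(195, 236)),
        background_gradient=(int(rng.integers(20, 61)), int(rng.integers(70, 111))),
        noise_sd=float(rng.uniform(5.0, 11.0)),
        pose_angle_deg=float(rng.uniform(-25.0, 25.0)),
        pose_offset_px=(int(rng.integers(-10, 11)), int(rng.integers(-10, 11))),
        seed=seed,
    )
    spec.validate()
    return spec


def _draw_implant_mask(spec: ImplantPhantomSpec, scale: int) -> Image.Image:
    """Draw the upright implant silhouette at ``scale`` x oversampling."""
    s = scale
    size = CANVAS * s
    img = Image.new("L", (size, size), 0)
    draw = ImageDraw.Draw(img)
    cx = cy = size // 2
    half_l = spec.stem_length_px * s // 2
    half_w = spec.stem_width_px * s // 2
    r = spec.head_radius_px * s
    # stem: vertical rod with a slight distal taper
    taper = max(1, half_w // 4)
    draw.polygon([
        (cx - half_w, cy - half_l), (cx + half_w, cy - half_l),
        (cx + half_w - taper, cy + half_l), (cx - half_w + taper, cy + half_l),
    ], fill=255)
    top = cy - half_l
    if spec.head_shape == "rounded":
        draw.ellipse([cx - r, top - 2 * r, cx + r, top], fill=255)
    elif spec.head_shape == "hemispherical":
        # half-disc sitting on the stem shoulder
        draw.pieslice([cx - r, top - r, cx + r, top + r], 180, 360, fill=255)
    else:  # angled: tilted triangular head
        draw.polygon([
            (cx - r, top), (cx + r, top - r), (cx + r // 2, top + r // 3),
        ], fill=255)
    if spec.collar:
        collar_w = half_w + max(2 * s, half_w // 2)
        draw.rectangle([cx - collar_w, top, cx + collar_w, top + 4 * s], fill=255)
    return img


def render_phantom(spec: ImplantPhantomSpec, antialias: bool = True) -> np.ndarray:
    """Render one phantom to a (224, 224, 3) uint8 array.

    Pipeline: draw the upright silhouette (oversampled 4x when
    ``antialias``), rotate by the pose angle about the image centre,
    translate by the pose offset, composite over a vertical soft-tissue
    intensity gradient, and add clipped Gaussian noise.  Deterministic in
    the spec (noise comes from ``spec.seed``).
    """
    spec.validate()
    scale = 4 if antialias else 1
    mask_img = _draw_implant_mask(spec, scale)
    resample = Image.Resampling.NEAREST
    mask_img = mask_img.rotate(spec.pose_angle_deg, resample=resample,
                               center=(mask_img.width / 2, mask_img.height / 2))
    if antialias:
        mask_img = mask_img.resize((CANVAS, CANVAS), Image.Resampling.BILINEAR)
    mask = np.asarray(mask_img, dtype=np.float64) / 255.0
    dx, dy = spec.pose_offset_px
    mask = np.roll(mask, (dy, dx), axis=(0, 1))

    g0, g1 = spec.background_gradient
    background = np.linspace(float(g0), float(g1), CANVAS)[:, None]
    background = np.broadcast_to(background, (CANVAS, CANVAS)).copy()
    img = background * (1.0 - mask) + float(spec.foreground_intensity) * mask
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return np.repeat(img[:, :, None], 3, axis=2)


def generate_dataset(spec: SyntheticDatasetSpec, out_dir: str | Path) -> pd.DataFrame:
    """Render a dataset and write one PNG per sample plus ``manifest.csv``.

    The manifest has columns ``path,label,split,seed``; splits are assigned
    round-robin within each class by ``train_fraction`` (default half/half)
    so both splits keep the class balance.  Returns the manifest frame.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if spec.total == 0:
        warnings.warn("generate_dataset called with zero total count")
        manifest = pd.DataFrame(columns=["path", "label", "split", "seed"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest

    rows = []
    index = 0
    for label in CLASS_LABELS:
        n = int(spec.counts_per_class.get(label, 0))
        n_train = int(round(n * spec.train_fraction))
        for i in range(n):
            seed = _sample_seed(spec.master_seed, index)
            pspec = sample_phantom_spec(label, seed, spec.difficulty)
            img = render_phantom(pspec)
            if spec.image_size != CANVAS:
                img = np.asarray(
                    Image.fromarray(img).resize(
                        (spec.image_size, spec.image_size),
                        Image.Resampling.BILINEAR))
            name = f"{label}_{i:04d}.png"
            Image.fromarray(img).save(out_dir / name)
            split = "train" if i < n_train else "test"
            rows.append({"path": name, "label": label, "split": split, "seed": seed})
            index += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    logger.info("generated %d synthetic images under %s", len(manifest), out_dir)
    return manifest
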