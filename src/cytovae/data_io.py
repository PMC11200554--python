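"""Annotation handling, cell cropping and training-time augmentation.

Source datasets annotate classified cells on whole micrographs rather than
shipping pre-cropped tiles, so the pipeline (i) drops annotations within a
margin of the image boundary (a full crop window must exist), (ii) cuts a
256 px window around each cell center and center-crops it to the 64 px model
input, and (iii) optionally augments with flips, rotation, translation and
brightness. Rotation/translation are applied to the larger window *before*
the final center crop, so no out-of-image background enters the model input.

Coordinate convention: 0-based, x = column, y = row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "AnnotationRecord",
    "AugmentationMode",
    "Augmentation",
    "read_annotations",
    "write_annotations",
    "load_image",
    "save_image",
    "filter_boundary",
    "extract_crop",
    "augment",
]

BETHESDA_CLASSES = ("NILM", "ASC-US", "LSIL", "ASC-H", "HSIL", "SCC")


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated cell: source image, center pixel and class label."""

    image_id: str
    center_x: int
    center_y: int
    class_label: str


class AugmentationMode(str, Enum):
    NONE = "none"
    FA = "fa"  # flip + affine (rotation, translation)
    FAB = "fab"  # FA + brightness


@dataclass(frozen=True)
class Augmentation:
    """Augmentation mode plus magnitude parameters.

    Defaults: rotation uniform over the full circle, translation up to 10% of
    the image side per axis, brightness factor in [0.8, 1.2], independent
    horizontal/vertical flips with probability 0.5. NONE is the identity; FA
    alters geometry only, never pixel intensities.
    """

    mode: AugmentationMode = AugmentationMode.NONE
    rotation_range: tuple[float, float] = (0.0, 360.0)
    translation_frac: float = 0.10
    brightness_range: tuple[float, float] = (0.8, 1.2)
    flip_prob: float = 0.5


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(path)
    required = {"image_id", "center_x", "center_y", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns {sorted(required)}")
    return [
        AnnotationRecord(str(r.image_id), int(r.center_x), int(r.center_y), str(r["class"]))
        for _, r in df.iterrows()
    ]


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "image_id": r.image_id,
                "center_x": r.center_x,
                "center_y": r.center_y,
                "class": r.class_label,
            }
            for r in records
        ],
        columns=["image_id", "center_x", "center_y", "class"],
    ).to_csv(path, index=False)


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/JPEG/TIFF into an RGB float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64)
    return arr / 255.0


def save_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def filter_boundary(
    records: list[AnnotationRecord],
    image_width: int,
    image_height: int,
    margin: int = 128,
) -> list[AnnotationRecord]:
    """Drop annotations within `margin` px of any image edge.

    Keeps exactly the records with margin <= center_x < width - margin and
    margin <= center_y < height - margin, preserving order. Idempotent.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if margin >= image_width / 2 or margin >= image_height / 2:
        warnings.warn(
            f"margin {margin} is at least half an image dimension "
            f"({image_width}x{image_height}); no annotation can survive",
            stacklevel=2,
        )
        return []
    return [
        r
        for r in records
        if margin <= r.center_x < image_width - margin
        and margin <= r.center_y < image_height - margin
    ]


def extract_crop(
    image: np.ndarray,
    record: AnnotationRecord,
    crop_size: int = 256,
    model_size: int = 64,
) -> np.ndarray:
    """Cut the model_size window centered on the annotated cell.

    Identical by construction to cutting the crop_size window first and then
    center-cropping it to model_size; the window is [c - s/2, c + s/2) on
    each axis with s = model_size.
    """
    h, w = image.shape[:2]
    half = crop_size // 2
    x0, y0 = record.center_x - half, record.center_y - half
    if x0 < 0 or y0 < 0 or x0 + crop_size > w or y0 + crop_size > h:
        raise ValueError(
            f"{crop_size}px crop at ({record.center_x}, {record.center_y}) "
            f"exceeds image bounds {w}x{h}"
        )
    mh = model_size // 2
    return image[
        record.center_y - mh : record.center_y - mh + model_size,
        record.center_x - mh : record.center_x - mh + model_size,
    ].copy()


def _affine_rgb(image: np.ndarray, matrix: np.ndarray, offset: np.ndarray) -> np.ndarray:
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = ndimage.affine_transform(
            image[..., c], matrix, offset=offset, order=1, mode="reflect"
        )
    return out


def augment(image: np.ndarray, aug: Augmentation | AugmentationMode, seed: int = 0) -> np.ndarray:
    """Apply one random augmentation draw; deterministic for a given seed.

    NONE returns the input unchanged. FA composes flips, a rotation about the
    image center and a translation into a single bilinear resample with
    reflection padding. FAB additionally multiplies by a brightness factor.
    The result is clipped to [0, 1].
    """
    if isinstance(aug, AugmentationMode):
        aug = Augmentation(mode=aug)
    if not isinstance(aug.mode, AugmentationMode):
        raise ValueError(f"unknown augmentation mode: {aug.mode!r}")
    if aug.mode is AugmentationMode.NONE:
        return image

    rng = np.random.default_rng(seed)
    h, w = image.shape[:2]
    flip_x = rng.random() < aug.flip_prob
    flip_y = rng.random() < aug.flip_prob
    angle = np.deg2rad(rng.uniform(*aug.rotation_range))
    tx = rng.uniform(-aug.translation_frac, aug.translation_frac) * w
    ty = rng.uniform(-aug.translation_frac, aug.translation_frac) * h

    # output (row, col) -> input coordinates: inverse of
    # translate∘rotate∘flip about the image center
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    cos, sin = np.cos(angle), np.sin(angle)
    rot_inv = np.array([[cos, sin], [-sin, cos]])  # rows are (y, x)
    flip = np.diag([-1.0 if flip_y else 1.0, -1.0 if flip_x else 1.0])
    matrix = flip @ rot_inv
    center = np.array([cy, cx])
    shift = np.array([ty, tx])
    offset = center - matrix @ (center + shift)
    out = _affine_rgb(image, matrix, offset)

    if aug.mode is AugmentationMode.FAB:
        out = out * rng.uniform(*aug.brightness_range)
    return np.clip(out, 0.0, 1.0)
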