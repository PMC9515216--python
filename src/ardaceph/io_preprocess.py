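"""Reading, screening, preprocessing, augmentation and split planning.

Preprocessing follows standard radiograph practice: per-image intensity
normalisation to [0, 1], CLAHE contrast enhancement, zero-padding to a
square frame so anatomy keeps its aspect ratio, and a resize to the fixed
network input size.  Augmentation is a mild seeded random affine plus a
random horizontal flip that also toggles the recorded facing direction.
"""

from __future__ import annotations

import datetime as _dt
import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import exposure, transform

from .core import AGE_MAX, AGE_MIN, AgedImage

#: Age-group bin edges; group i covers floor(age) in [edge_i, edge_{i+1}).
AGE_GROUP_EDGES = (4, 11, 16, 21, 26, 31, 36, 41)
AGE_GROUP_LABELS = ("4-10", "11-15", "16-20", "21-25", "26-30", "31-35", "36-40")


def decimal_age(birth_date: _dt.date, imaging_date: _dt.date) -> float:
    """Decimal age in years: day count divided by 365.25, to hundredths.

    The 365.25 divisor absorbs leap years over the multi-year intervals
    involved here.
    """
    days = (imaging_date - birth_date).days
    if days < 0:
        raise ValueError("imaging_date precedes birth_date")
    return round(days / 365.25, 2)


def age_group(age: float) -> str:
    """Seven-bin age-group label for a decimal age (by completed years)."""
    a = int(np.floor(age))
    for lo, hi, label in zip(AGE_GROUP_EDGES[:-1], AGE_GROUP_EDGES[1:], AGE_GROUP_LABELS):
        if lo <= a < hi:
            return label
    raise ValueError(f"age {age} outside the {AGE_MIN}-{AGE_MAX} study range")


def screen(image: AgedImage, annotations: set[str] | None = None) -> AgedImage:
    """Attach screening flags to an image.

    Only ``age_out_of_range`` is computed (age < 4 or > 40 years); the
    ``incomplete``, ``restoration`` and ``posture`` flags are manual
    annotations passed through from the caller, mirroring the manual visual
    screen applied to real radiographs.
    """
    if image.age is None or not np.isfinite(image.age):
        raise ValueError(f"image {image.id!r} has no usable age")
    flags = set(annotations or ())
    if image.age < AGE_MIN or image.age > AGE_MAX:
        flags.add("age_out_of_range")
    return image.with_(qc_flags=flags)


def filter_screened(images: list[AgedImage]) -> list[AgedImage]:
    """Drop every image that carries at least one screening flag."""
    return [im for im in images if not im.qc_flags]


def _pad_to_square(arr: np.ndarray, fill=0) -> np.ndarray:
    h, w = arr.shape
    side = max(h, w)
    top = (side - h) // 2
    left = (side - w) // 2
    out = np.full((side, side), fill, dtype=arr.dtype)
    out[top : top + h, left : left + w] = arr
    return out


def preprocess(
    image: AgedImage,
    target_size: tuple[int, int],
    clahe_clip: float = 0.01,
    clahe_tiles: int = 8,
) -> AgedImage:
    """CLAHE → zero-pad to square → resize to ``target_size``.

    The label map, when present, rides through the identical geometry with
    nearest-neighbour interpolation so labels stay integral.
    """
    px = image.pixels
    if px.size == 0 or min(px.shape) == 0:
        raise ValueError("degenerate image")
    if np.ptp(px) > 0:  # CLAHE is undefined on a flat image; leave it flat
        kernel = max(1, min(px.shape) // clahe_tiles)
        px = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=clahe_clip)
    px = _pad_to_square(px.astype(np.float64))
    px = transform.resize(px, target_size, order=1, anti_aliasing=True, preserve_range=True)
    px = np.clip(px, 0.0, 1.0)
    lm = None
    if image.label_map is not None:
        lm = _pad_to_square(image.label_map)
        lm = transform.resize(
            lm, target_size, order=0, anti_aliasing=False, preserve_range=True
        ).astype(image.label_map.dtype)
    return image.with_(pixels=px, label_map=lm)


@dataclass(frozen=True)
class AugmentConfig:
    """Bounds of the seeded random affine; defaults are mild and
    label-preserving."""

    rotation_deg: float = 10.0
    translate_frac: float = 0.05
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_prob: float = 0.5


def augment(image: AgedImage, seed: int, config: AugmentConfig | None = None) -> AgedImage:
    """Seeded random affine (rotation, translation, scale) + horizontal flip.

    The flip toggles ``orientation``.  A zero-amplitude configuration is the
    identity.  The same seed always yields the same output.
    """
    cfg = config or AugmentConfig()
    rng = np.random.default_rng(seed)
    h, w = image.pixels.shape
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    tx = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w
    ty = rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h
    scale = rng.uniform(*cfg.scale_range)
    do_flip = rng.uniform() < cfg.flip_prob

    px = image.pixels
    lm = image.label_map
    orientation = image.orientation
    identity = angle == 0 and tx == 0 and ty == 0 and scale == 1
    if not identity:
        # Rotate/scale about the image centre, then translate.
        centre = np.array([w / 2, h / 2])
        tf = (
            transform.AffineTransform(translation=-centre)
            + transform.AffineTransform(rotation=np.deg2rad(angle), scale=scale)
            + transform.AffineTransform(translation=centre + [tx, ty])
        )
        px = transform.warp(px, tf.inverse, order=1, preserve_range=True)
        if lm is not None:
            lm = transform.warp(
                lm.astype(float), tf.inverse, order=0, preserve_range=True
            ).astype(lm.dtype)
    if do_flip:
        px = np.fliplr(px)
        if lm is not None:
            lm = np.fliplr(lm)
        orientation = "left" if orientation == "right" else "right"
    return image.with_(pixels=px, label_map=lm, orientation=orientation)


@dataclass(frozen=True)
class SplitPlan:
    """Age-group-stratified train/val/test fractions."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("fractions must sum to 1")


def stratified_split(manifest: pd.DataFrame, plan: SplitPlan | None = None) -> pd.DataFrame:
    """Assign train/val/test within each of the seven age groups.

    Uses largest-remainder apportionment after a seeded shuffle, so a group
    of 100 at (0.70, 0.15, 0.15) splits exactly 70/15/15 and every subject
    lands in exactly one split.
    """
    plan = plan or SplitPlan()
    rng = np.random.default_rng(plan.seed)
    out = manifest.copy()
    out["age_group"] = out["age"].map(age_group)
    out["split"] = ""
    names = ("train", "val", "test")
    for label in AGE_GROUP_LABELS:
        idx = out.index[out["age_group"] == label].to_numpy()
        if len(idx) == 0:
            warnings.warn(f"age group {label} is empty; skipped", stacklevel=2)
            continue
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        quotas = np.array([f * n for f in plan.fractions])
        counts = np.floor(quotas).astype(int)
        rem = quotas - counts
        for _ in range(n - counts.sum()):
            j = int(np.argmax(rem))
            counts[j] += 1
            rem[j] = -1
        start = 0
        for name, c in zip(names, counts):
            out.loc[idx[start : start + c], "split"] = name
            start += c
    return out


def read_png(path: str | os.PathLike, **meta) -> AgedImage:
    """Read a grayscale PNG, min-max scaled per image to [0, 1]."""
    arr = np.asarray(iio.imread(path), dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return AgedImage(pixels=_minmax(arr), **meta)


def read_dicom(path: str | os.PathLike, **meta) -> AgedImage:
    """Read a single-frame grayscale DICOM (16-bit typical), scaled to [0, 1]."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise ValueError("only single-frame grayscale DICOM is supported")
    return AgedImage(pixels=_minmax(arr), **meta)


def _minmax(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)
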