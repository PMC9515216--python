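"""The three attention-concentrated crops: teeth, craniofacial, cervical spine.

Box corners are fixed expressions of the image width W and height H with
100-pixel offsets (for full-resolution ~2144x2304 frames):

    teeth          (0, H/2 - 100)        -> (2W/3 + 100, H)
    craniofacial   (0, 0)                -> (W, H/2 + 100)
    cervical spine (2W/3 - 100, H/2-100) -> (W, H)

Coordinates are (x = column rightward, y = row downward) from the top-left
corner, fractional values floored, boxes half-open [UL, LR).  The printed
geometry applies to right-facing profiles; left-facing images use the
horizontally mirrored boxes.  On frames much smaller than the reference
resolution the 100-pixel offsets scale proportionally.
"""

from __future__ import annotations

import numpy as np

from .core import AgedImage

REGION_NAMES = ("teeth", "craniofacial", "cervical_spine")

#: Reference frame the fixed 100-pixel offsets were defined on.
REF_W, REF_H = 2144, 2304
#: Below this frame size the offsets scale proportionally.
_SMALL_FRAME = 300


def _offsets(w: int, h: int) -> tuple[int, int]:
    if min(w, h) < _SMALL_FRAME:
        return (round(100 * w / REF_W), round(100 * h / REF_H))
    return (100, 100)


def region_box(name: str, w: int, h: int, orientation: str = "right") -> tuple[int, int, int, int]:
    """Half-open pixel box (x0, y0, x1, y1) of a named region.

    Raises on unknown names and on frames too small to carry the offsets.
    """
    ox, oy = _offsets(w, h)
    if w < 16 or h < 16 or w <= 3 * ox // 2 or h <= 2 * oy:
        raise ValueError(f"frame {w}x{h} too small for the region offsets")
    two_thirds = int(np.floor(2 * w / 3))
    half_h = int(np.floor(h / 2))
    if name == "teeth":
        box = (0, half_h - oy, two_thirds + ox, h)
    elif name == "craniofacial":
        box = (0, 0, w, half_h + oy)
    elif name == "cervical_spine":
        box = (two_thirds - ox, half_h - oy, w, h)
    else:
        raise ValueError(f"unknown region {name!r}; expected one of {REGION_NAMES}")
    x0, y0, x1, y1 = box
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w, x1), min(h, y1)
    if orientation == "left":
        x0, x1 = w - x1, w - x0
    elif orientation != "right":
        raise ValueError(f"unknown orientation {orientation!r}")
    return (x0, y0, x1, y1)


def mirror_box(box: tuple[int, int, int, int], w: int) -> tuple[int, int, int, int]:
    """Mirror a half-open box horizontally: x -> W - x with corners swapped."""
    x0, y0, x1, y1 = box
    return (w - x1, y0, w - x0, y1)


def apply_region(image: AgedImage, box: tuple[int, int, int, int], mode: str) -> AgedImage:
    """``select`` crops to the box; ``discard`` zeroes it out in place.

    Discarding keeps the full frame so network input geometry is unchanged
    across conditions.
    """
    x0, y0, x1, y1 = box
    h, w = image.pixels.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"box {box} not inside a {w}x{h} image")
    if mode == "select":
        lm = image.label_map[y0:y1, x0:x1] if image.label_map is not None else None
        return image.with_(pixels=image.pixels[y0:y1, x0:x1], label_map=lm)
    if mode == "discard":
        px = image.pixels.copy()
        px[y0:y1, x0:x1] = 0.0
        return image.with_(pixels=px)
    raise ValueError(f"unknown mode {mode!r}; expected 'select' or 'discard'")


def region_condition(image: AgedImage, mode: str, names: tuple[str, ...]) -> AgedImage:
    """Apply one experimental condition.

    ``select`` with several names keeps the union of their boxes (rest
    zeroed, frame kept); ``discard`` zeroes the named boxes.
    """
    h, w = image.pixels.shape
    boxes = [region_box(n, w, h, image.orientation) for n in names]
    union = np.zeros((h, w), dtype=bool)
    for x0, y0, x1, y1 in boxes:
        union[y0:y1, x0:x1] = True
    px = image.pixels.copy()
    if mode == "select":
        px[~union] = 0.0
    elif mode == "discard":
        px[union] = 0.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return image.with_(pixels=px)


def region_experiment(images, ages, conditions, train_fn, eval_fn):
    """Train/evaluate one model per select/discard condition.

    ``conditions`` is a list of ("select"|"discard", (region names...))
    pairs plus the implicit full-image baseline; ``train_fn(images, ages)``
    returns a fitted model and ``eval_fn(model, images, ages)`` a metrics
    row.  Returns a dict keyed by condition label.
    """
    for mode, names in conditions:
        for n in names:
            if n not in REGION_NAMES:
                raise ValueError(f"condition references unknown region {n!r}")
    results = {}
    model = train_fn(images, ages)
    results["baseline"] = eval_fn(model, images, ages)
    for mode, names in conditions:
        modified = [region_condition(im, mode, names) for im in images]
        model = train_fn(modified, ages)
        results[f"{mode}:{'+'.join(names)}"] = eval_fn(model, modified, ages)
    return results
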