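"""Core in-memory containers shared by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The study age range in decimal years.  Subjects outside this window are
#: flagged during screening and excluded from every downstream stage.
AGE_MIN = 4.0
AGE_MAX = 40.0

#: Screening flags.  Only ``age_out_of_range`` is computed from metadata;
#: the rest are manual annotations carried through from the caller.
QC_FLAGS = frozenset({"age_out_of_range", "incomplete", "restoration", "posture"})


@dataclass
class AgedImage:
    """One grayscale radiograph-like image with its age metadata.

    Attributes
    ----------
    id : str
        Subject identifier, unique within a cohort.
    pixels : ndarray of float, shape (H, W)
        Gray levels scaled to [0, 1].
    age : float
        Decimal age in years, rounded to hundredths.
    orientation : {"right", "left"}
        Which way the profile faces.  Horizontal flips toggle it.
    label_map : ndarray of int, shape (H, W), optional
        Integer instance labels aligned with ``pixels``; 0 is background.
    qc_flags : set of str
        Screening flags from :data:`QC_FLAGS`.
    """

    id: str
    pixels: np.ndarray
    age: float
    orientation: str = "right"
    label_map: np.ndarray | None = None
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D gray array")
        if self.orientation not in ("right", "left"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.label_map is not None:
            self.label_map = np.asarray(self.label_map)
            if self.label_map.shape != self.pixels.shape:
                raise ValueError("label_map shape must match pixels")
        bad = self.qc_flags - QC_FLAGS
        if bad:
            raise ValueError(f"unknown qc flags: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_(self, **kwargs) -> "AgedImage":
        """Return a shallow copy with some fields replaced."""
        return replace(self, **kwargs)
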