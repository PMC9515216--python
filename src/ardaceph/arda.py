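"""ARDA: per-age aggregation of salience maps and its quantification.

The ARDA map of integer age a is the element-wise mean of the normalised
salience maps of all subjects of that age,

    A_a = (1/N_a) sum_n M_{a,n},        a in {4, ..., 40},

with ages binned by completed years.  Ageing-significant regions are the
pixels of A_a at or above the median, 75th or 90th percentile of its own
pixel values; the quantified ARDA of an anatomical instance is the mean of
A_a over the intersection of the instance mask with the significant region
(missing — never zero — when the intersection is empty).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.colors import LinearSegmentedColormap
from scipy.stats import norm

from .core import AgedImage
from .saliency import SalienceMap

LEVELS = ("median", "p75", "p90")
_PERCENTILE = {"median": 50.0, "p75": 75.0, "p90": 90.0}

#: Fixed blue-to-red colormap used for every ARDA rendering.
ARDA_CMAP = LinearSegmentedColormap.from_list(
    "arda", ["blue", "cyan", "yellow", "red"]
)


@dataclass
class ArdaMap:
    values: np.ndarray
    age: int
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("an ARDA map needs at least one contributing subject")


@dataclass
class SignificantRegion:
    mask: np.ndarray
    level: str
    threshold_value: float


def build_arda(maps: list[SalienceMap]) -> list[ArdaMap]:
    """Average normalised salience maps per integer age (completed years)."""
    if not maps:
        return []
    grid = maps[0].values.shape
    sums: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for m in maps:
        if m.values.shape != grid:
            raise ValueError("all salience maps must share one grid")
        a = int(np.floor(m.age))
        if a not in sums:
            sums[a] = np.zeros(grid)
            counts[a] = 0
        sums[a] += m.values
        counts[a] += 1
    return [
        ArdaMap(values=sums[a] / counts[a], age=a, n_subjects=counts[a])
        for a in sorted(sums)
    ]


def significant_region(arda: ArdaMap, level: str) -> SignificantRegion:
    """Threshold an ARDA map at a percentile of its own pixel values.

    The tie rule is inclusive (>=), so a constant map is entirely
    significant at every level.
    """
    if level not in _PERCENTILE:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    thr = float(np.percentile(arda.values, _PERCENTILE[level]))
    return SignificantRegion(mask=arda.values >= thr, level=level, threshold_value=thr)


def quantify_instances(
    arda: ArdaMap,
    region: SignificantRegion,
    labels: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Mean ARDA inside (instance mask ∩ significant region) per instance.

    Returns a tidy frame (age, instance, level, value, n_pixels); an empty
    intersection yields value NaN with n_pixels 0.
    """
    labels = np.asarray(labels)
    if labels.shape != arda.values.shape:
        raise ValueError("label map must be aligned with the ARDA grid")
    rows = []
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        inter = (labels == lbl) & region.mask
        n_pix = int(inter.sum())
        value = float(arda.values[inter].mean()) if n_pix else np.nan
        name = names.get(int(lbl), str(int(lbl))) if names else str(int(lbl))
        rows.append(
            {
                "age": arda.age,
                "instance": name,
                "level": region.level,
                "value": value,
                "n_pixels": n_pix,
            }
        )
    return pd.DataFrame(rows, columns=["age", "instance", "level", "value", "n_pixels"])


def arda_surface(quants: pd.DataFrame, instance_order: list[str] | None = None) -> pd.DataFrame:
    """Tidy age × instance × level table for the surface plots.

    Rows ordered ages ascending, instances in declared order, levels
    median < p75 < p90; missing cells stay missing.
    """
    df = quants.copy()
    order = instance_order or sorted(df["instance"].unique())
    df["instance"] = pd.Categorical(df["instance"], categories=order, ordered=True)
    df["level"] = pd.Categorical(df["level"], categories=LEVELS, ordered=True)
    return df.sort_values(["age", "instance", "level"]).reset_index(drop=True)


def instance_stats(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of per-subject quantified salience per (instance, age).

    ``per_subject`` needs columns instance, age, value (one row per subject
    and instance).
    """
    g = per_subject.groupby(["instance", "age"], observed=True)["value"]
    out = g.agg(mu="mean", sigma=lambda v: v.std(ddof=0)).reset_index()
    return out


def normal_band(mu: float, sigma: float, k_sigma: float = 2.0) -> tuple[float, float, float]:
    """μ ± kσ band with its ideal-normal coverage percentage.

    Coverage is 100·[Φ(k) − Φ(−k)] to two decimals, e.g. 95.45 % at k = 2.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    low = float(mu - k_sigma * sigma)
    high = float(mu + k_sigma * sigma)
    coverage = round(float(100.0 * (norm.cdf(k_sigma) - norm.cdf(-k_sigma))), 2)
    return (low, high, coverage)


def render_arda(arda: ArdaMap, base: AgedImage, alpha: float = 0.5) -> np.ndarray:
    """Blue-to-red colormapped ARDA alpha-blended over the grayscale base.

    Returns an (H, W, 3) float RGB array in [0, 1].  The map is min-max
    scaled for display only; quantification never sees this scaling.
    """
    if arda.values.shape != base.pixels.shape:
        raise ValueError("ARDA map and base image grids differ")
    vals = arda.values
    peak = vals.max()
    disp = vals / peak if peak > 0 else vals
    rgb = ARDA_CMAP(disp)[..., :3]
    gray = np.repeat(base.pixels[..., None], 3, axis=2)
    return (1 - alpha) * gray + alpha * rgb
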