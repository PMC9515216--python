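"""Reference-cohort summary tables.

The default age bins, split ratios and region offsets in this package were
derived from a reference clinical LCR cohort of 20,174 screened radiographs
(ages 4–40).  Its published age-group and frame-size distributions are kept
here so configuration defaults remain traceable and internally consistent;
the images themselves are not part of this package.
"""

from __future__ import annotations

import pandas as pd

#: Age-group distribution of the reference cohort (counts of images).
AGE_DISTRIBUTION = pd.DataFrame(
    [
        ("4-10", 2599, 1822, 393, 384, 1264, 1335),
        ("11-15", 7652, 5354, 1148, 1150, 3072, 4580),
        ("16-20", 4591, 3211, 690, 690, 1713, 2878),
        ("21-25", 3044, 2137, 454, 453, 815, 2229),
        ("26-30", 1452, 1020, 210, 222, 297, 1155),
        ("31-35", 577, 408, 86, 83, 102, 475),
        ("36-40", 259, 190, 37, 32, 39, 220),
    ],
    columns=["age_group", "total", "train", "val", "test", "male", "female"],
)

#: Frame-size distribution of the reference cohort.
IMAGE_SIZE_DISTRIBUTION = pd.DataFrame(
    [
        (1804, 2136, 5338),
        (2136, 2304, 2050),
        (2140, 3044, 4000),
        (2144, 2304, 7179),
        (2148, 2304, 1524),
        (0, 0, 83),  # other sizes
    ],
    columns=["width", "height", "count"],
)


def cohort_totals() -> dict[str, int]:
    """Self-consistency sums over the reference tables."""
    return {
        "total": int(AGE_DISTRIBUTION["total"].sum()),
        "train": int(AGE_DISTRIBUTION["train"].sum()),
        "val": int(AGE_DISTRIBUTION["val"].sum()),
        "test": int(AGE_DISTRIBUTION["test"].sum()),
        "by_size": int(IMAGE_SIZE_DISTRIBUTION["count"].sum()),
    }
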