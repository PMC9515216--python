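"""Age-estimation metric suite.

Per age group and overall: MAE and the standard deviation of the absolute
error, the median signed error (ME.Med), the interquartile range of the
absolute error (IQR), the cumulative score at 5 years (CS-5: percent of
subjects whose absolute error is at most 5 years) and its mean-cumulative
variant MCS-5, taken here as the mean of CS-j over j = 1..5 years.  That
MCS-5 reading is interpretive and isolated in one function so it can be
swapped.

Groups are the seven five-year-ish bins spanning 4–40 years plus the 4–25
and 26–40 super-groups and an overall row.  ``evaluate`` recomputes every
cell with a brute-force per-row loop as a built-in self-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_preprocess import AGE_GROUP_LABELS, age_group

REPORT_GROUPS = (*AGE_GROUP_LABELS, "4-25", "26-40", "All")

_SUPER = {
    "4-25": ("4-10", "11-15", "16-20", "21-25"),
    "26-40": ("26-30", "31-35", "36-40"),
}


def cumulative_score(abs_err: np.ndarray, j: float) -> float:
    """CS-j: percent of subjects with |error| <= j years."""
    return float(100.0 * np.mean(abs_err <= j))


def mcs5(abs_err: np.ndarray) -> float:
    """Mean cumulative score at 5 years: mean of CS-j for j = 1..5.

    Interpretive definition of the "mean cumulative" variant; kept in one
    place deliberately.
    """
    return float(np.mean([cumulative_score(abs_err, j) for j in range(1, 6)]))


def _group_metrics(err: np.ndarray) -> dict[str, float]:
    ae = np.abs(err)
    return {
        "n": int(len(err)),
        "MAE": float(np.mean(ae)),
        "SD": float(np.std(ae)),
        "ME.Med": float(np.median(err)),
        "IQR": float(np.percentile(ae, 75) - np.percentile(ae, 25)),
        "CS-5": cumulative_score(ae, 5),
        "MCS-5": mcs5(ae),
    }


def evaluate(preds: pd.DataFrame) -> pd.DataFrame:
    """Metric table from a prediction set.

    ``preds`` needs columns ``y`` (true age, years) and ``y_pred``; an
    ``age_group`` column is derived from ``y`` when absent.  Returns one
    row per group in :data:`REPORT_GROUPS` (groups with no subjects are
    omitted).  Raises if any age falls outside the seven bins.
    """
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    df = preds.copy()
    if "age_group" not in df.columns:
        df["age_group"] = df["y"].map(age_group)
    unknown = set(df["age_group"]) - set(AGE_GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown age groups: {sorted(unknown)}")
    err = (df["y_pred"] - df["y"]).to_numpy(dtype=float)

    rows = {}
    for g in REPORT_GROUPS:
        if g == "All":
            sel = np.ones(len(df), bool)
        elif g in _SUPER:
            sel = df["age_group"].isin(_SUPER[g]).to_numpy()
        else:
            sel = (df["age_group"] == g).to_numpy()
        if sel.any():
            rows[g] = _group_metrics(err[sel])
    report = pd.DataFrame(rows).T
    report.index.name = "age_group"
    _self_check(df, err, report)
    return report


def _self_check(df: pd.DataFrame, err: np.ndarray, report: pd.DataFrame) -> None:
    """Brute-force recomputation of every cell from the raw rows."""
    for g, row in report.iterrows():
        errs = []
        for i in range(len(df)):
            grp = df["age_group"].iat[i]
            in_g = g == "All" or grp == g or (g in _SUPER and grp in _SUPER[g])
            if in_g:
                errs.append(err[i])
        errs = np.array(errs)
        assert len(errs) == row["n"]
        assert abs(np.mean(np.abs(errs)) - row["MAE"]) < 1e-9
        assert abs(100.0 * sum(abs(e) <= 5 for e in errs) / len(errs) - row["CS-5"]) < 1e-9


def percent_reduction(old: float, new: float) -> float:
    """Percent reduction 100 * (old - new) / old, to two decimals."""
    if old <= 0:
        raise ValueError("old value must be positive")
    return round(100.0 * (old - new) / old, 2)


def prediction_table(ids, y, y_pred, split: str | None = None) -> pd.DataFrame:
    """Assemble the tidy per-subject prediction set."""
    df = pd.DataFrame({"id": ids, "y": np.asarray(y, float), "y_pred": np.asarray(y_pred, float)})
    df["split"] = split if split is not None else ""
    df["age_group"] = df["y"].map(age_group)
    return df
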