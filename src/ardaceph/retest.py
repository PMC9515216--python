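"""ARDA-constrained age estimation with two-pass retest inference.

Age-related change is weak in adults, so a second, attention-constrained
model receives each older subject's own ageing-salience map (from the
frozen baseline) as an extra input channel.  During training, subjects with
true age above the cutoff KA get their salience channel; younger subjects
get a zero channel, so one two-channel network serves both regimes.  At
inference the true age is unknown: the baseline predicts first, and only
when that first-pass prediction exceeds KA (strictly) is the subject
re-estimated by the constrained model with its salience channel — the
second estimate is then final.  There is exactly one retest round.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import evaluate, prediction_table
from .model import CNNAgeRegressor
from .saliency import ageing_salience


def _salience_stack(model: CNNAgeRegressor, X: np.ndarray) -> np.ndarray:
    """Normalised salience channel for every image in (N, H, W)."""
    return np.stack(
        [ageing_salience(model, X[i], normalize=True).values for i in range(len(X))]
    )


class RetestAgeEstimator(RegressorMixin, BaseEstimator):
    """Baseline + ARDA-constrained model pair with retest inference.

    Parameters
    ----------
    ka : float, default 25
        Age cutoff in years (4 <= ka <= 40).  Above it the salience channel
        is attached in training, and a first-pass prediction above it
        triggers the retest.
    baseline : CNNAgeRegressor, optional
        A fitted baseline to reuse; one is trained when omitted.
    **train_params
        Forwarded to both underlying :class:`CNNAgeRegressor` instances.

    Attributes
    ----------
    baseline_ : CNNAgeRegressor
        The frozen single-channel model that also generates salience.
    constrained_ : CNNAgeRegressor
        The two-channel model trained with the salience constraint.
    """

    def __init__(self, ka: float = 25.0, baseline: CNNAgeRegressor | None = None,
                 epochs: int = 30, batch_size: int = 64, lr: float = 0.01,
                 channels: tuple[int, ...] = (8, 16, 16), seed: int = 0):
        self.ka = ka
        self.baseline = baseline
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.channels = channels
        self.seed = seed

    def _check_ka(self) -> None:
        if not 4.0 <= self.ka <= 40.0:
            raise ValueError("ka must lie in [4, 40] years")

    def fit(self, X, y):
        self._check_ka()
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if self.baseline is not None:
            check_is_fitted(self.baseline, "net_")
            self.baseline_ = self.baseline
        else:
            self.baseline_ = CNNAgeRegressor(
                in_channels=1, channels=self.channels, epochs=self.epochs,
                batch_size=self.batch_size, lr=self.lr, seed=self.seed,
            ).fit(X, y)
        sal = _salience_stack(self.baseline_, X)
        sal[y <= self.ka] = 0.0  # younger subjects: zero channel
        X2 = np.stack([X, sal], axis=1)
        self.constrained_ = CNNAgeRegressor(
            in_channels=2, channels=self.channels, epochs=self.epochs,
            batch_size=self.batch_size, lr=self.lr, seed=self.seed + 1,
        ).fit(X2, y)
        return self

    def predict_trace(self, X, ids=None) -> pd.DataFrame:
        """Two-pass retest inference with a full audit trail.

        Returns one row per subject: first-pass prediction ``y1``, the
        ``retested`` flag (true iff ``y1 > ka`` strictly), the second-pass
        ``y2`` (NaN when not retested) and the ``final`` estimate.
        """
        check_is_fitted(self, "constrained_")
        X = np.asarray(X, dtype=np.float64)
        if ids is None:
            ids = [str(i) for i in range(len(X))]
        y1 = self.baseline_.predict(X)
        retested = y1 > self.ka
        y2 = np.full(len(X), np.nan)
        if retested.any():
            sal = _salience_stack(self.baseline_, X[retested])
            X2 = np.stack([X[retested], sal], axis=1)
            y2[retested] = self.constrained_.predict(X2)
        final = np.where(retested, y2, y1)
        return pd.DataFrame(
            {"id": ids, "y1": y1, "retested": retested, "y2": y2, "final": final}
        )

    def predict(self, X) -> np.ndarray:
        return self.predict_trace(X)["final"].to_numpy()

    def predict_constrained(self, X) -> np.ndarray:
        """Always-constrained inference: every subject gets its salience
        channel (no retest gate)."""
        check_is_fitted(self, "constrained_")
        X = np.asarray(X, dtype=np.float64)
        sal = _salience_stack(self.baseline_, X)
        return self.constrained_.predict(np.stack([X, sal], axis=1))


def train_constrained(X, y, baseline: CNNAgeRegressor, ka: float = 25.0,
                      **train_params) -> RetestAgeEstimator:
    """Train the constrained model on top of a frozen fitted baseline."""
    est = RetestAgeEstimator(ka=ka, baseline=baseline, **train_params)
    return est.fit(X, y)


def retest_predict(est: RetestAgeEstimator, X, ids=None) -> pd.DataFrame:
    """Module-level alias for :meth:`RetestAgeEstimator.predict_trace`."""
    return est.predict_trace(X, ids=ids)


def audit_trace(trace: pd.DataFrame, ka: float) -> bool:
    """Check the retest contract on every row.

    retested <=> y1 > ka; final equals y2 when retested else y1.
    """
    gate_ok = (trace["retested"] == (trace["y1"] > ka)).all()
    final_ok = np.allclose(
        trace["final"], np.where(trace["retested"], trace["y2"], trace["y1"])
    )
    second_ok = trace.loc[~trace["retested"], "y2"].isna().all()
    return bool(gate_ok and final_ok and second_ok)


def compare_conditions(est: RetestAgeEstimator, X, y, ids=None) -> dict[str, pd.DataFrame]:
    """Metric reports for baseline, always-constrained and retest inference
    on the identical test subjects."""
    check_is_fitted(est, "constrained_")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if ids is None:
        ids = [str(i) for i in range(len(X))]
    preds = {
        "baseline": est.baseline_.predict(X),
        "constrained": est.predict_constrained(X),
        "retest": est.predict(X),
    }
    return {
        name: evaluate(prediction_table(ids, y, p, split="test"))
        for name, p in preds.items()
    }
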