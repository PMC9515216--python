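"""The CNN age regressor, as a scikit-learn estimator.

Training minimises the mean absolute error (L1 loss)

    L = (1/N) sum_n |y'_n - y_n|

with Adam and a cosine learning-rate decay; the model with the best
validation loss is kept.  Everything — initialisation, batch order,
train/val carve-out — is a pure function of ``seed``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .nn import Adam, TinyCNN


def l1_loss(pred, true) -> float:
    """Mean absolute error in years: (1/N) sum |y' - y|."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("pred and true must have the same length")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(pred - true)))


def _as_nchw(X: np.ndarray, in_channels: int) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 3:
        X = X[:, None]
    if X.ndim != 4:
        raise ValueError("X must be (N, H, W) or (N, C, H, W)")
    if X.shape[1] != in_channels:
        raise ValueError(f"expected {in_channels} input channel(s), got {X.shape[1]}")
    return X


class CNNAgeRegressor(RegressorMixin, BaseEstimator):
    """CNN age regression on grayscale image stacks.

    Parameters
    ----------
    in_channels : int, default 1
        2 when a salience channel is concatenated to the image.
    channels : tuple of int, default (8, 16, 16)
        Conv-stage widths of the tiny backbone; the last is the number of
        attention feature maps.
    epochs, batch_size, lr : training schedule (Adam, cosine decay).
    val_fraction : float
        Fraction of the training set held out for best-epoch selection.
    fit_intercept : bool, default False
        When False the output unit has no trainable intercept, so the
        predicted age decomposes entirely into spatial feature
        contributions.  This keeps the attention analysis identifiable: a
        free intercept lets the optimiser book the age-constant part of
        the prediction either on the intercept or on age-invariant image
        structure, and only the latter pollutes the salience maps.
    seed : int
        Determines initialisation, the val carve-out and batch order.

    Attributes
    ----------
    net_ : TinyCNN
        The fitted network (best-validation weights).
    history_ : DataFrame
        Per-epoch train and validation L1 loss.
    best_epoch_ : int
    """

    def __init__(
        self,
        in_channels: int = 1,
        channels: tuple[int, ...] = (8, 16, 16),
        epochs: int = 30,
        batch_size: int = 64,
        lr: float = 0.01,
        val_fraction: float = 0.15,
        fit_intercept: bool = False,
        seed: int = 0,
        verbose: int = 0,
    ):
        self.in_channels = in_channels
        self.channels = channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.val_fraction = val_fraction
        self.fit_intercept = fit_intercept
        self.seed = seed
        self.verbose = verbose

    def fit(self, X, y):
        X = _as_nchw(X, self.in_channels)
        y = np.asarray(y, dtype=np.float64).ravel()
        if len(X) != len(y) or len(y) == 0:
            raise ValueError("X and y must be nonempty and the same length")
        rng = np.random.default_rng(self.seed)
        n = len(y)
        n_val = int(round(self.val_fraction * n)) if n > 1 else 0
        order = rng.permutation(n)
        val_idx, train_idx = order[:n_val], order[n_val:]
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]

        net = TinyCNN(self.in_channels, tuple(self.channels), seed=int(rng.integers(2**31)))
        if self.fit_intercept:
            # Start the intercept at the mean training age: with L1 + Adam
            # the update magnitude is bounded by the learning rate, so
            # starting the output at 0 would waste most of a short schedule
            # drifting to the cohort mean.
            net.fc.b[:] = yt.mean()
        opt = Adam(net.params(), lr=self.lr)
        best_val = np.inf
        best_weights = net.get_weights()
        best_epoch = 0
        history = []
        for epoch in range(self.epochs):
            opt.lr = self.lr * 0.5 * (1 + np.cos(np.pi * epoch / max(1, self.epochs)))
            perm = rng.permutation(len(yt))
            losses = []
            for start in range(0, len(yt), self.batch_size):
                idx = perm[start : start + self.batch_size]
                yb = yt[idx]
                pred = net.forward(Xt[idx], train=True)
                loss = np.mean(np.abs(pred - yb))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss!r}"
                    )
                net.backward(np.sign(pred - yb) / len(yb))
                grads = net.grads()
                if not self.fit_intercept:
                    grads[-1][:] = 0.0  # intercept stays at 0
                opt.step(grads)
                losses.append(loss)
            train_loss = float(np.mean(losses))
            val_loss = l1_loss(self._predict_net(net, Xv), yv) if n_val else train_loss
            history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best_weights = net.get_weights()
                best_epoch = epoch
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.3f}  val {val_loss:.3f}")
        net.set_weights(best_weights)
        self.net_ = net
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best_epoch
        self.n_features_in_ = X.shape[1] * X.shape[2] * X.shape[3]
        return self

    @staticmethod
    def _predict_net(net: TinyCNN, X: np.ndarray, batch: int = 256) -> np.ndarray:
        if len(X) == 0:
            return np.empty(0)
        return np.concatenate([net.predict(X[i : i + batch]) for i in range(0, len(X), batch)])

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self._predict_net(self.net_, _as_nchw(X, self.in_channels))

    def feature_maps(self, X) -> np.ndarray:
        """Post-ReLU attention feature maps, shape (N, K, h, w)."""
        check_is_fitted(self, "net_")
        return self.net_.features(_as_nchw(X, self.in_channels))

    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        self.net_.save(path)

    def load_weights(self, path) -> "CNNAgeRegressor":
        """Load a checkpoint written by :meth:`save` into this estimator."""
        self.net_ = TinyCNN.load(path)
        self.n_features_in_ = None
        return self
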