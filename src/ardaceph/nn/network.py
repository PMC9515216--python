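"""The tiny CNN age regressor.

Three strided conv/ReLU stages end in a K-channel spatial feature map (the
attention target layer), followed by global average pooling and a single
linear output unit that predicts decimal age.  The post-ReLU feature map of
the last conv stage is the layer the Grad-CAM analysis attaches to, so the
network exposes both the map itself and the analytic gradient of the output
with respect to it.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, GlobalAvgPool, Linear, ReLU


class TinyCNN:
    """Small strided CNN: (in_channels, H, W) -> scalar age.

    Parameters
    ----------
    in_channels : int
        1 for plain images, 2 when a salience channel is concatenated.
    channels : tuple of int
        Output channels of the three conv stages; the last entry is the
        number K of attention feature maps.
    seed : int
        Fully determines the He-normal initialisation.
    """

    def __init__(self, in_channels: int = 1, channels: tuple[int, ...] = (8, 16, 16), seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.seed = seed
        self.convs = [
            Conv2d(in_channels, c1, 3, stride=2, padding=1, rng=rng),
            Conv2d(c1, c2, 3, stride=2, padding=1, rng=rng),
            Conv2d(c2, c3, 3, stride=1, padding=1, rng=rng),
        ]
        self.relus = [ReLU(), ReLU(), ReLU()]
        self.pool = GlobalAvgPool()
        self.fc = Linear(c3, 1, rng=rng)

    # ---- forward -----------------------------------------------------

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Post-ReLU feature maps of the last conv stage, shape (N, K, h, w)."""
        h = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(h, train=train), train=train)
        return h

    def head(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """Pool + linear head: (N, K, h, w) -> (N,) predicted ages."""
        return self.fc.forward(self.pool.forward(feats, train=train), train=train)[:, 0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.head(self.features(x, train=train), train=train)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)

    # ---- backward ----------------------------------------------------

    def backward(self, dy: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output), filling every layer's grads."""
        g = self.fc.backward(dy[:, None])
        g = self.pool.backward(g)
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            g = relu.backward(g)
            g = conv.backward(g)

    def feature_gradient(self, feats: np.ndarray) -> np.ndarray:
        """d(output)/d(feature map), same shape as ``feats``.

        With a mean-pool + linear head this is v_k / Z per channel, but it
        is computed by backpropagating through the head so it stays correct
        if the head changes.
        """
        n, k, h, w = feats.shape
        self.pool.forward(feats, train=True)
        self.fc.forward(np.zeros((n, k)), train=True)  # populate shapes only
        g = self.fc.backward(np.ones((n, 1)))
        return self.pool.backward(g)

    # ---- parameters --------------------------------------------------

    def layers(self):
        return [*self.convs, self.fc]

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers() for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers() for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # ---- checkpointing ----------------------------------------------

    def save(self, path) -> None:
        meta = np.array([self.in_channels, *self.channels, self.seed])
        np.savez(path, meta=meta, *self.params())

    @classmethod
    def load(cls, path) -> "TinyCNN":
        with np.load(path) as data:
            meta = data["meta"]
            net = cls(in_channels=int(meta[0]), channels=tuple(int(c) for c in meta[1:-1]), seed=int(meta[-1]))
            weights = [data[f"arr_{i}"] for i in range(len(net.params()))]
        net.set_weights(weights)
        return net
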