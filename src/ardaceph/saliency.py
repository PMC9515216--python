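"""Grad-CAM ageing-salience maps from the trained age regressor.

For a regression network the backpropagated scalar is the predicted age
itself.  The weight of the k-th feature map is the global average of the
output's gradient over that map,

    w_k = (1/Z) sum_ij d(y_hat) / d(F_kij),

and the salience map is the rectified weighted sum of the feature maps,

    M = ReLU(sum_k w_k F_k),

bilinearly upsampled to the preprocessed image grid and (by default)
min-max normalised per subject so maps are comparable across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .model import CNNAgeRegressor


@dataclass
class GradCamContext:
    """Feature maps and gradients at the attention target layer for one
    subject."""

    features: np.ndarray  # (K, h, w)
    grad: np.ndarray      # (K, h, w) — d(y_hat)/dF
    y_hat: float

    def __post_init__(self) -> None:
        if self.features.shape != self.grad.shape or self.features.ndim != 3:
            raise ValueError("features and grad must share shape (K, h, w)")

    @property
    def z(self) -> int:
        return self.features.shape[1] * self.features.shape[2]


@dataclass
class SalienceMap:
    values: np.ndarray
    subject_id: str = ""
    age: float = np.nan
    normalized: bool = False

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("salience values must be non-negative")


def gradcam_context(model: CNNAgeRegressor, image: np.ndarray) -> GradCamContext:
    """Forward + backward pass for one image (H, W) or (C, H, W)."""
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    feats = model.net_.features(x[None])
    y_hat = float(model.net_.head(feats)[0])
    grad = model.net_.feature_gradient(feats)
    return GradCamContext(features=feats[0], grad=grad[0], y_hat=y_hat)


def channel_weights(ctx: GradCamContext) -> np.ndarray:
    """Per-channel weights: the gradient globally averaged over each map."""
    if ctx.grad is None:
        raise RuntimeError("gradients not populated")
    return ctx.grad.mean(axis=(1, 2))


def salience_map(ctx: GradCamContext, weights: np.ndarray) -> SalienceMap:
    """Rectified weighted sum of the feature maps, at feature resolution."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (ctx.features.shape[0],):
        raise ValueError("need one weight per feature map")
    m = np.maximum(np.tensordot(weights, ctx.features, axes=1), 0.0)
    return SalienceMap(values=m)


def to_image_grid(
    smap: SalienceMap, target: tuple[int, int], normalize: bool = True
) -> SalienceMap:
    """Bilinear upsampling to the image grid, with optional min-max scaling.

    Corner-aligned bilinear interpolation; an identically-zero map stays
    zero under normalisation.
    """
    h, w = smap.values.shape
    th, tw = target
    if th < h or tw < w:
        raise ValueError("target grid must be at least the source size")
    rows = np.linspace(0, h - 1, th)
    cols = np.linspace(0, w - 1, tw)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    vals = ndimage.map_coordinates(smap.values, [rr, cc], order=1, mode="nearest")
    if normalize:
        peak = vals.max()
        if peak > 0:
            vals = vals / peak
    return SalienceMap(
        values=vals, subject_id=smap.subject_id, age=smap.age, normalized=normalize
    )


def ageing_salience(
    model: CNNAgeRegressor,
    image: np.ndarray,
    subject_id: str = "",
    age: float = np.nan,
    target: tuple[int, int] | None = None,
    normalize: bool = True,
) -> SalienceMap:
    """Full Grad-CAM pipeline for one subject.

    ``target`` defaults to the input image grid.
    """
    img = np.asarray(image, dtype=np.float64)
    grid = target or (img.shape[-2], img.shape[-1])
    ctx = gradcam_context(model, img)
    raw = salience_map(ctx, channel_weights(ctx))
    raw.subject_id, raw.age = subject_id, age
    return to_image_grid(raw, grid, normalize=normalize)


def cohort_salience(
    model: CNNAgeRegressor,
    images: np.ndarray,
    ids,
    ages,
    normalize: bool = True,
) -> list[SalienceMap]:
    """Salience maps for a stack of images (N, H, W) or (N, C, H, W)."""
    return [
        ageing_salience(model, images[i], subject_id=str(ids[i]), age=float(ages[i]),
                        normalize=normalize)
        for i in range(len(images))
    ]


class SalienceEnsemble:
    """Grad-CAM salience averaged over independently initialised extractors.

    A single under-constrained regressor can book part of its prediction on
    arbitrary image structure, which shows up as initialisation-dependent
    salience.  Averaging each subject's normalised map over a few
    independently seeded extractors cancels that training noise — the same
    variance-reduction idea the per-age cohort averaging applies across
    subjects — and leaves the attention the task itself determines.

    Parameters
    ----------
    n_members : int, default 3
        Number of extractors; member i trains with ``seed + i``.
    **model_params
        Forwarded to every underlying :class:`CNNAgeRegressor`.

    Attributes
    ----------
    members_ : list of CNNAgeRegressor
        The fitted extractors; ``members_[0]`` is the primary model used
        wherever a single network is required (e.g. retest inference).
    """

    def __init__(self, n_members: int = 3, seed: int = 0, **model_params):
        self.n_members = n_members
        self.seed = seed
        self.model_params = model_params

    def fit(self, X, y) -> "SalienceEnsemble":
        self.members_ = [
            CNNAgeRegressor(seed=self.seed + i, **self.model_params).fit(X, y)
            for i in range(self.n_members)
        ]
        return self

    @property
    def primary_(self) -> CNNAgeRegressor:
        return self.members_[0]

    def predict(self, X) -> np.ndarray:
        """Ensemble-mean age prediction."""
        return np.mean([m.predict(X) for m in self.members_], axis=0)

    def cohort_salience(self, images, ids, ages) -> list[SalienceMap]:
        """Per-subject normalised salience, averaged across members."""
        per_member = [cohort_salience(m, images, ids, ages) for m in self.members_]
        out = []
        for i in range(len(images)):
            vals = np.mean([pm[i].values for pm in per_member], axis=0)
            out.append(SalienceMap(values=vals, subject_id=str(ids[i]),
                                   age=float(ages[i]), normalized=True))
        return out
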