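"""Perceptual distance backends (weighted deep-feature comparison).

The perceptual distance between two images is computed LPIPS-style: extract
feature stacks at one or more layers, unit-normalize each spatial position's
channel vector, weight channels, and average the squared differences over
spatial positions, summing over layers:

    D(x, y) = sum_l  (1 / (H_l W_l)) * sum_{h,w} || w_l ⊙ (x̂_l - ŷ_l) ||²

The formula is backend-parametric. :class:`RandomConvPerceptual` realizes it
with a fixed-seed random convolutional feature extractor, which requires no
pretrained weights and runs anywhere; random projections preserve enough
image structure to drive inversion at desk scale. :class:`PixelPerceptual`
is the degenerate identity-feature backend whose distance reduces exactly to
the mean squared pixel difference — useful as an oracle.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .imaging import ImageGrid

__all__ = ["PerceptualBackend", "RandomConvPerceptual", "PixelPerceptual",
           "image_to_chw"]

_EPS = 1e-10


def image_to_chw(img: ImageGrid | np.ndarray) -> np.ndarray:
    """H×W×C ImageGrid/array -> (C, H, W) float array."""
    px = img.pixels if isinstance(img, ImageGrid) else np.asarray(img)
    if px.ndim == 2:
        px = px[:, :, None]
    return np.ascontiguousarray(np.transpose(px, (2, 0, 1)).astype(np.float64))


class PerceptualBackend:
    """Contract: scalar distance plus an optional per-position map."""

    def distance(self, x, y) -> float:
        xt, yt = Tensor(image_to_chw(x)), Tensor(image_to_chw(y))
        return float(self.distance_t(xt, yt).data)

    def distance_t(self, x: Tensor, y: Tensor) -> Tensor:
        """Differentiable distance on (C, H, W) Tensors."""
        raise NotImplementedError

    def spatial_map(self, x, y) -> np.ndarray:
        """Per-position distance contributions, upsampled to image size."""
        raise NotImplementedError


class _FeaturePerceptual(PerceptualBackend):
    """Shared machinery: feature layers -> normalized weighted differences."""

    #: whether channel vectors are unit-normalized before weighting
    normalize: bool = True

    def features(self, x: Tensor) -> list[Tensor]:
        raise NotImplementedError

    def layer_weights(self) -> list[np.ndarray]:
        """One (C_l,) nonnegative weight vector per feature layer."""
        raise NotImplementedError

    def _normalized(self, f: Tensor) -> Tensor:
        if not self.normalize:
            return f
        norm = (f.square().sum(axis=0, keepdims=True) + _EPS).sqrt()
        return f / norm

    def _layer_maps(self, x: Tensor, y: Tensor) -> list[Tensor]:
        maps = []
        for f_x, f_y, w in zip(self.features(x), self.features(y),
                               self.layer_weights()):
            d = self._normalized(f_x) - self._normalized(f_y)
            wd = Tensor(np.asarray(w)[:, None, None]) * d
            maps.append(wd.square().sum(axis=0))  # (H_l, W_l)
        return maps

    def distance_t(self, x: Tensor, y: Tensor) -> Tensor:
        if x.data.shape != y.data.shape:
            raise ValueError(f"shape mismatch {x.data.shape} vs {y.data.shape}")
        total = None
        for m in self._layer_maps(x, y):
            term = m.mean()
            total = term if total is None else total + term
        return total

    def spatial_map(self, x, y) -> np.ndarray:
        xc, yc = image_to_chw(x), image_to_chw(y)
        if xc.shape != yc.shape:
            raise ValueError(f"shape mismatch {xc.shape} vs {yc.shape}")
        H, W = xc.shape[1:]
        out = np.zeros((H, W))
        for m in self._layer_maps(Tensor(xc), Tensor(yc)):
            h, w = m.data.shape
            if H % h == 0 and W % w == 0:
                # exact integer nearest upsampling keeps the spatial mean
                out += np.kron(m.data, np.ones((H // h, W // w)))
            else:
                from skimage.transform import resize
                out += resize(m.data, (H, W), order=0, anti_aliasing=False)
        return out


class RandomConvPerceptual(_FeaturePerceptual):
    """Fixed-seed random-convolution feature extractor (no downloads).

    Two 3×3 conv + leaky-ReLU stages with 2× average pooling between them
    give features at full and half resolution; channel weights are fixed
    positive draws. Deterministic for a given seed.
    """

    def __init__(self, seed: int = 0, channels: int = 8, in_channels: int = 3):
        rng = np.random.default_rng(seed)
        C = channels
        self.w1 = rng.standard_normal((C, in_channels, 3, 3)) / np.sqrt(
            9 * in_channels)
        self.b1 = np.zeros(C)
        self.w2 = rng.standard_normal((C, C, 3, 3)) / np.sqrt(9 * C)
        self.b2 = np.zeros(C)
        self._lw = [rng.uniform(0.5, 1.5, C), rng.uniform(0.5, 1.5, C)]

    def features(self, x: Tensor) -> list[Tensor]:
        f1 = x.conv2d(Tensor(self.w1), Tensor(self.b1)).leaky_relu()
        f2 = f1.avg_pool2().conv2d(Tensor(self.w2), Tensor(self.b2)).leaky_relu()
        return [f1, f2]

    def layer_weights(self) -> list[np.ndarray]:
        return self._lw


class PixelPerceptual(_FeaturePerceptual):
    """Identity features, no normalization: distance == mean squared diff."""

    normalize = False

    def __init__(self, in_channels: int = 3):
        self.in_channels = in_channels

    def features(self, x: Tensor) -> list[Tensor]:
        return [x]

    def layer_weights(self) -> list[np.ndarray]:
        # 1/sqrt(C) weights make the channel-sum an elementwise mean
        return [np.full(self.in_channels, 1.0 / np.sqrt(self.in_channels))]
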