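"""Differentiable-generator contract and a CPU-scale toy synthesizer.

The appraisal pipeline only requires a generator ``G`` that (i) maps a latent
vector plus a set of per-resolution noise maps to an image, (ii) is
deterministic given its weights, and (iii) exposes gradients with respect to
latent, noise and weights. Production use targets a pretrained StyleGAN2
generator through this same contract (latent dimension 512, 18 noise maps at
resolutions 1024 down to 8); the test and acceptance path uses
:class:`ToyGenerator`, a small fixed-weight convolutional synthesizer that is
constructed (not trained) from a seed. Inversion only needs a differentiable,
expressive map, so random weights suffice at desk scale.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .imaging import ImageGrid

__all__ = ["GeneratorSpec", "ToyGenerator", "mean_latent", "init_noise",
           "STYLEGAN2_NOISE_PROFILE"]

# StyleGAN2-class profile: 18 noise maps at square resolutions from 1024 down
# to 8. The pipeline consumes only this (count, resolution) signature; the
# backend adapter owns the exact layer wiring.
STYLEGAN2_NOISE_PROFILE = tuple(
    [1024, 512, 512, 256, 256, 128, 128, 64, 64, 32, 32, 16, 16, 8, 8, 8, 8, 8]
)


class GeneratorSpec:
    """Contract for a differentiable image synthesizer.

    Attributes
    ----------
    latent_dim : int
        Dimension of the intermediate latent vector ``w``.
    noise_profile : tuple[int, ...]
        Ordered square resolutions of the per-layer noise maps.
    output_side : int
        Side length of the synthesized square RGB image.
    """

    latent_dim: int
    noise_profile: tuple[int, ...]
    output_side: int

    def map_latent(self, z: np.ndarray) -> np.ndarray:
        """Mapping-network transform z -> w."""
        raise NotImplementedError

    def synthesize(self, latent: np.ndarray, noise_maps: list[np.ndarray],
                   weights: dict | None = None) -> ImageGrid:
        """Render an image from (latent, noise) with the given weights."""
        raise NotImplementedError

    def synthesize_t(self, latent: Tensor, noise_maps: list[Tensor],
                     weights: dict[str, Tensor]) -> Tensor:
        """Differentiable synthesis returning a (3, S, S) Tensor in [0, 1]."""
        raise NotImplementedError

    def get_weights(self) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        raise NotImplementedError

    def copy(self) -> "GeneratorSpec":
        return copy.deepcopy(self)


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) / np.sqrt(fan_in)


class ToyGenerator(GeneratorSpec):
    """Small fixed-weight convolutional generator for desk-scale runs.

    A latent vector is projected to an 8×8 feature map and refined through
    four conv blocks at resolutions 8, 16, 32, 64, each injecting one noise
    map scaled by a learned per-layer gain, with a final sigmoid to-RGB
    head. The low capacity and small noise gains make its outputs smooth —
    it can approximate a smooth face well but not a sharp localized anomaly,
    which is exactly the behaviour the normalization step relies on.

    Identical seeds give bit-identical weights.
    """

    BLOCK_RES = (8, 16, 32, 64)

    def __init__(self, seed: int = 0, latent_dim: int = 16,
                 channels: int = 16, output_side: int = 64,
                 mapping: str = "linear", noise_gain: float = 0.05):
        if output_side != 64:
            raise ValueError("ToyGenerator is fixed at 64-px output")
        self.latent_dim = latent_dim
        self.channels = channels
        self.output_side = output_side
        self.noise_profile = (64, 32, 16, 8)
        self.seed = seed
        rng = np.random.default_rng(seed)
        C = channels
        self._mapping_kind = mapping
        # mapping network: fixed (non-adapted) linear map, norm-preserving
        A = rng.standard_normal((latent_dim, latent_dim)) / np.sqrt(latent_dim)
        self._map_matrix = A
        w: dict[str, np.ndarray] = {}
        w["fc_w"] = _he(rng, (C * 8 * 8, latent_dim), latent_dim)
        w["fc_b"] = np.zeros(C * 8 * 8)
        for res in self.BLOCK_RES:
            w[f"conv{res}_w"] = _he(rng, (C, C, 3, 3), 9 * C) * np.sqrt(2.0)
            w[f"conv{res}_b"] = np.zeros(C)
            w[f"noise{res}_gain"] = np.array(noise_gain)
        w["rgb_w"] = _he(rng, (3, C, 3, 3), 9 * C)
        w["rgb_b"] = np.zeros(3)
        self._weights = w

    # -- weights -----------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self._weights.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        if set(weights) != set(self._weights):
            raise ValueError("weight keys do not match generator profile")
        self._weights = {k: np.asarray(v, dtype=np.float64).copy()
                         for k, v in weights.items()}

    def save_weights(self, path) -> None:
        np.savez(path, **self._weights)

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights({k: data[k] for k in data.files})

    # -- synthesis ---------------------------------------------------------

    def map_latent(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float64)
        if self._mapping_kind == "identity":
            return z.copy()
        return z @ self._map_matrix.T

    def synthesize_t(self, latent: Tensor, noise_maps: list[Tensor],
                     weights: dict[str, Tensor]) -> Tensor:
        if latent.data.shape != (self.latent_dim,):
            raise ValueError(
                f"latent shape {latent.data.shape} != ({self.latent_dim},)")
        if len(noise_maps) != len(self.noise_profile):
            raise ValueError("noise map count does not match profile")
        by_res = {n.data.shape[0]: n for n in noise_maps}
        C = self.channels
        x = weights["fc_w"].matvec(latent) + weights["fc_b"]
        x = x.reshape(C, 8, 8).leaky_relu()
        for res in self.BLOCK_RES:
            if res > 8:
                x = x.upsample2()
            x = x.conv2d(weights[f"conv{res}_w"], weights[f"conv{res}_b"])
            x = x + weights[f"noise{res}_gain"] * by_res[res]
            x = x.leaky_relu()
        img = x.conv2d(weights["rgb_w"], weights["rgb_b"]).sigmoid()
        return img

    def synthesize(self, latent: np.ndarray, noise_maps: list[np.ndarray],
                   weights: dict | None = None) -> ImageGrid:
        w = weights if weights is not None else self._weights
        wt = {k: Tensor(v) for k, v in w.items()}
        out = self.synthesize_t(Tensor(np.asarray(latent, dtype=np.float64)),
                                [Tensor(np.asarray(n)) for n in noise_maps],
                                wt)
        # (3, S, S) -> H×W×C unit-range image
        return ImageGrid(np.transpose(out.data, (1, 2, 0)),
                         range_tag="unit", colorspace="RGB")

    def weight_tensors(self, weights: dict[str, np.ndarray] | None = None,
                       requires_grad: bool = False) -> dict[str, Tensor]:
        src = weights if weights is not None else self.get_weights()
        return {k: Tensor(v.copy(), requires_grad=requires_grad)
                for k, v in src.items()}


def mean_latent(gen: GeneratorSpec, n_samples: int = 10_000,
                seed: int = 0) -> np.ndarray:
    """Mean intermediate latent μ over mapped standard-normal draws.

    The production default of 10,000 samples matches the initialization used
    for latent optimization against the pretrained generator.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, gen.latent_dim))
    w = gen.map_latent(z)
    return w.mean(axis=0)


def init_noise(gen: GeneratorSpec, seed: int = 0) -> list[np.ndarray]:
    """One standard-normal map per entry of the generator's noise profile."""
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((r, r)) for r in gen.noise_profile]
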