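"""Latent inversion: project a face onto the generator's latent space.

Starting from the mean intermediate latent μ and freshly drawn noise maps,
the inverter minimizes

    L = D_perc(x_org, G(w, n)) + α · R(n)

by adaptive-moment gradient steps on the latent ``w`` and every noise map.
``R`` is the noise-randomness regularizer: for each noise map and each level
of its 2×2-mean-pooled pyramid (down to 8×8), the squared normalized lag-1
autocorrelations in the horizontal and vertical directions. Penalizing these
keeps signal from leaking into the noise maps — they must stay random — while
still letting the optimizer use them to absorb fine texture.

α defaults to 1e5 and the production iteration budget is 450; both are
config. The learning rate follows the standard projector recipe: linear
ramp-up over the first 5% of steps, cosine ramp-down over the last 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .generators import GeneratorSpec, init_noise, mean_latent
from .imaging import ImageGrid
from .perceptual import PerceptualBackend, image_to_chw

__all__ = ["InversionConfig", "LatentState", "noise_regularizer",
           "noise_regularizer_t", "invert"]


class DivergenceError(RuntimeError):
    """Raised when the optimization loss becomes non-finite."""


@dataclass
class InversionConfig:
    """Knobs of the latent-optimization loop (defaults are production scale)."""

    iterations: int = 450
    alpha: float = 1e5
    lr: float = 0.05
    mean_latent_samples: int = 10_000
    seed: int = 0
    ramp_up_frac: float = 0.05
    ramp_down_frac: float = 0.25
    early_stop_window: int = 25
    early_stop_delta: float = 1e-5


@dataclass
class LatentState:
    """Latent vector + noise maps being optimized, with the loss history."""

    w: np.ndarray
    noise_maps: list[np.ndarray]
    step: int = 0
    loss_trace: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.loss_trace) != self.step:
            raise ValueError("loss_trace length must equal step count")

    @property
    def image_losses(self) -> np.ndarray:
        return np.array([t[0] for t in self.loss_trace])


def _pyramid_t(n: Tensor, min_side: int = 8) -> list[Tensor]:
    levels = [n]
    while levels[-1].data.shape[0] > min_side:
        levels.append(levels[-1].avg_pool2())
    return levels


def _lag1_terms_t(level: Tensor) -> Tensor:
    r = level.data.shape[0]
    inv_r2 = 1.0 / (r * r)
    horiz = (level[:, 1:] * level[:, :-1]).sum() * inv_r2
    vert = (level[1:, :] * level[:-1, :]).sum() * inv_r2
    return horiz.square() + vert.square()


def noise_regularizer_t(noise_maps: list[Tensor]) -> Tensor:
    """Differentiable randomness penalty over all maps and pyramid levels."""
    total = None
    for n in noise_maps:
        for level in _pyramid_t(n):
            term = _lag1_terms_t(level)
            total = term if total is None else total + term
    return total


def noise_regularizer(noise_maps: list[np.ndarray]) -> float:
    """Squared normalized lag-1 autocorrelation summed over pyramid levels.

    For a map of side r the horizontal term is
    ``((1/r²) Σ n(x,y) n(x−1,y))²`` with clamped boundaries (out-of-range
    neighbors skipped); the vertical term is analogous. Each map contributes
    one pair per level of its 2×2 mean-pool pyramid, down to 8×8.
    """
    return float(noise_regularizer_t([Tensor(np.asarray(n, dtype=np.float64))
                                      for n in noise_maps]).data)


def _lr_schedule(t: int, total: int, cfg: InversionConfig) -> float:
    if total <= 1:
        return cfg.lr
    frac = t / total
    ramp = min(1.0, frac / max(cfg.ramp_up_frac, 1e-9))
    down_start = 1.0 - cfg.ramp_down_frac
    if frac > down_start:
        ramp *= 0.5 * (1.0 + np.cos(
            np.pi * (frac - down_start) / cfg.ramp_down_frac))
    return cfg.lr * ramp


def invert(gen: GeneratorSpec, target: ImageGrid,
           backend: PerceptualBackend,
           cfg: InversionConfig | None = None) -> LatentState:
    """Find the latent state whose synthesis best matches ``target``.

    Deterministic for a fixed config seed. Raises :class:`DivergenceError`
    (naming the iteration) if the loss becomes non-finite.
    """
    cfg = cfg or InversionConfig()
    if target.height != gen.output_side or target.width != gen.output_side:
        raise ValueError(
            f"target is {target.height}×{target.width}, generator expects "
            f"{gen.output_side}×{gen.output_side}")
    from .imaging import convert_range
    target_chw = image_to_chw(convert_range(target, "unit"))

    mu = mean_latent(gen, cfg.mean_latent_samples, seed=cfg.seed)
    noise0 = init_noise(gen, seed=cfg.seed + 1)

    w_t = Tensor(mu.copy(), requires_grad=True)
    noise_t = [Tensor(n.copy(), requires_grad=True) for n in noise0]
    weights_t = gen.weight_tensors(requires_grad=False)
    params = {"w": w_t, **{f"n{i}": n for i, n in enumerate(noise_t)}}
    opt = Adam(params, lr=cfg.lr)

    trace: list[tuple[float, float]] = []
    target_t = Tensor(target_chw)
    for it in range(cfg.iterations):
        opt.zero_grad()
        synth = gen.synthesize_t(w_t, noise_t, weights_t)
        img_loss = backend.distance_t(target_t, synth)
        reg = noise_regularizer_t(noise_t)
        loss = img_loss + cfg.alpha * reg
        if not np.isfinite(loss.data):
            raise DivergenceError(f"non-finite loss at iteration {it}")
        loss.backward()
        opt.step(lr=_lr_schedule(it, cfg.iterations, cfg))
        trace.append((float(img_loss.data), float(reg.data)))
        if (cfg.early_stop_window and len(trace) > cfg.early_stop_window):
            recent = [t[0] for t in trace[-cfg.early_stop_window - 1:]]
            if recent[0] - min(recent[1:]) < cfg.early_stop_delta:
                break

    return LatentState(w=w_t.data.copy(),
                       noise_maps=[n.data.copy() for n in noise_t],
                       step=len(trace), loss_trace=trace)
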