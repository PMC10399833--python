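"""Model adaptation: brief fine-tuning of the generator around one face.

After inversion, the synthesized face still lacks identity-preserving detail
that the pretrained latent space cannot express. Adaptation freezes the
inverted latent (and its noise maps) and gradient-descends the *generator
weights* on

    L = D_perc(x_org, G'(w)) + D_L2(x_org, G'(w)),

on a copy G' of the generator, so the original object is never modified.
Stopping matters: a short budget (50 iterations at production scale)
recovers normal detail, while running much longer starts reconstructing the
anomaly itself and destroys the normalization — the severity signal lives in
what adaptation deliberately does not recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .generators import GeneratorSpec
from .imaging import ImageGrid, convert_range
from .inversion import DivergenceError, LatentState
from .perceptual import PerceptualBackend, image_to_chw

__all__ = ["AdaptationConfig", "AdaptationResult", "adaptation_loss", "adapt"]


@dataclass
class AdaptationConfig:
    """Adaptation knobs (production default: 50 iterations).

    The default optimizer is plain gradient descent: its steps are
    proportional to the gradient, so the weight update stays concentrated
    where the one-face objective actually pulls, leaving the rest of the
    latent space nearly untouched. Adaptive-moment descent is available but
    moves every weight at a similar rate, which erodes that locality.
    """

    iterations: int = 50
    lr: float = 0.5
    optimizer: str = "gd"  # "gd" | "adam"
    momentum: float = 0.0
    snapshot_iters: tuple[int, ...] = ()


@dataclass
class AdaptationResult:
    """Adapted weights, the normalized face, and the per-iteration trace."""

    adapted_weights: dict[str, np.ndarray]
    normalized_image: ImageGrid
    loss_trace: list[tuple[float, float]] = field(default_factory=list)
    snapshots: dict[int, ImageGrid] = field(default_factory=dict)

    @property
    def total_losses(self) -> np.ndarray:
        return np.array([p + l2 for p, l2 in self.loss_trace])


def adaptation_loss(x_org: ImageGrid, x_norm: ImageGrid,
                    backend: PerceptualBackend) -> float:
    """Perceptual distance plus mean squared pixel difference (both unit range)."""
    if x_org.shape != x_norm.shape:
        raise ValueError(f"shape mismatch {x_org.shape} vs {x_norm.shape}")
    a = convert_range(x_org, "unit")
    b = convert_range(x_norm, "unit")
    perc = backend.distance(a, b)
    l2 = float(np.mean((a.pixels - b.pixels) ** 2))
    return perc + l2


def adapt(gen: GeneratorSpec, x_org: ImageGrid, latent: LatentState,
          backend: PerceptualBackend,
          cfg: AdaptationConfig | None = None) -> AdaptationResult:
    """Fine-tune a copy of the generator weights with the latent frozen."""
    cfg = cfg or AdaptationConfig()
    if latent.w.shape != (gen.latent_dim,):
        raise ValueError("latent does not match the generator profile")
    if [n.shape[0] for n in latent.noise_maps] != list(gen.noise_profile):
        raise ValueError("noise maps do not match the generator profile")
    if x_org.height != gen.output_side or x_org.width != gen.output_side:
        raise ValueError("image does not match the generator output side")

    target_t = Tensor(image_to_chw(convert_range(x_org, "unit")))
    w_t = Tensor(latent.w.copy())           # frozen
    noise_t = [Tensor(n.copy()) for n in latent.noise_maps]  # frozen
    weights_t = gen.weight_tensors(requires_grad=True)
    if cfg.optimizer == "adam":
        opt = Adam(weights_t, lr=cfg.lr)
    elif cfg.optimizer == "gd":
        opt = None
        velocity = {k: np.zeros_like(v.data) for k, v in weights_t.items()}
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")

    def render() -> ImageGrid:
        out = gen.synthesize_t(w_t, noise_t,
                               {k: Tensor(v.data) for k, v in weights_t.items()})
        return ImageGrid(np.transpose(out.data, (1, 2, 0)),
                         range_tag="unit", colorspace="RGB")

    trace: list[tuple[float, float]] = []
    snapshots: dict[int, ImageGrid] = {}
    if 0 in cfg.snapshot_iters:
        snapshots[0] = render()
    for it in range(cfg.iterations):
        for v in weights_t.values():
            v.grad = None
        synth = gen.synthesize_t(w_t, noise_t, weights_t)
        perc = backend.distance_t(target_t, synth)
        l2 = (target_t - synth).square().mean()
        loss = perc + l2
        if not np.isfinite(loss.data):
            raise DivergenceError(f"non-finite loss at iteration {it}")
        loss.backward()
        if opt is not None:
            opt.step()
        else:
            for k, v in weights_t.items():
                velocity[k] = cfg.momentum * velocity[k] + v.grad
                v.data = v.data - cfg.lr * velocity[k]
        trace.append((float(perc.data), float(l2.data)))
        if (it + 1) in cfg.snapshot_iters:
            snapshots[it + 1] = render()

    return AdaptationResult(
        adapted_weights={k: v.data.copy() for k, v in weights_t.items()},
        normalized_image=render(),
        loss_trace=trace,
        snapshots=snapshots,
    )
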