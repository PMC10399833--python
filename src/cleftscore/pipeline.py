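"""End-to-end orchestration: preprocess → invert → adapt → heatmap → score.

:class:`RunConfig` carries every stage parameter. The defaults are the
production settings for a 1024-px pretrained face generator (face fraction
0.6, inter-eye distance 100 px, 450 inversion + 50 adaptation iterations,
α = 1e5, 20-rating minimum); :func:`toy_run_config` returns the desk-scale
counterpart used with :class:`~cleftscore.generators.ToyGenerator` — a 64-px
frame with the iteration budgets scaled to the toy problem.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .adaptation import AdaptationConfig, adapt

from .generators import GeneratorSpec, ToyGenerator
from .heatmaps import Heatmap, erode, perceptual_map, pse_map, rgb_to_ycbcr, ssim_map
from .imaging import ImageGrid, LandmarkSet, convert_range
from .inversion import InversionConfig, invert
from .perceptual import PerceptualBackend, RandomConvPerceptual
from .preprocess import LandmarkTruthBackend, PreprocessConfig, preprocess_face
from .scoring import (RatingTable, aggregate_ratings, build_mask, pearson,
                      scale_scores, score)

__all__ = ["RunConfig", "toy_run_config", "make_generator", "make_backend",
           "normalize_face", "compute_heatmap", "run_pipeline",
           "run_ablation", "evaluate_scores"]

HEATMAP_METHODS = ("pse", "ssim", "perceptual")
VARIANTS = ("base", "ycbcr", "erosion", "both")
MASK_KINDS = ("oral_nasal", "face_excluding_eyes")


@dataclass
class RunConfig:
    """All stage parameters of one appraisal run."""

    # preprocessing
    face_fraction: float = 0.6
    eye_distance: float = 100.0
    crop_side: int = 1024
    # normalization; the generator and perceptual nets play the role of
    # fixed pretrained models, so their construction seeds are independent
    # of the run seed
    generator: str = "stylegan2"
    generator_seed: int = 0
    perceptual: str = "randconv"
    perceptual_seed: int = 0
    inversion_iters: int = 450
    alpha: float = 1e5
    inversion_lr: float = 0.05
    inversion_early_stop: int = 0  # 0: fixed budget (batch consistency)
    mean_latent_samples: int = 10_000
    adaptation_iters: int = 50
    adaptation_lr: float = 0.5
    adaptation_optimizer: str = "gd"
    # heatmap + scoring
    heatmap_method: str = "pse"
    ycbcr: bool = True
    erode: bool = True
    erode_target: str = "images"  # or "heatmap"
    pse_channels: str = "all"
    mask_kind: str = "oral_nasal"
    energy: str = "frobenius"
    # evaluation
    min_ratings: int = 20
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        if self.heatmap_method not in HEATMAP_METHODS:
            raise ValueError(f"unknown heatmap method {self.heatmap_method!r}")
        if self.mask_kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.mask_kind!r}")
        if self.erode_target not in ("images", "heatmap"):
            raise ValueError(f"unknown erode target {self.erode_target!r}")
        if self.inversion_iters < 0 or self.adaptation_iters < 0:
            raise ValueError("iteration counts must be nonnegative")


def toy_run_config(seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale configuration for the 64-px toy generator.

    120 inversion + 20 adaptation iterations are enough on the toy problem;
    the inter-eye target of 20 px keeps the 100:1024 facial framing ratio,
    and adaptation steps are kept small so the brief fine-tune recovers
    smooth identity detail without reconstructing localized anomalies.
    """
    base = dict(generator="toy", crop_side=64, eye_distance=20.0,
                inversion_iters=120, adaptation_iters=20,
                mean_latent_samples=2000, seed=seed)
    base.update(overrides)
    return RunConfig(**base)


def make_generator(cfg: RunConfig) -> GeneratorSpec:
    if cfg.generator == "toy":
        return ToyGenerator(seed=cfg.generator_seed)
    raise NotImplementedError(
        f"generator backend {cfg.generator!r} is not available in this build; "
        "use 'toy' or plug a GeneratorSpec implementation in directly")


def make_backend(cfg: RunConfig) -> PerceptualBackend:
    if cfg.perceptual == "randconv":
        return RandomConvPerceptual(seed=cfg.perceptual_seed)
    raise NotImplementedError(f"perceptual backend {cfg.perceptual!r}")


def normalize_face(gen: GeneratorSpec, x_org: ImageGrid,
                   backend: PerceptualBackend, cfg: RunConfig,
                   use_adaptation: bool = True):
    """Inversion (+ optional adaptation) of one canonical face.

    Returns ``(x_norm, latent_state, adaptation_result_or_None)``.
    """
    inv_cfg = InversionConfig(iterations=cfg.inversion_iters, alpha=cfg.alpha,
                              lr=cfg.inversion_lr,
                              mean_latent_samples=cfg.mean_latent_samples,
                              early_stop_window=cfg.inversion_early_stop,
                              seed=cfg.seed)
    state = invert(gen, x_org, backend, inv_cfg)
    if not use_adaptation or cfg.adaptation_iters == 0:
        x_norm = gen.synthesize(state.w, state.noise_maps)
        return x_norm, state, None
    ad_cfg = AdaptationConfig(iterations=cfg.adaptation_iters,
                              lr=cfg.adaptation_lr,
                              optimizer=cfg.adaptation_optimizer)
    result = adapt(gen, convert_range(x_org, "unit"), state, backend, ad_cfg)
    return result.normalized_image, state, result


def compute_heatmap(x_org: ImageGrid, x_norm: ImageGrid, cfg: RunConfig,
                    backend: PerceptualBackend | None = None) -> Heatmap:
    """Difference heatmap with the configured color/erosion/method chain.

    Heatmap-stage arithmetic uses the byte-range convention; the choice
    rescales the absolute score S but not any ranking or correlation.
    """
    a = convert_range(x_org, "byte")
    b = convert_range(x_norm, "byte")
    if cfg.ycbcr:
        a, b = rgb_to_ycbcr(a), rgb_to_ycbcr(b)
    if cfg.erode and cfg.erode_target == "images":
        a, b = erode(a), erode(b)
    flags = dict(ycbcr_applied=cfg.ycbcr, erosion_applied=cfg.erode)
    if cfg.heatmap_method == "pse":
        heat = pse_map(a, b, channels=cfg.pse_channels, **flags)
    elif cfg.heatmap_method == "ssim":
        heat = ssim_map(a, b, **flags)
    elif cfg.heatmap_method == "perceptual":
        if backend is None:
            raise ValueError("perceptual heatmap needs a backend")
        heat = perceptual_map(backend, a, b, **flags)
    else:
        raise ValueError(f"unknown heatmap method {cfg.heatmap_method!r}")
    if cfg.erode and cfg.erode_target == "heatmap":
        from scipy.ndimage import grey_erosion
        heat = Heatmap(grey_erosion(heat.values, size=(3, 3), mode="nearest"),
                       method=heat.method, **flags)
    return heat


def _normalize_batch(items, cfg: RunConfig, use_adaptation: bool):
    """Preprocess + normalize every (image_id, image, landmarks) item."""
    gen = make_generator(cfg)
    backend = make_backend(cfg)
    pre_cfg = PreprocessConfig(face_fraction=cfg.face_fraction,
                               eye_distance=cfg.eye_distance,
                               side=cfg.crop_side)
    out = []
    for image_id, img, lm in items:
        t0 = time.perf_counter()
        canon, canon_lm, meta = preprocess_face(
            img, LandmarkTruthBackend(lm), pre_cfg)
        x_norm, state, _ = normalize_face(gen, canon, backend, cfg,
                                          use_adaptation=use_adaptation)
        meta["seconds"] = time.perf_counter() - t0
        meta["final_image_loss"] = (state.loss_trace[-1][0]
                                    if state.loss_trace else None)
        out.append((image_id, canon, canon_lm, x_norm, meta))
    return out, backend


def run_pipeline(cfg: RunConfig, items) -> tuple[pd.DataFrame, dict]:
    """Score a batch of faces end to end.

    ``items`` is an iterable of ``(image_id, ImageGrid, LandmarkSet)``.
    Returns the scores table and a run-metadata dict. Per-image failures are
    recorded and skipped; the metadata lists them.
    """
    cfg.validate()
    t_start = time.perf_counter()
    rows, failures = [], []
    items = list(items)
    normalized, backend = [], None
    if items:
        try:
            normalized, backend = _normalize_batch(items, cfg, True)
        except Exception:
            # fall back to per-image processing so one bad image cannot
            # void the batch
            normalized = []
            for item in items:
                try:
                    got, backend = _normalize_batch([item], cfg, True)
                    normalized.extend(got)
                except Exception as exc:
                    failures.append({"image_id": item[0], "error": str(exc)})
    for image_id, canon, canon_lm, x_norm, meta in normalized:
        try:
            heat = compute_heatmap(canon, x_norm, cfg, backend)
            mask = build_mask(canon_lm, cfg.mask_kind, cfg.crop_side)
            sc = score(heat, mask, energy=cfg.energy)
            rows.append({"image_id": image_id, "raw_energy": sc.raw_energy,
                         "score": sc.score, "method": sc.method,
                         "mask_kind": sc.mask_kind,
                         "seconds": meta["seconds"]})
        except Exception as exc:
            failures.append({"image_id": image_id, "error": str(exc)})
    frame = pd.DataFrame(rows, columns=["image_id", "raw_energy", "score",
                                        "method", "mask_kind", "seconds"])
    finite = np.isfinite(frame["score"].to_numpy()) if len(frame) else []
    if len(frame) >= 2 and np.sum(finite) == len(frame):
        frame["scaled_score"] = scale_scores(frame["score"].to_numpy())
    else:
        frame["scaled_score"] = np.nan
    metadata = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "n_images": len(items), "n_failed": len(failures),
                "failures": failures,
                "wall_seconds": time.perf_counter() - t_start}
    return frame, metadata


def evaluate_scores(scores: pd.DataFrame, ratings: RatingTable,
                    min_ratings: int = 20) -> tuple[float, int]:
    """Pearson r between machine scores and per-image mean human ratings."""
    means = aggregate_ratings(ratings, min_ratings)
    merged = scores.set_index("image_id")["score"].to_frame().join(
        means.rename("rating"), how="inner").dropna()
    r = pearson(merged["score"].to_numpy(), merged["rating"].to_numpy())
    return r, len(merged)


def run_ablation(cfg: RunConfig, items, ratings: RatingTable,
                 arms: tuple[bool, ...] = (True, False)) -> pd.DataFrame:
    """Machine–human Pearson r over the full method × processing × mask grid.

    For each adaptation arm the grid is 3 heatmap methods × 4 processing
    variants (base, +YCbCr, +erosion, +both) × 2 mask kinds = 24 cells.
    Normalization is computed once per image per arm and reused.
    """
    cfg.validate()
    means = aggregate_ratings(ratings, cfg.min_ratings)
    records = []
    for use_adaptation in arms:
        normalized, backend = _normalize_batch(items, cfg, use_adaptation)
        for method in HEATMAP_METHODS:
            for variant in VARIANTS:
                vcfg = replace(cfg, heatmap_method=method,
                               ycbcr=variant in ("ycbcr", "both"),
                               erode=variant in ("erosion", "both"))
                for mask_kind in MASK_KINDS:
                    scores, ids = [], []
                    for image_id, canon, canon_lm, x_norm, _ in normalized:
                        heat = compute_heatmap(canon, x_norm, vcfg, backend)
                        mask = build_mask(canon_lm, mask_kind, cfg.crop_side)
                        scores.append(score(heat, mask, energy=cfg.energy).score)
                        ids.append(image_id)
                    frame = pd.Series(scores, index=ids, name="score")
                    joined = frame.to_frame().join(means.rename("rating"),
                                                   how="inner").dropna()
                    r = pearson(joined["score"].to_numpy(),
                                joined["rating"].to_numpy())
                    records.append({
                        "adaptation": "with" if use_adaptation else "without",
                        "method": method.upper(), "variant": variant,
                        "mask_kind": mask_kind, "pearson_r": r,
                        "n": len(joined)})
    return pd.DataFrame.from_records(records)
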