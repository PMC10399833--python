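"""Shared fixtures: toy generator, perceptual backends, fixture faces, and
session-scoped end-to-end batches reused by several appraisal tests."""

from __future__ import annotations

import numpy as np
import pytest

from cleftscore.fixtures import FixtureSpec, graded_faces, make_face
from cleftscore.generators import ToyGenerator
from cleftscore.inversion import InversionConfig, invert
from cleftscore.perceptual import PixelPerceptual, RandomConvPerceptual
from cleftscore.pipeline import run_pipeline, toy_run_config
from cleftscore.preprocess import (LandmarkTruthBackend, PreprocessConfig,
                                   preprocess_face)


@pytest.fixture(scope="session")
def toy_gen() -> ToyGenerator:
    return ToyGenerator(seed=0)


@pytest.fixture(scope="session")
def rand_backend() -> RandomConvPerceptual:
    return RandomConvPerceptual(seed=0)


@pytest.fixture(scope="session")
def pixel_backend() -> PixelPerceptual:
    return PixelPerceptual()


@pytest.fixture(scope="session")
def base_face():
    """Schematic fixture face with ground-truth landmarks (side 96)."""
    return make_face(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def toy_canonical():
    """A fixture face carried through toy-scale preprocessing (64 px)."""
    img, lm = make_face(FixtureSpec(seed=0))
    cfg = PreprocessConfig(face_fraction=0.6, eye_distance=20.0, side=64)
    canon, canon_lm, meta = preprocess_face(img, LandmarkTruthBackend(lm), cfg)
    return canon, canon_lm


@pytest.fixture(scope="session")
def toy_inversion(toy_gen, rand_backend, toy_canonical):
    """Toy-scale inversion of the canonical fixture face (120 iterations)."""
    canon, _ = toy_canonical
    cfg = InversionConfig(iterations=120, seed=0, mean_latent_samples=2000,
                          early_stop_window=0)
    return invert(toy_gen, canon, rand_backend, cfg)


@pytest.fixture(scope="session")
def graded_batch():
    """End-to-end scores for 10 planted amplitudes on one base face.

    This is the package's core severity experiment: the same face with a
    cleft-like defect of growing magnitude, each normalized by the toy
    generator and scored with the default PSE + YCbCr + erosion pipeline.
    """
    amplitudes = np.linspace(0.1, 1.0, 10)
    spec = FixtureSpec(seed=0)
    items = [(f"img_{i:03d}", planted, lm)
             for i, (planted, _base, lm, _a)
             in enumerate(graded_faces(amplitudes, spec))]
    cfg = toy_run_config(seed=0)
    frame, meta = run_pipeline(cfg, items)
    return frame, meta, amplitudes
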