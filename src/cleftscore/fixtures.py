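"""Synthetic study material: faces, planted anomalies, and simulated raters.

No clinical imagery ships with the package; every input the pipeline and the
test suite need is generated deterministically from a seed:

* :func:`make_face` — a smooth schematic face (skin ellipse, eye blobs, nose
  ridge, mouth band, textured background) with all 68 landmarks placed
  analytically at the drawn features;
* :func:`plant_anomaly` — a localized structural warp plus intensity notch
  at the philtrum/upper-lip region, scaled by an amplitude in [0, 1], which
  emulates the structural (rather than chromatic) character of a cleft;
* :func:`simulate_ratings` — rater panels whose mean response is a noisy,
  saturating monotone function of the planted amplitude, mirroring the way
  human sensitivity to an anomaly grows quickly and then levels off.

Geometry is expressed in units of the interocular distance, so the same
construction works at any frame size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates

from .imaging import ImageGrid, LandmarkSet
from .scoring import RatingTable

__all__ = ["FixtureSpec", "make_face", "plant_anomaly", "simulate_ratings",
           "graded_faces"]


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for one fixture; identical specs give identical output."""

    seed: int = 0
    image_side: int = 96
    eye_distance: float = 24.0
    anomaly_amplitude: float = 0.0
    rater_count: int = 25
    rating_noise_sd: float = 0.5


def _soft_ellipse(rows, cols, center, semi, softness=1.0):
    """Smooth 0–1 blob: 1 inside the ellipse, sigmoid falloff at the rim."""
    d = np.sqrt(((rows - center[0]) / semi[0]) ** 2
                + ((cols - center[1]) / semi[1]) ** 2)
    return 1.0 / (1.0 + np.exp((d - 1.0) * max(semi) / softness))


def _landmarks(eye_mid, u: float) -> np.ndarray:
    """All 68 points in the iBUG layout, in interocular units around eye_mid."""
    er, ec = eye_mid
    fr, fc = er + 0.40 * u, ec          # face-ellipse center
    a_r, a_c = 1.35 * u, 1.20 * u       # face-ellipse semi-axes
    pts = np.zeros((68, 2))
    # jaw 0..16 along the lower face ellipse (image-left to image-right)
    theta = np.pi - np.arange(17) * np.pi / 16
    pts[0:17, 0] = fr + a_r * np.sin(theta)
    pts[0:17, 1] = fc + a_c * np.cos(theta)
    # brows 17..26, five per side
    for k, side in ((0, -1), (1, +1)):
        ecol = ec + side * u / 2
        off = np.linspace(-0.35 * u, 0.35 * u, 5)
        pts[17 + 5 * k:22 + 5 * k, 0] = er - 0.45 * u
        pts[17 + 5 * k:22 + 5 * k, 1] = ecol + off
    # nose bridge 27..30 and base 31..35
    pts[27:31, 0] = er + np.linspace(0.15, 0.70, 4) * u
    pts[27:31, 1] = ec
    pts[31:36, 0] = er + 0.85 * u
    pts[31:36, 1] = ec + np.array([-0.22, -0.11, 0.0, 0.11, 0.22]) * u
    # eyes 36..47: regular elliptical hexagons strictly inside the drawn
    # eye blobs; symmetric placement makes the centroid the eye center
    ang = np.arange(6) * np.pi / 3
    for k, side in ((0, -1), (1, +1)):
        ecol = ec + side * u / 2
        pts[36 + 6 * k:42 + 6 * k, 0] = er + 0.10 * u * np.sin(ang)
        pts[36 + 6 * k:42 + 6 * k, 1] = ecol + 0.15 * u * np.cos(ang)
    # mouth: outer 48..59 (12 points), inner 60..67 (8 points)
    mr, mc = er + 1.25 * u, ec
    a12 = np.arange(12) * np.pi / 6
    pts[48:60, 0] = mr + 0.12 * u * np.sin(a12)
    pts[48:60, 1] = mc + 0.50 * u * np.cos(a12)
    a8 = np.arange(8) * np.pi / 4
    pts[60:68, 0] = mr + 0.06 * u * np.sin(a8)
    pts[60:68, 1] = mc + 0.30 * u * np.cos(a8)
    return pts


def make_face(spec: FixtureSpec) -> tuple[ImageGrid, LandmarkSet]:
    """Deterministic schematic face with analytically placed landmarks."""
    S = spec.image_side
    if S < 32:
        raise ValueError("image_side must be >= 32")
    u = spec.eye_distance
    rng = np.random.default_rng(spec.seed)
    rows, cols = np.mgrid[0:S, 0:S].astype(np.float64)
    er, ec = 0.42 * S, 0.5 * S          # eye line placement in the frame
    eye_mid = (er, ec)

    # textured background
    tex = gaussian_filter(rng.standard_normal((S, S)), S / 24.0)
    tex = tex / (np.abs(tex).max() + 1e-12) * 0.08
    img = np.stack([0.35 + tex, 0.40 + tex, 0.45 + tex], axis=2)

    def paint(mask2d, color):
        for c in range(3):
            img[:, :, c] = img[:, :, c] * (1 - mask2d) + color[c] * mask2d

    fr, fc = er + 0.40 * u, ec
    face = _soft_ellipse(rows, cols, (fr, fc), (1.35 * u, 1.20 * u),
                         softness=u / 8)
    # gentle vertical shading keeps the skin non-constant
    shade = 1.0 - 0.15 * (rows - (fr - 1.35 * u)) / (2.7 * u)
    paint(face, (0.80, 0.62, 0.52))
    img *= np.clip(shade, 0.8, 1.0)[:, :, None] * face[:, :, None] \
        + (1 - face[:, :, None])

    for side in (-1, +1):
        eye = _soft_ellipse(rows, cols, (er, ec + side * u / 2),
                            (0.14 * u, 0.18 * u), softness=u / 12)
        paint(eye, (0.13, 0.10, 0.10))
        brow = _soft_ellipse(rows, cols, (er - 0.45 * u, ec + side * u / 2),
                             (0.07 * u, 0.38 * u), softness=u / 14)
        paint(brow, (0.30, 0.20, 0.15))
    nose = _soft_ellipse(rows, cols, (er + 0.5 * u, ec),
                         (0.40 * u, 0.10 * u), softness=u / 12)
    paint(0.5 * nose, (0.62, 0.45, 0.38))
    mouth = _soft_ellipse(rows, cols, (er + 1.25 * u, ec),
                          (0.12 * u, 0.50 * u), softness=u / 12)
    paint(mouth, (0.55, 0.25, 0.25))

    img = np.clip(img, 0.0, 1.0)
    lm = LandmarkSet(_landmarks(eye_mid, u))
    return ImageGrid(img, range_tag="unit", colorspace="RGB"), lm


def plant_anomaly(img: ImageGrid, lm: LandmarkSet, amplitude: float,
                  seed: int = 0) -> ImageGrid:
    """Plant a graded cleft-like defect at the philtrum/upper-lip region.

    The defect is a horizontal structural warp pulling tissue away from the
    midline plus a darkened notch between the nose base and the upper lip,
    both scaled by ``amplitude``. Amplitude 0 is the identity; pixels
    outside a bounded oral/nasal neighborhood are untouched.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return img
    u = lm.interocular_distance
    nose_base = lm.points[33]
    mouth_top = lm.points[51]
    center = (nose_base + mouth_top) / 2.0
    S = img.height
    rows, cols = np.mgrid[0:S, 0:img.width].astype(np.float64)

    # compactly supported cos^2 window (exactly zero outside the ellipse)
    d = np.sqrt(((rows - center[0]) / (0.45 * u)) ** 2
                + ((cols - center[1]) / (0.30 * u)) ** 2)
    win = np.where(d < 1.0, np.cos(0.5 * np.pi * np.minimum(d, 1.0)) ** 2, 0.0)

    # structural warp: sample columns pushed toward the midline so the
    # rendered tissue separates away from it
    dx = amplitude * 0.30 * u * win * np.tanh((cols - center[1]) / (0.12 * u))
    out = np.empty_like(img.pixels)
    coords = np.stack([rows, cols - dx])
    for c in range(img.channels):
        out[:, :, c] = map_coordinates(img.pixels[:, :, c], coords,
                                       order=1, mode="nearest")

    # intensity notch along the philtrum midline
    notch = win * np.exp(-((cols - center[1]) / (0.10 * u)) ** 2)
    hi = 1.0 if img.range_tag == "unit" else 255.0
    out = np.clip(out - amplitude * 0.5 * hi * notch[:, :, None], 0.0, hi)
    return img.with_pixels(out)


def response_curve(amplitude) -> np.ndarray:
    """Saturating monotone anomaly→rating-drop curve g(a) = a / (a + 0.3)."""
    a = np.asarray(amplitude, dtype=np.float64)
    return a / (a + 0.3)


def simulate_ratings(amplitudes, spec: FixtureSpec,
                     image_ids=None) -> RatingTable:
    """Simulated 1–7 rater panel for faces of the given planted amplitudes.

    Each rater's vote is ``clip(round(7 − 6·g(a) + ε), 1, 7)`` with
    ``ε ~ N(0, rating_noise_sd)``, ``spec.rater_count`` raters per image.
    """
    if spec.rater_count < 1:
        raise ValueError("rater_count must be >= 1")
    rng = np.random.default_rng(spec.seed)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if image_ids is None:
        image_ids = [f"img_{i:03d}" for i in range(len(amplitudes))]
    rows = []
    for img_id, a in zip(image_ids, amplitudes):
        base = 7.0 - 6.0 * response_curve(a)
        noise = rng.normal(0.0, spec.rating_noise_sd, spec.rater_count)
        votes = np.clip(np.rint(base + noise), 1, 7).astype(int)
        for r, v in enumerate(votes):
            rows.append((img_id, f"rater_{r:03d}", v))
    return RatingTable(pd.DataFrame(rows, columns=list(RatingTable.COLUMNS)))


def graded_faces(amplitudes, spec: FixtureSpec, vary_faces: bool = False
                 ) -> list[tuple[ImageGrid, ImageGrid, LandmarkSet, float]]:
    """Paired fixtures: (anomalous image, pre-anomaly image, landmarks, amplitude).

    The pre-anomaly image is a ground-truth "normalized" counterpart, letting
    the heatmap and scoring stages be exercised independently of the
    generator stages. With ``vary_faces`` each item uses a different base
    face seed; otherwise a single base face is reused.
    """
    out = []
    for i, a in enumerate(np.asarray(amplitudes, dtype=np.float64)):
        face_spec = replace(spec, seed=spec.seed + (i if vary_faces else 0),
                            anomaly_amplitude=float(a))
        base, lm = make_face(face_spec)
        planted = plant_anomaly(base, lm, float(a), seed=spec.seed + 1000 + i)
        out.append((planted, base, lm, float(a)))
    return out
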