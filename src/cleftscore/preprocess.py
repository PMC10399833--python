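"""Canonicalize a face photo for the generator: background, pose, scale, crop.

The generator expects faces framed the way its training corpus was: roughly
60% face to 40% background, eyes horizontal, inter-eye distance 100 px, in a
1024×1024 crop (all configurable; the toy pipeline uses a 64-px frame).

The stages run in a fixed order — background adjustment, eye alignment,
interocular rescale, canonical crop — and every stage that moves pixels also
returns the consistently transformed landmark set, so downstream masks stay
registered to the image.

Face/landmark detection is a pluggable backend. The production backend
would wrap a conventional cascade detector plus a 68-landmark predictor;
tests and fixtures inject ground-truth landmarks through
:class:`LandmarkTruthBackend`, so the suite never depends on a model
download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import rescale as _sk_rescale
from skimage.transform import warp as _sk_warp
from skimage.transform import AffineTransform

from .imaging import ImageGrid, LandmarkSet

__all__ = ["FaceBox", "DetectorBackend", "LandmarkTruthBackend",
           "PreprocessConfig", "mirror_canvas", "adjust_background",
           "blur_background", "align_eyes", "scale_to_interocular",
           "crop_canonical", "preprocess_face"]


class GeometryError(ValueError):
    """Degenerate geometry (coincident eyes, empty box, ...)."""


@dataclass(frozen=True)
class FaceBox:
    """Axis-aligned face bounding box in pixel units."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise GeometryError("face box must have positive size")

    @property
    def area(self) -> int:
        return self.height * self.width

    @property
    def center(self) -> tuple[float, float]:
        return (self.top + (self.height - 1) / 2.0,
                self.left + (self.width - 1) / 2.0)

    def inside(self, img: ImageGrid) -> bool:
        return (self.top >= 0 and self.left >= 0
                and self.top + self.height <= img.height
                and self.left + self.width <= img.width)

    def shifted(self, drow: int, dcol: int) -> "FaceBox":
        return FaceBox(self.top + drow, self.left + dcol,
                       self.height, self.width)


class DetectorBackend:
    """Face-detection contract; deterministic for a fixed image."""

    def detect_face(self, img: ImageGrid) -> FaceBox:
        raise NotImplementedError

    def detect_landmarks(self, img: ImageGrid, box: FaceBox) -> LandmarkSet:
        raise NotImplementedError


class LandmarkTruthBackend(DetectorBackend):
    """Backend carrying known landmarks (synthetic fixtures, CSV annotations).

    The face box is derived from the landmarks the way a holistic face
    detector frames a head: a square of ``box_scale`` interocular distances
    per side, centered a little below the eye line. With the default scale,
    a canonically cropped face comes out at the target 60% face fraction,
    which makes the full preprocess idempotent.
    """

    def __init__(self, landmarks: LandmarkSet, box_scale: float = 7.9,
                 center_drop: float = 0.2):
        self.landmarks = landmarks
        self.box_scale = box_scale
        self.center_drop = center_drop

    def detect_face(self, img: ImageGrid) -> FaceBox:
        lm = self.landmarks
        d = lm.interocular_distance
        if d <= 0:
            raise GeometryError("coincident eye centers")
        side = self.box_scale * d
        cr = lm.eye_midpoint[0] + self.center_drop * side
        cc = lm.eye_midpoint[1]
        top = int(round(cr - side / 2))
        left = int(round(cc - side / 2))
        bottom = int(round(cr + side / 2))
        right = int(round(cc + side / 2))
        top, left = max(top, 0), max(left, 0)
        bottom, right = min(bottom, img.height), min(right, img.width)
        return FaceBox(top, left, bottom - top, right - left)

    def detect_landmarks(self, img: ImageGrid, box: FaceBox) -> LandmarkSet:
        return self.landmarks


@dataclass
class PreprocessConfig:
    """Frame geometry targets (defaults are production scale)."""

    face_fraction: float = 0.6
    eye_distance: float = 100.0
    side: int = 1024
    blur_sigma: float = 5.0
    crop_v_offset_frac: float = 0.08  # crop center sits this far below eyes
    fraction_tolerance: float = 0.05


def mirror_canvas(img: ImageGrid) -> ImageGrid:
    """3H×3W canvas: the image surrounded by its 8 flipped replicates."""
    H, W = img.height, img.width
    big = np.pad(img.pixels, ((H, H), (W, W), (0, 0)), mode="symmetric")
    return img.with_pixels(big)


def blur_background(img: ImageGrid, box: FaceBox,
                    sigma: float) -> ImageGrid:
    """Composite the sharp face box over a Gaussian-blurred background.

    A binary foreground mask (the face box dilated by 3σ) is Gaussian-
    smoothed into 0–1 weights; face-box interior pixels therefore stay
    unchanged to well within one byte level.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pad = int(math.ceil(3 * sigma))
    mask = np.zeros((img.height, img.width))
    t = max(box.top - pad, 0)
    l = max(box.left - pad, 0)
    b = min(box.top + box.height + pad, img.height)
    r = min(box.left + box.width + pad, img.width)
    mask[t:b, l:r] = 1.0
    weights = np.clip(gaussian_filter(mask, sigma), 0.0, 1.0)[:, :, None]
    blurred = np.empty_like(img.pixels)
    for c in range(img.channels):
        blurred[:, :, c] = gaussian_filter(img.pixels[:, :, c], sigma)
    out = weights * img.pixels + (1.0 - weights) * blurred
    return img.with_pixels(out)


def adjust_background(img: ImageGrid, box: FaceBox,
                      target_face_fraction: float = 0.6,
                      blur_sigma: float = 5.0,
                      fraction_tolerance: float = 0.05
                      ) -> tuple[ImageGrid, FaceBox]:
    """Bring the face-to-image area ratio to the target fraction.

    A too-small face fraction is fixed by cropping background margins
    symmetrically around the face box; a too-large fraction by surrounding
    the image with its 8 flipped replicates, blurring the added background,
    and cropping the enlarged canvas. Returns the adjusted image and the
    face box in its coordinates.
    """
    if box.area <= 1:
        raise GeometryError("degenerate face box")
    if not box.inside(img):
        raise GeometryError("face box lies outside the image")
    if not 0 < target_face_fraction < 1:
        raise ValueError("target_face_fraction must be in (0, 1)")
    H, W = img.height, img.width
    frac = box.area / (H * W)
    if abs(frac - target_face_fraction) <= fraction_tolerance * target_face_fraction:
        return img, box
    k = math.sqrt(frac / target_face_fraction)  # window scale vs current
    h2, w2 = int(round(H * k)), int(round(W * k))
    cr, cc = box.center
    if k <= 1.0:  # crop margins
        r0 = int(round(cr - h2 / 2))
        c0 = int(round(cc - w2 / 2))
        r0 = min(max(r0, 0), H - h2)
        c0 = min(max(c0, 0), W - w2)
        out = img.with_pixels(img.pixels[r0:r0 + h2, c0:c0 + w2])
        return out, box.shifted(-r0, -c0)
    big = mirror_canvas(img)
    big_box = box.shifted(H, W)
    big = blur_background(big, big_box, blur_sigma)
    r0 = int(round(cr + H - h2 / 2))
    c0 = int(round(cc + W - w2 / 2))
    r0 = min(max(r0, 0), 3 * H - h2)
    c0 = min(max(c0, 0), 3 * W - w2)
    out = big.with_pixels(big.pixels[r0:r0 + h2, c0:c0 + w2])
    return out, big_box.shifted(-r0, -c0)


def _warp_affine(img: ImageGrid, forward_xy: np.ndarray,
                 output_shape=None) -> ImageGrid:
    """Warp with a forward (input→output) 3×3 matrix in (x=col, y=row)."""
    tform = AffineTransform(matrix=np.linalg.inv(forward_xy))
    out = _sk_warp(img.pixels, tform, order=1, mode="edge",
                   preserve_range=True, output_shape=output_shape)
    hi = 1.0 if img.range_tag == "unit" else 255.0
    return img.with_pixels(np.clip(out, 0.0, hi))


def _apply_to_points(forward_xy: np.ndarray, pts_rc: np.ndarray) -> np.ndarray:
    xy = np.column_stack([pts_rc[:, 1], pts_rc[:, 0], np.ones(len(pts_rc))])
    out = xy @ forward_xy.T
    return np.column_stack([out[:, 1], out[:, 0]])


def align_eyes(img: ImageGrid, lm: LandmarkSet
               ) -> tuple[ImageGrid, LandmarkSet, float]:
    """Rotate about the eye midpoint so the eye-center segment is horizontal.

    Returns the rotated image, transformed landmarks, and the applied
    rotation angle in degrees.
    """
    p_r, p_l = lm.right_eye_center, lm.left_eye_center
    if np.allclose(p_r, p_l):
        raise GeometryError("coincident eye centers")
    theta = math.atan2(p_l[0] - p_r[0], p_l[1] - p_r[1])  # angle of eye line
    if abs(theta) < 1e-12:
        return img, lm, 0.0
    c, s = math.cos(-theta), math.sin(-theta)
    cx, cy = lm.eye_midpoint[1], lm.eye_midpoint[0]
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    t1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    t2 = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    forward = t2 @ rot @ t1
    out = _warp_affine(img, forward)
    new_lm = lm.transformed(lambda p: _apply_to_points(forward, p))
    return out, new_lm, math.degrees(-theta)


def scale_to_interocular(img: ImageGrid, lm: LandmarkSet,
                         target_distance: float = 100.0
                         ) -> tuple[ImageGrid, LandmarkSet, float]:
    """Isotropic rescale so the eye-center distance hits the target."""
    d = lm.interocular_distance
    if d <= 0:
        raise GeometryError("zero eye-center distance")
    s = target_distance / d
    if abs(s - 1.0) < 1e-9:
        return img, lm, 1.0
    out = _sk_rescale(img.pixels, s, channel_axis=2, order=1,
                      anti_aliasing=(s < 1), preserve_range=True)
    hi = 1.0 if img.range_tag == "unit" else 255.0
    new_img = img.with_pixels(np.clip(out, 0.0, hi))
    new_lm = lm.transformed(lambda p: p * s)
    return new_img, new_lm, s


def crop_canonical(img: ImageGrid, lm: LandmarkSet, side: int = 1024,
                   v_offset_frac: float = 0.08
                   ) -> tuple[ImageGrid, LandmarkSet, tuple[int, int]]:
    """side×side window centered on the face anchor (eyes shifted down).

    Pads by reflection when the window overruns the canvas, so the crop
    always succeeds. Returns image, landmarks, and the crop origin in the
    (possibly padded) source frame.
    """
    anchor_r = lm.eye_midpoint[0] + v_offset_frac * side
    anchor_c = lm.eye_midpoint[1]
    r0 = int(round(anchor_r - side / 2))
    c0 = int(round(anchor_c - side / 2))
    pad_top = max(-r0, 0)
    pad_left = max(-c0, 0)
    pad_bottom = max(r0 + side - img.height, 0)
    pad_right = max(c0 + side - img.width, 0)
    px = img.pixels
    if pad_top or pad_left or pad_bottom or pad_right:
        px = np.pad(px, ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0)),
                    mode="reflect")
    rr, cc = r0 + pad_top, c0 + pad_left
    out = img.with_pixels(px[rr:rr + side, cc:cc + side])
    new_lm = lm.transformed(lambda p: p - np.array([r0, c0]))
    return out, new_lm, (r0, c0)


def preprocess_face(img: ImageGrid, backend: DetectorBackend,
                    cfg: PreprocessConfig | None = None
                    ) -> tuple[ImageGrid, LandmarkSet, dict]:
    """Run the full canonicalization chain; returns image, landmarks, metadata."""
    cfg = cfg or PreprocessConfig()
    box = backend.detect_face(img)
    lm = backend.detect_landmarks(img, box)
    img2, box2 = adjust_background(img, box, cfg.face_fraction,
                                   blur_sigma=cfg.blur_sigma,
                                   fraction_tolerance=cfg.fraction_tolerance)
    shift = np.array([box2.top - box.top, box2.left - box.left], dtype=float)
    lm = lm.transformed(lambda p: p + shift)
    img3, lm, angle = align_eyes(img2, lm)
    img4, lm, scale = scale_to_interocular(img3, lm, cfg.eye_distance)
    img5, lm, origin = crop_canonical(img4, lm, cfg.side,
                                      cfg.crop_v_offset_frac)
    meta = {"rotation_deg": angle, "scale": scale, "crop_origin": origin,
            "face_fraction_in": box.area / (img.height * img.width)}
    return img5, lm, meta
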