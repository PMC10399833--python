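"""Core raster and landmark types shared by every pipeline stage.

All images travel through the pipeline as :class:`ImageGrid` objects: a plain
``float64`` H×W×C array tagged with an explicit value range (``unit`` for
[0, 1], ``byte`` for [0, 255]) and a colorspace. Conversions between ranges
and colorspaces are always explicit; no stage silently rescales.

Coordinates are 0-based ``(row, col)`` with the origin at the top-left, the
usual raster convention, so crop arithmetic is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "ImageGrid",
    "LandmarkSet",
    "RegionMask",
    "load_image",
    "save_image",
    "convert_range",
    "load_landmarks_csv",
    "save_landmarks_csv",
    "RIGHT_EYE_IDX",
    "LEFT_EYE_IDX",
    "JAW_IDX",
    "BROW_IDX",
    "NOSE_IDX",
    "OUTER_MOUTH_IDX",
    "INNER_MOUTH_IDX",
]

_RANGE_MAX = {"unit": 1.0, "byte": 255.0}
_RANGE_TOL = 1e-6

# Standard 68-point landmark layout (iBUG convention, 0-based).
JAW_IDX = list(range(0, 17))
BROW_IDX = list(range(17, 27))
NOSE_IDX = list(range(27, 36))
RIGHT_EYE_IDX = list(range(36, 42))  # subject's right, image-left
LEFT_EYE_IDX = list(range(42, 48))
OUTER_MOUTH_IDX = list(range(48, 60))
INNER_MOUTH_IDX = list(range(60, 68))


class ImageFormatError(ValueError):
    """Raised for unreadable or unsupported image files."""


@dataclass(frozen=True)
class ImageGrid:
    """H×W×C float raster with explicit range and colorspace tags.

    Parameters
    ----------
    pixels
        ``float64`` array of shape (H, W, C); C is 3 for RGB/YCbCr, 1 for gray.
    range_tag
        ``"unit"`` for values in [0, 1] or ``"byte"`` for [0, 255].
    colorspace
        ``"RGB"``, ``"YCbCr"`` or ``"gray"``.
    """

    pixels: np.ndarray
    range_tag: str = "unit"
    colorspace: str = "RGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be H×W×C, got shape {px.shape}")
        object.__setattr__(self, "pixels", px)
        if self.range_tag not in _RANGE_MAX:
            raise ValueError(f"unknown range_tag {self.range_tag!r}")
        if self.colorspace not in ("RGB", "YCbCr", "gray"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")
        expected_c = 1 if self.colorspace == "gray" else 3
        if px.shape[2] != expected_c:
            raise ValueError(
                f"{self.colorspace} image must have {expected_c} channels, "
                f"got {px.shape[2]}"
            )
        hi = _RANGE_MAX[self.range_tag]
        if px.size and (px.min() < -hi * _RANGE_TOL - _RANGE_TOL
                        or px.max() > hi * (1 + _RANGE_TOL) + _RANGE_TOL):
            raise ValueError(
                f"pixel values [{px.min():g}, {px.max():g}] outside declared "
                f"{self.range_tag} range [0, {hi:g}]"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **tags) -> "ImageGrid":
        """Return a copy with new pixel data (tags preserved unless overridden)."""
        kw = {"range_tag": self.range_tag, "colorspace": self.colorspace}
        kw.update(tags)
        return ImageGrid(pixels, **kw)


@dataclass(frozen=True)
class LandmarkSet:
    """The 68 facial landmarks of the standard annotation scheme.

    ``points`` is a (68, 2) float array of (row, col) pixel coordinates.
    Eye centers are the centroids of the six landmarks of each eye.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.shape != (68, 2):
            raise ValueError(f"expected 68 (row, col) points, got {pts.shape}")
        object.__setattr__(self, "points", pts)

    @property
    def right_eye_center(self) -> np.ndarray:
        return self.points[RIGHT_EYE_IDX].mean(axis=0)

    @property
    def left_eye_center(self) -> np.ndarray:
        return self.points[LEFT_EYE_IDX].mean(axis=0)

    @property
    def eye_centers(self) -> np.ndarray:
        return np.stack([self.right_eye_center, self.left_eye_center])

    @property
    def eye_midpoint(self) -> np.ndarray:
        return self.eye_centers.mean(axis=0)

    @property
    def interocular_distance(self) -> float:
        return float(np.linalg.norm(self.left_eye_center - self.right_eye_center))

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` ((N, 2) rows/cols -> (N, 2)) to every point."""
        return LandmarkSet(np.asarray(fn(self.points), dtype=np.float64))

    def inside(self, img: ImageGrid) -> bool:
        r, c = self.points[:, 0], self.points[:, 1]
        return bool((r >= 0).all() and (c >= 0).all()
                    and (r <= img.height - 1).all() and (c <= img.width - 1).all())


@dataclass(frozen=True)
class RegionMask:
    """Binary H×W mask selecting a scoring region (e.g. the oral/nasal area)."""

    mask: np.ndarray
    region_kind: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any():
            raise ValueError("mask selects no pixels")
        object.__setattr__(self, "mask", m)
        if self.region_kind not in ("oral_nasal", "face_excluding_eyes", "custom"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def load_image(path: str | Path) -> ImageGrid:
    """Load a PNG/JPEG file as a byte-range RGB :class:`ImageGrid`.

    Channel order is R, G, B regardless of the on-disk codec convention.
    Grayscale files are promoted to RGB; CMYK and other exotic modes, and
    files carrying a non-identity EXIF orientation, are rejected.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            exif = im.getexif()
            orientation = exif.get(0x0112, 1)
            if orientation not in (0, 1):
                raise ImageFormatError(
                    f"{path}: EXIF orientation {orientation} is not supported; "
                    "re-save the image with orientation applied"
                )
            if im.mode in ("L", "I;16"):
                im = im.convert("RGB")
            if im.mode != "RGB":
                raise ImageFormatError(
                    f"{path}: unsupported image mode {im.mode!r} (need RGB)"
                )
            arr = np.asarray(im, dtype=np.float64)
    except ImageFormatError:
        raise
    except Exception as exc:  # decode errors name the offending path
        raise ImageFormatError(f"cannot decode image file {path}: {exc}") from exc
    return ImageGrid(arr, range_tag="byte", colorspace="RGB")


def save_image(img: ImageGrid, path: str | Path) -> None:
    """Write an ImageGrid to PNG/JPEG (8-bit). Lossless round-trip for PNG."""
    byte = convert_range(img, "byte")
    arr = np.clip(np.rint(byte.pixels), 0, 255).astype(np.uint8)
    if img.colorspace == "gray":
        Image.fromarray(arr[:, :, 0], mode="L").save(path)
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def convert_range(img: ImageGrid, target: str) -> ImageGrid:
    """Linearly rescale between the unit [0,1] and byte [0,255] conventions."""
    if target not in _RANGE_MAX:
        raise ValueError(f"unknown range_tag {target!r}")
    if target == img.range_tag:
        return img
    factor = _RANGE_MAX[target] / _RANGE_MAX[img.range_tag]
    return ImageGrid(img.pixels * factor, range_tag=target,
                     colorspace=img.colorspace)


def load_landmarks_csv(path: str | Path) -> LandmarkSet:
    """Read a 68-row ``row,col`` CSV into a LandmarkSet."""
    pts = np.loadtxt(path, delimiter=",", dtype=np.float64)
    return LandmarkSet(pts)


def save_landmarks_csv(lm: LandmarkSet, path: str | Path) -> None:
    np.savetxt(path, lm.points, delimiter=",", fmt="%.6f")
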