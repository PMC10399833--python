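"""Difference heatmaps between an original face and its normalized version.

Three comparators are available — pixel-wise squared error (PSE), windowed
SSIM dissimilarity, and a perceptual feature-difference map — with two
optional processing steps around them: a BT.601 RGB→YCbCr transform applied
to both images first (structural anomalies live in luma, lighting drift in
chroma), and a 3×3 morphological erosion applied to both images before
differencing to suppress speckle noise from the synthesis step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import grey_erosion
from skimage.metrics import structural_similarity

from .imaging import ImageGrid, convert_range
from .perceptual import PerceptualBackend

__all__ = ["Heatmap", "rgb_to_ycbcr", "pse_map", "ssim_map",
           "perceptual_map", "erode"]

# BT.601 full-swing RGB (unit range) -> studio-swing YCbCr (byte range).
_YCBCR_MATRIX = np.array([
    [65.481, 128.553, 24.966],
    [-37.797, -74.203, 112.0],
    [112.0, -93.786, -18.214],
])
_YCBCR_OFFSET = np.array([16.0, 128.0, 128.0])


@dataclass(frozen=True)
class Heatmap:
    """Nonnegative H×W difference map plus provenance flags."""

    values: np.ndarray
    method: str
    ycbcr_applied: bool = False
    erosion_applied: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("heatmap values must be 2-D")
        if v.size and v.min() < -1e-9:
            raise ValueError("heatmap values must be nonnegative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))
        if self.method not in ("PSE", "SSIM", "perceptual"):
            raise ValueError(f"unknown heatmap method {self.method!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def rgb_to_ycbcr(img: ImageGrid) -> ImageGrid:
    """BT.601 RGB→YCbCr with offsets (16, 128, 128).

    The transform coefficients assume gamma-corrected unit-range R'G'B'
    input and produce byte-scale Y'CbCr, so the input is range-converted
    first and the output is tagged byte-range.
    """
    if img.colorspace != "RGB":
        raise ValueError(f"expected RGB input, got {img.colorspace}")
    rgb = convert_range(img, "unit").pixels
    ycc = rgb @ _YCBCR_MATRIX.T + _YCBCR_OFFSET
    return ImageGrid(ycc, range_tag="byte", colorspace="YCbCr")


def _check_pair(x: ImageGrid, y: ImageGrid) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if x.colorspace != y.colorspace:
        raise ValueError(
            f"colorspace mismatch {x.colorspace} vs {y.colorspace}")
    if x.range_tag != y.range_tag:
        raise ValueError(f"range mismatch {x.range_tag} vs {y.range_tag}")


def pse_map(x_org: ImageGrid, x_norm: ImageGrid,
            channels: str = "all", **flags) -> Heatmap:
    """Pixel-wise squared error, channel-summed to a single-channel map.

    ``channels="first"`` restricts the sum to channel 0 (the luma channel of
    a YCbCr pair).
    """
    _check_pair(x_org, x_norm)
    d = x_org.pixels - x_norm.pixels
    sq = d * d
    if channels == "first":
        values = sq[:, :, 0]
    else:
        values = sq.sum(axis=2)
    return Heatmap(values, method="PSE", **flags)


def ssim_map(x_org: ImageGrid, x_norm: ImageGrid, window: int = 7,
             c1: float | None = None, c2: float | None = None,
             **flags) -> Heatmap:
    """Windowed SSIM dissimilarity map, ``1 − SSIM``, channel-averaged.

    Local means, variances and covariance are taken over a uniform
    ``window``×``window`` neighborhood; the stabilizers default to
    c1 = (0.01·L)², c2 = (0.03·L)² with L the dynamic range.
    """
    _check_pair(x_org, x_norm)
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window > min(x_org.height, x_org.width):
        raise ValueError("window larger than image")
    L = 1.0 if x_org.range_tag == "unit" else 255.0
    k1 = 0.01 if c1 is None else float(np.sqrt(c1) / L)
    k2 = 0.03 if c2 is None else float(np.sqrt(c2) / L)
    _, smap = structural_similarity(
        x_org.pixels, x_norm.pixels, win_size=window, data_range=L,
        channel_axis=2, K1=k1, K2=k2, full=True)
    return Heatmap(np.clip(1.0 - smap.mean(axis=2), 0.0, None),
                   method="SSIM", **flags)


def perceptual_map(backend: PerceptualBackend, x_org: ImageGrid,
                   x_norm: ImageGrid, **flags) -> Heatmap:
    """Per-position weighted squared feature difference at image resolution."""
    _check_pair(x_org, x_norm)
    if not hasattr(backend, "spatial_map"):
        raise TypeError("backend does not provide a spatial map")
    values = backend.spatial_map(x_org, x_norm)
    return Heatmap(values, method="perceptual", **flags)


def erode(img: ImageGrid) -> ImageGrid:
    """3×3 neighborhood-minimum filter, applied independently per channel.

    Edge pixels take the minimum over their in-bounds neighborhood.
    """
    out = np.empty_like(img.pixels)
    for c in range(img.channels):
        # nearest-edge padding replicates in-bounds values, so the border
        # minimum equals the in-bounds-neighborhood minimum
        out[:, :, c] = grey_erosion(img.pixels[:, :, c], size=(3, 3),
                                    mode="nearest")
    return img.with_pixels(out)
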