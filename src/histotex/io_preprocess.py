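"""Image input and preprocessing.

Reads histology images and binary ROI masks, downsamples by block mean,
converts RGB to grayscale luminance, rescales intensities, and quantizes
in-ROI gray values into the discrete levels that all four texture matrices
are built on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger("histotex")

# ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class RasterImage:
    """A 2D scalar or RGB image with physical pixel spacing (µm/pixel)."""

    pixels: np.ndarray
    pixel_spacing: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2D scalar or 2D + channel axis")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class ROIMask:
    """Boolean region-of-interest mask aligned to an image grid."""

    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantizedImage:
    """Integer gray-level grid: levels in 1..ng inside the ROI, 0 outside."""

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)


def load_image(path: str | Path, pixel_spacing: float) -> RasterImage:
    """Read a TIFF or PNG image from disk.

    RGB images are kept as three channels; an alpha channel, if present,
    is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            pixels = tifffile.imread(path)
        else:
            pixels = np.asarray(Image.open(path))
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    if pixels.ndim == 3 and pixels.shape[2] not in (1, 3):
        raise ValueError(f"unsupported channel count {pixels.shape[2]} in {path}")
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    return RasterImage(pixels=np.asarray(pixels, dtype=float),
                       pixel_spacing=pixel_spacing,
                       provenance=str(path))


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write an image as TIFF (float) or PNG (clipped uint8)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(img.pixels, dtype=np.float32))
    else:
        arr = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


def load_mask(path: str | Path, label: str = "custom") -> ROIMask:
    """Read a co-registered binary mask image; any nonzero pixel is in-ROI."""
    img = load_image(path, pixel_spacing=1.0)
    pixels = img.pixels
    if pixels.ndim == 3:
        pixels = pixels.max(axis=2)
    return ROIMask(mask=pixels > 0, label=label)


def downsample(img: RasterImage, factor: int) -> RasterImage:
    """Block-mean downsample by an integer factor.

    Each output pixel is the mean of a ``factor x factor`` input block;
    trailing rows/columns that do not fill a block are dropped. Pixel
    spacing is multiplied by the factor.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("downsample factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return RasterImage(img.pixels.copy(), img.pixel_spacing, img.provenance)
    h, w = img.shape
    nh, nw = h // factor, w // factor
    if nh < 1 or nw < 1:
        raise ValueError("image smaller than downsampling factor")
    trimmed = img.pixels[: nh * factor, : nw * factor]
    if trimmed.ndim == 2:
        out = trimmed.reshape(nh, factor, nw, factor).mean(axis=(1, 3))
    else:
        out = trimmed.reshape(nh, factor, nw, factor, -1).mean(axis=(1, 3))
    return RasterImage(out, img.pixel_spacing * factor, img.provenance)


def to_grayscale(img: RasterImage) -> RasterImage:
    """Convert RGB to scalar luminance (BT.601); scalar input is returned as is."""
    if img.n_channels == 1:
        return img
    if img.n_channels != 3:
        raise ValueError(f"cannot convert {img.n_channels}-channel image to gray")
    gray = img.pixels @ _LUMA
    return RasterImage(gray, img.pixel_spacing, img.provenance)


def normalize_intensity(img: RasterImage, low: float = 0.0,
                        high: float = 255.0) -> RasterImage:
    """Min-max rescale a scalar image to [low, high].

    A constant image maps to ``low``.
    """
    if img.n_channels != 1:
        raise ValueError("normalize_intensity expects a scalar image")
    pix = img.pixels.astype(float)
    lo, hi = pix.min(), pix.max()
    if hi > lo:
        pix = low + (pix - lo) * (high - low) / (hi - lo)
    else:
        pix = np.full_like(pix, low)
    return RasterImage(pix, img.pixel_spacing, img.provenance)


def quantize(img: RasterImage, roi: ROIMask, ng: int) -> QuantizedImage:
    """Quantize in-ROI intensities into ``ng`` equal-width gray-level bins.

    Bins span the in-ROI [min, max]; level = 1-based bin index, 0 outside
    the ROI. A constant ROI maps every pixel to level 1 (ng is kept as
    metadata so downstream matrices retain their nominal size).
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    if img.n_channels != 1:
        raise ValueError("quantize expects a grayscale image")
    if img.shape != roi.mask.shape:
        raise ValueError("ROI shape does not match image shape")
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")
    pix = img.pixels.astype(float)
    vals = pix[roi.mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(img.shape, dtype=np.int32)
    if hi > lo:
        width = (hi - lo) / ng
        lv = np.floor((pix - lo) / width).astype(np.int32) + 1
        np.clip(lv, 1, ng, out=lv)
        levels[roi.mask] = lv[roi.mask]
        edges = np.linspace(lo, hi, ng + 1)
    else:
        levels[roi.mask] = 1
        edges = np.linspace(lo, lo + 1.0, ng + 1)  # degenerate range
    return QuantizedImage(levels=levels, ng=ng, bin_edges=edges,
                          pixel_spacing=img.pixel_spacing)


def preprocess(img: RasterImage, roi: ROIMask, ng: int = 32,
               downsample_factor: int = 1) -> QuantizedImage:
    """Full preprocessing chain: downsample, grayscale, normalize, quantize.

    The mask is assumed co-registered with the image *after* downsampling;
    pass ``downsample_factor=1`` when the image is already at analysis
    resolution.
    """
    out = downsample(img, downsample_factor)
    out = to_grayscale(out)
    out = normalize_intensity(out)
    return quantize(out, roi, ng)


def save_quantized(q: QuantizedImage, path: str | Path) -> None:
    """Write levels as TIFF with a JSON sidecar holding bin edges."""
    path = Path(path)
    tifffile.imwrite(path, q.levels.astype(np.int32))
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"ng": q.ng, "bin_edges": q.bin_edges.tolist(),
                   "pixel_spacing_um": q.pixel_spacing}, fh, indent=1)
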