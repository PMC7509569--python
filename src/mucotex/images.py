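"""Image containers and the photograph preprocessing chain.

Clinical photographs enter the pipeline as RGB or 8-bit grey images.  Before
any texture feature is computed they pass through a fixed chain that mirrors
common practice for standardizing mucosa photographs:

1. crop a region of interest (ROI, by default 300 x 300 px from the lesion
   center),
2. high-pass filter (unsharp-style residual: image minus Gaussian blur, offset
   to mid-grey 128) to maximize local contrast,
3. linear level stretch so the observed range spans the full 0-255 scale,
4. uniform quantization to 4-bit grey (16 levels), the working depth of all
   texture matrices downstream.

Images are thin dataclasses over ``numpy`` arrays; all coordinates are 0-based,
row-major, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage import exposure

from .exceptions import DegenerateDataError, ValidationError

__all__ = [
    "RgbImage",
    "GreyImage",
    "RoiSpec",
    "load_image",
    "save_image",
    "extract_roi",
    "to_grey",
    "high_pass",
    "equalize_levels",
    "quantize",
    "preprocess",
]


@dataclass(frozen=True)
class RgbImage:
    """Colour photograph: ``pixels`` is an (H, W, 3) uint8 array."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"RGB pixel array must be (H, W, 3), got {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must contain at least one pixel")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GreyImage:
    """Quantized grey image: ``pixels`` is an (H, W) integer array with values
    in ``[0, 2**bit_depth - 1]``.  4-bit images live in 8-bit containers
    holding levels 0-15."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"grey pixel array must be 2-D, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must contain at least one pixel")
        if not 1 <= self.bit_depth <= 8:
            raise ValidationError(f"bit_depth must be in 1..8, got {self.bit_depth}")
        px = px.astype(np.int64)
        if px.min() < 0 or px.max() >= 2**self.bit_depth:
            raise ValidationError(
                f"pixel values outside [0, {2**self.bit_depth - 1}] "
                f"for bit_depth={self.bit_depth}"
            )
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_levels(self) -> int:
        return 2**self.bit_depth


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular crop: ``top``/``left`` offsets plus ``height``/``width`` extents."""

    top: int
    left: int
    height: int = 300
    width: int = 300

    def __post_init__(self) -> None:
        if self.top < 0 or self.left < 0:
            raise ValidationError("ROI offsets must be non-negative")
        if self.height < 1 or self.width < 1:
            raise ValidationError("ROI extents must be positive")

    @classmethod
    def centered(cls, img_height: int, img_width: int, height: int = 300, width: int = 300) -> "RoiSpec":
        """ROI of the given extent centered in an ``img_height x img_width`` frame."""
        if height > img_height or width > img_width:
            raise ValidationError("centered ROI larger than the image")
        return cls(top=(img_height - height) // 2, left=(img_width - width) // 2,
                   height=height, width=width)


def load_image(path: str | Path) -> RgbImage | GreyImage:
    """Read a TIFF or PNG photograph.

    Greyscale files come back as 8-bit :class:`GreyImage`; colour files as
    :class:`RgbImage` (alpha channels are dropped).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("L", "I;16", "I"):
                arr = np.asarray(im.convert("L"))
                return GreyImage(arr, bit_depth=8)
            arr = np.asarray(im.convert("RGB"))
            return RgbImage(arr)
    except FileNotFoundError:
        raise
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc


def save_image(img: RgbImage | GreyImage, path: str | Path) -> None:
    """Write an image as PNG or uncompressed TIFF (by file extension).

    Sub-8-bit grey images are stored in an 8-bit container holding their raw
    levels (a 4-bit image holds values 0-15).
    """
    path = Path(path)
    pil = Image.fromarray(img.pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        pil.save(path, format="TIFF", compression=None)
    else:
        pil.save(path)


def extract_roi(img: RgbImage | GreyImage, roi: RoiSpec):
    """Crop ``roi`` out of ``img``.  The ROI must lie fully inside the image;
    out-of-bounds specs raise rather than clamp."""
    if roi.top + roi.height > img.height or roi.left + roi.width > img.width:
        raise ValidationError(
            f"ROI {roi} exceeds image bounds {img.height}x{img.width}"
        )
    sub = img.pixels[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()
    if isinstance(img, RgbImage):
        return RgbImage(sub)
    return GreyImage(sub, bit_depth=img.bit_depth)


def to_grey(img: RgbImage) -> GreyImage:
    """RGB to 8-bit grey via Rec. 601 luma: round(0.299 R + 0.587 G + 0.114 B)."""
    px = img.pixels.astype(np.float64)
    grey = np.rint(0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2])
    return GreyImage(np.clip(grey, 0, 255).astype(np.uint8), bit_depth=8)


def high_pass(img: GreyImage, radius: float = 10.0) -> GreyImage:
    """High-pass filter as the residual against a Gaussian blur.

    ``output = clip(img - gaussian_blur(img, radius) + 128)``.  ``radius`` is
    the Gaussian sigma in pixels.  A constant image maps to constant 128, and
    the output of a zero-mean texture stays centered near mid-grey.
    """
    if img.bit_depth != 8:
        raise ValidationError("high_pass expects an 8-bit grey image")
    if radius <= 0:
        raise ValidationError(f"blur radius must be positive, got {radius}")
    px = img.pixels.astype(np.float64)
    blur = ndimage.gaussian_filter(px, sigma=radius, mode="reflect")
    out = np.clip(np.rint(px - blur + 128.0), 0, 255).astype(np.uint8)
    return GreyImage(out, bit_depth=8)


def equalize_levels(img: GreyImage, mode: str = "stretch") -> GreyImage:
    """Unify image contrast.

    ``mode="stretch"`` (default) linearly maps the observed min to 0 and max to
    255, preserving the texture's grey-level ordering and relative spacing.
    ``mode="rank"`` applies classical rank-based histogram equalization instead.
    Constant images carry no contrast to unify and raise
    :class:`DegenerateDataError`.
    """
    if img.bit_depth != 8:
        raise ValidationError("equalize_levels expects an 8-bit grey image")
    px = img.pixels
    lo, hi = int(px.min()), int(px.max())
    if lo == hi:
        raise DegenerateDataError("constant image: contrast stretch is undefined")
    if mode == "stretch":
        out = np.rint((px.astype(np.float64) - lo) * (255.0 / (hi - lo)))
    elif mode == "rank":
        out = np.rint(exposure.equalize_hist(px) * 255.0)
    else:
        raise ValidationError(f"unknown equalize mode {mode!r} (use 'stretch' or 'rank')")
    return GreyImage(np.clip(out, 0, 255).astype(np.uint8), bit_depth=8)


def quantize(img: GreyImage, bit_depth: int = 4) -> GreyImage:
    """Uniformly re-bin an 8-bit image to ``bit_depth`` bits.

    ``level' = floor(level * 2**bit_depth / 256)`` — a monotone non-decreasing
    map onto ``[0, 2**bit_depth - 1]``.
    """
    if img.bit_depth != 8:
        raise ValidationError("quantize expects an 8-bit grey image")
    if not 1 <= bit_depth <= 8:
        raise ValidationError(f"target bit_depth must be in 1..8, got {bit_depth}")
    out = (img.pixels.astype(np.int64) * 2**bit_depth) // 256
    return GreyImage(out.astype(np.uint8), bit_depth=bit_depth)


def preprocess(
    img: RgbImage | GreyImage,
    roi: RoiSpec | None = None,
    highpass_radius: float = 10.0,
    equalize_mode: str = "stretch",
    bits: int = 4,
) -> GreyImage:
    """Full chain: [crop ROI] -> grey -> high-pass -> level stretch -> quantize."""
    if roi is not None:
        img = extract_roi(img, roi)
    if isinstance(img, RgbImage):
        img = to_grey(img)
    img = high_pass(img, radius=highpass_radius)
    img = equalize_levels(img, mode=equalize_mode)
    return quantize(img, bit_depth=bits)
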