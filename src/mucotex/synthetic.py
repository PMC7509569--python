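"""Synthetic two-class mucosa-like textures.

Clinical photograph sets for this problem are not publicly deposited, so the
pipeline is exercised on generated 300 x 300 textures that emulate the
qualitative contrast between the two tissue classes:

* ``normal`` — fine chaotic texture: Gaussian white noise smoothed with a
  short correlation length (default 1 px), rescaled to 8-bit grey.  Entropy is
  high and spatially even; runs are short.
* ``lesion`` — plate-organized texture: noise smoothed with a long correlation
  length (default 12 px) is quantile-thresholded into dark foci (below the
  plate-fraction quantile, default 15% of the area) set in a bright homogeneous
  surround, each plate filled with its mean level plus a little within-plate
  noise.  Homogeneous plates give long runs, low entropy, and — through the
  brightness asymmetry the dark foci induce after contrast standardization —
  high deep-scale LL wavelet energy.

Both classes share one code path, so setting the lesion correlation length to
the fine value and disabling plates makes the classes statistically
indistinguishable — a useful null for the downstream statistics.

Generation is deterministic per seed; cohorts derive per-image seeds from a
master seed through ``numpy.random.SeedSequence``, which is reproducible
across platforms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .images import GreyImage, save_image

__all__ = ["TextureParams", "normal_params", "lesion_params", "generate_image",
           "generate_cohort", "write_cohort"]

# class defaults: correlation length of the latent noise field, in pixels
FINE_CORR_LENGTH = 1.0
COARSE_CORR_LENGTH = 12.0


@dataclass(frozen=True)
class TextureParams:
    """Knobs of the texture generator.

    ``corr_length`` is the Gaussian smoothing width of the latent noise field;
    ``plate_fraction`` the quantile below which pixels form the dark foci
    plates (the rest is the bright surround); ``plate_noise_sd`` the
    within-plate grey-level noise; ``contrast`` the fraction of the 0-255
    range the texture spans.
    """

    label: str
    seed: int
    size: int = 300
    corr_length: float = FINE_CORR_LENGTH
    plates: bool = False
    plate_fraction: float = 0.15
    plate_noise_sd: float = 4.0
    contrast: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValidationError("size must be >= 64 (wavelet scale-6 feasibility)")
        if self.corr_length < 1:
            raise ValidationError("corr_length must be >= 1 pixel")
        if not 0 < self.plate_fraction < 1:
            raise ValidationError("plate_fraction must be in (0, 1)")
        if self.plate_noise_sd < 0 or not 0 < self.contrast <= 1:
            raise ValidationError("plate_noise_sd must be >= 0 and contrast in (0, 1]")


def normal_params(seed: int, **overrides) -> TextureParams:
    """Default fine-texture (normal mucosa) parameters."""
    kwargs = {"corr_length": FINE_CORR_LENGTH, "plates": False, **overrides}
    return TextureParams(label="normal", seed=seed, **kwargs)


def lesion_params(seed: int, **overrides) -> TextureParams:
    """Default plate-texture (lesion) parameters."""
    kwargs = {"corr_length": COARSE_CORR_LENGTH, "plates": True, **overrides}
    return TextureParams(label="lesion", seed=seed, **kwargs)


def generate_image(params: TextureParams) -> GreyImage:
    """Render one 8-bit texture from its parameters (deterministic per seed)."""
    rng = np.random.default_rng(params.seed)
    field = ndimage.gaussian_filter(
        rng.standard_normal((params.size, params.size)), sigma=params.corr_length,
        mode="reflect")
    if params.plates:
        field = _platify(field, params.plate_fraction)
    lo, hi = float(field.min()), float(field.max())
    if hi == lo:  # cannot happen for a noise field, but keep the contract total
        grey = np.full_like(field, 128.0)
    else:
        grey = 128.0 + ((field - lo) / (hi - lo) - 0.5) * (params.contrast * 255.0)
    if params.plates and params.plate_noise_sd > 0:
        grey = grey + rng.normal(0.0, params.plate_noise_sd, grey.shape)
    return GreyImage(np.clip(np.rint(grey), 0, 255).astype(np.uint8), bit_depth=8)


def _platify(field: np.ndarray, fraction: float) -> np.ndarray:
    """Quantile-threshold a smooth field into two plate sets.

    Pixels below the ``fraction`` quantile become the dark foci, the rest the
    bright surround; each set is filled with its mean field value.  Small dark
    foci embedded in a brighter plate reproduce the characteristic lesion
    appearance and its brightness asymmetry.
    """
    thr = np.quantile(field, fraction)
    dark = field <= thr
    out = np.empty_like(field)
    out[dark] = field[dark].mean()
    out[~dark] = field[~dark].mean()
    return out


def generate_cohort(n_per_class: int, seed: int, size: int = 300,
                    normal_overrides: dict | None = None,
                    lesion_overrides: dict | None = None,
                    ) -> tuple[list[GreyImage], list[str]]:
    """Generate a labelled cohort of ``n_per_class`` images per class.

    Per-image seeds are spawned deterministically from the master seed, so the
    same master seed always yields the identical cohort.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    child = np.random.SeedSequence(seed).generate_state(2 * n_per_class, dtype=np.uint32)
    child = (child & 0x7FFFFFFF).astype(np.int64)
    images: list[GreyImage] = []
    labels: list[str] = []
    for i in range(n_per_class):
        p = normal_params(int(child[2 * i]), size=size, **(normal_overrides or {}))
        images.append(generate_image(p))
        labels.append("normal")
        p = lesion_params(int(child[2 * i + 1]), size=size, **(lesion_overrides or {}))
        images.append(generate_image(p))
        labels.append("lesion")
    return images, labels


def write_cohort(images: list[GreyImage], labels: list[str], out_dir: str | Path,
                 fmt: str = "png") -> Path:
    """Write a cohort as numbered image files plus a ``labels.csv`` manifest.

    Returns the manifest path.
    """
    if fmt not in ("png", "tiff"):
        raise ValidationError("fmt must be 'png' or 'tiff'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "png" if fmt == "png" else "tif"
    manifest = out_dir / "labels.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, lab) in enumerate(zip(images, labels)):
            name = f"{i:04d}_{lab}.{ext}"
            save_image(img, out_dir / name)
            writer.writerow([name, lab])
    return manifest
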