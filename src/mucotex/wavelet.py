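"""2-D discrete Haar wavelet decomposition and LL-subband energies.

One analysis step splits a grid into four half-resolution subbands with the
orthonormal Haar pair L = [1/sqrt2, 1/sqrt2], H = [1/sqrt2, -1/sqrt2]:
LL (approximation), LH, HL, HH (details).  Scales are obtained by recursing
on LL.  With orthonormal filters each step conserves energy (Parseval), and a
constant image of level c has every LL coefficient equal to c * 2**s at scale
s, all details zero.

Odd subband dimensions are truncated to even before pairing (floor halving),
so a 300 x 300 region decomposes as 300 -> 150 -> 75 -> 37 -> 18 -> 9 -> 4,
which makes scale 6 feasible on the standard region of interest.

The subband energy reported as a texture feature is

    E_{subband, scale} = sum_xy d(x, y)^2 / n

with n the number of coefficients in that subband.  Deep-scale LL energy
captures large-scale brightness organization: plate-like textures score higher
than fine-grained ones at matched global contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .images import GreyImage

__all__ = ["WaveletDecomposition", "haar_decompose", "wavelet_energy", "ll_energies"]

SUBBANDS = ("LL", "LH", "HL", "HH")


@dataclass(frozen=True)
class WaveletDecomposition:
    """Subband coefficient grids keyed by (scale, subband); scale = 1..max_scale."""

    subbands: dict[tuple[int, str], np.ndarray]
    max_scale: int

    def band(self, scale: int, subband: str) -> np.ndarray:
        if subband not in SUBBANDS:
            raise ValidationError(f"subband must be one of {SUBBANDS}, got {subband!r}")
        if not 1 <= scale <= self.max_scale:
            raise ValidationError(
                f"scale {scale} unavailable (decomposition holds scales 1..{self.max_scale})"
            )
        return self.subbands[(scale, subband)]


def _haar_step(x: np.ndarray) -> dict[str, np.ndarray]:
    """One orthonormal 2-D Haar analysis step with floor truncation of odd dims."""
    h, w = x.shape
    x = x[: h - h % 2, : w - w % 2]
    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    return {
        "LL": (a + b + c + d) / 2.0,
        "LH": (a - b + c - d) / 2.0,
        "HL": (a + b - c - d) / 2.0,
        "HH": (a - b - c + d) / 2.0,
    }


def haar_decompose(img: GreyImage, max_scale: int) -> WaveletDecomposition:
    """Recursive Haar analysis of the LL band down to ``max_scale`` levels."""
    if max_scale < 1:
        raise ValidationError("max_scale must be >= 1")
    feasible = int(np.floor(np.log2(min(img.height, img.width))))
    if min(img.height, img.width) < 2**max_scale:
        raise ValidationError(
            f"image {img.height}x{img.width} too small for {max_scale} scales; "
            f"maximum feasible scale is {feasible}"
        )
    bands: dict[tuple[int, str], np.ndarray] = {}
    ll = img.pixels.astype(np.float64)
    for s in range(1, max_scale + 1):
        step = _haar_step(ll)
        for name in SUBBANDS:
            bands[(s, name)] = step[name]
        ll = step["LL"]
    return WaveletDecomposition(subbands=bands, max_scale=max_scale)


def wavelet_energy(dec: WaveletDecomposition, subband: str = "LL", scale: int = 5) -> float:
    """Mean squared coefficient of one subband: E = sum d^2 / n."""
    d = dec.band(scale, subband)
    return float((d.astype(np.float64) ** 2).sum() / d.size)


def ll_energies(img: GreyImage, scales: tuple[int, ...] = (5, 6)) -> dict[str, float]:
    """LL-subband energies at the requested scales, keyed ``WavEnLL_s<scale>``."""
    dec = haar_decompose(img, max_scale=max(scales))
    return {f"WavEnLL_s{s}": wavelet_energy(dec, "LL", s) for s in scales}
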