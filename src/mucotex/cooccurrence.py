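"""Grey-level co-occurrence matrix (GLCM) entropy features.

The GLCM at displacement (distance ``d``, direction ``theta``) is the
normalized joint distribution ``p(i, j)`` of grey-level pairs separated by
that displacement.  Counting is symmetric (each ordered pair and its transpose
both contribute), borders are not padded, and the normalizer is the realized
number of valid pairs — so ``p`` always sums to 1 and is symmetric.

Two Shannon statistics are computed, in nats (natural log):

    Entropy   = -sum_ij p(i, j) log p(i, j)
    DifEntrp  = -sum_k  p_{x-y}(k) log p_{x-y}(k)

where ``p_{x-y}(k) = sum_{|i-j|=k} p(i, j)`` is the absolute-difference
marginal.  Difference entropy can never exceed entropy (the map
``(i, j) -> |i - j|`` only merges outcomes).  The screening pipeline uses
inter-pixel distance 5 and averages both features over the four principal
directions; chessboard geometry is used on the diagonals (45 degrees at
distance d pairs pixels offset by (-d, +d)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .images import GreyImage

__all__ = [
    "ANGLES",
    "CoocMatrix",
    "cooccurrence_matrix",
    "entropy",
    "difference_entropy",
    "cooccurrence_features",
    "entropy_map",
]

ANGLES = (0, 45, 90, 135)

# pixel offset (drow, dcol) of the second pixel of a pair, per direction
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class CoocMatrix:
    """Normalized symmetric co-occurrence distribution ``p[i, j]``."""

    p: np.ndarray  # (n_levels, n_levels) float64, sums to 1
    n_levels: int
    distance: int
    angle: int

    @property
    def diff_marginal(self) -> np.ndarray:
        """p_{x-y}(k) for k = 0..n_levels-1."""
        i, j = np.indices(self.p.shape)
        k = np.abs(i - j)
        out = np.zeros(self.n_levels)
        np.add.at(out, k.ravel(), self.p.ravel())
        return out

    @property
    def px(self) -> np.ndarray:
        """Row-sum marginal p_x(i)."""
        return self.p.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        """Column-sum marginal p_y(j)."""
        return self.p.sum(axis=0)

    @property
    def mu_x(self) -> float:
        return float(np.arange(self.n_levels) @ self.px)

    @property
    def mu_y(self) -> float:
        return float(np.arange(self.n_levels) @ self.py)

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.n_levels)
        return float(np.sqrt((i - self.mu_x) ** 2 @ self.px))

    @property
    def sigma_y(self) -> float:
        j = np.arange(self.n_levels)
        return float(np.sqrt((j - self.mu_y) ** 2 @ self.py))


def cooccurrence_matrix(img: GreyImage, distance: int = 5, angle: int = 0) -> CoocMatrix:
    """Build the symmetric, normalized GLCM of ``img`` at one displacement.

    The image extent along the displacement must strictly exceed ``distance``
    so at least one pair exists; pairs with either pixel outside the image are
    simply skipped (no padding).
    """
    if angle not in _OFFSETS:
        raise ValidationError(f"angle must be one of {ANGLES}, got {angle}")
    if distance < 1:
        raise ValidationError(f"distance must be >= 1, got {distance}")
    drow, dcol = (o * distance for o in _OFFSETS[angle])
    h, w = img.height, img.width
    if abs(drow) >= h and drow != 0:
        raise ValidationError(f"distance {distance} >= image height {h} along angle {angle}")
    if abs(dcol) >= w and dcol != 0:
        raise ValidationError(f"distance {distance} >= image width {w} along angle {angle}")
    px = img.pixels.astype(np.int64)
    r0, r1 = max(0, -drow), h - max(0, drow)
    c0, c1 = max(0, -dcol), w - max(0, dcol)
    a = px[r0:r1, c0:c1].ravel()
    b = px[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol].ravel()
    n = img.n_levels
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    counts = counts + counts.T  # symmetric accumulation
    p = counts / counts.sum()
    return CoocMatrix(p=p, n_levels=n, distance=distance, angle=angle)


def _check_normalized(com: CoocMatrix) -> None:
    if abs(float(com.p.sum()) - 1.0) > 1e-8 or (com.p < 0).any():
        raise ValidationError("co-occurrence matrix is not a normalized distribution")


def _shannon(p: np.ndarray) -> float:
    """-sum p log p in nats, with 0 log 0 = 0."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy(com: CoocMatrix) -> float:
    """Joint entropy of the pair distribution, in [0, 2 log N_g] nats."""
    _check_normalized(com)
    return _shannon(com.p.ravel())


def difference_entropy(com: CoocMatrix) -> float:
    """Entropy of the |i-j| marginal, in [0, log N_g] nats."""
    _check_normalized(com)
    return _shannon(com.diff_marginal)


def cooccurrence_features(img: GreyImage, distance: int = 5) -> dict[str, float]:
    """Direction-averaged entropy and difference entropy at one distance,
    plus per-direction values keyed ``Entropy_0`` etc."""
    out: dict[str, float] = {}
    ent, dif = [], []
    for a in ANGLES:
        com = cooccurrence_matrix(img, distance=distance, angle=a)
        e, de = entropy(com), difference_entropy(com)
        out[f"Entropy_{a}"] = e
        out[f"DifEntrp_{a}"] = de
        ent.append(e)
        dif.append(de)
    out["Entropy"] = float(np.mean(ent))
    out["DifEntrp"] = float(np.mean(dif))
    return out


def entropy_map(img: GreyImage, window: int = 31, distance: int = 5, step: int = 1) -> np.ndarray:
    """Sliding-window local GLCM entropy map (direction-averaged)."""
    if window <= distance:
        raise ValidationError("window must exceed the co-occurrence distance")
    if window > min(img.height, img.width):
        raise ValidationError("window larger than the image")
    px = img.pixels
    h_out = (img.height - window) // step + 1
    w_out = (img.width - window) // step + 1
    out = np.empty((h_out, w_out), dtype=np.float64)
    for r in range(h_out):
        for c in range(w_out):
            sub = GreyImage(px[r * step : r * step + window, c * step : c * step + window],
                            bit_depth=img.bit_depth)
            vals = [entropy(cooccurrence_matrix(sub, distance=distance, angle=a))
                    for a in ANGLES]
            out[r, c] = np.mean(vals)
    return out
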