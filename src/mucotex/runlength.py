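"""Grey-level run-length matrix (RLM) features.

A *run* is a maximal string of pixels with the same grey level along a scan
line.  ``p(i, j)`` counts runs of level ``i`` (``i = 0..N_g - 1``) and length
``j`` (``j = 1..N_r``); ``C = sum p(i, j)`` is the total number of runs.  The
two emphasis statistics used here are the inverse-moment forms

    LngREmph = sum_ij j^2 p(i, j) / C        (long-run emphasis)
    ShrtREmph = sum_ij p(i, j) / j^2 / C     (short-run emphasis)

LngREmph >= 1 with equality iff every run has length 1; ShrtREmph is in
(0, 1] with equality at 1 under the same condition.  Scan directions are the
four principal ones (0, 45, 90, 135 degrees); classifier-facing features are
the mean over the four, which removes orientation dependence, while
per-direction values remain available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, ValidationError
from .images import GreyImage

__all__ = [
    "DIRECTIONS",
    "RunLengthMatrix",
    "run_length_matrix",
    "long_run_emphasis",
    "short_run_emphasis",
    "run_length_features",
    "short_run_emphasis_map",
]

DIRECTIONS = (0, 45, 90, 135)


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts ``counts[i, j-1]`` for grey level ``i`` and run length ``j``."""

    counts: np.ndarray  # (n_levels, max_run_length) int64
    n_levels: int
    max_run_length: int
    direction: int

    @property
    def total_runs(self) -> int:
        """C — the number of maximal runs counted."""
        return int(self.counts.sum())


def _scan_lines(pixels: np.ndarray, direction: int):
    """Yield the 1-D scan lines of ``pixels`` for a principal direction."""
    if direction == 0:
        yield from pixels
    elif direction == 90:
        yield from pixels.T
    elif direction in (45, 135):
        # 135 deg runs along main diagonals; 45 deg along anti-diagonals.
        grid = np.fliplr(pixels) if direction == 45 else pixels
        h, w = grid.shape
        for off in range(-(h - 1), w):
            yield np.diagonal(grid, offset=off)
    else:
        raise ValidationError(f"direction must be one of {DIRECTIONS}, got {direction}")


def run_length_matrix(img: GreyImage, direction: int = 0) -> RunLengthMatrix:
    """Count maximal runs of ``img`` along one principal direction.

    ``max_run_length`` is max(height, width), the longest run any scan line
    could hold; trailing all-zero columns are permitted.
    """
    px = img.pixels
    if px.size == 0:
        raise ValidationError("empty image")
    n_levels = img.n_levels
    n_r = max(px.shape)
    counts = np.zeros((n_levels, n_r), dtype=np.int64)
    for line in _scan_lines(px, direction):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # maximal runs: split at value changes
        breaks = np.flatnonzero(np.diff(line))
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [line.size - 1]))
        lengths = ends - starts + 1
        np.add.at(counts, (line[starts].astype(np.int64), lengths - 1), 1)
    return RunLengthMatrix(counts=counts, n_levels=n_levels, max_run_length=n_r,
                           direction=direction)


def _check_nonempty(rlm: RunLengthMatrix) -> int:
    c = rlm.total_runs
    if c == 0:
        raise DegenerateDataError("run-length matrix holds no runs (C = 0)")
    return c


def long_run_emphasis(rlm: RunLengthMatrix) -> float:
    """LngREmph = sum_ij j^2 p(i, j) / C."""
    c = _check_nonempty(rlm)
    j = np.arange(1, rlm.max_run_length + 1, dtype=np.float64)
    return float((rlm.counts.sum(axis=0) * j**2).sum() / c)


def short_run_emphasis(rlm: RunLengthMatrix) -> float:
    """ShrtREmph = sum_ij p(i, j) / j^2 / C."""
    c = _check_nonempty(rlm)
    j = np.arange(1, rlm.max_run_length + 1, dtype=np.float64)
    return float((rlm.counts.sum(axis=0) / j**2).sum() / c)


def run_length_features(img: GreyImage) -> dict[str, float]:
    """Direction-averaged RLM features plus the per-direction values.

    Returns ``{"LngREmph": ..., "ShrtREmph": ..., "LngREmph_0": ..., ...}``.
    """
    out: dict[str, float] = {}
    lng, shrt = [], []
    for d in DIRECTIONS:
        rlm = run_length_matrix(img, direction=d)
        l, s = long_run_emphasis(rlm), short_run_emphasis(rlm)
        out[f"LngREmph_{d}"] = l
        out[f"ShrtREmph_{d}"] = s
        lng.append(l)
        shrt.append(s)
    out["LngREmph"] = float(np.mean(lng))
    out["ShrtREmph"] = float(np.mean(shrt))
    return out


def short_run_emphasis_map(img: GreyImage, window: int = 15, step: int = 1) -> np.ndarray:
    """Per-pixel local short-run-emphasis map over a sliding square window.

    Returns a float array of shape ``((H - window)//step + 1,
    (W - window)//step + 1)`` with the direction-averaged ShrtREmph of each
    window — the "feature map" rendering used for lesion overlays.
    """
    if window < 2 or window > min(img.height, img.width):
        raise ValidationError("window must be >= 2 and fit inside the image")
    px = img.pixels
    h_out = (img.height - window) // step + 1
    w_out = (img.width - window) // step + 1
    out = np.empty((h_out, w_out), dtype=np.float64)
    for r in range(h_out):
        for c in range(w_out):
            sub = GreyImage(px[r * step : r * step + window, c * step : c * step + window],
                            bit_depth=img.bit_depth)
            vals = [short_run_emphasis(run_length_matrix(sub, d)) for d in DIRECTIONS]
            out[r, c] = np.mean(vals)
    return out
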