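"""Six-feature texture vector and feature-table assembly.

The screening feature set is: long- and short-run emphasis (run-length
matrix), entropy and difference entropy (co-occurrence matrix at distance 5),
and LL-subband Haar wavelet energy at scales 5 and 6.  All matrix features are
averaged over the four principal directions.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import pandas as pd

from .cooccurrence import cooccurrence_features
from .exceptions import ValidationError
from .images import GreyImage
from .runlength import run_length_features
from .wavelet import ll_energies

__all__ = ["FEATURE_COLUMNS", "LABELS", "extract_features", "build_feature_table",
           "validate_feature_table"]

FEATURE_COLUMNS = ("LngREmph", "ShrtREmph", "Entropy", "DifEntrp", "WavEnLL_s5", "WavEnLL_s6")
LABELS = ("normal", "lesion")


def extract_features(img: GreyImage, glcm_distance: int = 5,
                     wavelet_scales: tuple[int, ...] = (5, 6)) -> dict[str, float]:
    """Compute the six texture features of one preprocessed grey image."""
    out: dict[str, float] = {}
    rl = run_length_features(img)
    co = cooccurrence_features(img, distance=glcm_distance)
    out["LngREmph"] = rl["LngREmph"]
    out["ShrtREmph"] = rl["ShrtREmph"]
    out["Entropy"] = co["Entropy"]
    out["DifEntrp"] = co["DifEntrp"]
    out.update(ll_energies(img, scales=wavelet_scales))
    return out


def build_feature_table(images: Iterable[GreyImage], labels: Sequence[str],
                        glcm_distance: int = 5) -> pd.DataFrame:
    """Feature table: one row per image, six feature columns plus ``label``."""
    images = list(images)
    if len(images) != len(labels):
        raise ValidationError(f"{len(images)} images but {len(labels)} labels")
    rows = []
    for img, lab in zip(images, labels):
        row = extract_features(img, glcm_distance=glcm_distance)
        row["label"] = lab
        rows.append(row)
    table = pd.DataFrame(rows, columns=[*FEATURE_COLUMNS, "label"])
    validate_feature_table(table)
    return table


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check the feature-table contract: all six columns, binary labels, no NaN."""
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}")
    if "label" not in table.columns:
        raise ValidationError("feature table missing 'label' column")
    if table[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValidationError("feature table contains missing values")
    bad = set(table["label"]) - set(LABELS)
    if bad:
        raise ValidationError(f"unknown labels {sorted(bad)}; expected {LABELS}")
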