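"""Probabilistic neural network (Parzen-kernel density classifier).

Specht's classical PNN: features are z-scored with training statistics, each
class k keeps its training vectors verbatim (no iterative training), and the
class score of a query x is the prior times the mean isotropic Gaussian
kernel over the class's standardized training vectors,

    score_k(x) = prior_k * (1/n_k) * sum_i exp(-||z(x) - z_i||^2 / (2 sigma^2)).

Prediction is the argmax; an exact tie goes to the positive (lesion) class —
in a screening instrument a false negative is costlier than a false positive.
The smoothing width sigma lives in standardized-feature units and is tuned by
maximizing leave-one-out (LOO) accuracy over a grid.  Evaluation is LOO with
standardization re-estimated inside every fold, which also makes the
evaluated metrics exactly invariant to affine rescaling of any input column.

The screening model uses three inputs: ShrtREmph, Entropy and WavEnLL_s5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError
from .features import validate_feature_table

__all__ = [
    "PNN_FEATURES",
    "DEFAULT_SIGMA_GRID",
    "PNNModel",
    "ConfusionCounts",
    "fit",
    "fit_table",
    "class_score",
    "predict",
    "evaluate_loo",
    "evaluate_loo_table",
    "evaluate_resubstitution",
    "select_sigma",
]

PNN_FEATURES = ("ShrtREmph", "Entropy", "WavEnLL_s5")

# sigma grid in standardized units; spans very local kernels to near-linear ones
DEFAULT_SIGMA_GRID = tuple(np.round(np.geomspace(0.05, 3.0, 25), 6))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with the lesion class positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        """TP / (TP + FN) — fraction of lesions recognized."""
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """TN / (TN + FP) — fraction of normal mucosa recognized."""
        return self.tn / (self.tn + self.fp)

    def percent_metrics(self, ndigits: int = 0) -> dict[str, float]:
        """Sensitivity and specificity as rounded percentages."""
        return {
            "sensitivity_pct": round(100.0 * self.sensitivity, ndigits),
            "specificity_pct": round(100.0 * self.specificity, ndigits),
        }


@dataclass(frozen=True)
class PNNModel:
    labels: tuple[str, ...]
    patterns: tuple[np.ndarray, ...]  # standardized training vectors per class
    priors: tuple[float, ...]
    sigma: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    positive_label: str = "lesion"


def _standardize_params(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.ones(x.shape[1])
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateDataError(f"zero training SD in feature column(s) {bad}")
    return mean, sd


def fit(x: np.ndarray, y, sigma: float, priors: dict[str, float] | None = None,
        positive_label: str = "lesion") -> PNNModel:
    """Fit a PNN: z-score the features and store each class's vectors.

    ``priors`` defaults to the empirical class frequencies.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValidationError("x must be (n, d) with one label per row")
    if sigma <= 0:
        raise ValidationError(f"sigma must be positive, got {sigma}")
    labels = tuple(dict.fromkeys(y.tolist()))  # first-appearance order
    if len(labels) < 2:
        raise ValidationError("need at least two classes")
    mean, sd = _standardize_params(x)
    z = (x - mean) / sd
    patterns = tuple(z[y == lab] for lab in labels)
    if priors is None:
        pri = tuple(len(p) / len(y) for p in patterns)
    else:
        pri = tuple(float(priors[lab]) for lab in labels)
        if abs(sum(pri) - 1.0) > 1e-9:
            raise ValidationError("priors must sum to 1")
    return PNNModel(labels=labels, patterns=patterns, priors=pri, sigma=float(sigma),
                    feature_mean=mean, feature_sd=sd, positive_label=positive_label)


def fit_table(table: pd.DataFrame, sigma: float,
              features: tuple[str, ...] = PNN_FEATURES) -> PNNModel:
    """Fit on a feature table using the screening feature triple."""
    validate_feature_table(table)
    x = table[list(features)].to_numpy(dtype=np.float64)
    return fit(x, table["label"].to_numpy(), sigma=sigma)


def class_score(model: PNNModel, x) -> dict[str, float]:
    """Per-class Parzen score of one query vector (unnormalized posterior)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != model.feature_mean.shape:
        raise ValidationError(
            f"query has {x.shape} features, model expects {model.feature_mean.shape}")
    z = (x - model.feature_mean) / model.feature_sd
    out = {}
    for lab, pats, pri in zip(model.labels, model.patterns, model.priors):
        d2 = ((pats - z) ** 2).sum(axis=1)
        out[lab] = float(pri * np.exp(-d2 / (2.0 * model.sigma**2)).mean())
    return out


def predict(model: PNNModel, x) -> str:
    """Argmax class; exact ties resolve to the positive (lesion) class."""
    scores = class_score(model, x)
    best = max(scores.values())
    winners = [lab for lab, s in scores.items() if s == best]
    if len(winners) > 1 and model.positive_label in winners:
        return model.positive_label
    return winners[0]


def _loo_predictions(x: np.ndarray, y: np.ndarray, sigma: float,
                     positive_label: str) -> np.ndarray:
    n = x.shape[0]
    preds = np.empty(n, dtype=object)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit(x[keep], y[keep], sigma=sigma, positive_label=positive_label)
        preds[i] = predict(model, x[i])
    return preds


def evaluate_loo(x, y, sigma: float, positive_label: str = "lesion"
                 ) -> tuple[ConfusionCounts, float, float]:
    """Leave-one-out evaluation.

    Each case is predicted by a model fitted on all other cases, with feature
    standardization re-estimated per fold.  Returns the confusion counts plus
    sensitivity and specificity as fractions.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValidationError("LOO evaluation needs two classes with >= 2 cases each")
    if positive_label not in classes:
        raise ValidationError(f"positive label {positive_label!r} absent from labels")
    preds = _loo_predictions(x, y, sigma, positive_label)
    pos = y == positive_label
    hit = preds == y
    cc = ConfusionCounts(tp=int((pos & hit).sum()), fn=int((pos & ~hit).sum()),
                         tn=int((~pos & hit).sum()), fp=int((~pos & ~hit).sum()))
    return cc, cc.sensitivity, cc.specificity


def evaluate_loo_table(table: pd.DataFrame, sigma: float,
                       features: tuple[str, ...] = PNN_FEATURES
                       ) -> tuple[ConfusionCounts, float, float]:
    validate_feature_table(table)
    x = table[list(features)].to_numpy(dtype=np.float64)
    return evaluate_loo(x, table["label"].to_numpy(), sigma=sigma)


def evaluate_resubstitution(x, y, sigma: float, positive_label: str = "lesion"
                            ) -> ConfusionCounts:
    """Training-set (resubstitution) confusion counts, for comparison with LOO."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    model = fit(x, y, sigma=sigma, positive_label=positive_label)
    preds = np.array([predict(model, xi) for xi in x], dtype=object)
    pos = y == positive_label
    hit = preds == y
    return ConfusionCounts(tp=int((pos & hit).sum()), fn=int((pos & ~hit).sum()),
                           tn=int((~pos & hit).sum()), fp=int((~pos & ~hit).sum()))


def select_sigma(x, y, grid=DEFAULT_SIGMA_GRID, positive_label: str = "lesion") -> float:
    """Grid-search sigma by LOO accuracy; ties resolve to the smallest sigma."""
    grid = [float(s) for s in grid]
    if not grid:
        raise ValidationError("sigma grid is empty")
    if any(s <= 0 for s in grid):
        raise ValidationError("sigma candidates must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    best_sigma, best_acc = None, -1.0
    for s in sorted(grid):
        preds = _loo_predictions(x, y, s, positive_label)
        acc = float((preds == y).mean())
        if acc > best_acc:
            best_sigma, best_acc = s, acc
    return best_sigma
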