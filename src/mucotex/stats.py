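"""Two-group feature statistics: normality screening and one-way ANOVA.

Each feature is summarized per group as mean +/- sample SD (n-1 denominator),
screened for normality with the Shapiro-Wilk test, and compared between
groups with a one-way ANOVA (two groups, so F with df (1, n_A + n_B - 2) and
F = t^2 of the pooled two-sample t).  The normality flag is reported but does
not gate the ANOVA: non-normal features are still tested, mirroring standard
reporting practice for this kind of feature table.  Significance threshold
throughout is p < 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, ValidationError
from .features import FEATURE_COLUMNS, LABELS, validate_feature_table

__all__ = ["shapiro_wilk", "one_way_anova", "summarize", "render_summary"]

ALPHA = 0.05


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston's algorithm via scipy).

    Returns ``(W, p)``; samples with p < 0.05 are flagged as lacking a normal
    distribution in the group summary.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs a 1-D sample with 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def one_way_anova(group_a, group_b) -> tuple[float, float]:
    """One-way ANOVA between two samples: returns ``(F, p)``.

    With two groups this is algebraically the squared pooled two-sample t.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            raise DegenerateDataError("zero within-group variance and equal means: F undefined")
        return float("inf"), 0.0
    f, p = sps.f_oneway(a, b)
    return float(f), float(p)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Group summary of a feature table, one row per feature.

    Columns: per-group mean and sample SD, per-group normality flag
    (Shapiro-Wilk p >= 0.05), ANOVA F and p, and a significance flag at 0.05.
    """
    validate_feature_table(table)
    normal = table[table["label"] == "normal"]
    lesion = table[table["label"] == "lesion"]
    for name, grp in zip(LABELS, (normal, lesion)):
        if len(grp) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 rows")
    rows = []
    for feat in FEATURE_COLUMNS:
        a = normal[feat].to_numpy(dtype=np.float64)
        b = lesion[feat].to_numpy(dtype=np.float64)
        try:
            f, p = one_way_anova(a, b)
        except DegenerateDataError:
            f, p = 0.0, 1.0
        rows.append({
            "feature": feat,
            "normal_mean": a.mean(),
            "normal_sd": a.std(ddof=1),
            "normal_is_gaussian": _gaussian_flag(a),
            "lesion_mean": b.mean(),
            "lesion_sd": b.std(ddof=1),
            "lesion_is_gaussian": _gaussian_flag(b),
            "F": f,
            "p": p,
            "significant": p < ALPHA,
        })
    return pd.DataFrame(rows).set_index("feature")


def _gaussian_flag(x: np.ndarray) -> bool:
    try:
        _, p = shapiro_wilk(x)
    except (ValidationError, DegenerateDataError):
        return False
    return p >= ALPHA


def render_summary(summary: pd.DataFrame) -> str:
    """Plain-text rendering in the 'mean +/- SD' style of a clinical table;
    an asterisk marks groups flagged as lacking a normal distribution."""
    lines = [f"{'Textural feature':<14} {'normal mucosa':>20} {'lesion':>20} {'ANOVA':>22}"]
    for feat, r in summary.iterrows():
        na = "*" if not r["normal_is_gaussian"] else ""
        la = "*" if not r["lesion_is_gaussian"] else ""
        lines.append(
            f"{feat:<14} "
            f"{r['normal_mean']:>12.4g} ± {r['normal_sd']:<.4g}{na:<2} "
            f"{r['lesion_mean']:>12.4g} ± {r['lesion_sd']:<.4g}{la:<2} "
            f"F = {r['F']:.3g}; p = {r['p']:.3g}"
        )
    lines.append("* lack of normal distribution (Shapiro-Wilk p < 0.05)")
    return "\n".join(lines)
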