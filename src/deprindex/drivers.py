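"""Item-level attribution of poor index agreement.

For a given extreme-decile comparison, each indicator item is compared
between the poor- and good-agreement tract groups with a two-sided Welch
(unequal-variance) t-test, and the standardized mean difference is reported
as Cohen's D with the classic pooled-SD denominator. Effects are classified
negligible/small/medium/large at |D| thresholds 0.20 / 0.50 / 0.80, and an
item is flagged a *driver* of poor agreement when its comparison is
significant at p < 0.05 with a large effect. Items are compared on two
scales: their native scale (proportions in [0, 1] are multiplied by 100
first, dollars stay in dollars) and their national percentile-rank scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ADI_DOLLAR_ITEMS, ALL_ITEMS

__all__ = [
    "welch_ttest",
    "cohens_d",
    "classify_effect",
    "compare_items",
    "select_drivers",
    "urban_fractions",
    "EFFECT_THRESHOLDS",
]

#: |Cohen's D| lower bounds of the small / medium / large classes.
EFFECT_THRESHOLDS: tuple[float, float, float] = (0.20, 0.50, 0.80)

#: Items stored as proportions in [0, 1]; these are rescaled x100 before
#: group comparison so their means print on a 0-100 scale. Dollar items and
#: the unitless income-disparity ratio are compared on their native scale.
PROPORTION_ITEMS: frozenset[str] = frozenset(ALL_ITEMS) - ADI_DOLLAR_ITEMS - frozenset(
    {"per_capita_income", "income_disparity"}
)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch-Satterthwaite df, p)."""
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def student_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided pooled-variance (Student) t-test; returns (t, df, p)."""
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray, denominator: str = "pooled") -> float:
    """Cohen's D of group a minus group b.

    The default denominator is the pooled SD
    ``sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))``; ``denominator="glass"``
    uses the second (control) group's SD instead (Glass's delta). A zero
    denominator leaves D undefined (NaN).
    """
    n1, n2 = len(a), len(b)
    s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
    if denominator == "pooled":
        denom = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    elif denominator == "glass":
        denom = np.sqrt(s2)
    else:
        raise ValueError(f"unknown Cohen's D denominator {denominator!r}")
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float((np.mean(a) - np.mean(b)) / denom)


def classify_effect(d: float) -> str:
    """Effect-size class of |d|: negligible < 0.20 <= small < 0.50 <= medium < 0.80 <= large."""
    if not np.isfinite(d):
        return "undefined"
    small, medium, large = EFFECT_THRESHOLDS
    a = abs(d)
    if a < small:
        return "negligible"
    if a < medium:
        return "small"
    if a < large:
        return "medium"
    return "large"


def compare_items(
    poor_group: pd.DataFrame,
    good_group: pd.DataFrame,
    items: list[str] | None = None,
    comparison_label: str = "",
    test: str = "welch",
    d_denominator: str = "pooled",
    rescale_items: frozenset[str] | set[str] | None = None,
) -> pd.DataFrame:
    """Per-item poor-vs-good group comparison table.

    ``poor_group`` / ``good_group`` are tract item tables (one column per
    item, one row per tract). Columns in ``rescale_items`` (default: the
    catalogued proportion items) are multiplied by 100 before comparison so
    means print on the 0-100 scale the reports use. Returns one row per item
    with means, Welch t / df / p, signed Cohen's D (poor minus good), effect
    class, and the driver flag set by :func:`select_drivers`.
    """
    if items is None:
        items = [c for c in poor_group.columns if c in good_group.columns]
    if rescale_items is None:
        rescale_items = PROPORTION_ITEMS
    ttest = welch_ttest if test == "welch" else student_ttest
    rows = []
    for item in items:
        a = poor_group[item].to_numpy(dtype=float)
        b = good_group[item].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {
                    "comparison_label": comparison_label,
                    "item": item,
                    "n_poor": len(a),
                    "n_good": len(b),
                    "mean_poor": float(np.mean(a)) if len(a) else float("nan"),
                    "mean_good": float(np.mean(b)) if len(b) else float("nan"),
                    "t_statistic": float("nan"),
                    "degrees_freedom": float("nan"),
                    "p_value": float("nan"),
                    "cohens_d": float("nan"),
                    "effect_class": "undefined",
                }
            )
            continue
        if item in rescale_items:
            a, b = a * 100.0, b * 100.0
        t, df, p = ttest(a, b)
        d = cohens_d(a, b, d_denominator)
        rows.append(
            {
                "comparison_label": comparison_label,
                "item": item,
                "n_poor": len(a),
                "n_good": len(b),
                "mean_poor": float(np.mean(a)),
                "mean_good": float(np.mean(b)),
                "t_statistic": t,
                "degrees_freedom": df,
                "p_value": p,
                "cohens_d": d,
                "effect_class": classify_effect(d),
            }
        )
    return select_drivers(pd.DataFrame(rows))


def select_drivers(
    comparisons: pd.DataFrame,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Flag driver items: significant (p < alpha) with a large effect.

    No multiple-testing adjustment is applied by default;
    ``adjust="benjamini-hochberg"`` replaces the raw p-value criterion with a
    BH-adjusted one at the same alpha.
    """
    out = comparisons.copy()
    p = out["p_value"].to_numpy(dtype=float)
    if adjust == "benjamini-hochberg":
        ok = np.isfinite(p)
        padj = np.full_like(p, np.nan)
        if ok.any():
            padj[ok] = stats.false_discovery_control(p[ok], method="bh")
        p = padj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["is_driver"] = (p < alpha) & (out["effect_class"] == "large")
    return out


def urban_fractions(groups: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Urban tract share per comparison subgroup.

    ``groups`` maps a group key (e.g. ``"2b"``) to a tract table with a
    boolean ``urban`` column. Returns columns ``group, n, n_urban,
    urban_share``.
    """
    rows = []
    for key, df in groups.items():
        n = len(df)
        n_urban = int(df["urban"].astype(bool).sum()) if n else 0
        rows.append(
            {
                "group": key,
                "n": n,
                "n_urban": n_urban,
                "urban_share": n_urban / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
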