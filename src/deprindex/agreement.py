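"""Tract-level agreement analysis between the two indices.

Each tract carries a continuous ADI value (0-100 percentile scale), a
continuous SVI value (0-1 percentile scale), and a decile for each index.
Agreement is summarised by Spearman correlations (continuous and decile),
a 10x10 decile cross-tabulation, a three-way agreement class per tract
(good: decile difference 0-1; poor: >= 6; intermediate otherwise), and
eight extreme-decile comparison groups. The comparison groups anchor on the
top and bottom decile of each index in turn (I: ADI decile 10, II: SVI
decile 10, III: ADI decile 1, IV: SVI decile 1) and contrast the
good-agreement ("a") against the poor-agreement ("b") tracts inside each
anchor set, reporting group sizes, shares of the anchor count, and mean
index scores with the SVI mean rescaled x100 for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AgreementThresholds

__all__ = [
    "pair_indices",
    "spearman_rho",
    "decile_crosstab",
    "classify_agreement",
    "agreement_summary",
    "build_comparisons",
    "comparison_gap",
    "subgroup_share",
    "summarize_by_state",
    "threshold_diagnostic",
    "COMPARISON_ANCHORS",
]

#: label -> (anchoring index, anchored decile)
COMPARISON_ANCHORS: dict[str, tuple[str, int]] = {
    "I": ("adi", 10),
    "II": ("svi", 10),
    "III": ("adi", 1),
    "IV": ("svi", 1),
}


def pair_indices(
    tract_adi: pd.DataFrame,
    tract_svi: pd.DataFrame,
    tracts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join the two per-tract score tables, dropping tracts missing either.

    Expects the ADI table with columns ``tract_id, value, decile`` and the
    SVI table indexed by tract_id with ``overall_percentile, decile``.
    Returns one row per complete tract: ``tract_id, adi_value, svi_value,
    adi_decile, svi_decile, delta``, plus ``state_code`` and ``urban`` when a
    tract attribute table is supplied.
    """
    a = tract_adi.set_index("tract_id")
    merged = pd.DataFrame(
        {
            "adi_value": a["value"],
            "adi_decile": a["decile"],
            "svi_value": tract_svi["overall_percentile"],
            "svi_decile": tract_svi["decile"],
        }
    )
    merged = merged.dropna()
    if tracts is not None:
        attrs = tracts.set_index("tract_id")
        for col in ("state_code", "urban"):
            if col in attrs.columns:
                merged[col] = attrs[col].reindex(merged.index)
    merged = merged.astype({"adi_decile": int, "svi_decile": int})
    merged["delta"] = (merged["adi_decile"] - merged["svi_decile"]).abs()
    return merged.rename_axis("tract_id").reset_index()


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Pairs with a missing member are dropped first; a constant sequence
    leaves the statistic undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("Spearman correlation needs at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def decile_crosstab(records: pd.DataFrame) -> pd.DataFrame:
    """10x10 tract-count grid: rows ADI decile 1-10, columns SVI decile 1-10."""
    idx = pd.RangeIndex(1, 11)
    if len(records) == 0:
        return pd.DataFrame(0, index=idx.rename("adi_decile"), columns=idx.rename("svi_decile"))
    ct = pd.crosstab(records["adi_decile"], records["svi_decile"])
    return ct.reindex(index=idx, columns=idx, fill_value=0).rename_axis(
        index="adi_decile", columns="svi_decile"
    )


def classify_agreement(
    records: pd.DataFrame, thresholds: AgreementThresholds | None = None
) -> pd.DataFrame:
    """Attach the agreement class (good / intermediate / poor) to each tract."""
    thresholds = thresholds or AgreementThresholds()
    out = records.copy()
    delta = out["delta"].to_numpy()
    cls = np.where(
        delta <= thresholds.good_max_delta,
        "good",
        np.where(delta >= thresholds.poor_min_delta, "poor", "intermediate"),
    )
    out["agreement_class"] = cls
    return out


def agreement_summary(records: pd.DataFrame) -> dict[str, float]:
    """National headline numbers for a classified tract table.

    Returns total tract count, shares of good and poor agreement, and the
    Spearman correlation of the continuous scores and of the decile scores,
    both on the identical tract set.
    """
    n = len(records)
    return {
        "n_total": n,
        "share_good": float((records["agreement_class"] == "good").mean()) if n else float("nan"),
        "share_poor": float((records["agreement_class"] == "poor").mean()) if n else float("nan"),
        "rho_continuous": spearman_rho(records["adi_value"], records["svi_value"]),
        "rho_decile": spearman_rho(records["adi_decile"], records["svi_decile"]),
    }


def comparison_gap(mean_adi: float, mean_svi_x100: float) -> float:
    """Absolute ADI-SVI mean difference after rounding both means to 1 decimal.

    This is the printed-report arithmetic: e.g. means 90.6 and 32.0 give a
    gap of 58.6.
    """
    return abs(round(round(mean_adi, 1) - round(mean_svi_x100, 1), 1))


def subgroup_share(n_subgroup: int, n_anchor: int) -> float:
    """Share of an anchor decile falling in a subgroup, as a proportion."""
    if n_anchor <= 0:
        return float("nan")
    return n_subgroup / n_anchor


@dataclass(frozen=True)
class ComparisonResult:
    """One row of the extreme-decile mean-score comparison table."""

    label: str  # 1a, 1b, ..., 4b
    anchor_index: str  # ADI or SVI
    tail: str  # top or bottom
    subgroup: str  # good or poor
    n_anchor: int
    n_subgroup: int
    share: float
    share_of_all: float
    mean_adi: float
    mean_svi_x100: float
    abs_difference: float
    unrounded_difference: float


def build_comparisons(
    records: pd.DataFrame, thresholds: AgreementThresholds | None = None
) -> pd.DataFrame:
    """The eight good/poor mean-score comparisons (groups 1a..4b).

    For each anchor (ADI/SVI top and bottom decile) the good- and
    poor-agreement subgroups are summarised: n, share of the anchor decile
    count, share of all tracts, mean ADI, mean SVI x 100, and the absolute
    difference of the two means rounded to one decimal (plus the unrounded
    gap). Empty subgroups report n=0 with missing means.
    """
    if "agreement_class" not in records.columns:
        records = classify_agreement(records, thresholds)
    n_all = len(records)
    rows = []
    for roman, (index, dec) in COMPARISON_ANCHORS.items():
        anchor = records.loc[records[f"{index}_decile"] == dec]
        n_anchor = len(anchor)
        arabic = {"I": "1", "II": "2", "III": "3", "IV": "4"}[roman]
        for sub, suffix in (("good", "a"), ("poor", "b")):
            grp = anchor.loc[anchor["agreement_class"] == sub]
            n_sub = len(grp)
            if n_sub:
                mean_adi = float(grp["adi_value"].mean())
                mean_svi = float(grp["svi_value"].mean()) * 100.0
                gap = comparison_gap(mean_adi, mean_svi)
                raw_gap = abs(mean_adi - mean_svi)
            else:
                mean_adi = mean_svi = gap = raw_gap = float("nan")
            rows.append(
                ComparisonResult(
                    label=f"{arabic}{suffix}",
                    anchor_index=index.upper(),
                    tail="top" if dec == 10 else "bottom",
                    subgroup=sub,
                    n_anchor=n_anchor,
                    n_subgroup=n_sub,
                    share=subgroup_share(n_sub, n_anchor),
                    share_of_all=n_sub / n_all if n_all else float("nan"),
                    mean_adi=mean_adi,
                    mean_svi_x100=mean_svi,
                    abs_difference=gap,
                    unrounded_difference=raw_gap,
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize_by_state(records: pd.DataFrame) -> pd.DataFrame:
    """Counts of good and poor agreement tracts per state."""
    g = records.groupby("state_code")["agreement_class"]
    out = pd.DataFrame(
        {
            "n_tracts": g.size(),
            "n_good": g.apply(lambda s: int((s == "good").sum())),
            "n_poor": g.apply(lambda s: int((s == "poor").sum())),
        }
    )
    return out.reset_index()


def threshold_diagnostic(records: pd.DataFrame) -> pd.DataFrame:
    """Marginal tract counts motivating the poor-agreement cutoff.

    For each index, counts of its top-decile (and bottom-decile) tracts
    across the other index's deciles — non-monotone bumps in these margins
    are the distributional irregularity the >= 6-decile cutoff responds to.
    """
    rows = []
    for index, other in (("adi", "svi"), ("svi", "adi")):
        for dec in (10, 1):
            margin = (
                records.loc[records[f"{index}_decile"] == dec, f"{other}_decile"]
                .value_counts()
                .reindex(range(1, 11), fill_value=0)
                .sort_index()
            )
            for other_dec, count in margin.items():
                rows.append(
                    {
                        "anchor_index": index.upper(),
                        "anchor_decile": dec,
                        "other_index": other.upper(),
                        "other_decile": other_dec,
                        "n_tracts": int(count),
                    }
                )
    return pd.DataFrame(rows)
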