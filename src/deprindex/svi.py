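"""Social Vulnerability Index construction at census-tract level.

Each of the 15 indicators is percentile-ranked across tracts in [0, 1] with
average ranks for ties, after orienting the item so that larger transformed
values mean more vulnerability (per capita income is rank-reversed). Item
percentiles are summed within each of the four themes; theme sums are
percentile-ranked to give theme rankings, and the overall score is the
percentile rank of the summed theme sums (equivalently of the 15-item
percentile sum). Overall percentiles are finally grouped into deciles
(decile 10 = most vulnerable).

Tracts are a :class:`pandas.DataFrame` with columns ``tract_id, state_code,
population, urban`` plus the 15 item columns of
:data:`deprindex.config.SVI_ITEMS`.
"""

from __future__ import annotations

import pandas as pd

from .config import SVI_THEMES, SviConfig
from .adi import assign_deciles, percentile_rank

__all__ = ["rank_items", "theme_scores", "overall_svi", "svi_deciles", "compute_svi"]


def rank_items(tracts: pd.DataFrame, config: SviConfig | None = None) -> pd.DataFrame:
    """Directional percentile rank of every item, in [0, 1].

    Items flagged ``lower_is_vulnerable`` are negated before ranking so their
    smallest values map to percentile 1. Tracts missing an item get a
    missing percentile for it (and hence missing theme/overall scores
    downstream). Returns a frame indexed by tract_id with one column per item.
    """
    config = config or SviConfig()
    out = {}
    indexed = tracts.set_index("tract_id")
    for item, direction in config.directions.items():
        vals = indexed[item].astype(float)
        if direction == "lower_is_vulnerable":
            vals = -vals
        out[item] = percentile_rank(vals, scale=1.0)
    return pd.DataFrame(out, index=indexed.index)


def theme_scores(
    item_percentiles: pd.DataFrame, config: SviConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-theme percentile sums and their percentile ranks.

    theme_sum = sum of the theme's item percentiles per tract; theme
    percentile = rank of that sum across tracts, in [0, 1].
    """
    config = config or SviConfig()
    unknown = set(config.theme_map) - set(item_percentiles.columns)
    if unknown:
        raise KeyError(f"theme_map names items absent from the percentile table: {sorted(unknown)}")
    sums = pd.DataFrame(
        {t: item_percentiles[config.theme_items(t)].sum(axis=1, skipna=False) for t in SVI_THEMES}
    )
    pcts = pd.DataFrame({t: percentile_rank(sums[t], scale=1.0) for t in SVI_THEMES})
    return sums, pcts


def overall_svi(
    theme_sums: pd.DataFrame,
    theme_percentiles: pd.DataFrame | None = None,
    config: SviConfig | None = None,
) -> pd.DataFrame:
    """Overall vulnerability score: sum the themes, percentile-rank the sum.

    The default base is the four theme sums (so overall_sum equals the
    15-item percentile sum); ``config.overall_base = "theme_percentiles"``
    ranks the sum of theme percentile ranks instead. Returns columns
    ``overall_sum, overall_percentile`` indexed by tract.
    """
    config = config or SviConfig()
    if config.overall_base == "theme_percentiles":
        if theme_percentiles is None:
            raise ValueError("theme_percentiles required for overall_base='theme_percentiles'")
        base = theme_percentiles.sum(axis=1, skipna=False)
    else:
        base = theme_sums.sum(axis=1, skipna=False)
    return pd.DataFrame(
        {"overall_sum": base, "overall_percentile": percentile_rank(base, scale=1.0)}
    )


def svi_deciles(overall_percentiles: pd.Series) -> pd.Series:
    """Decile groups 1-10 of the overall percentile (shared decile rule)."""
    return assign_deciles(overall_percentiles)


def compute_svi(tracts: pd.DataFrame, config: SviConfig | None = None) -> pd.DataFrame:
    """Run the full SVI construction on a tract table.

    Returns a frame indexed by tract_id holding the 15 item percentiles, the
    four theme sums (``theme_sum_<theme>``) and percentiles
    (``theme_pct_<theme>``), ``overall_sum``, ``overall_percentile`` and
    ``decile``.
    """
    config = config or SviConfig()
    item_pct = rank_items(tracts, config)
    sums, pcts = theme_scores(item_pct, config)
    overall = overall_svi(sums, pcts, config)
    out = item_pct.copy()
    for t in SVI_THEMES:
        out[f"theme_sum_{t}"] = sums[t]
        out[f"theme_pct_{t}"] = pcts[t]
    out["overall_sum"] = overall["overall_sum"]
    out["overall_percentile"] = overall["overall_percentile"]
    out["decile"] = svi_deciles(overall["overall_percentile"])
    return out
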