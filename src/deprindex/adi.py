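"""Area Deprivation Index construction.

The ADI scores each census block group by multiplying 17 socioeconomic
indicators by their factor score coefficients and summing; the sums are
standardized to mean 100 / SD 20 and converted to national percentile
rankings in [0, 100] (100 = most deprived). Block groups with fewer than 30
housing units, fewer than 100 people, more than one third of their
population in group quarters, or a Census-acknowledged data error are
excluded. Percentiles are then aggregated to census tracts by
population-weighted means and the tract values ranked into deciles
(decile 10 = most deprived).

Block groups are represented as a :class:`pandas.DataFrame` with one row per
unit and columns ``blockgroup_id, tract_id, state_code, population,
housing_units, group_quarters_pop, census_error`` plus the 17 item columns
named in :data:`deprindex.config.ADI_ITEMS`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ADI_ITEMS, AdiConfig, DegenerateInputError

__all__ = [
    "apply_exclusions",
    "compute_raw_adi",
    "estimate_coefficients",
    "standardize",
    "percentile_rank",
    "aggregate_to_tract",
    "assign_deciles",
    "compute_adi",
]


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(blockgroups: pd.DataFrame, config: AdiConfig | None = None) -> pd.DataFrame:
    """Flag block groups that fail the ADI suppression rules.

    The rules use strict inequalities (housing_units < 30, population < 100,
    group-quarters share > 1/3) and are checked in that order; the first rule
    violated is recorded as the reason. A true ``census_error`` flag forces
    exclusion when no threshold rule fires. Returns a frame with columns
    ``blockgroup_id, excluded, exclusion_reason``.
    """
    config = config or AdiConfig()
    hu = blockgroups["housing_units"].to_numpy(dtype=float)
    pop = blockgroups["population"].to_numpy(dtype=float)
    gq = blockgroups["group_quarters_pop"].to_numpy(dtype=float)
    err = (
        blockgroups["census_error"].astype(bool).to_numpy()
        if "census_error" in blockgroups.columns
        else np.zeros(len(blockgroups), dtype=bool)
    )

    # group-quarters fraction: a zero population cannot host anyone, so the
    # unit is excluded by the population rule before the ratio is evaluated
    with np.errstate(divide="ignore", invalid="ignore"):
        gq_frac = np.where(pop > 0, gq / np.where(pop > 0, pop, 1.0), np.inf)

    reason = np.full(len(blockgroups), "none", dtype=object)
    # ~(x >= threshold) so that missing counts also fail the rule
    rules = [
        ("housing_units", ~(hu >= config.exclusion_min_housing_units)),
        ("population", ~(pop >= config.exclusion_min_population)),
        ("group_quarters", gq_frac > config.exclusion_max_gq_fraction),
        ("census_error", err),
    ]
    for name, mask in rules:
        hit = (reason == "none") & mask
        reason[hit] = name

    return pd.DataFrame(
        {
            "blockgroup_id": blockgroups["blockgroup_id"].to_numpy(),
            "excluded": reason != "none",
            "exclusion_reason": reason,
        }
    )


# ---------------------------------------------------------------------------
# raw score
# ---------------------------------------------------------------------------

def compute_raw_adi(blockgroups: pd.DataFrame, config: AdiConfig) -> pd.Series:
    """Factor-weighted sum of the 17 items per block group.

    ``raw_i = sum_k coefficient_k * item_value_{ik}``. Sign-flipped
    (prosperity) items enter via negative coefficients supplied in the
    config. Units with any missing item value get NaN, never a silent zero.
    Returns a Series indexed by blockgroup_id.
    """
    if config.coefficients is None:
        raise ValueError("config.coefficients is None; call estimate_coefficients first")
    items = blockgroups[list(ADI_ITEMS)].astype(float)
    coef = pd.Series({k: float(v) for k, v in config.coefficients.items()})[list(ADI_ITEMS)]
    raw = items.to_numpy() @ coef.to_numpy()
    raw = pd.Series(raw, index=blockgroups["blockgroup_id"], name="raw_score")
    raw[items.isna().any(axis=1).to_numpy()] = np.nan
    return raw


def estimate_coefficients(
    blockgroups: pd.DataFrame,
    n_iter: int = 50,
    tol: float = 1e-8,
) -> dict[str, float]:
    """Estimate item coefficients by single-factor principal-axis factoring.

    Communalities are initialised from squared multiple correlations and
    iterated on the reduced correlation matrix of the standardized 17 items;
    the dominant factor's loadings, divided by each item's sample SD so they
    apply directly to raw item values, are the coefficients. The factor is
    oriented so the family-poverty item loads positively (higher score =
    more deprived).

    Loading-proportional weights (rather than regression-method factor
    scores ``R^-1 lambda``) are used deliberately: they keep every
    indicator's contribution proportional to how strongly it tracks the
    common factor, which is the fixed-composite behaviour of a released
    deprivation index. Regression scoring would instead down-weight any
    indicator carrying extra non-factor variance, optimising the factor
    estimate but erasing exactly the item-driven divergences this package
    is built to study.
    """
    items = blockgroups[list(ADI_ITEMS)].astype(float).dropna()
    if len(items) < len(ADI_ITEMS) + 2:
        raise DegenerateInputError("too few complete block groups to estimate coefficients")
    sd = items.std(ddof=1)
    if (sd <= 0).any():
        raise DegenerateInputError("constant item column; factoring undefined")
    r = np.corrcoef(items.to_numpy(), rowvar=False)
    r_inv = np.linalg.pinv(r)
    h2 = 1.0 - 1.0 / np.diag(r_inv)  # squared multiple correlations
    for _ in range(n_iter):
        reduced = r.copy()
        np.fill_diagonal(reduced, h2)
        w_eig, v_eig = np.linalg.eigh(reduced)
        lam = v_eig[:, -1] * np.sqrt(max(w_eig[-1], 0.0))
        h2_new = np.clip(lam**2, 0.0, 0.999)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    if lam[list(ADI_ITEMS).index("pct_families_below_poverty")] < 0:
        lam = -lam
    return {item: float(l / s) for item, l, s in zip(ADI_ITEMS, lam, sd.to_numpy())}


# ---------------------------------------------------------------------------
# standardization and ranking
# ---------------------------------------------------------------------------

def standardize(raw_scores: pd.Series, config: AdiConfig | None = None) -> pd.Series:
    """Rescale raw sums to the conventional mean-100 / SD-20 index scale.

    ``out = m + s * (raw - mean(raw)) / sd(raw)`` over non-missing units. The
    SD denominator follows ``config.sd_convention`` (sample ``n-1`` by
    default). Constant input leaves the scale undefined and raises.
    """
    config = config or AdiConfig()
    vals = raw_scores.dropna()
    if len(vals) < 2:
        raise DegenerateInputError("standardization needs at least 2 non-missing scores")
    ddof = 1 if config.sd_convention == "sample" else 0
    sd = float(vals.std(ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("raw scores are constant; SD undefined for scaling")
    out = config.standard_mean + config.standard_sd * (raw_scores - vals.mean()) / sd
    return out.rename("standardized")


def percentile_rank(values: pd.Series, scale: float = 100.0) -> pd.Series:
    """Average-rank percentile transform onto [0, scale].

    ``pct = scale * (rank - 1) / (n - 1)`` with average ranks for ties, so
    the minimum maps to 0 and the maximum to ``scale`` (most deprived).
    Missing values stay missing and do not enter n.
    """
    vals = values.dropna()
    n = len(vals)
    if n < 2:
        raise DegenerateInputError("percentile ranking needs at least 2 non-missing values")
    ranks = stats.rankdata(vals.to_numpy(), method="average")
    pct = pd.Series(scale * (ranks - 1.0) / (n - 1.0), index=vals.index)
    return pct.reindex(values.index).rename("percentile")


def aggregate_to_tract(
    bg_scores: pd.Series,
    blockgroups: pd.DataFrame,
) -> pd.DataFrame:
    """Population-weighted mean of block-group scores per tract.

    Excluded or missing members (NaN score) contribute neither weight nor
    value; a tract whose members are all missing is flagged missing. Returns
    columns ``tract_id, value, missing``.
    """
    df = pd.DataFrame(
        {
            "tract_id": blockgroups["tract_id"].to_numpy(),
            "pop": blockgroups["population"].to_numpy(dtype=float),
            "score": bg_scores.reindex(blockgroups["blockgroup_id"]).to_numpy(),
        }
    )
    ok = df["score"].notna() & (df["pop"] > 0)
    df.loc[~ok, "pop"] = 0.0
    df["wx"] = np.where(ok, df["pop"] * df["score"], 0.0)
    g = df.groupby("tract_id", sort=True)[["pop", "wx"]].sum()
    value = np.where(g["pop"] > 0, g["wx"] / g["pop"].replace(0, np.nan), np.nan)
    return pd.DataFrame(
        {"tract_id": g.index.to_numpy(), "value": value, "missing": g["pop"].to_numpy() == 0}
    ).reset_index(drop=True)


def assign_deciles(values: pd.Series) -> pd.Series:
    """Partition units into 10 rank-ordered, near-equal-count decile groups.

    Units are stably ordered by (value, identifier) and sliced into ten
    groups whose sizes differ by at most one; decile 10 holds the largest
    values (most deprived). The identifier tie-break makes the assignment
    deterministic across runs. Missing values get a missing decile.
    """
    vals = values.dropna()
    n = len(vals)
    if n < 10:
        raise DegenerateInputError("decile assignment needs at least 10 non-missing values")
    ids = vals.index.astype(str).to_numpy()
    order = np.lexsort((ids, vals.to_numpy()))
    deciles = np.empty(n, dtype=float)
    for k in range(1, 11):
        lo, hi = (k - 1) * n // 10, k * n // 10
        deciles[order[lo:hi]] = k
    out = pd.Series(deciles, index=vals.index)
    return out.reindex(values.index).rename("decile")


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def compute_adi(
    blockgroups: pd.DataFrame, config: AdiConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full ADI construction on a block-group table.

    Returns ``(blockgroup_scores, tract_scores)``: the first with columns
    ``blockgroup_id, excluded, exclusion_reason, raw_score, standardized,
    national_percentile``, the second with ``tract_id, value, decile,
    missing``.
    """
    config = config or AdiConfig()
    excl = apply_exclusions(blockgroups, config)
    retained = blockgroups.loc[~excl["excluded"].to_numpy()].reset_index(drop=True)
    if config.coefficients is None:
        config = AdiConfig(
            coefficients=estimate_coefficients(retained),
            directions=config.directions,
            exclusion_min_housing_units=config.exclusion_min_housing_units,
            exclusion_min_population=config.exclusion_min_population,
            exclusion_max_gq_fraction=config.exclusion_max_gq_fraction,
            standard_mean=config.standard_mean,
            standard_sd=config.standard_sd,
            sd_convention=config.sd_convention,
            aggregate_on=config.aggregate_on,
        )
    raw = compute_raw_adi(retained, config)
    std = standardize(raw, config)
    pct = percentile_rank(std)

    scores = excl.copy()
    for name, series in (("raw_score", raw), ("standardized", std), ("national_percentile", pct)):
        scores[name] = series.reindex(scores["blockgroup_id"]).to_numpy()

    bg_quantity = pct if config.aggregate_on == "percentile" else std
    tract = aggregate_to_tract(bg_quantity, retained)
    dec = assign_deciles(tract.set_index("tract_id")["value"])
    tract["decile"] = dec.reindex(tract["tract_id"]).to_numpy()
    return scores, tract
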