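"""Synthetic census-style indicator data with a latent-factor structure.

The generator emulates the statistical skeleton of the American Community
Survey tables both indices are built from, without any real data: census
block groups nested 1-5 per tract, tracts nested in states, FIPS-like
identifiers, and 27 indicator items driven by

* a dominant latent *deprivation* factor ``D`` (one draw per tract,
  standard normal) loading on every item — poverty, income, and education
  items carry the largest loadings;
* a second latent *urban housing-market* factor
  ``H = housing_urban_shift * urban + housing_confound_strength * eps``
  (``eps`` standard normal per tract, ``urban ~ Bernoulli``) loading only
  on the three housing-price items (median home value, monthly mortgage,
  gross rent).

Proportion items are inverse-logit of ``mu + loading*D + noise`` (always in
[0, 1]); dollar items are exponential of ``base + loading*D + gamma*H +
noise`` (always positive, heavy right tail, as housing costs are). Because
the ADI weights housing-price items (negatively) while the SVI contains
none of them, raising ``housing_confound_strength`` makes expensive urban
tracts look less deprived to the ADI but not to the SVI — the controllable
divergence mechanism this package analyses.

Tract item values are population-weighted means of their block groups.
A configurable fraction of block groups is forced to violate one ADI
exclusion rule (tiny housing stock, tiny population, or a dominant
group-quarters population) to exercise the suppression logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ADI_ITEMS, ALL_ITEMS, SVI_ITEMS

__all__ = ["SyntheticParams", "generate_geography", "write_fixture"]


# ---------------------------------------------------------------------------
# item models: (kind, location, deprivation loading, housing gamma)
# location is on the logit scale for proportions / log scale for dollars.
# ---------------------------------------------------------------------------

_PROPORTION_MODEL: dict[str, tuple[float, float]] = {
    # item: (logit mean, deprivation loading) — poverty, income and
    # education items carry the heaviest loadings
    "pct_families_below_poverty": (-2.2, 1.2),
    "pct_below_poverty": (-1.9, 1.2),
    "pct_below_150_poverty": (-1.4, 1.1),
    "pct_unemployed": (-2.8, 0.8),
    "pct_white_collar": (-0.5, -0.9),
    "pct_hs_diploma_or_higher": (1.5, -1.0),
    "pct_less_than_9th_grade": (-3.0, 0.9),
    "pct_no_hs_diploma": (-1.9, 1.0),
    "pct_owner_occupied": (0.6, -0.7),
    "pct_single_parent": (-2.0, 1.0),
    "pct_no_telephone": (-3.5, 0.8),
    "pct_no_vehicle": (-2.5, 0.9),
    "pct_no_plumbing": (-4.5, 0.5),
    "pct_crowded": (-3.2, 0.9),
    "pct_age_65_plus": (-1.7, 0.1),
    "pct_age_17_under": (-1.2, 0.2),
    "pct_disability": (-1.8, 0.5),
    "pct_minority": (-0.8, 0.8),
    "pct_limited_english": (-3.0, 0.6),
    "pct_multi_unit": (-1.5, 0.4),
    "pct_mobile_homes": (-2.5, 0.3),
    "pct_group_quarters": (-3.5, 0.1),
}

_POSITIVE_MODEL: dict[str, tuple[float, float, float]] = {
    # item: (log mean, deprivation loading, housing gamma). gamma > 0 only
    # for the three housing-price items.
    "median_family_income": (np.log(70_000.0), -0.35, 0.0),
    "per_capita_income": (np.log(34_000.0), -0.35, 0.0),
    "median_home_value": (np.log(220_000.0), -0.35, 0.65),
    "median_monthly_mortgage": (np.log(1_500.0), -0.30, 0.55),
    "median_gross_rent": (np.log(1_000.0), -0.25, 0.50),
    "income_disparity": (np.log(1.2), 0.6, 0.0),
}

assert set(_PROPORTION_MODEL) | set(_POSITIVE_MODEL) == set(ALL_ITEMS)


def _default_loadings() -> dict[str, float]:
    out = {k: v[1] for k, v in _PROPORTION_MODEL.items()}
    out.update({k: v[1] for k, v in _POSITIVE_MODEL.items()})
    return out


@dataclass(frozen=True)
class SyntheticParams:
    """Knobs of the synthetic geography and indicator generator.

    ``deprivation_loading`` maps each of the 27 items to its signed loading
    on the latent deprivation factor (logit/log scale units per SD of D).
    ``housing_confound_strength`` scales the idiosyncratic spread of the
    urban housing-market factor H and ``housing_urban_shift`` its mean lift
    in urban tracts; both are in SD units of the latent factors. ``noise_sd``
    is the block-group-level item noise on the logit/log scale.
    """

    n_states: int = 5
    tracts_per_state: int = 200
    blockgroups_per_tract_range: tuple[int, int] = (1, 5)
    urban_probability: float = 0.3
    deprivation_loading: dict[str, float] = field(default_factory=_default_loadings)
    housing_confound_strength: float = 1.0
    housing_urban_shift: float = 3.0
    noise_sd: float = 0.3
    population_range: tuple[int, int] = (600, 3000)
    exclusion_edge_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.blockgroups_per_tract_range
        plo, phi = self.population_range
        if self.n_states < 0 or self.tracts_per_state < 0:
            raise ValueError("n_states and tracts_per_state must be non-negative")
        if not (1 <= lo <= hi):
            raise ValueError("blockgroups_per_tract_range must satisfy 1 <= lo <= hi")
        if not (1 <= plo <= phi):
            raise ValueError("population_range must satisfy 1 <= lo <= hi")
        for name in ("urban_probability", "exclusion_edge_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.housing_confound_strength < 0 or self.housing_urban_shift < 0:
            raise ValueError("housing factor parameters must be non-negative")
        if set(self.deprivation_loading) != set(ALL_ITEMS):
            raise ValueError("deprivation_loading must cover all 27 items")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticParams":
        import json

        with open(path) as fh:
            doc = json.load(fh)
        for key in ("blockgroups_per_tract_range", "population_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "deprivation_loading" in doc:
            merged = _default_loadings()
            merged.update(doc["deprivation_loading"])
            doc["deprivation_loading"] = merged
        return cls(**doc)


BLOCKGROUP_COLUMNS = [
    "blockgroup_id",
    "tract_id",
    "state_code",
    "population",
    "housing_units",
    "group_quarters_pop",
    "census_error",
    *ADI_ITEMS,
]

TRACT_COLUMNS = ["tract_id", "state_code", "population", "ruca_code", "urban", *SVI_ITEMS]


def generate_geography(params: SyntheticParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a full synthetic geography: block-group and tract tables.

    Deterministic given ``params`` (including its seed). Returns
    ``(blockgroups, tracts)`` with the column layouts of
    :data:`BLOCKGROUP_COLUMNS` and :data:`TRACT_COLUMNS`; tract items are
    population-weighted means of their member block groups and tract
    populations are exact sums of member populations.
    """
    rng = np.random.default_rng(params.seed)
    n_tracts = params.n_states * params.tracts_per_state
    if n_tracts == 0:
        return (
            pd.DataFrame(columns=BLOCKGROUP_COLUMNS),
            pd.DataFrame(columns=TRACT_COLUMNS),
        )

    # --- tract-level latents -------------------------------------------------
    state_idx = np.repeat(np.arange(params.n_states), params.tracts_per_state)
    state_code = np.char.zfill((state_idx + 1).astype(str), 2)
    tract_num = np.concatenate(
        [np.arange(1, params.tracts_per_state + 1)] * params.n_states
    )
    tract_id = np.array(
        [f"{s}001{t:06d}" for s, t in zip(state_code, tract_num)], dtype=object
    )
    deprivation = rng.standard_normal(n_tracts)
    urban = rng.random(n_tracts) < params.urban_probability
    housing = (
        params.housing_urban_shift * urban.astype(float)
        + params.housing_confound_strength * rng.standard_normal(n_tracts)
    )

    # --- block-group skeleton ------------------------------------------------
    lo, hi = params.blockgroups_per_tract_range
    n_bg_per_tract = rng.integers(lo, hi + 1, size=n_tracts)
    bg_tract_idx = np.repeat(np.arange(n_tracts), n_bg_per_tract)
    n_bg = len(bg_tract_idx)
    bg_seq = np.concatenate([np.arange(1, k + 1) for k in n_bg_per_tract])
    bg_id = np.array(
        [f"{tract_id[t]}{s}" for t, s in zip(bg_tract_idx, bg_seq)], dtype=object
    )

    plo, phi = params.population_range
    population = rng.integers(plo, phi + 1, size=n_bg)
    housing_units = np.maximum(
        1, np.round(population / 2.4 * rng.uniform(0.85, 1.15, size=n_bg)).astype(int)
    )

    # --- items ---------------------------------------------------------------
    items = {}
    d_bg = deprivation[bg_tract_idx]
    h_bg = housing[bg_tract_idx]
    for item in ALL_ITEMS:
        lam = params.deprivation_loading[item]
        noise = params.noise_sd * rng.standard_normal(n_bg)
        if item in _PROPORTION_MODEL:
            mu = _PROPORTION_MODEL[item][0]
            items[item] = 1.0 / (1.0 + np.exp(-(mu + lam * d_bg + noise)))
        else:
            base, _, gamma = _POSITIVE_MODEL[item]
            items[item] = np.exp(base + lam * d_bg + gamma * h_bg + noise)

    group_quarters = np.minimum(
        population, np.round(population * items["pct_group_quarters"]).astype(int)
    )

    # --- forced exclusion-rule edge cases ------------------------------------
    n_edge = int(np.floor(params.exclusion_edge_fraction * n_bg))
    if n_edge > 0:
        edge_idx = rng.choice(n_bg, size=n_edge, replace=False)
        for j, bg in enumerate(edge_idx):
            rule = j % 3
            if rule == 0:
                housing_units[bg] = int(rng.integers(0, 30))
            elif rule == 1:
                population[bg] = int(rng.integers(1, 100))
                group_quarters[bg] = min(group_quarters[bg], population[bg])
            else:
                # push group-quarters share strictly above 1/3
                group_quarters[bg] = int(population[bg] // 3 + 1)

    blockgroups = pd.DataFrame(
        {
            "blockgroup_id": bg_id,
            "tract_id": tract_id[bg_tract_idx],
            "state_code": state_code[bg_tract_idx],
            "population": population,
            "housing_units": housing_units,
            "group_quarters_pop": group_quarters,
            "census_error": False,
            **{item: items[item] for item in ADI_ITEMS},
        },
        columns=BLOCKGROUP_COLUMNS,
    )

    # --- tract aggregation ---------------------------------------------------
    w = population.astype(float)
    agg = {"population": np.bincount(bg_tract_idx, weights=w, minlength=n_tracts)}
    for item in SVI_ITEMS:
        # population-weighted mean, except group quarters which is an exact
        # count-based share so tract group-quarters population reconciles
        if item == "pct_group_quarters":
            num = np.bincount(bg_tract_idx, weights=group_quarters.astype(float), minlength=n_tracts)
        else:
            num = np.bincount(bg_tract_idx, weights=w * items[item], minlength=n_tracts)
        agg[item] = num / agg["population"]

    tracts = pd.DataFrame(
        {
            "tract_id": tract_id,
            "state_code": state_code,
            "population": agg["population"].astype(int),
            "ruca_code": np.where(urban, 1, 7),
            "urban": urban,
            **{item: agg[item] for item in SVI_ITEMS},
        },
        columns=TRACT_COLUMNS,
    )
    return blockgroups, tracts


def write_fixture(
    blockgroups: pd.DataFrame, tracts: pd.DataFrame, path: str | Path
) -> tuple[Path, Path]:
    """Write ``blockgroups.csv`` and ``tracts.csv`` under ``path``.

    The files follow the package's CSV schemas and round-trip losslessly
    through :func:`deprindex.cli_io.read_blockgroups` /
    :func:`~deprindex.cli_io.read_tracts` (the in-memory ``urban`` flag is
    serialised as a RUCA code and re-derived on read).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    bg_path = path / "blockgroups.csv"
    tract_path = path / "tracts.csv"
    blockgroups.to_csv(bg_path, index=False)
    tracts.drop(columns=["urban"]).to_csv(tract_path, index=False)
    return bg_path, tract_path
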