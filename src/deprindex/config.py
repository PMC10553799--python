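"""Item catalogs and configuration objects for the two deprivation indices.

The Area Deprivation Index (ADI) is a factor-weighted composite of 17
block-group census indicators of income, education, employment, and housing
quality. The CDC Social Vulnerability Index (SVI) is a percentile-rank
composite of 15 tract indicators in four themes. The catalogs below fix the
snake_case item names used throughout the package, the measurement scale of
each item, and the direction each item enters its index.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

# ---------------------------------------------------------------------------
# ADI: 17 items. "neg" marks items with negative factor loadings (prosperity
# indicators: larger values mean *less* deprivation).
# ---------------------------------------------------------------------------

ADI_ITEMS: tuple[str, ...] = (
    "pct_families_below_poverty",
    "pct_below_150_poverty",
    "income_disparity",
    "median_family_income",
    "pct_unemployed",
    "pct_white_collar",
    "pct_hs_diploma_or_higher",
    "pct_less_than_9th_grade",
    "pct_owner_occupied",
    "median_monthly_mortgage",
    "median_gross_rent",
    "median_home_value",
    "pct_single_parent",
    "pct_no_telephone",
    "pct_no_vehicle",
    "pct_no_plumbing",
    "pct_crowded",
)

#: Items whose factor loading is negative (higher value = less deprived).
ADI_NEGATIVE_ITEMS: frozenset[str] = frozenset(
    {
        "median_family_income",
        "pct_white_collar",
        "pct_hs_diploma_or_higher",
        "pct_owner_occupied",
        "median_monthly_mortgage",
        "median_gross_rent",
        "median_home_value",
    }
)

#: ADI items measured in US dollars (all others are proportions in [0, 1],
#: except income_disparity which is a positive unitless ratio).
ADI_DOLLAR_ITEMS: frozenset[str] = frozenset(
    {
        "median_family_income",
        "median_monthly_mortgage",
        "median_gross_rent",
        "median_home_value",
    }
)

# ---------------------------------------------------------------------------
# SVI: 15 items in four themes.
# ---------------------------------------------------------------------------

SVI_THEMES: tuple[str, ...] = (
    "socioeconomic_status",
    "household_composition_disability",
    "minority_status_language",
    "housing_type_transportation",
)

SVI_THEME_MAP: dict[str, str] = {
    "pct_below_poverty": "socioeconomic_status",
    "pct_unemployed": "socioeconomic_status",
    "per_capita_income": "socioeconomic_status",
    "pct_no_hs_diploma": "socioeconomic_status",
    "pct_age_65_plus": "household_composition_disability",
    "pct_age_17_under": "household_composition_disability",
    "pct_disability": "household_composition_disability",
    "pct_single_parent": "household_composition_disability",
    "pct_minority": "minority_status_language",
    "pct_limited_english": "minority_status_language",
    "pct_multi_unit": "housing_type_transportation",
    "pct_mobile_homes": "housing_type_transportation",
    "pct_crowded": "housing_type_transportation",
    "pct_no_vehicle": "housing_type_transportation",
    "pct_group_quarters": "housing_type_transportation",
}

SVI_ITEMS: tuple[str, ...] = tuple(SVI_THEME_MAP)

#: Direction each SVI item enters the ranking. Per capita income is the only
#: item where a *lower* value indicates more vulnerability; its ranks are
#: reversed before percentile conversion. The minority item is stored as the
#: minority share (1 - non-Hispanic-White share), so it ranks upward.
SVI_DIRECTIONS: dict[str, str] = {
    item: ("lower_is_vulnerable" if item == "per_capita_income" else "higher_is_vulnerable")
    for item in SVI_ITEMS
}

#: All distinct indicator items across both indices (27 in total; five are
#: shared: poverty, unemployment, single-parent, no-vehicle, crowding).
ALL_ITEMS: tuple[str, ...] = ADI_ITEMS + tuple(
    i for i in SVI_ITEMS if i not in set(ADI_ITEMS)
)

#: RUCA (Rural Urban Commuting Area) codes conventionally treated as urban.
DEFAULT_RUCA_URBAN_CODES: frozenset[int] = frozenset({1, 2, 3})


class ConfigError(ValueError):
    """Invalid or inconsistent configuration."""


class DegenerateInputError(ValueError):
    """Input too small or constant for the requested statistic."""


@dataclass(frozen=True)
class AdiConfig:
    """Parameters of ADI construction.

    ``coefficients`` holds the factor score coefficient of each of the 17
    items (sign included); when ``None`` the pipeline estimates them from the
    input data by single-factor principal-axis factoring. The three exclusion
    thresholds implement the index's block-group suppression rules: fewer
    than 30 housing units, fewer than 100 people, or more than one third of
    the population in group quarters.
    """

    coefficients: Mapping[str, float] | None = None
    directions: frozenset[str] = ADI_NEGATIVE_ITEMS
    exclusion_min_housing_units: int = 30
    exclusion_min_population: int = 100
    exclusion_max_gq_fraction: float = 1.0 / 3.0
    standard_mean: float = 100.0
    standard_sd: float = 20.0
    # "sample" (n-1 denominator, default) or "population" (n denominator).
    sd_convention: str = "sample"
    # tract aggregation operates on this block-group quantity
    aggregate_on: str = "percentile"

    def __post_init__(self) -> None:
        if self.standard_sd <= 0:
            raise ConfigError("standard_sd must be positive")
        if self.sd_convention not in ("sample", "population"):
            raise ConfigError(f"unknown sd_convention {self.sd_convention!r}")
        if self.aggregate_on not in ("percentile", "standardized"):
            raise ConfigError(f"unknown aggregate_on {self.aggregate_on!r}")
        if self.coefficients is not None:
            got = set(self.coefficients)
            if got != set(ADI_ITEMS):
                missing = set(ADI_ITEMS) - got
                extra = got - set(ADI_ITEMS)
                raise ConfigError(
                    f"coefficients must cover exactly the 17 ADI items; "
                    f"missing={sorted(missing)}, unexpected={sorted(extra)}"
                )


@dataclass(frozen=True)
class SviConfig:
    """Parameters of SVI construction."""

    theme_map: Mapping[str, str] = field(default_factory=lambda: dict(SVI_THEME_MAP))
    directions: Mapping[str, str] = field(default_factory=lambda: dict(SVI_DIRECTIONS))
    # overall ranking base: "theme_sums" ranks the sum of the four theme sums
    # (equivalently the 15-item percentile sum); "theme_percentiles" ranks the
    # sum of the four theme percentile ranks instead.
    overall_base: str = "theme_sums"

    def __post_init__(self) -> None:
        items = set(self.theme_map)
        if len(items) != 15:
            raise ConfigError(f"theme_map must contain exactly 15 items, got {len(items)}")
        themes = set(self.theme_map.values())
        if themes != set(SVI_THEMES):
            raise ConfigError(f"theme_map must use the four standard themes, got {sorted(themes)}")
        if set(self.directions) != items:
            raise ConfigError("directions must cover exactly the theme_map items")
        bad = set(self.directions.values()) - {"higher_is_vulnerable", "lower_is_vulnerable"}
        if bad:
            raise ConfigError(f"unknown direction values {sorted(bad)}")
        if self.overall_base not in ("theme_sums", "theme_percentiles"):
            raise ConfigError(f"unknown overall_base {self.overall_base!r}")

    def theme_items(self, theme: str) -> list[str]:
        return [i for i, t in self.theme_map.items() if t == theme]


@dataclass(frozen=True)
class AgreementThresholds:
    """Decile-difference cutoffs defining agreement classes.

    A tract pair agrees well when its ADI and SVI deciles differ by at most
    ``good_max_delta`` and poorly when they differ by at least
    ``poor_min_delta``; everything between is intermediate.
    """

    good_max_delta: int = 1
    poor_min_delta: int = 6

    def __post_init__(self) -> None:
        if not (0 <= self.good_max_delta < self.poor_min_delta <= 9):
            raise ConfigError(
                "thresholds must satisfy 0 <= good_max_delta < poor_min_delta <= 9, "
                f"got good_max_delta={self.good_max_delta}, poor_min_delta={self.poor_min_delta}"
            )


@dataclass(frozen=True)
class RunConfig:
    """Everything a full pipeline run needs."""

    blockgroup_csv: str
    tract_csv: str
    output_dir: str
    adi: AdiConfig = field(default_factory=AdiConfig)
    svi: SviConfig = field(default_factory=SviConfig)
    thresholds: AgreementThresholds = field(default_factory=AgreementThresholds)
    ruca_urban_codes: frozenset[int] = DEFAULT_RUCA_URBAN_CODES
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = json.load(fh)
        kwargs = dict(doc)
        if "adi" in kwargs:
            adi = dict(kwargs["adi"])
            if "directions" in adi:
                adi["directions"] = frozenset(adi["directions"])
            kwargs["adi"] = AdiConfig(**adi)
        if "svi" in kwargs:
            kwargs["svi"] = SviConfig(**kwargs["svi"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = AgreementThresholds(**kwargs["thresholds"])
        if "ruca_urban_codes" in kwargs:
            kwargs["ruca_urban_codes"] = frozenset(int(c) for c in kwargs["ruca_urban_codes"])
        return cls(**kwargs)

    def to_json(self) -> str:
        doc = dataclasses.asdict(self)
        doc["ruca_urban_codes"] = sorted(self.ruca_urban_codes)
        doc["adi"]["directions"] = sorted(self.adi.directions)
        return json.dumps(doc, indent=2)
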