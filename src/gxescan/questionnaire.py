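"""Harmonization of drinking-questionnaire answers into exposure variables.

Converts the raw questionnaire fields (drinking status, drinking frequency,
weekly beverage volumes) into grams of ethanol per week (WAC), grams per day
(DAC), US standard drinks per day (14 g ethanol) and the five-tier
consumption stratum used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "STATUS_VOCAB",
    "FREQUENCY_DAYS",
    "ETHANOL_CONTENT",
    "GRAMS_PER_DRINK",
    "TIER_CUTPOINTS_DRINKS",
    "DrinkingProfile",
    "ExposureRecord",
    "frequency_to_days",
    "beverage_to_ethanol_grams",
    "assign_tier",
    "compute_exposure",
]

#: Closed vocabulary of drinking-status answers. Only ``current`` counts as a
#: drinker; former / never / never-because-intolerant are all non-drinkers.
STATUS_VOCAB = frozenset({"current", "former", "never", "never_intolerant"})

#: Six-category drinking frequency -> numeric days per week.
FREQUENCY_DAYS: Mapping[str, float] = {
    "less than 1 day/month": 0.0,
    "1-3 days/month": 0.5,
    "1-2 days/week": 1.5,
    "3-4 days/week": 3.5,
    "5-6 days/week": 5.5,
    "every day": 7.0,
}

#: Ethanol content per reference serving: beverage -> (reference ml, grams).
#: Conversion is linear in volume.
ETHANOL_CONTENT: Mapping[str, tuple[float, float]] = {
    "sake": (180.0, 23.0),
    "shochu": (180.0, 36.0),
    "chu-hai": (180.0, 12.96),
    "beer": (633.0, 23.0),
    "whisky": (30.0, 10.0),
    "wine": (100.0, 12.0),
}

#: One US standard drink in grams of ethanol.
GRAMS_PER_DRINK = 14.0

#: Lower bounds (drinks/day) of tiers 0..4; intervals are half-open
#: [lo, next_lo) except the last, which is unbounded above.
TIER_CUTPOINTS_DRINKS = (0.0, 0.1, 1.0, 2.0, 3.0)


class VocabularyError(ValueError):
    """An answer outside the questionnaire's closed vocabulary."""


@dataclass(frozen=True)
class DrinkingProfile:
    """One subject's raw drinking answers.

    ``beverage_volumes`` maps beverage type to millilitres consumed per
    (drinking) week.
    """

    status: str
    frequency_category: str
    beverage_volumes: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.status not in STATUS_VOCAB:
            raise VocabularyError(f"unknown drinking status: {self.status!r}")
        if self.frequency_category not in FREQUENCY_DAYS:
            raise VocabularyError(
                f"unknown frequency category: {self.frequency_category!r}"
            )
        for bev, vol in self.beverage_volumes.items():
            if bev not in ETHANOL_CONTENT:
                raise VocabularyError(f"unknown beverage: {bev!r}")
            if vol < 0:
                raise ValueError(f"negative volume for {bev}: {vol}")


@dataclass(frozen=True)
class ExposureRecord:
    """Analysis-ready alcohol exposure for one subject."""

    wac: float  # g ethanol / week
    dac: float  # g ethanol / day
    dac_drinks: float  # standard drinks / day
    tier: int  # 0..4
    frequency_days: float  # days / week


def frequency_to_days(category: str) -> float:
    """Map a drinking-frequency answer to numeric days per week."""
    try:
        return FREQUENCY_DAYS[category]
    except KeyError:
        raise VocabularyError(f"unknown frequency category: {category!r}") from None


def beverage_to_ethanol_grams(beverage: str, volume_ml: float) -> float:
    """Grams of ethanol in ``volume_ml`` of ``beverage``.

    Linear in volume from the per-serving reference content, e.g. 180 ml of
    sake carries 23 g of ethanol, so 360 ml carries 46 g.
    """
    if beverage not in ETHANOL_CONTENT:
        raise VocabularyError(f"unknown beverage: {beverage!r}")
    if volume_ml < 0:
        raise ValueError(f"volume must be >= 0, got {volume_ml}")
    ref_ml, ref_g = ETHANOL_CONTENT[beverage]
    return volume_ml * ref_g / ref_ml


def assign_tier(dac_drinks: float) -> int:
    """Five-tier consumption stratum from drinks/day.

    tier 0: < 0.1; tier 1: [0.1, 1); tier 2: [1, 2); tier 3: [2, 3);
    tier 4: >= 3 drinks/day.
    """
    if dac_drinks < 0:
        raise ValueError("drinks/day must be >= 0")
    tier = 0
    for t, lo in enumerate(TIER_CUTPOINTS_DRINKS[1:], start=1):
        if dac_drinks >= lo:
            tier = t
    return tier


def compute_exposure(profile: DrinkingProfile) -> ExposureRecord:
    """Weekly/daily ethanol grams, standard drinks and tier for one subject.

    WAC is the sum of ethanol grams over the reported weekly beverage
    volumes; DAC = WAC / 7; drinks/day = DAC / 14 g. Any non-current
    drinking status forces WAC = DAC = 0 and tier 0, regardless of reported
    volumes.
    """
    freq_days = frequency_to_days(profile.frequency_category)
    if profile.status != "current":
        return ExposureRecord(0.0, 0.0, 0.0, 0, freq_days)
    wac = sum(
        beverage_to_ethanol_grams(bev, vol)
        for bev, vol in profile.beverage_volumes.items()
    )
    dac = wac / 7.0
    drinks = dac / GRAMS_PER_DRINK
    return ExposureRecord(wac, dac, drinks, assign_tier(drinks), freq_days)
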