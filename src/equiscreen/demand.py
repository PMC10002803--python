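"""Annual screening-mammography demand under competing guideline rules.

Three demand specifications convert a tract's female age-band counts into
the number of screenings owed per year:

``uspstf``
    Biennial screening for women aged 50-74; half of the eligible
    population is screened in any given year (steady state).
``race``
    The USPSTF rule plus biennial screening of Black women aged 40-49.
    Black women in the 40-49 band are estimated by applying the
    tract-level percent-Black fraction to the band count (no
    age-by-race cross-tabulation is available at tract level).
``acr``
    Annual screening for all women aged 40 and older, with no upper
    age cap; the full eligible population is owed a screening each year.

Demand values are real-valued; rounding happens only at report time so
the allocation stage is free of order-dependent rounding artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PER_UNIT_ANNUAL",
    "PER_UNIT_HOURLY",
    "CapacityModel",
    "DemandSpecification",
    "SPEC_NAMES",
    "demand_uspstf",
    "demand_race_based",
    "demand_acr",
    "demand_specification",
    "facility_capacity",
]

#: Screenings one mammography unit can perform per year.
PER_UNIT_ANNUAL = 4500.0

#: Documentation constant: maximum screenings per unit per business hour.
PER_UNIT_HOURLY = 3.0

SPEC_NAMES = ("uspstf", "race", "acr")


@dataclass(frozen=True)
class CapacityModel:
    """Annual throughput model for a mammography site.

    Capacity scales linearly in the number of active units.
    """

    per_unit_annual: float = PER_UNIT_ANNUAL
    per_hour: float = PER_UNIT_HOURLY

    def __post_init__(self) -> None:
        if self.per_unit_annual <= 0:
            raise ValueError("per_unit_annual must be positive")


def facility_capacity(units: int, model: CapacityModel = CapacityModel()) -> float:
    """Annual screening capacity of a site with ``units`` mammography units."""
    if units < 1:
        raise ValueError(f"a facility must have at least one unit, got {units}")
    return units * model.per_unit_annual


def demand_uspstf(tract) -> float:
    """Annual screenings owed under biennial screening of women 50-74."""
    return tract.women_50_74 / 2.0


def demand_race_based(tract) -> float:
    """USPSTF demand plus biennial screening of Black women aged 40-49."""
    return tract.women_50_74 / 2.0 + tract.pct_black_women * tract.women_40_49 / 2.0


def demand_acr(tract) -> float:
    """Annual screenings owed under annual screening of all women 40+."""
    return float(tract.women_40_49 + tract.women_50_74 + tract.women_over_74)


DEMAND_FUNCTIONS = {
    "uspstf": demand_uspstf,
    "race": demand_race_based,
    "acr": demand_acr,
}


@dataclass(frozen=True)
class DemandSpecification:
    """Per-tract annual screening demand under one guideline rule."""

    name: str
    annual_screenings: Mapping[str, float]
    table: pd.DataFrame = field(repr=False)

    def total(self) -> float:
        return float(sum(self.annual_screenings.values()))


def demand_specification(tracts: Iterable, name: str) -> DemandSpecification:
    """Evaluate one demand rule over every tract.

    The returned table carries the per-component provenance: the
    age-band-by-interval contributions that sum to each tract's total.
    """
    if name not in DEMAND_FUNCTIONS:
        raise ValueError(f"unknown demand specification {name!r}; choose from {SPEC_NAMES}")
    rows = []
    for t in tracts:
        biennial_50_74 = t.women_50_74 / 2.0
        biennial_black_40_49 = t.pct_black_women * t.women_40_49 / 2.0
        annual_40_plus = float(t.women_40_49 + t.women_50_74 + t.women_over_74)
        if name == "uspstf":
            total = biennial_50_74
            components = {"biennial_50_74": biennial_50_74}
        elif name == "race":
            total = biennial_50_74 + biennial_black_40_49
            components = {
                "biennial_50_74": biennial_50_74,
                "biennial_black_40_49": biennial_black_40_49,
            }
        else:
            total = annual_40_plus
            components = {"annual_40_plus": annual_40_plus}
        rows.append({"tract_id": t.tract_id, "spec_name": name,
                     "annual_screenings": total, **components})
    table = pd.DataFrame(rows)
    annual = {r["tract_id"]: r["annual_screenings"] for r in rows}
    return DemandSpecification(name=name, annual_screenings=annual, table=table)
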