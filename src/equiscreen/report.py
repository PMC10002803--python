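"""Report tables with integer percentage shares.

Percentages in summary tables are rounded half-up to integers,
matching the granularity at which inventory shares are usually
printed; unrounded values are kept in ``*_share_raw`` columns.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["round_half_up", "pct_share", "inventory_summary"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero-point-five up."""
    return int(math.floor(x + 0.5))


def pct_share(part: float, whole: float) -> int:
    """Integer percent ``part`` is of ``whole`` (half-up)."""
    if whole == 0:
        raise ValueError("whole must be non-zero")
    return round_half_up(100.0 * part / whole)


def inventory_summary(tracts: Iterable, facilities: Sequence) -> pd.DataFrame:
    """Counts and percent shares by county, plus a statewide row.

    Columns cover population, facilities, units, BICOE sites and BICOE
    units, each with the county's integer share of the statewide
    total, and the within-row percent of facilities that are BICOE.
    """
    tracts = list(tracts)
    facilities = list(facilities)
    counties = sorted({f.county for f in facilities if f.county is not None}
                      | {t.county for t in tracts})

    def tally(county=None):
        fs = facilities if county is None else [f for f in facilities
                                                if f.county == county]
        ts = tracts if county is None else [t for t in tracts
                                            if t.county == county]
        return {
            "population": sum(t.population for t in ts),
            "facilities": len(fs),
            "units": sum(f.units for f in fs),
            "bicoe_sites": sum(1 for f in fs if f.bicoe),
            "bicoe_units": sum(f.units for f in fs if f.bicoe),
        }

    state = tally()
    rows = []
    for name, t in [("statewide", state)] + [(c, tally(c)) for c in counties]:
        row = {"county": name, **t}
        for key in ("population", "facilities", "units", "bicoe_sites",
                    "bicoe_units"):
            if state[key] > 0:
                row[f"{key}_share_raw"] = 100.0 * t[key] / state[key]
                row[f"{key}_share_pct"] = pct_share(t[key], state[key])
            else:
                row[f"{key}_share_raw"] = float("nan")
                row[f"{key}_share_pct"] = None
        row["pct_facilities_bicoe"] = (
            pct_share(t["bicoe_sites"], t["facilities"]) if t["facilities"] else None)
        rows.append(row)
    return pd.DataFrame(rows)
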