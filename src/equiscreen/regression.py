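"""Poisson rate models of per-tract mammography access.

Outcomes are per-tract counts (facilities, units, BICOE facilities,
BICOE units).  Every model standardizes its covariates within the
fitted stratum (sample SD, n-1 denominator), includes log population
as an offset, and reports exponentiated coefficients as rate ratios
per standard deviation with 95% Wald intervals on the log scale.

Strata with too few outcome events (< MIN_EVENTS) are flagged
unavailable instead of reporting unstable estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "COVARIATE_ORDER",
    "OUTCOMES",
    "STRATA",
    "MIN_EVENTS",
    "RateModelSpec",
    "RateModelResult",
    "ModelDegenerateError",
    "standardize",
    "fit_rate_model",
    "stratified_fits",
    "counts_by_tract",
]

#: Fixed covariate order used across generation, fitting and reporting.
COVARIATE_ORDER = (
    "deprivation",
    "women_40_49",
    "women_50_74",
    "women_over_74",
    "pct_black_women",
    "pct_vehicle",
    "bus_stops",
)

OUTCOMES = ("facilities", "units", "bicoe_facilities", "bicoe_units")
STRATA = ("statewide", "urban", "rural")

#: A stratum model is suppressed when its outcome total is below this.
MIN_EVENTS = 5


class ModelDegenerateError(RuntimeError):
    """Raised when a fit fails to converge or is separation-like."""


@dataclass(frozen=True)
class RateModelSpec:
    outcome: str = "facilities"
    covariates: Sequence[str] = COVARIATE_ORDER
    stratum: str = "statewide"

    def __post_init__(self):
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}, got {self.stratum!r}")


@dataclass(frozen=True)
class RateModelResult:
    """Rate ratios per SD with 95% CIs and the scaling constants used."""

    spec: RateModelSpec
    table: pd.DataFrame            # covariate, rr, ci_low, ci_high
    intercept: float
    scaling: Mapping[str, tuple]   # covariate -> (mean, sd)
    n_tracts: int
    n_events: float
    converged: bool

    def rr(self, covariate: str) -> float:
        return float(self.table.set_index("covariate").loc[covariate, "rr"])


def standardize(column, name: str = "covariate") -> tuple[np.ndarray, float, float]:
    """Center and scale to unit sample SD; returns (z, mean, sd)."""
    x = np.asarray(column, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"covariate {name!r} is constant; cannot standardize")
    return (x - mean) / sd, mean, sd


def _design(tracts: Sequence, covariates: Sequence[str]):
    cols, scaling = {}, {}
    for name in covariates:
        raw = [getattr(t, name) for t in tracts]
        z, mean, sd = standardize(raw, name)
        cols[name] = z
        scaling[name] = (mean, sd)
    X = pd.DataFrame(cols)
    return sm.add_constant(X, has_constant="add"), scaling


def fit_rate_model(spec: RateModelSpec, tracts: Sequence, counts) -> RateModelResult:
    """Maximum-likelihood Poisson fit with a log-population offset."""
    tracts = list(tracts)
    if spec.stratum != "statewide":
        keep = [i for i, t in enumerate(tracts) if t.county == spec.stratum]
        tracts = [tracts[i] for i in keep]
        counts = np.asarray(counts, dtype=float)[keep]
    y = np.asarray(counts, dtype=float)
    if len(tracts) == 0:
        raise ValueError(f"no tracts in stratum {spec.stratum!r}")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    pop = np.array([t.population for t in tracts], dtype=float)
    if np.any(pop <= 0):
        raise ValueError("all tracts must be populated")
    X, scaling = _design(tracts, spec.covariates)
    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(pop))
    res = model.fit(maxiter=200)
    if not res.converged:
        raise ModelDegenerateError(
            f"Poisson fit did not converge (outcome={spec.outcome}, "
            f"stratum={spec.stratum})")
    params = res.params
    se = res.bse
    if np.any(~np.isfinite(se)) or np.any(se[1:] > 50):
        raise ModelDegenerateError(
            f"separation-like degeneracy (outcome={spec.outcome}, "
            f"stratum={spec.stratum}): unstable standard errors")
    rows = []
    for name in spec.covariates:
        beta, s = params[name], se[name]
        rows.append({
            "covariate": name,
            "rr": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * s)),
            "ci_high": float(np.exp(beta + 1.96 * s)),
        })
    return RateModelResult(
        spec=spec,
        table=pd.DataFrame(rows),
        intercept=float(params["const"]),
        scaling=scaling,
        n_tracts=len(tracts),
        n_events=float(y.sum()),
        converged=bool(res.converged),
    )


def counts_by_tract(tracts: Sequence, facilities: Iterable) -> dict[str, np.ndarray]:
    """Per-tract outcome counts from a facility inventory.

    Facilities carrying a ``tract_id`` are counted there; otherwise a
    facility is attributed to the tract with the nearest centroid.
    """
    index = {t.tract_id: i for i, t in enumerate(tracts)}
    out = {o: np.zeros(len(tracts), dtype=int) for o in OUTCOMES}
    for f in facilities:
        tid = getattr(f, "tract_id", None)
        if tid is None or tid not in index:
            d2 = [(t.centroid_x - f.x) ** 2 + (t.centroid_y - f.y) ** 2
                  for t in tracts]
            tid = tracts[int(np.argmin(d2))].tract_id
        i = index[tid]
        out["facilities"][i] += 1
        out["units"][i] += f.units
        if f.bicoe:
            out["bicoe_facilities"][i] += 1
            out["bicoe_units"][i] += f.units
    return out


def stratified_fits(tracts: Sequence, counts_by_outcome: Mapping[str, Sequence],
                    min_events: int = MIN_EVENTS) -> pd.DataFrame:
    """Fit every outcome in every stratum; suppress sparse strata.

    Returns a long table (outcome, stratum, covariate, rr, ci_low,
    ci_high, flag).  A stratum whose outcome total is below
    ``min_events`` gets a single ``unavailable`` row with NaN
    estimates rather than an unstable fit.
    """
    tracts = list(tracts)
    present = sorted({t.county for t in tracts})
    strata = ["statewide"] + [s for s in STRATA if s in present]
    rows = []
    for outcome, counts in counts_by_outcome.items():
        counts = np.asarray(counts, dtype=float)
        for stratum in strata:
            if stratum == "statewide":
                total = counts.sum()
            else:
                total = counts[[t.county == stratum for t in tracts]].sum()
            if total < min_events:
                rows.append({"outcome": outcome, "stratum": stratum,
                             "covariate": None, "rr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "flag": "unavailable"})
                continue
            spec = RateModelSpec(outcome=outcome, stratum=stratum)
            try:
                result = fit_rate_model(spec, tracts, counts)
            except ModelDegenerateError as exc:
                rows.append({"outcome": outcome, "stratum": stratum,
                             "covariate": None, "rr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "flag": f"degenerate: {exc}"})
                continue
            for rec in result.table.to_dict("records"):
                rows.append({"outcome": outcome, "stratum": stratum,
                             **rec, "flag": "ok"})
    return pd.DataFrame(rows)
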