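"""Composite healthcare-supply index and city typology.

The supply level of a city-year is the equal-weighted sum of four per-capita
indicators — healthcare institutions, beds, doctors, and health expenditure —
each divided by resident population and min-max normalized over the POOLED
city-year panel.  Pooled normalization puts every year on a common scale, so
index levels are comparable across years and a single high/low threshold can
be applied to the multi-year geometric mean.  With unit weights the index
ranges over [0, 4].

Each city is then classified on two axes: supply level (geometric mean of
its index over years, high vs low) and inter-annual variability (temporal
coefficient of variation, equal vs unequal), giving the four-way typology
high-equal / high-unequal / low-equal / low-unequal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateNormalizationError,
    GeometricMeanDomainError,
    MissingDataError,
)

__all__ = [
    "INDICATORS",
    "deflate",
    "composite_index",
    "classify_cities",
    "LEVEL_THRESHOLD",
    "CV_THRESHOLD",
]

INDICATORS = ("institutions", "beds", "doctors", "health_expenditure")

#: Default dividing line between high and low multi-year supply level.
LEVEL_THRESHOLD = 1.27
#: Default dividing line between equal and unequal inter-annual variation.
CV_THRESHOLD = 0.32


def deflate(nominal_series: pd.Series, deflator_index: pd.Series, base_year) -> pd.Series:
    """Convert a nominal currency series to base-year prices.

    ``output_t = nominal_t * deflator(base_year) / deflator(t)``; the
    base-year value is unchanged.  Both series are indexed by year.
    """
    nominal = pd.Series(nominal_series, dtype=float)
    deflator = pd.Series(deflator_index, dtype=float)
    needed = set(nominal.index) | {base_year}
    missing = sorted(y for y in needed if y not in deflator.index)
    if missing:
        raise MissingDataError(f"deflator missing for years: {missing}")
    if (deflator <= 0).any():
        raise MissingDataError("deflator values must be positive")
    return nominal * deflator.loc[base_year] / deflator.loc[nominal.index].to_numpy()


def composite_index(
    panel: pd.DataFrame,
    indicators=INDICATORS,
    population_col: str = "population",
    out_col: str = "supply_index",
) -> pd.DataFrame:
    """Fill the composite supply index on a copy of the panel.

    Each indicator is divided by population, min-max normalized over the
    pooled city-year panel, and the four normalized values are summed with
    unit weights.  Also emits ``percap_<indicator>`` columns.
    """
    out = panel.copy()
    total = np.zeros(len(out))
    for ind in indicators:
        percap = out[ind].to_numpy(dtype=float) / out[population_col].to_numpy(dtype=float)
        lo, hi = percap.min(), percap.max()
        if hi == lo:
            raise DegenerateNormalizationError(
                f"indicator {ind!r} is constant across the panel; "
                "min-max normalization is degenerate"
            )
        out[f"percap_{ind}"] = percap
        total = total + (percap - lo) / (hi - lo)
    out[out_col] = total
    return out


def classify_cities(
    panel: pd.DataFrame,
    level_threshold: float = LEVEL_THRESHOLD,
    cv_threshold: float = CV_THRESHOLD,
    value_col: str = "supply_index",
    city_col: str = "city_id",
) -> pd.DataFrame:
    """Four-way city typology from the multi-year index series.

    Per city: ``geo_mean`` is the geometric mean of the index over years and
    ``temporal_cv`` the sample-sd/mean over years.  Boundary conventions:
    ``geo_mean >= level_threshold`` is high, ``temporal_cv <= cv_threshold``
    is equal.
    """
    rows = []
    for cid, grp in panel.groupby(city_col, sort=True):
        v = grp[value_col].to_numpy(dtype=float)
        if (v <= 0).any():
            raise GeometricMeanDomainError(
                f"city {cid!r} has non-positive index values; geometric mean undefined"
            )
        geo = float(np.exp(np.mean(np.log(v))))
        cv = float(v.std(ddof=1) / v.mean())
        level = "high" if geo >= level_threshold else "low"
        equality = "equal" if cv <= cv_threshold else "unequal"
        rows.append(
            {
                "city_id": cid,
                "geo_mean": geo,
                "temporal_cv": cv,
                "level": level,
                "equality": equality,
                "type_label": f"{level}-{equality}",
            }
        )
    return pd.DataFrame(rows)
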