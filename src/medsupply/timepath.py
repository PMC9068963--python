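"""Dynamic-LISA time-path geometry.

Each city traces a trajectory L_{i,t} = (z_it, lag_it) through the Moran
scatterplot, where z_it is its cross-sectionally standardized index in year
t and lag_it the spatial lag of the standardized index.  Two geometric
summaries describe the local spatio-temporal dynamics:

* **relative length**  N~_i = N * len_i / sum_j len_j, where len_i is the
  total Euclidean path length of city i.  Values above 1 mark cities whose
  local spatial structure moved more than average; sum_i N~_i = N.
* **curvature**  D_i = len_i / d(L_{i,1}, L_{i,T}) — total path length over
  net start-to-end displacement (tortuosity).  D_i = 1 for a straight
  monotone trajectory and grows with directional volatility; it is
  undefined when start and end coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError, UndefinedStatisticError
from .weights import SpatialWeights

__all__ = ["TimePath", "moran_scatter_paths", "relative_length", "curvature", "timepath_table"]


@dataclass(frozen=True)
class TimePath:
    """Per-city Moran-scatterplot trajectory."""

    city_id: object
    coords: np.ndarray  # (T, 2): (z, spatial lag) per year, in year order

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    @property
    def net_displacement(self) -> float:
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))


def moran_scatter_paths(
    panel: pd.DataFrame,
    W: SpatialWeights,
    value_col: str = "supply_index",
    city_col: str = "city_id",
    year_col: str = "year",
) -> list[TimePath]:
    """Moran-scatter trajectories, one per city, ordered as ``W.ids``.

    The index is z-standardized per year (population sd, the Moran
    scatterplot convention), lags use the row-standardized weights, and the
    panel must be balanced.
    """
    wide = panel.pivot(index=city_col, columns=year_col, values=value_col)
    if wide.isna().any().any():
        missing = wide.isna().stack()
        bad = list(missing[missing].index[:5])
        raise BalanceError(f"panel is unbalanced; missing city-years include {bad}")
    wide = wide.loc[list(W.ids)]
    if not W.standardized:
        W = W.standardize()
    x = wide.to_numpy(dtype=float)
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    lag = W.matrix @ z
    return [
        TimePath(city_id=cid, coords=np.column_stack([z[i], lag[i]]))
        for i, cid in enumerate(W.ids)
    ]


def relative_length(paths: list[TimePath]) -> pd.Series:
    """Relative path length N~_i = N * len_i / sum_j len_j (sums to N)."""
    lengths = np.array([p.total_length for p in paths])
    total = lengths.sum()
    if total == 0:
        raise UndefinedStatisticError(
            "all time paths are stationary; relative length undefined"
        )
    return pd.Series(
        len(paths) * lengths / total,
        index=[p.city_id for p in paths],
        name="relative_length",
    )


def curvature(paths: list[TimePath]) -> pd.Series:
    """Tortuosity D_i = total path length / net displacement (NaN when the
    trajectory returns to its starting point)."""
    vals = []
    for p in paths:
        net = p.net_displacement
        vals.append(p.total_length / net if net > 0 else np.nan)
    return pd.Series(vals, index=[p.city_id for p in paths], name="curvature")


def timepath_table(paths: list[TimePath]) -> pd.DataFrame:
    """Per-city summary: relative length, curvature, total length, net displacement."""
    rel = relative_length(paths)
    curv = curvature(paths)
    return pd.DataFrame(
        {
            "city_id": [p.city_id for p in paths],
            "relative_length": rel.to_numpy(),
            "curvature": curv.to_numpy(),
            "total_length": [p.total_length for p in paths],
            "net_displacement": [p.net_displacement for p in paths],
        }
    )
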