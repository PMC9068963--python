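"""Global and local Moran statistics with inference.

Global Moran's I measures spatial autocorrelation of a cross-section:

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z_i = x_i - mean(x)

with expectation E[I] = -1/(n-1) under the null of no spatial association.
Inference is available under the normal approximation with the
randomization (permutation-exact) variance, or by Monte-Carlo permutation.

The local Moran (LISA) decomposes I into per-unit contributions

    I_i = z_i * sum_j w_ij z_j

where z are z-scores (population-sd standardization), so that with a
row-standardized W the identity (1/n) sum_i I_i = I holds exactly.  Each
unit is classified into a Moran-scatterplot quadrant: HH and LL mark local
clusters (positive association), HL and LH mark local outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError
from .weights import SpatialWeights

__all__ = ["MoranResult", "global_moran", "local_moran", "quadrant_shares"]

QUADRANTS = ("HH", "LL", "LH", "HL")


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with its null moments and a one-sided p-value."""

    I: float
    expectation: float
    variance: float
    z: float
    p: float
    method: str
    n_perm: int = 0


def _check_values(values, n_min: int = 4) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ConfigurationError("values must be one-dimensional")
    if x.shape[0] < n_min:
        raise ConfigurationError(f"need at least {n_min} units, got {x.shape[0]}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("values are constant; Moran's I is undefined")
    return x


def _moran_stat(x: np.ndarray, W: SpatialWeights) -> float:
    z = x - x.mean()
    n = z.shape[0]
    return float(n / W.s0 * (z @ W.lag(z)) / (z @ z))


def _randomization_variance(x: np.ndarray, W: SpatialWeights) -> float:
    """Closed-form Var(I) under random relabeling of the observed values."""
    n = x.shape[0]
    w = W.matrix
    s0 = W.s0
    wt = w.T.tocsr()
    s1 = float(((w + wt).power(2)).sum()) / 2.0
    row = np.asarray(w.sum(axis=1)).ravel()
    col = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((row + col) ** 2).sum())
    z = x - x.mean()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    e_i = -1.0 / (n - 1)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    den = (n - 1) * (n - 2) * (n - 3) * s0**2
    return num / den - e_i**2


def global_moran(
    values,
    W: SpatialWeights,
    method: str = "normal",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MoranResult:
    """Global Moran's I with normal-approximation or permutation inference.

    Parameters
    ----------
    values : array-like of shape (n,)
        Cross-sectional attribute, ordered as ``W.ids``.
    W : SpatialWeights
        Spatial weights; any standardization state is accepted.
    method : {"normal", "permutation"}
        ``normal`` uses the randomization variance and a Gaussian reference;
        ``permutation`` relabels the values ``n_perm`` times and reports
        ``p = (#{I_perm >= I_obs} + 1)/(n_perm + 1)``.
    alternative : {"greater", "two-sided"}
        One-sided (positive autocorrelation, the default) or two-sided test.
    """
    x = _check_values(values)
    if x.shape[0] != W.n:
        raise ConfigurationError("values length must match weights order")
    i_obs = _moran_stat(x, W)
    n = x.shape[0]
    e_i = -1.0 / (n - 1)
    if method == "normal":
        var = _randomization_variance(x, W)
        z = (i_obs - e_i) / np.sqrt(var)
        p = stats.norm.sf(z)
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(z))
        return MoranResult(i_obs, e_i, var, float(z), float(min(p, 1.0)), "normal")
    if method == "permutation":
        rng = np.random.default_rng(seed)
        sims = np.empty(n_perm)
        for b in range(n_perm):
            sims[b] = _moran_stat(rng.permutation(x), W)
        var = float(sims.var(ddof=1))
        z = (i_obs - sims.mean()) / sims.std(ddof=1)
        if alternative == "two-sided":
            extreme = np.abs(sims - sims.mean()) >= abs(i_obs - sims.mean())
        else:
            extreme = sims >= i_obs
        p = (extreme.sum() + 1) / (n_perm + 1)
        return MoranResult(i_obs, e_i, var, float(z), float(p), "permutation", n_perm)
    raise ConfigurationError(f"unknown inference method: {method!r}")


def _zscores(x: np.ndarray) -> np.ndarray:
    # population (n-denominator) sd: makes (1/n) sum I_i == I exact
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd


def local_moran(
    values,
    W: SpatialWeights,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Local Moran statistics, quadrant labels, and conditional-permutation p.

    Returns a DataFrame with one row per unit: ``city_id``, ``z`` (z-score),
    ``lag`` (spatial lag of z-scores), ``I_i``, ``quadrant`` and ``p_i``.
    Ties (z or lag exactly 0) are assigned to the "high" side.
    """
    x = _check_values(values)
    if x.shape[0] != W.n:
        raise ConfigurationError("values length must match weights order")
    if not W.standardized:
        W = W.standardize()
    n = x.shape[0]
    z = _zscores(x)
    lag = W.lag(z)
    i_local = z * lag

    hi = z >= 0
    hi_lag = lag >= 0
    quadrant = np.where(
        hi & hi_lag, "HH", np.where(~hi & ~hi_lag, "LL", np.where(hi, "HL", "LH"))
    )

    # conditional permutation: hold z_i fixed, permute the other n-1 values
    # among the neighbor slots
    rng = np.random.default_rng(seed)
    m = W.matrix.tocsr()
    p_i = np.empty(n)
    others_idx = np.arange(n)
    for i in range(n):
        nbrs = m.indices[m.indptr[i] : m.indptr[i + 1]]
        wts = m.data[m.indptr[i] : m.indptr[i + 1]]
        if len(nbrs) == 0:
            p_i[i] = 1.0
            continue
        pool = z[others_idx != i]
        draws = rng.permuted(
            np.broadcast_to(pool, (n_perm, n - 1)).copy(), axis=1
        )[:, : len(nbrs)]
        sims = z[i] * (draws @ wts)
        p_i[i] = ((sims >= i_local[i]).sum() + 1) / (n_perm + 1)

    return pd.DataFrame(
        {
            "city_id": list(W.ids),
            "z": z,
            "lag": lag,
            "I_i": i_local,
            "quadrant": quadrant,
            "p_i": p_i,
        }
    )


def quadrant_shares(lisa: pd.DataFrame) -> pd.Series:
    """Percent of units per Moran quadrant (all units, no significance filter)."""
    if len(lisa) == 0:
        raise ConfigurationError("empty LISA result")
    counts = lisa["quadrant"].value_counts()
    shares = pd.Series({q: 100.0 * counts.get(q, 0) / len(lisa) for q in QUADRANTS})
    shares.name = "share_pct"
    return shares
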