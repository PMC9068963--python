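"""Synthetic city-panel generator with known ground truth.

Emulates the structure of a prefecture-city health-supply panel: n cities
observed over T years, six socio-economic covariates with tunable spatial
autocorrelation, a response assembled from known (possibly space-time
varying) coefficient surfaces plus Gaussian noise, and four raw healthcare
indicators (institutions, beds, doctors, expenditure) from which the
composite supply index can be rebuilt downstream.

The generating model mirrors a spatially varying coefficient regression:

    y_i = beta_0(u_i, v_i, t_i) + sum_k beta_k(u_i, v_i, t_i) x_ik + eps_i

Coefficient surfaces may be constant, linear in (u, v, t), or a Gaussian
bump; time is a linear index scaled to [0, 1] so temporal distances are
commensurate with the unit-square spatial coordinates.  Covariate spatial
autocorrelation is induced by the SAR-style smoother (I - rho W)^-1 applied
to i.i.d. normal draws, with W a row-standardized k-nearest-neighbor graph
(k=4); an AR(1) process (phi=0.7) adds temporal persistence.  Everything is
driven by a single integer seed, and the full truth (coefficients, noise
draws, coordinates) is returned alongside the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .weights import knn_weights

__all__ = [
    "COVARIATES",
    "SimulationConfig",
    "SimulationTruth",
    "generate_geometry",
    "generate_panel",
    "constant_surfaces",
    "default_surfaces",
]

COVARIATES = ("Pgdp", "Pfin", "Dens", "Urba", "Disp", "Inru")

#: Per-capita scale of each raw indicator (arbitrary positive units; the
#: composite index is invariant to them).
_INDICATOR_SCALES = {
    "institutions": 5e-4,
    "beds": 6e-3,
    "doctors": 3e-3,
    "health_expenditure": 2e3,
}


def default_surfaces() -> dict:
    """Default coefficient surfaces: a north-south intercept gradient,
    two Gaussian-bump covariate effects, and signs echoing the stylized
    facts of city health-supply panels (urbanization positive, density and
    urban-rural income gap negative)."""
    return {
        "intercept": {"kind": "linear", "intercept": 1.8, "du": 0.0, "dv": -0.6, "dt": 0.5},
        "Pgdp": {
            "kind": "gaussian-bump",
            "center": [0.3, 0.3, 0.7],
            "width": 0.35,
            "amplitude": 0.6,
            "baseline": -0.1,
        },
        "Pfin": {"kind": "linear", "intercept": 0.3, "du": 0.0, "dv": 0.0, "dt": -0.5},
        "Dens": {"kind": "constant", "value": -0.3},
        "Urba": {"kind": "linear", "intercept": 0.3, "du": 0.0, "dv": 0.0, "dt": 0.2},
        "Disp": {
            "kind": "gaussian-bump",
            "center": [0.7, 0.6, 0.5],
            "width": 0.4,
            "amplitude": 0.4,
            "baseline": 0.1,
        },
        "Inru": {"kind": "constant", "value": -0.25},
    }


def bump_surfaces(seed: int = 0, amplitude: float = 0.8, width: float = 0.3) -> dict:
    """Gaussian-bump surfaces for every covariate (strongly varying
    coefficients), with bump centers drawn from the given seed.  Useful for
    parameter-recovery experiments where the local fit should beat a pooled
    regression."""
    rng = np.random.default_rng(seed)
    out = {"intercept": {"kind": "linear", "intercept": 1.8, "du": 0.0, "dv": -0.6, "dt": 0.5}}
    for i, name in enumerate(COVARIATES):
        sign = 1.0 if i % 2 == 0 else -1.0
        out[name] = {
            "kind": "gaussian-bump",
            "center": rng.uniform(0.1, 0.9, size=3).tolist(),
            "width": width,
            "amplitude": sign * amplitude,
            "baseline": float(rng.uniform(-0.2, 0.2)),
        }
    return out


def constant_surfaces(values: dict | None = None) -> dict:
    """Constant coefficient surfaces (useful for exact-recovery tests)."""
    base = {"intercept": 1.5, "Pgdp": 0.4, "Pfin": 0.2, "Dens": -0.3,
            "Urba": 0.3, "Disp": 0.25, "Inru": -0.25}
    if values:
        base.update(values)
    return {k: {"kind": "constant", "value": v} for k, v in base.items()}


@dataclass(frozen=True)
class SimulationConfig:
    n_cities: int = 41
    n_years: int = 13
    start_year: int = 2007
    layout: str = "random-uniform"
    spatial_autocorr_rho: float = 0.6
    temporal_ar: float = 0.7
    coefficient_surfaces: dict = field(default_factory=default_surfaces)
    noise_sd: float = 0.1
    population_log_sd: float = 0.5
    indicator_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 4:
            raise ConfigurationError("n_cities must be at least 4")
        if self.n_years < 2:
            raise ConfigurationError("n_years must be at least 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if not 0 <= self.spatial_autocorr_rho < 1:
            raise ConfigurationError(
                "spatial_autocorr_rho must lie in [0, 1) for the SAR smoother "
                "to be invertible"
            )
        if self.layout not in ("grid", "random-uniform"):
            raise ConfigurationError(f"unknown layout: {self.layout!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind a synthetic panel: one row per city-year in the
    same order as the panel, with the true coefficient of every covariate,
    the realized noise draw, coordinates, and the scaled time index."""

    true_beta: pd.DataFrame
    noise_draws: np.ndarray
    coords: pd.DataFrame
    times: np.ndarray


def generate_geometry(n_cities: int, layout: str = "random-uniform", seed: int = 0) -> pd.DataFrame:
    """City coordinates in the unit square.

    ``grid`` places cities on the smallest m-by-m lattice with m^2 >= n,
    filled row-major; ``random-uniform`` draws i.i.d. uniform points
    (resampling the astronomically unlikely duplicate).
    """
    if n_cities < 4:
        raise ConfigurationError("n_cities must be at least 4")
    if layout == "grid":
        m = math.isqrt(n_cities - 1) + 1
        cols, rows = np.meshgrid(np.arange(m), np.arange(m))
        u = (cols.ravel() / (m - 1))[:n_cities]
        v = (rows.ravel() / (m - 1))[:n_cities]
    elif layout == "random-uniform":
        rng = np.random.default_rng(seed)
        pts = rng.uniform(size=(n_cities, 2))
        while len(np.unique(pts, axis=0)) != n_cities:  # pragma: no cover
            pts = rng.uniform(size=(n_cities, 2))
        u, v = pts[:, 0], pts[:, 1]
    else:
        raise ConfigurationError(f"unknown layout: {layout!r}")
    return pd.DataFrame(
        {"city_id": [f"C{i:02d}" for i in range(n_cities)], "u": u, "v": v}
    )


def _evaluate_surface(spec: dict, u, v, t) -> np.ndarray:
    kind = spec.get("kind")
    if kind == "constant":
        return np.full_like(np.asarray(u, dtype=float), float(spec["value"]))
    if kind == "linear":
        return (
            float(spec.get("intercept", 0.0))
            + float(spec.get("du", 0.0)) * u
            + float(spec.get("dv", 0.0)) * v
            + float(spec.get("dt", 0.0)) * t
        )
    if kind == "gaussian-bump":
        c = spec["center"]
        w = float(spec["width"])
        d2 = (u - c[0]) ** 2 + (v - c[1]) ** 2 + (t - c[2]) ** 2
        return float(spec.get("baseline", 0.0)) + float(spec["amplitude"]) * np.exp(
            -d2 / (2 * w * w)
        )
    raise ConfigurationError(f"unknown surface kind: {kind!r}")


def _spatiotemporal_field(rng, smoother, n, T, phi) -> np.ndarray:
    """(n, T) field: SAR-smoothed cross-sections with AR(1) persistence."""
    out = np.empty((n, T))
    innov = smoother @ rng.standard_normal(n)
    out[:, 0] = innov
    scale = math.sqrt(1.0 - phi * phi)
    for t in range(1, T):
        innov = smoother @ rng.standard_normal(n)
        out[:, t] = phi * out[:, t - 1] + scale * innov
    return out


def generate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a balanced city-year panel and its ground truth.

    The returned panel carries, per city-year: coordinates, population, the
    six covariates (pooled-standardized), four raw indicator columns, and a
    ``supply_index`` column holding the simulated response itself.  The
    truth object allows exact reconstruction:
    ``supply_index - (beta_0 + sum_k beta_k x_k) == noise_draws``.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_cities, config.n_years
    geom = generate_geometry(n, config.layout, seed=config.seed)
    years = np.arange(config.start_year, config.start_year + T)
    t_scaled = (years - years[0]) / (years[-1] - years[0])

    rho = config.spatial_autocorr_rho
    if rho > 0:
        w = knn_weights(geom[["u", "v"]].to_numpy(), k=min(4, n - 1), standardize=True)
        smoother = np.linalg.inv(np.eye(n) - rho * w.to_dense())
    else:
        smoother = np.eye(n)

    # covariates: spatially autocorrelated, temporally persistent, then
    # standardized over the pooled panel so effect sizes are comparable
    fields = {}
    for name in COVARIATES:
        f = _spatiotemporal_field(rng, smoother, n, T, config.temporal_ar)
        fields[name] = (f - f.mean()) / f.std(ddof=0)

    # long format, city-major then year (balanced)
    city_idx = np.repeat(np.arange(n), T)
    year_idx = np.tile(np.arange(T), n)
    u = geom["u"].to_numpy()[city_idx]
    v = geom["v"].to_numpy()[city_idx]
    tt = t_scaled[year_idx]

    surfaces = config.coefficient_surfaces
    missing = [k for k in ("intercept", *COVARIATES) if k not in surfaces]
    if missing:
        raise ConfigurationError(f"coefficient_surfaces missing entries: {missing}")

    beta = {"intercept": _evaluate_surface(surfaces["intercept"], u, v, tt)}
    response = beta["intercept"].copy()
    x_long = {}
    for name in COVARIATES:
        x = fields[name][city_idx, year_idx]
        b = _evaluate_surface(surfaces[name], u, v, tt)
        beta[name] = b
        x_long[name] = x
        response = response + b * x
    noise = config.noise_sd * rng.standard_normal(n * T)
    response = response + noise

    population = np.exp(
        math.log(5e5) + config.population_log_sd * rng.standard_normal(n)
    )[city_idx]

    panel = pd.DataFrame(
        {
            "city_id": geom["city_id"].to_numpy()[city_idx],
            "year": years[year_idx],
            "u": u,
            "v": v,
            "population": population,
            **{k: x_long[k] for k in COVARIATES},
            "supply_index": response,
        }
    )

    # raw indicators: positive per-capita values sharing the composite latent.
    # Redraw the indicator noise if a single record is the pooled minimum of
    # all four per-capita indicators at once: such a record would score an
    # exact 0 on the min-max composite, putting it outside the domain of the
    # geometric-mean typology the panel is meant to exercise.
    latent = 0.5 * (response - response.mean()) / max(response.std(ddof=0), 1e-12)
    logs = {
        ind: latent + config.indicator_noise_sd * rng.standard_normal(n * T)
        for ind in _INDICATOR_SCALES
    }
    argmins = {int(np.argmin(v)) for v in logs.values()}
    if len(argmins) == 1:
        # decouple the minima: swap the lowest and second-lowest values of the
        # first indicator so no record is the pooled minimum of all four at
        # once (such a record would score an exact 0 on the min-max composite,
        # outside the domain of the geometric-mean typology)
        first = next(iter(_INDICATOR_SCALES))
        order = np.argsort(logs[first])
        i_min, i_second = order[0], order[1]
        logs[first][[i_min, i_second]] = logs[first][[i_second, i_min]]
    for ind, scale in _INDICATOR_SCALES.items():
        panel[ind] = scale * np.exp(logs[ind]) * population

    truth_beta = pd.DataFrame(
        {
            "city_id": panel["city_id"],
            "year": panel["year"],
            "beta_intercept": beta["intercept"],
            **{f"beta_{k}": beta[k] for k in COVARIATES},
        }
    )
    truth = SimulationTruth(
        true_beta=truth_beta, noise_draws=noise, coords=geom.copy(), times=tt
    )
    return panel, truth


def write_panel(panel: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a panel as CSV with the generating seed recorded in a header comment."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# medsupply synthetic panel, seed={seed}\n")
        panel.to_csv(fh, index=False)


def write_truth(truth: SimulationTruth, path, seed: int | None = None) -> None:
    """Write the truth table (coefficients + noise) as a sidecar CSV."""
    tab = truth.true_beta.copy()
    tab["noise"] = truth.noise_draws
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# medsupply simulation truth, seed={seed}\n")
        tab.to_csv(fh, index=False)
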