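"""Geographically and temporally weighted regression (GTWR).

At every space-time location i the model

    y_i = beta_0(u_i, v_i, t_i) + sum_k beta_k(u_i, v_i, t_i) x_ik + eps_i

is estimated by weighted least squares,

    beta_hat(i) = (X' W(i) X)^{-1} X' W(i) y,

with Gaussian kernel weights decaying in the combined spatio-temporal
distance

    d2_ij = (u_i - u_j)^2 + (v_i - v_j)^2 + tau * (t_i - t_j)^2,
    w_ij  = exp(-d2_ij / h^2).

Only the ratio tau of temporal to spatial distance is identifiable jointly
with the bandwidth h, so a single tau parameter is used and the spatial
scale is absorbed into h.  Coordinates are normalized to the unit square
(and time to [0, 1]) by default, which makes h interpretable as a fraction
of the study domain.  The bandwidth (and optionally tau) is selected by
leave-one-out cross-validation with the self-weight set to zero.

The estimator follows the scikit-learn protocol: ``GTWR().fit(X, y,
coords=...)`` with per-observation (u, v, t) coordinates, fitted attributes
with trailing underscores, and ``predict(X, coords=...)`` refitting local
models at the query locations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import ConfigurationError, SingularFitError

__all__ = [
    "GTWR",
    "st_weights",
    "fit_gtwr",
    "select_bandwidth",
    "summarize_coefficients",
    "DEFAULT_BANDWIDTH_GRID",
    "DEFAULT_TAU_GRID",
]

DEFAULT_BANDWIDTH_GRID = (0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.7, 1.0)
DEFAULT_TAU_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def st_weights(
    focal_coord: np.ndarray,
    all_coords: np.ndarray,
    bandwidth: float,
    tau: float = 1.0,
) -> np.ndarray:
    """Gaussian spatio-temporal kernel weights of one focal point against all.

    ``focal_coord`` is (u, v, t); ``all_coords`` has shape (n, 3).  A
    coincident observation (zero distance) gets weight exactly 1.
    """
    if bandwidth <= 0:
        raise ConfigurationError("bandwidth must be positive")
    if tau < 0:
        raise ConfigurationError("tau must be nonnegative")
    f = np.asarray(focal_coord, dtype=float)
    c = np.asarray(all_coords, dtype=float)
    d2 = (c[:, 0] - f[0]) ** 2 + (c[:, 1] - f[1]) ** 2 + tau * (c[:, 2] - f[2]) ** 2
    return np.exp(-d2 / bandwidth**2)


def _weight_matrix(coords: np.ndarray, query: np.ndarray, h: float, tau: float) -> np.ndarray:
    d2 = (
        (query[:, None, 0] - coords[None, :, 0]) ** 2
        + (query[:, None, 1] - coords[None, :, 1]) ** 2
        + tau * (query[:, None, 2] - coords[None, :, 2]) ** 2
    )
    return np.exp(-d2 / (h * h))


def _batched_wls(X: np.ndarray, y: np.ndarray, W: np.ndarray, ridge_scale: float):
    """Solve beta(i) = (X'W(i)X)^-1 X'W(i)y for every row i of W.

    Returns (A, beta) with A the (possibly ridge-stabilized) normal
    matrices.  A single ridge pass (1e-8 of the mean normal-matrix diagonal)
    is attempted on rank deficiency; persistent singularity raises
    :class:`SingularFitError` naming the observation.
    """
    A = np.einsum("mn,np,nq->mpq", W, X, X, optimize=True)
    b = np.einsum("mn,np,n->mp", W, X, y, optimize=True)
    try:
        return A, np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        pass
    p = A.shape[1]
    tr = np.einsum("mpp->m", A) / p
    A = A + (ridge_scale * tr)[:, None, None] * np.eye(p)
    try:
        return A, np.linalg.solve(A, b[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        bad = [
            int(i)
            for i in range(A.shape[0])
            if np.linalg.matrix_rank(A[i]) < p
        ]
        raise SingularFitError(
            f"rank-deficient local design after ridge fallback at observations {bad[:5]}"
        ) from None


class GTWR(RegressorMixin, BaseEstimator):
    """Geographically and temporally weighted regression estimator.

    Parameters
    ----------
    bandwidth : float or None, default=None
        Gaussian kernel bandwidth h on the normalized coordinate scale.
        ``None`` selects h by leave-one-out CV over ``bandwidth_grid``.
    tau : float or None, default=1.0
        Temporal-to-spatial distance ratio.  ``None`` selects tau jointly
        with h over ``tau_grid``.
    bandwidth_grid, tau_grid : sequence of float or None
        Candidate grids for CV selection; package defaults when ``None``.
    normalize_coords : bool, default=True
        Map (u, v) to the unit square and t to [0, 1] before distances.
    standardize_X : bool, default=True
        Z-standardize covariates (population sd) before fitting so local
        coefficient magnitudes are comparable across variables.
    significance_z : float, default=1.96
        |t| threshold used by :func:`summarize_coefficients` (two-sided 5%).
    ridge_scale : float, default=1e-8
        Relative ridge added once to rank-deficient local normal matrices.

    Attributes
    ----------
    beta_ : ndarray of shape (m, k+1)
        Local coefficients, intercept first.
    local_se_, local_t_ : ndarray of shape (m, k+1)
        Local standard errors and t-values.
    residuals_ : ndarray of shape (m,)
    hat_trace_, sigma2_, r2_, adj_r2_, cv_score_ : float
    bandwidth_, tau_ : float
        The fitted (possibly CV-selected) kernel parameters.
    cv_curve_ : DataFrame or None
        Leave-one-out CV score per (h, tau) candidate when selection ran.
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        tau: float | None = 1.0,
        kernel: str = "gaussian",
        bandwidth_grid=None,
        tau_grid=None,
        normalize_coords: bool = True,
        standardize_X: bool = True,
        significance_z: float = 1.96,
        ridge_scale: float = 1e-8,
    ):
        self.bandwidth = bandwidth
        self.tau = tau
        self.kernel = kernel
        self.bandwidth_grid = bandwidth_grid
        self.tau_grid = tau_grid
        self.normalize_coords = normalize_coords
        self.standardize_X = standardize_X
        self.significance_z = significance_z
        self.ridge_scale = ridge_scale

    # -- helpers -----------------------------------------------------------

    def _normalize(self, coords: np.ndarray, fit: bool = False) -> np.ndarray:
        if not self.normalize_coords:
            return coords
        if fit:
            lo = coords.min(axis=0)
            span = coords.max(axis=0) - lo
            span[span == 0] = 1.0
            self._coord_lo_, self._coord_span_ = lo, span
        return (coords - self._coord_lo_) / self._coord_span_

    def _design(self, X: np.ndarray, fit: bool = False) -> np.ndarray:
        if self.standardize_X:
            if fit:
                self._x_mean_ = X.mean(axis=0)
                sd = X.std(axis=0, ddof=0)
                sd[sd == 0] = 1.0
                self._x_sd_ = sd
            X = (X - self._x_mean_) / self._x_sd_
        return np.column_stack([np.ones(len(X)), X])

    def _cv_score(self, Xd, y, coords, h, tau) -> float:
        W = _weight_matrix(coords, coords, h, tau)
        np.fill_diagonal(W, 0.0)
        try:
            _, beta = _batched_wls(Xd, y, W, self.ridge_scale)
        except SingularFitError:
            return np.inf
        resid = y - np.einsum("mp,mp->m", Xd, beta)
        if not np.all(np.isfinite(resid)):
            return np.inf
        return float(resid @ resid)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, coords=None):
        """Fit local models at every observation.

        Parameters
        ----------
        X : array-like of shape (m, k)
            Covariates (no intercept column).
        y : array-like of shape (m,)
        coords : array-like of shape (m, 3)
            Per-observation (u, v, t) coordinates.  Required.
        """
        if self.kernel != "gaussian":
            raise ConfigurationError(f"unsupported kernel: {self.kernel!r}")
        if coords is None:
            raise ConfigurationError("GTWR.fit requires coords=(u, v, t) per observation")
        X, y = check_X_y(X, y, y_numeric=True)
        coords = check_array(coords)
        if coords.shape != (X.shape[0], 3):
            raise ConfigurationError("coords must have shape (n_obs, 3)")
        m, k = X.shape
        if m <= k + 2:
            raise ConfigurationError("need more observations than covariates + 2")
        self.n_features_in_ = k

        c = self._normalize(coords, fit=True)
        Xd = self._design(X, fit=True)

        self.cv_curve_ = None
        h, tau = self.bandwidth, self.tau
        if h is None or tau is None:
            h_grid = list(self.bandwidth_grid or DEFAULT_BANDWIDTH_GRID) if h is None else [h]
            t_grid = list(self.tau_grid or DEFAULT_TAU_GRID) if tau is None else [tau]
            rows = []
            for hc in h_grid:
                for tc in t_grid:
                    rows.append(
                        {"bandwidth": hc, "tau": tc, "cv": self._cv_score(Xd, y, c, hc, tc)}
                    )
            curve = pd.DataFrame(rows)
            if not np.isfinite(curve["cv"]).any():
                raise SingularFitError("leave-one-out CV failed at every grid point")
            best = curve.loc[curve["cv"].idxmin()]
            h, tau = float(best["bandwidth"]), float(best["tau"])
            self.cv_curve_ = curve
            self.cv_score_ = float(best["cv"])
        else:
            self.cv_score_ = self._cv_score(Xd, y, c, h, tau)
        self.bandwidth_, self.tau_ = float(h), float(tau)

        W = _weight_matrix(c, c, self.bandwidth_, self.tau_)
        A, beta = _batched_wls(Xd, y, W, self.ridge_scale)
        fitted = np.einsum("mp,mp->m", Xd, beta)
        resid = y - fitted

        # hat diagonal: S_ii = w_ii x_i' A_i^{-1} x_i with w_ii = 1
        ainv_x = np.linalg.solve(A, Xd[:, :, None])[:, :, 0]
        hat_diag = np.einsum("mp,mp->m", Xd, ainv_x) * np.diag(W)
        tr_s = float(hat_diag.sum())

        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        sigma2 = rss / (m - tr_s)
        a_inv = np.linalg.inv(A)
        B = np.einsum("mn,np,nq->mpq", W * W, Xd, Xd, optimize=True)
        cov = a_inv @ B @ a_inv * sigma2
        # tiny negative diagonals can appear from ill-conditioned local fits
        se = np.sqrt(np.clip(np.einsum("mpp->mp", cov), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))

        self.beta_ = beta
        self.local_se_ = se
        self.local_t_ = tvals
        self.residuals_ = resid
        self.fitted_values_ = fitted
        self.hat_trace_ = tr_s
        self.sigma2_ = float(sigma2)
        self.r2_ = 1.0 - rss / tss
        self.adj_r2_ = 1.0 - (1.0 - self.r2_) * (m - 1) / (m - tr_s - 1)
        # pooled-style accessors (mean local coefficients)
        self.intercept_ = float(beta[:, 0].mean())
        self.coef_ = beta[:, 1:].mean(axis=0)
        # retained so predict() can refit local models at query points
        self._train_X_ = Xd
        self._train_y_ = y
        self._train_coords_ = c
        return self

    def predict(self, X, coords=None):
        """Predict at new locations by fitting a local model at each query point."""
        check_is_fitted(self, "beta_")
        if coords is None:
            raise ConfigurationError("GTWR.predict requires coords=(u, v, t)")
        X = check_array(X)
        coords = check_array(coords)
        Xd = self._design(X)
        c = self._normalize(coords)
        W = _weight_matrix(self._train_coords_, c, self.bandwidth_, self.tau_)
        _, beta = _batched_wls(self._train_X_, self._train_y_, W, self.ridge_scale)
        return np.einsum("mp,mp->m", Xd, beta)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


# -- module-level wrappers over the estimator ------------------------------


def _panel_arrays(panel: pd.DataFrame, covariates, value_col="supply_index"):
    X = panel[list(covariates)].to_numpy(dtype=float)
    y = panel[value_col].to_numpy(dtype=float)
    years = panel["year"].to_numpy()
    t = years.astype(float)
    coords = np.column_stack([panel["u"].to_numpy(), panel["v"].to_numpy(), t])
    return X, y, coords, years


def fit_gtwr(
    panel: pd.DataFrame,
    covariates,
    bandwidth: float | None = None,
    tau: float | None = 1.0,
    value_col: str = "supply_index",
    **kwargs,
) -> GTWR:
    """Fit a GTWR on a tidy city-year panel (u, v, year columns required)."""
    X, y, coords, _ = _panel_arrays(panel, covariates, value_col)
    model = GTWR(bandwidth=bandwidth, tau=tau, **kwargs)
    return model.fit(X, y, coords=coords)


def select_bandwidth(
    panel: pd.DataFrame,
    covariates,
    candidate_h=None,
    candidate_tau=None,
    value_col: str = "supply_index",
    **kwargs,
):
    """Leave-one-out CV bandwidth/tau selection; returns (h*, tau*, cv_curve)."""
    candidate_h = list(candidate_h or DEFAULT_BANDWIDTH_GRID)
    candidate_tau = list(candidate_tau or DEFAULT_TAU_GRID)
    model = GTWR(
        bandwidth=None, tau=None, bandwidth_grid=candidate_h, tau_grid=candidate_tau, **kwargs
    )
    X, y, coords, _ = _panel_arrays(panel, covariates, value_col)
    model.fit(X, y, coords=coords)
    return model.bandwidth_, model.tau_, model.cv_curve_


def summarize_coefficients(
    model: GTWR,
    years,
    covariates,
    alpha_t: float | None = None,
) -> dict:
    """Annual mean coefficients plus sign and significance shares.

    Returns ``{"yearly_means": DataFrame(year x covariate),
    "shares": DataFrame(covariate x [positive_pct, negative_pct,
    significant_pct])}``.  A coefficient of exactly zero counts as positive.
    """
    check_is_fitted(model, "beta_")
    years = np.asarray(years)
    thr = model.significance_z if alpha_t is None else alpha_t
    beta = model.beta_[:, 1:]
    tvals = model.local_t_[:, 1:]
    covariates = list(covariates)
    df = pd.DataFrame(beta, columns=covariates)
    df["year"] = years
    yearly = df.groupby("year").mean()
    pos = 100.0 * (beta >= 0).mean(axis=0)
    sig = 100.0 * (np.abs(tvals) >= thr).mean(axis=0)
    shares = pd.DataFrame(
        {"positive_pct": pos, "negative_pct": 100.0 - pos, "significant_pct": sig},
        index=covariates,
    )
    return {"yearly_means": yearly, "shares": shares}
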