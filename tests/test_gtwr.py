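"""GTWR: kernel weights, exactness limits, inference plumbing, and selection."""

import numpy as np
import pandas as pd
import pytest

from medsupply.errors import ConfigurationError
from medsupply.gtwr import (
    GTWR,
    fit_gtwr,
    select_bandwidth,
    st_weights,
    summarize_coefficients,
)
from medsupply.simulate import (
    COVARIATES,
    SimulationConfig,
    bump_surfaces,
    constant_surfaces,
    generate_panel,
)


def gwr_reference_loop(X, y, coords, h, tau):
    """Independent per-point weighted-least-squares loop (no shared code path)."""
    m = len(y)
    Xd = np.column_stack([np.ones(m), X])
    betas = np.empty((m, Xd.shape[1]))
    for i in range(m):
        d2 = (
            (coords[:, 0] - coords[i, 0]) ** 2
            + (coords[:, 1] - coords[i, 1]) ** 2
            + tau * (coords[:, 2] - coords[i, 2]) ** 2
        )
        w = np.exp(-d2 / h**2)
        WX = Xd * w[:, None]
        betas[i] = np.linalg.solve(Xd.T @ WX, WX.T @ y)
    return betas


class TestSTWeights:
    def test_coincident_observation_weight_one(self):
        w = st_weights([0.2, 0.3, 0.5], [[0.2, 0.3, 0.5]], bandwidth=0.1)
        assert w[0] == 1.0

    def test_tau_zero_ignores_time(self):
        pts = np.array([[0.5, 0.5, 0.0], [0.5, 0.5, 9.0]])
        w = st_weights([0.0, 0.0, 0.0], pts, bandwidth=0.3, tau=0.0)
        assert w[0] == w[1]

    def test_huge_bandwidth_all_weights_one(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(size=(50, 3))
        w = st_weights([0.0, 0.0, 0.0], pts, bandwidth=1e6)
        np.testing.assert_allclose(w, 1.0, atol=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            st_weights([0, 0, 0], [[0, 0, 0]], bandwidth=0.0)
        with pytest.raises(ConfigurationError):
            st_weights([0, 0, 0], [[0, 0, 0]], bandwidth=1.0, tau=-1.0)


class TestExactnessLimits:
    @pytest.mark.parametrize("h,tau", [(0.15, 0.5), (0.3, 1.0), (2.0, 4.0)])
    def test_noiseless_constant_coefficients_recovered(self, h, tau):
        cfg = SimulationConfig(
            n_cities=16, n_years=5, seed=2, noise_sd=0.0,
            coefficient_surfaces=constant_surfaces(),
        )
        panel, truth = generate_panel(cfg)
        model = fit_gtwr(panel, COVARIATES, bandwidth=h, tau=tau, standardize_X=False)
        expected = truth.true_beta[
            ["beta_intercept"] + [f"beta_{c}" for c in COVARIATES]
        ].to_numpy()
        np.testing.assert_allclose(model.beta_, expected, atol=1e-8)
        assert model.r2_ == pytest.approx(1.0, abs=1e-10)

    def test_large_bandwidth_matches_pooled_ols(self, default_panel):
        panel, _ = default_panel
        model = fit_gtwr(
            panel, COVARIATES, bandwidth=1e4, tau=1.0, standardize_X=False
        )
        X = np.column_stack(
            [np.ones(len(panel))] + [panel[c].to_numpy() for c in COVARIATES]
        )
        y = panel["supply_index"].to_numpy()
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(
            model.beta_, np.broadcast_to(ols, model.beta_.shape), atol=1e-6
        )

    def test_single_slice_tau_zero_matches_reference_gwr_loop(self):
        cfg = SimulationConfig(n_cities=25, n_years=2, seed=4)
        panel, _ = generate_panel(cfg)
        one_year = panel[panel["year"] == panel["year"].min()].reset_index(drop=True)
        X = one_year[list(COVARIATES)].to_numpy()
        y = one_year["supply_index"].to_numpy()
        coords = np.column_stack(
            [one_year["u"], one_year["v"], np.zeros(len(one_year))]
        )
        model = GTWR(
            bandwidth=0.3, tau=0.0, normalize_coords=False, standardize_X=False
        ).fit(X, y, coords=coords)
        ref = gwr_reference_loop(X, y, coords, h=0.3, tau=0.0)
        np.testing.assert_allclose(model.beta_, ref, atol=1e-10)


class TestFitDiagnostics:
    def test_residual_identity_and_hat_trace_bounds(self, default_panel):
        panel, _ = default_panel
        model = fit_gtwr(panel, COVARIATES, bandwidth=0.2, tau=1.0)
        Xd = np.column_stack(
            [np.ones(len(panel)), model._design(panel[list(COVARIATES)].to_numpy())[:, 1:]]
        )
        y = panel["supply_index"].to_numpy()
        np.testing.assert_allclose(
            model.residuals_,
            y - np.einsum("mp,mp->m", Xd, model.beta_),
            atol=1e-10,
        )
        k1 = len(COVARIATES) + 1
        assert k1 <= model.hat_trace_ <= len(panel)
        assert model.adj_r2_ <= model.r2_

    def test_in_sample_predict_matches_fitted_values(self, default_panel):
        panel, _ = default_panel
        X = panel[list(COVARIATES)].to_numpy()
        y = panel["supply_index"].to_numpy()
        coords = np.column_stack([panel["u"], panel["v"], panel["year"].astype(float)])
        model = GTWR(bandwidth=0.25, tau=1.0).fit(X, y, coords=coords)
        pred = model.predict(X, coords=coords)
        np.testing.assert_allclose(pred, model.fitted_values_, atol=1e-10)

    def test_sklearn_clone_and_params_roundtrip(self):
        from sklearn.base import clone

        model = GTWR(bandwidth=0.3, tau=2.0)
        cloned = clone(model)
        assert cloned.get_params()["bandwidth"] == 0.3
        assert cloned.get_params()["tau"] == 2.0


class TestBandwidthSelection:
    def test_single_value_grid_returned_with_score(self, default_panel):
        panel, _ = default_panel
        h, tau, curve = select_bandwidth(
            panel, COVARIATES, candidate_h=[0.25], candidate_tau=[1.0]
        )
        assert h == 0.25 and tau == 1.0
        assert len(curve) == 1 and np.isfinite(curve["cv"]).all()

    def test_selected_point_minimizes_cv(self, default_panel):
        panel, _ = default_panel
        h, tau, curve = select_bandwidth(
            panel, COVARIATES, candidate_h=[0.1, 0.3, 0.8], candidate_tau=[0.5, 2.0]
        )
        best = curve.loc[curve["cv"].idxmin()]
        assert h == best["bandwidth"] and tau == best["tau"]
        valid = curve[np.isfinite(curve["cv"])]
        assert (best["cv"] <= valid["cv"]).all()

    def test_varying_surfaces_select_smaller_bandwidth(self):
        """Strongly varying coefficient surfaces demand a more local fit."""
        wins = 0
        for seed in range(5):
            hs = {}
            for name, surf in [
                ("vary", bump_surfaces(seed)),
                ("const", constant_surfaces()),
            ]:
                cfg = SimulationConfig(seed=seed, coefficient_surfaces=surf)
                panel, _ = generate_panel(cfg)
                h, _, _ = select_bandwidth(panel, COVARIATES, candidate_tau=[1.0])
                hs[name] = h
            wins += int(hs["vary"] < hs["const"])
        assert wins >= 4


class TestSummaries:
    def test_positive_share_and_yearly_mean_partition(self, default_panel):
        panel, _ = default_panel
        model = fit_gtwr(panel, COVARIATES, bandwidth=0.2, tau=1.0)
        summary = summarize_coefficients(model, panel["year"].to_numpy(), COVARIATES)
        shares = summary["shares"]
        np.testing.assert_allclose(
            shares["positive_pct"] + shares["negative_pct"], 100.0, atol=1e-12
        )
        assert shares["significant_pct"].between(0, 100).all()
        assert summary["yearly_means"].shape == (
            panel["year"].nunique(), len(COVARIATES),
        )

    def test_yearly_mean_direct_average(self):
        """24 coefficients of +1 and 17 of -1 average to 7/41."""
        model = GTWR(bandwidth=0.5)
        beta = np.ones((41, 2))
        beta[24:, 1] = -1.0
        model.beta_ = beta
        model.local_t_ = np.full((41, 2), 3.0)
        model.significance_z = 1.96
        summary = summarize_coefficients(model, np.full(41, 2007), ["X1"])
        assert summary["yearly_means"].loc[2007, "X1"] == pytest.approx(7 / 41)
        assert summary["shares"].loc["X1", "positive_pct"] == pytest.approx(
            100 * 24 / 41
        )

    def test_all_positive_coefficients_100_percent(self, default_panel):
        panel, _ = default_panel
        model = fit_gtwr(panel, COVARIATES, bandwidth=0.2, tau=1.0)
        model.beta_ = np.abs(model.beta_)
        summary = summarize_coefficients(model, panel["year"].to_numpy(), COVARIATES)
        assert (summary["shares"]["positive_pct"] == 100.0).all()
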