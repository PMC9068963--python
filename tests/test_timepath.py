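"""Dynamic-LISA time-path geometry: lengths, curvature, conservation, symmetry."""

import numpy as np
import pandas as pd
import pytest

from medsupply.errors import BalanceError, UndefinedStatisticError
from medsupply.timepath import (
    TimePath,
    curvature,
    moran_scatter_paths,
    relative_length,
    timepath_table,
)
from medsupply.weights import SpatialWeights


def triangle_weights():
    adj = np.ones((3, 3)) - np.eye(3)
    return SpatialWeights(ids=["A", "B", "C"], matrix=adj).standardize()


def toy_values_panel(values_by_year):
    rows = []
    for year, vals in values_by_year.items():
        for cid, v in zip("ABC", vals):
            rows.append({"city_id": cid, "year": year, "supply_index": v})
    return pd.DataFrame(rows)


class TestScatterPaths:
    def test_hand_computed_coords_3x2(self):
        panel = toy_values_panel({2007: [1.0, 2.0, 3.0], 2008: [4.0, 6.0, 8.0]})
        paths = moran_scatter_paths(panel, triangle_weights())
        # year 2007: mean 2, pop sd sqrt(2/3); z = (-1, 0, 1)/sd
        sd1 = np.sqrt(2.0 / 3.0)
        z1 = np.array([-1, 0, 1]) / sd1
        # lag for complete graph: average of the other two = -z/2
        by_id = {p.city_id: p for p in paths}
        np.testing.assert_allclose(
            by_id["A"].coords[0], [z1[0], -z1[0] / 2], atol=1e-12
        )
        # year 2008: values 4,6,8; z = (-1,0,1)*(2/sd2), sd2 = sqrt(8/3)
        sd2 = np.sqrt(8.0 / 3.0)
        np.testing.assert_allclose(
            by_id["C"].coords[1], [2 / sd2, -1 / sd2], atol=1e-12
        )

    def test_stationary_city_has_zero_segments(self):
        panel = toy_values_panel({2007: [1.0, 2.0, 3.0], 2008: [2.0, 4.0, 6.0]})
        # z-scores identical across years (values scale uniformly)
        paths = moran_scatter_paths(panel, triangle_weights())
        for p in paths:
            np.testing.assert_allclose(p.segment_lengths, 0.0, atol=1e-12)

    def test_year_reversal_reverses_coords_keeps_lengths(self):
        panel = toy_values_panel(
            {2007: [1.0, 5.0, 2.0], 2008: [3.0, 1.0, 4.0], 2009: [2.0, 2.0, 5.0]}
        )
        fwd = moran_scatter_paths(panel, triangle_weights())
        rev_panel = panel.copy()
        rev_panel["year"] = 2009 - (rev_panel["year"] - 2007)
        rev = moran_scatter_paths(rev_panel, triangle_weights())
        f, r = fwd[0], rev[0]
        np.testing.assert_allclose(f.coords, r.coords[::-1], atol=1e-12)
        np.testing.assert_allclose(
            sorted(f.segment_lengths), sorted(r.segment_lengths), atol=1e-12
        )

    def test_unbalanced_panel_rejected(self):
        panel = toy_values_panel({2007: [1.0, 2.0, 3.0], 2008: [4.0, 6.0, 8.0]})
        with pytest.raises(BalanceError):
            moran_scatter_paths(panel.iloc[:-1], triangle_weights())


class TestRelativeLength:
    def path_with_lengths(self, cid, lengths):
        xs = np.concatenate([[0.0], np.cumsum(lengths)])
        return TimePath(city_id=cid, coords=np.column_stack([xs, np.zeros_like(xs)]))

    def test_equal_lengths_give_ones(self):
        paths = [self.path_with_lengths(i, [1.0, 1.0]) for i in range(5)]
        np.testing.assert_allclose(relative_length(paths), 1.0, atol=1e-12)

    def test_direct_evaluation_1_1_2_4(self):
        paths = [
            self.path_with_lengths(i, [l]) for i, l in enumerate([1.0, 1.0, 2.0, 4.0])
        ]
        np.testing.assert_allclose(
            relative_length(paths), [0.5, 0.5, 1.0, 2.0], atol=1e-12
        )

    def test_conservation_sums_to_N(self, default_panel, default_weights):
        panel, _ = default_panel
        paths = moran_scatter_paths(panel, default_weights)
        assert relative_length(paths).sum() == pytest.approx(len(paths), abs=1e-10)

    def test_all_stationary_rejected(self):
        paths = [
            TimePath(city_id=i, coords=np.zeros((3, 2))) for i in range(3)
        ]
        with pytest.raises(UndefinedStatisticError):
            relative_length(paths)


class TestCurvature:
    def test_straight_monotone_path_is_one(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        d = curvature([TimePath(city_id="A", coords=coords)])
        assert d.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_right_angle_path_is_sqrt2(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        d = curvature([TimePath(city_id="A", coords=coords)])
        assert d.iloc[0] == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_closed_loop_is_undefined_not_fatal(self):
        loop = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 0.0]])
        line = np.array([[0.0, 0.0], [1.0, 0.0]])
        d = curvature(
            [TimePath(city_id="A", coords=loop), TimePath(city_id="B", coords=line)]
        )
        assert np.isnan(d.loc["A"])
        assert d.loc["B"] == pytest.approx(1.0)

    def test_curvature_at_least_one_on_fixture(self, default_panel, default_weights):
        panel, _ = default_panel
        d = curvature(moran_scatter_paths(panel, default_weights)).dropna()
        assert (d >= 1.0 - 1e-12).all()

    def test_rotation_invariance_of_both_statistics(self, default_panel, default_weights):
        panel, _ = default_panel
        paths = moran_scatter_paths(panel, default_weights)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = [
            TimePath(city_id=p.city_id, coords=p.coords @ rot.T) for p in paths
        ]
        np.testing.assert_allclose(
            relative_length(paths), relative_length(rotated), atol=1e-10
        )
        np.testing.assert_allclose(
            curvature(paths), curvature(rotated), atol=1e-10
        )


def test_timepath_table_columns(default_panel, default_weights):
    panel, _ = default_panel
    tab = timepath_table(moran_scatter_paths(panel, default_weights))
    assert list(tab.columns) == [
        "city_id", "relative_length", "curvature", "total_length", "net_displacement",
    ]
    assert len(tab) == panel["city_id"].nunique()
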