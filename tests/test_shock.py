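"""Shock engine: value-share mapping, shock formula, triangular bounds."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollenomics import shock as sk
from pollenomics._util import round_half_up


def _dep(rows):
    return pd.DataFrame(rows, columns=["crop_id", "D_mean", "D_min", "D_max"])


def _phi(rows):
    return pd.DataFrame(rows, columns=["commodity_id", "phi"])


def _shares(rows):
    return pd.DataFrame(rows, columns=["region_id", "commodity_id", "crop_id", "share"])


def _values(rows):
    return pd.DataFrame(rows, columns=["region_id", "commodity_id", "crop_id", "value_eur"])


class TestValueShares:
    def test_normalization(self):
        out = sk.map_crops_to_commodities(
            _values([("R", "C", "a", 60.0), ("R", "C", "b", 40.0)])
        )
        assert out.set_index("crop_id")["share"].to_dict() == {"a": 0.6, "b": 0.4}

    def test_single_crop_commodity(self):
        out = sk.map_crops_to_commodities(_values([("R", "C", "a", 123.0)]))
        assert out["share"].tolist() == [1.0]

    def test_zero_value_commodity_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero-value"):
            out = sk.map_crops_to_commodities(
                _values([("R", "C", "a", 0.0), ("R", "C", "b", 0.0), ("R", "D", "c", 5.0)])
            )
        assert set(out["commodity_id"]) == {"D"}

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sk.map_crops_to_commodities(_values([("R", "C", "a", -1.0)]))

    def test_crop_in_two_commodities_rejected(self):
        with pytest.raises(ValueError, match="more than one commodity"):
            sk.map_crops_to_commodities(
                _values([("R", "C", "a", 1.0), ("R", "D", "a", 1.0)])
            )


class TestCommodityShock:
    @pytest.mark.parametrize(
        "share_d, phi_val, expected_pct",
        [
            # single rapeseed-like crop: share 1, D=0.270, phi=0.596 -> 16.1%
            ([(1.0, 0.270)], 0.596, 16.1),
            # two crops at phi=0.5: 0.5*(0.6*0.5 + 0.4*1.0) = 0.35
            ([(0.6, 0.5), (0.4, 1.0)], 0.5, 35.0),
        ],
    )
    def test_shock_formula(self, share_d, phi_val, expected_pct):
        shares = _shares([("R", "C", f"c{i}", s) for i, (s, _) in enumerate(share_d)])
        dep = _dep([(f"c{i}", d, np.nan, np.nan) for i, (_, d) in enumerate(share_d)])
        phi = _phi([("C", phi_val)])
        out = sk.compute_commodity_shock(shares, phi, dep)
        assert sk.shock_percent(out["s_mean"].iloc[0]) == expected_pct
        assert out["multiplier_mean"].iloc[0] == pytest.approx(1 - out["s_mean"].iloc[0])

    def test_zero_phi_means_zero_shock(self):
        out = sk.compute_commodity_shock(
            _shares([("R", "C", "a", 1.0)]), _phi([("C", 0.0)]), _dep([("a", 0.9, np.nan, np.nan)])
        )
        assert out["s_mean"].iloc[0] == 0.0

    def test_full_dependence_capped(self):
        out = sk.compute_commodity_shock(
            _shares([("R", "C", "a", 1.0)]), _phi([("C", 1.0)]), _dep([("a", 1.0, np.nan, np.nan)])
        )
        assert out["s_mean"].iloc[0] == 0.999
        assert out["multiplier_mean"].iloc[0] == pytest.approx(0.001)

    def test_missing_phi_rejected(self):
        with pytest.raises(ValueError, match="phi"):
            sk.compute_commodity_shock(
                _shares([("R", "C", "a", 1.0)]), _phi([("D", 0.5)]), _dep([("a", 0.5, np.nan, np.nan)])
            )

    def test_monotone_in_dependence_and_phi(self):
        rng = np.random.default_rng(7)
        shares = _shares([("R", "C", "a", 0.6), ("R", "C", "b", 0.4)])
        base_dep = [0.4, 0.6]
        base_phi = 0.5
        s0 = sk.compute_commodity_shock(
            shares, _phi([("C", base_phi)]),
            _dep([("a", base_dep[0], np.nan, np.nan), ("b", base_dep[1], np.nan, np.nan)]),
        )["s_mean"].iloc[0]
        for _ in range(25):
            bump_d = rng.uniform(0, 0.3, 2)
            bump_p = rng.uniform(0, 0.4)
            s1 = sk.compute_commodity_shock(
                shares, _phi([("C", min(base_phi + bump_p, 1.0))]),
                _dep([
                    ("a", min(base_dep[0] + bump_d[0], 1.0), np.nan, np.nan),
                    ("b", min(base_dep[1] + bump_d[1], 1.0), np.nan, np.nan),
                ]),
            )["s_mean"].iloc[0]
            assert s1 >= s0 - 1e-12


class TestTriangular:
    # closed-form oracle: Q(p) = a + sqrt(p (b-a)(c-a)) for p <= F(c),
    # b - sqrt((1-p)(b-a)(b-c)) above
    @staticmethod
    def _oracle(a, c, b, p):
        fc = (c - a) / (b - a)
        if p <= fc:
            return a + math.sqrt(p * (b - a) * (c - a))
        return b - math.sqrt((1 - p) * (b - a) * (b - c))

    @pytest.mark.parametrize(
        "a, c, b, p, expected",
        [
            (0.0, 0.5, 1.0, 0.025, 0.1118033988749895),
            (0.0, 0.5, 1.0, 0.975, 0.8881966011250105),
            (0.0, 0.5, 1.0, 0.0, 0.0),
            (0.0, 0.5, 1.0, 1.0, 1.0),
        ],
    )
    def test_quantile_matches_closed_form(self, a, c, b, p, expected):
        got = sk.triangular_quantile(a, c, b, p)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(self._oracle(a, c, b, p) if 0 < p < 1 else expected, abs=1e-12)

    def test_degenerate_point_mass(self):
        for p in (0.0, 0.3, 1.0):
            assert sk.triangular_quantile(0.3, 0.3, 0.3, p) == 0.3

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sk.triangular_quantile(1.0, 0.5, 0.0, 0.5)
        with pytest.raises(ValueError):
            sk.triangular_quantile(0.0, 0.5, 1.0, 1.5)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(0, 0.4),
        mode_frac=st.floats(0.01, 0.99),
        width=st.floats(0.05, 0.6),
        p=st.floats(0.001, 0.999),
    )
    def test_quantile_cdf_round_trip(self, a, mode_frac, width, p):
        b = a + width
        c = a + mode_frac * width
        x = sk.triangular_quantile(a, c, b, p)
        assert sk.triangular_cdf(a, c, b, x) == pytest.approx(p, abs=1e-9)


class TestShockBounds:
    def test_fallback_bounds_scale_the_mean(self):
        # pseudo-cereal with no interval data: D=0.187, phi=0.230 -> 4.3%,
        # +/-50% fallback gives (2.2%, 6.5%)
        shares = _shares([("R", "OCER", "buckwheat", 1.0)])
        dep = _dep([("buckwheat", 0.187, np.nan, np.nan)])
        phi = _phi([("OCER", 0.230)])
        mean = sk.compute_commodity_shock(shares, phi, dep)
        bounds = sk.derive_shock_bounds(shares, phi, dep)
        assert sk.shock_percent(mean["s_mean"].iloc[0]) == 4.3
        assert sk.shock_percent(bounds["s_low"].iloc[0]) == 2.2
        assert sk.shock_percent(bounds["s_high"].iloc[0]) == 6.5

    def test_tiny_coverage_collapses_to_zero_width(self):
        # both quantiles tend to the median; for a symmetric interval the
        # median equals the mean, so the bounds collapse onto the mean shock
        shares = _shares([("R", "C", "a", 1.0)])
        dep = _dep([("a", 0.5, 0.2, 0.8)])
        phi = _phi([("C", 0.6)])
        mean = sk.compute_commodity_shock(shares, phi, dep)["s_mean"].iloc[0]
        bounds = sk.derive_shock_bounds(shares, phi, dep, coverage=1e-9)
        assert bounds["s_low"].iloc[0] == pytest.approx(mean, rel=1e-3)
        assert bounds["s_high"].iloc[0] == pytest.approx(mean, rel=1e-3)

    def test_degenerate_interval_equals_mean(self):
        shares = _shares([("R", "C", "a", 1.0)])
        dep = _dep([("a", 0.5, 0.5, 0.5)])
        phi = _phi([("C", 0.6)])
        bounds = sk.derive_shock_bounds(shares, phi, dep)
        assert bounds["s_low"].iloc[0] == pytest.approx(0.3)
        assert bounds["s_high"].iloc[0] == pytest.approx(0.3)

    def test_invalid_coverage_rejected(self):
        shares = _shares([("R", "C", "a", 1.0)])
        with pytest.raises(ValueError, match="coverage"):
            sk.derive_shock_bounds(
                shares, _phi([("C", 0.5)]), _dep([("a", 0.5, 0.2, 0.9)]), coverage=1.2
            )


class TestDeclineRate:
    @pytest.mark.parametrize(
        "cumulative, n, expected",
        [(0.90, 14, 0.15166), (0.5, 1, 0.5), (0.75, 2, 0.5)],
    )
    def test_rate(self, cumulative, n, expected):
        assert sk.annual_decline_rate(cumulative, n) == pytest.approx(expected, abs=5e-6)

    def test_collapse_rate_reported_as_percent(self):
        assert round_half_up(100 * sk.annual_decline_rate(0.90, 14), 1) == 15.2

    def test_total_decline_rejected(self):
        with pytest.raises(ValueError):
            sk.annual_decline_rate(1.0, 14)

    def test_decline_spec_invariant(self):
        spec = sk.DeclineSpec(cumulative_decline=0.9, n_periods=14)
        assert (1 - spec.annual_rate) ** spec.n_periods == pytest.approx(0.1, abs=1e-9)


class TestShockTable:
    def test_extra_european_regions_unshocked(self, dataset, shock_table):
        extra = dataset.regions.loc[~dataset.regions["in_europe"], "region_id"]
        sub = shock_table[shock_table["region_id"].isin(extra)]
        assert (sub[["s_mean", "s_low", "s_high"]] == 0.0).all().all()
        assert (sub[["multiplier_mean", "multiplier_low", "multiplier_high"]] == 1.0).all().all()

    def test_bounds_ordering_and_cap(self, shock_table):
        assert (shock_table["s_low"] <= shock_table["s_mean"] + 1e-12).all()
        assert (shock_table["s_mean"] <= shock_table["s_high"] + 1e-12).all()
        assert (shock_table["s_high"] <= 0.999).all()

    def test_deterministic(self, dataset):
        from pollenomics.sensitivity import build_shocks

        a, b = build_shocks(dataset), build_shocks(dataset)
        pd.testing.assert_frame_equal(a, b)

    def test_source_swap_changes_values_not_schema(self, dataset):
        from pollenomics.sensitivity import build_shocks

        a = build_shocks(dataset)
        b = build_shocks(dataset, dependence=dataset.dependence_alt)
        assert list(a.columns) == list(b.columns)
        assert len(a) == len(b)
        assert not np.allclose(a["s_mean"], b["s_mean"])

    def test_unclassified_region_rejected(self, dataset):
        shares = sk.map_crops_to_commodities(dataset.production_values)
        with pytest.raises(ValueError, match="not classified"):
            sk.build_shock_table(
                dataset.dependence, dataset.wild_contribution, shares,
                europe_regions={"EU01"}, all_regions={"EU01"},
            )
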