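"""Market core: calibration identity, solver oracle, Armington, indicators."""

import numpy as np
import pandas as pd
import pytest

from pollenomics import market as mk
from pollenomics import sensitivity as sens

from conftest import make_closed_market


def closed_form_price(m, eps_s, eps_d):
    """Autarky oracle: supply m*p^eps_s = demand p^eps_d at p0 = q0 = 1."""
    return (1.0 / m) ** (1.0 / (eps_s + abs(eps_d)))


class TestClosedMarketOracle:
    @pytest.mark.parametrize(
        "eps_s, eps_d, m, p_star, q_star",
        [
            (0.5, -0.5, 0.9, 1.1111111111, 0.9486832981),
            # q* = m^(eps_s/(eps_s+|eps_d|)) ... = 0.9^0.375
            (0.5, -0.3, 0.9, 1.1407667734, 0.9612601554),
        ],
    )
    def test_solver_matches_closed_form(self, eps_s, eps_d, m, p_star, q_star):
        model = make_closed_market(eps_s, eps_d)
        state = mk.solve_equilibrium(
            model, shock_multiplier=np.array([[m]]), tol=1e-10
        )
        oracle = closed_form_price(m, eps_s, eps_d)
        assert oracle == pytest.approx(p_star, abs=1e-9)
        assert state.producer_price[0, 0] == pytest.approx(oracle, abs=1e-8)
        assert state.supply[0, 0] == pytest.approx(q_star, abs=1e-8)

    def test_king_davenant_revenue(self):
        # inelastic demand: a negative yield shock raises producer revenue;
        # elastic demand lowers it
        inelastic = make_closed_market(0.5, -0.3)
        s1 = mk.solve_equilibrium(inelastic, shock_multiplier=np.array([[0.9]]), tol=1e-10)
        rev = s1.producer_price[0, 0] * s1.supply[0, 0]
        assert rev > 1.0
        assert round(100 * (rev - 1.0), 1) == 9.7

        elastic = make_closed_market(0.5, -1.5)
        s2 = mk.solve_equilibrium(elastic, shock_multiplier=np.array([[0.9]]), tol=1e-10)
        assert s2.producer_price[0, 0] * s2.supply[0, 0] < 1.0


class TestCalibration:
    def test_zero_shock_reproduces_baseline(self, model):
        state = mk.solve_equilibrium(model)
        b = model.baseline
        assert np.allclose(state.producer_price, b.producer_price, rtol=1e-6)
        assert np.allclose(state.supply, b.production, rtol=1e-6)
        assert np.allclose(state.demand, b.demand, rtol=1e-6)
        assert state.iterations <= 2

    def test_calibration_residual_tiny(self, model):
        assert model.calibration_residual < 1e-8

    def test_unbalanced_trade_rejected(self, dataset):
        b = mk.BaselineMarket.from_dataset(dataset)
        b.production = b.production * 1.05  # break the balance identity
        with pytest.raises(ValueError, match="balance"):
            mk.calibrate_baseline(b)


class TestSupplyResponse:
    def test_zero_shock_baseline_prices(self, model):
        n, c = model.baseline.production.shape
        supply, area, yields, rbar = mk.supply_response(
            model, np.ones((n, c)), np.ones((n, c))
        )
        assert np.allclose(supply, model.baseline.production)
        assert np.allclose(area, model.baseline.area)
        assert np.allclose(rbar, 1.0)

    def test_pure_shock_pass_through(self):
        # fixed prices, eta=0, no land response: supply falls exactly by s
        model = make_closed_market(0.5, -0.5)
        supply, _, yields, _ = mk.supply_response(
            model, np.array([[1.0]]), np.array([[0.9]])
        )
        assert supply[0, 0] == pytest.approx(0.9, abs=1e-12)
        assert yields[0, 0] == pytest.approx(0.9, abs=1e-12)

    def test_intensification_buffers_yield(self):
        # with eta > 0 the equilibrium price rise claws back part of the
        # yield shock: realized yield falls by less than 10%
        model = make_closed_market(0.5, -0.5)
        model.baseline.eta[:] = 0.2
        state = mk.solve_equilibrium(model, shock_multiplier=np.array([[0.9]]), tol=1e-10)
        assert state.producer_price[0, 0] > 1.0
        assert state.realized_yield[0, 0] > 0.9
        assert state.realized_yield[0, 0] < 1.0


class TestArmington:
    def test_equal_prices_return_base_shares(self):
        shares0 = np.array([0.7, 0.3])
        dom, bil, r_c = mk.armington_allocate(
            total_demand=10.0,
            domestic_price_ratio=1.0,
            import_price_ratios=np.array([1.0, 1.0]),
            dom_value_share0=0.5,
            import_value_shares0=shares0,
            base_domestic=5.0,
            base_imports_bilateral=np.array([3.5, 1.5]),
            sigma1=2.0,
            sigma2=4.0,
        )
        assert r_c == pytest.approx(1.0)
        assert dom == pytest.approx(5.0)
        assert np.allclose(bil, [3.5, 1.5])

    def test_leontief_limit_fixes_quantity_proportions(self):
        dom, bil, _ = mk.armington_allocate(
            total_demand=10.0,
            domestic_price_ratio=1.0,
            import_price_ratios=np.array([1.4, 0.7]),
            dom_value_share0=0.5,
            import_value_shares0=np.array([0.7, 0.3]),
            base_domestic=5.0,
            base_imports_bilateral=np.array([3.5, 1.5]),
            sigma1=1e-9,
            sigma2=1e-9,
        )
        assert bil[0] / bil[1] == pytest.approx(3.5 / 1.5, rel=1e-6)

    def test_value_share_reallocation(self):
        # independent derivation: w_i proportional to alpha_i p_i^(1-sigma);
        # base value shares (0.7, 0.3), sigma2=2, origin 2 price +10%:
        # w = (0.7, 0.3/1.1) renormalized = (0.71963, 0.28037)
        ratios = np.array([1.0, 1.1])
        shares0 = np.array([0.7, 0.3])
        sigma2 = 2.0
        expected = shares0 * ratios ** (1 - sigma2)
        expected = expected / expected.sum()
        assert expected[0] == pytest.approx(0.719626, abs=1e-6)

        dom, bil, _ = mk.armington_allocate(
            total_demand=10.0,
            domestic_price_ratio=1.0,
            import_price_ratios=ratios,
            dom_value_share0=0.5,
            import_value_shares0=shares0,
            base_domestic=5.0,
            base_imports_bilateral=np.array([3.5, 1.5]),
            sigma1=2.0,
            sigma2=sigma2,
        )
        values = bil * ratios
        got = values / values.sum()
        assert np.allclose(got, expected, atol=1e-9)

    def test_sigma_one_log_limit(self):
        shares = np.array([0.6, 0.4])
        ratios = np.array([1.2, 0.8])
        idx = mk.ces_price_index(shares, ratios, 1.0)
        assert idx == pytest.approx(np.exp(0.6 * np.log(1.2) + 0.4 * np.log(0.8)))


class TestPriceTransmission:
    def test_wedge_arithmetic(self):
        assert mk.apply_price_transmission(100.0, 0.0) == 100.0
        landed = mk.apply_price_transmission(100.0, 0.25)
        assert landed == 125.0
        assert landed - 100.0 == 25.0  # per-unit wedge revenue

    def test_negative_wedge_rejected(self):
        with pytest.raises(ValueError):
            mk.apply_price_transmission(100.0, -0.1)


class TestEquilibrium:
    def test_market_clearing_residual(self, state):
        assert state.converged
        assert state.max_residual <= 1e-6

    def test_deterministic_bit_identical(self, model, shock_table):
        a = mk.solve_equilibrium(model, shocks=shock_table)
        b = mk.solve_equilibrium(model, shocks=shock_table)
        assert np.array_equal(a.producer_price, b.producer_price)
        assert np.array_equal(a.flows, b.flows)
        assert a.iterations == b.iterations

    def test_direction_of_spillovers(self, dataset, model, state):
        # Europe-confined shock: world price of shocked commodities weakly
        # up, extra-European production of them weakly up
        b = model.baseline
        dep = dataset.commodities["pollination_dependent"].to_numpy()
        w = b.production * b.producer_price
        for j in np.where(dep)[0]:
            world_p0 = (w[:, j] * b.producer_price[:, j]).sum() / w[:, j].sum()
            world_p1 = (w[:, j] * state.producer_price[:, j]).sum() / w[:, j].sum()
            assert world_p1 >= world_p0 - 1e-9
            assert (state.supply[~b.in_europe, j] >= b.production[~b.in_europe, j] - 1e-9).all()

    def test_non_convergence_raises_with_trajectory(self, model, shock_table):
        with pytest.raises(mk.ConvergenceError) as err:
            mk.solve_equilibrium(model, shocks=shock_table, max_iter=2)
        assert len(err.value.trajectory) >= 2


class TestIndicators:
    def test_self_sufficiency_autarky(self):
        out = mk.compute_trade_indicators(
            production=np.array([[100.0]]),
            demand=np.array([[100.0]]),
            flows=np.zeros((1, 1, 1)),
            region_mask=np.array([True]),
            commodity_ids=["X"],
        )
        assert out["self_sufficiency_pct"].iloc[0] == 100.0
        assert out["export_intensity_pct"].iloc[0] == 0.0

    def test_ratio_arithmetic(self):
        flows = np.zeros((2, 2, 1))
        flows[0, 1, 0] = 13.1  # bloc exports
        out = mk.compute_trade_indicators(
            production=np.array([[103.4], [50.0]]),
            demand=np.array([[100.0], [53.4]]),
            flows=flows,
            region_mask=np.array([True, False]),
            commodity_ids=["X"],
        )
        assert out["self_sufficiency_pct"].iloc[0] == pytest.approx(103.4)
        assert out["export_intensity_pct"].iloc[0] == pytest.approx(100 * 13.1 / 103.4)

    def test_zero_denominator_flagged_undefined(self):
        out = mk.compute_trade_indicators(
            production=np.array([[0.0]]),
            demand=np.array([[0.0]]),
            flows=np.zeros((1, 1, 1)),
            region_mask=np.array([True]),
            commodity_ids=["X"],
        )
        assert not out["defined"].iloc[0]
        assert np.isnan(out["self_sufficiency_pct"].iloc[0])


class TestAggregation:
    def test_single_group_equals_own_change(self, dataset, model, state):
        out = mk.aggregate_outputs(
            model, state,
            groups={"g": [model.commodity_ids[0]]},
            blocs={"world": np.ones(len(model.region_ids), bool)},
        )
        b = model.baseline
        w = (b.production * b.producer_price)[:, 0]
        expected = 100 * ((state.supply[:, 0] / b.production[:, 0] - 1) * w / w.sum()).sum()
        assert out["production_pct"].iloc[0] == pytest.approx(expected)

    def test_empty_group_rejected(self, model, state):
        with pytest.raises(ValueError, match="empty"):
            mk.aggregate_outputs(
                model, state, groups={"g": ["nonexistent"]},
                blocs={"world": np.ones(len(model.region_ids), bool)},
            )

    def test_land_expansion_buffers_production(self, dataset, model, state):
        # with positive land-supply elasticity the value-weighted production
        # decline is smaller in magnitude than the value-weighted yield shock
        b = model.baseline
        dep = np.where(dataset.commodities["pollination_dependent"].to_numpy())[0]
        sel = np.ix_(b.in_europe, dep)
        w = (b.production * b.producer_price)[sel]
        w = w / w.sum()
        shock_mag = (w * (1 - state.multiplier[sel])).sum()
        prod_decline = -(w * (state.supply[sel] / b.production[sel] - 1)).sum()
        assert (b.land_elasticity > 0).all()
        assert prod_decline < shock_mag
        # and total European cropland expands
        assert state.land[b.in_europe].sum() > b.area[b.in_europe].sum()
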