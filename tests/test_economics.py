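import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wheatgains import datasets
from wheatgains.economics import (
    EconError,
    GainCoverageError,
    SurplusParams,
    additional_production_kg,
    benefit_cost_ratio,
    producer_benefits,
    rations,
    surplus,
    surplus_series,
)
from wheatgains.genetic_gain import cumulative_gain


@pytest.fixture(scope="module")
def econ():
    return datasets.load_econ_series()


@pytest.fixture(scope="module")
def costs():
    return datasets.load_program_costs()


class TestProducerBenefits:
    def test_1993_winter_row(self, econ, reference_gains):
        """20,612 ha x 112.98 kg/ha at $382.12/t is ~$889,883 in 1993."""
        result = producer_benefits(econ, reference_gains)
        assert result.per_year.loc[1993, "winter"] == pytest.approx(
            889_883, rel=1e-3
        )
        assert result.per_year.loc[1993, "total"] == pytest.approx(
            889_883, rel=1e-3
        )  # spring/facultative gains start only in 1994

    def test_total_benefits_1992_2015(self, econ, reference_gains):
        result = producer_benefits(econ, reference_gains)
        assert result.total == pytest.approx(106_453_777, rel=5e-3)
        assert result.average == pytest.approx(result.total / 24)

    def test_zero_area_means_zero_benefits(self, econ, reference_gains):
        zeroed = econ.copy()
        for wt in reference_gains:
            zeroed[f"area_{wt}_ha"] = 0.0
        result = producer_benefits(zeroed, reference_gains)
        assert (result.per_year["total"] == 0).all()

    def test_benefits_linear_in_price_and_area(self, econ, reference_gains):
        base = producer_benefits(econ, reference_gains).total
        scaled_price = econ.copy()
        scaled_price["price_2016usd_per_ton"] *= 3.0
        assert producer_benefits(scaled_price, reference_gains).total == (
            pytest.approx(3.0 * base)
        )
        scaled_area = econ.copy()
        for wt in reference_gains:
            scaled_area[f"area_{wt}_ha"] *= 0.5
        assert producer_benefits(scaled_area, reference_gains).total == (
            pytest.approx(0.5 * base)
        )

    def test_missing_gain_years_reported(self, econ, reference_gains):
        short = {
            wt: cumulative_gain(s.beta1, s.y0, 2010, wt)
            for wt, s in reference_gains.items()
        }
        with pytest.raises(GainCoverageError, match="2015"):
            producer_benefits(econ, short)

    def test_missing_area_column_reported(self, econ, reference_gains):
        with pytest.raises(EconError, match="area_spring_irrigated_ha"):
            producer_benefits(
                econ.drop(columns="area_spring_irrigated_ha"), reference_gains
            )


class TestBenefitCostRatio:
    def test_equal_series_give_unity_at_any_rate(self):
        b = pd.Series([10.0, 20.0, 30.0], index=[2000, 2001, 2002])
        for r in (0.0, 0.1, 0.5):
            assert benefit_cost_ratio(b, b, r=r) == pytest.approx(1.0)

    def test_undiscounted_ratio_on_published_series(self, econ, costs,
                                                    reference_gains):
        benefits = producer_benefits(econ, reference_gains).per_year["total"]
        assert benefit_cost_ratio(benefits, costs, r=0.0) == pytest.approx(
            5.10, rel=5e-3
        )

    def test_front_loaded_benefits_gain_from_discounting(self):
        years = pd.Index(range(2000, 2010))
        benefits = pd.Series(np.linspace(100, 10, 10), index=years)
        costs = pd.Series(50.0, index=years)
        ratios = [
            benefit_cost_ratio(benefits, costs, r=r)
            for r in (0.0, 0.05, 0.1, 0.2)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))

    def test_invariant_to_common_rescaling(self, econ, costs, reference_gains):
        benefits = producer_benefits(econ, reference_gains).per_year["total"]
        r1 = benefit_cost_ratio(benefits, costs, r=0.1025)
        r2 = benefit_cost_ratio(7 * benefits, 7 * costs, r=0.1025)
        assert r1 == pytest.approx(r2)

    def test_zero_costs_rejected(self):
        b = pd.Series([1.0], index=[2000])
        with pytest.raises(EconError, match="zero"):
            benefit_cost_ratio(b, 0 * b)


class TestRations:
    def test_1993_rations_from_additional_kilograms(self, econ, reference_gains):
        addkg = additional_production_kg(econ, reference_gains)
        assert addkg.loc[1993] == pytest.approx(2_328_744, rel=1e-3)
        result = rations(addkg, per_capita=60.9)
        assert result.rounded.loc[1993] == pytest.approx(38_239, rel=1e-3)

    def test_average_annual_rations(self, econ, reference_gains):
        addkg = additional_production_kg(econ, reference_gains)
        result = rations(addkg, per_capita=60.9)
        assert result.average == pytest.approx(253_318, rel=5e-3)

    def test_zero_kilograms_zero_rations(self):
        result = rations(pd.Series([0.0, 0.0], index=[2000, 2001]), 60.9)
        assert (result.annual == 0).all() and result.average == 0.0

    def test_mass_conservation_before_rounding(self, econ, reference_gains):
        addkg = additional_production_kg(econ, reference_gains)
        result = rations(addkg, per_capita=60.9)
        assert (result.annual * 60.9).sum() == pytest.approx(addkg.sum())

    def test_nonpositive_per_capita_rejected(self):
        with pytest.raises(EconError):
            rations(pd.Series([1.0], index=[2000]), 0.0)


pos = st.floats(min_value=1e-3, max_value=1e9, allow_nan=False)
shifts = st.floats(min_value=1e-6, max_value=0.5, allow_nan=False)
elasticities = st.floats(min_value=0.01, max_value=5.0, allow_nan=False)


class TestSurplus:
    def test_no_shift_no_surplus_in_either_variant(self):
        for variant in ("parallel-alston", "incidence"):
            params = SurplusParams(supply_shift=0.0, variant=variant)
            s = surplus(300.0, 1e6, params)
            assert s.consumer == 0.0 and s.producer == 0.0 and s.net == 0.0

    @given(P=pos, Q=pos, K=shifts)
    def test_incidence_ratio_is_elasticity_ratio(self, P, Q, K):
        """The incidence variant fixes dCS/|dPS| at eps/eta (~3.0909 at the
        published elasticities) independent of price, quantity, and shift."""
        params = SurplusParams(supply_shift=K, variant="incidence")
        s = surplus(P, Q, params)
        assert s.consumer / abs(s.producer) == pytest.approx(
            0.68 / 0.22, rel=1e-9
        )
        assert s.producer < 0

    @given(P=pos, Q=pos, K=shifts, eta=elasticities, eps=elasticities)
    def test_parallel_variant_producer_surplus_nonnegative(self, P, Q, K, eta, eps):
        params = SurplusParams(
            demand_elasticity=eta, supply_elasticity=eps, supply_shift=K,
            variant="parallel-alston",
        )
        s = surplus(P, Q, params)
        Z = K * eps / (eps + eta)
        assert K >= Z
        assert s.producer >= 0
        assert s.net == pytest.approx(s.consumer + s.producer)

    def test_series_reports_net_as_sum(self):
        idx = pd.Index([2000, 2001], name="year")
        out = surplus_series(
            pd.Series([300.0, 310.0], index=idx),
            pd.Series([1e6, 1.1e6], index=idx),
            SurplusParams(),
        )
        np.testing.assert_allclose(
            out["net_surplus"],
            out["consumer_surplus"] + out["producer_surplus"],
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(EconError):
            SurplusParams(demand_elasticity=-0.22)
        with pytest.raises(EconError):
            SurplusParams(supply_shift=1.2)
        with pytest.raises(EconError):
            surplus(0.0, 1e6, SurplusParams())
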