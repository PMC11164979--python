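"""Unit and property tests for function aggregation and derived composites."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agroemf._errors import (
    ConfigurationError,
    DegenerateRangeError,
    DomainError,
    EmptyCommunityError,
    MassGainError,
    MissingDataError,
)
from agroemf.constants import SoilConstants, c_to_co2_factor
from agroemf.functions import (
    aggregate_panel,
    bait_lamina_consumption,
    carbon_stock,
    carbon_stock_and_flux,
    composite_mean,
    litterbag_mass_loss,
    microbial_biomass_from_mirr,
    minmax_normalize,
    nitrogen_surplus,
    nmin_unit_convert,
    nmin_unit_invert,
    normalize_table,
    shannon_index,
    soil_health,
    soil_multidiversity,
)


def _panel(rows):
    return pd.DataFrame(rows, columns=["plot_id", "year", "function", "value"])


class TestAggregatePanel:
    def test_two_point_mean(self):
        panel = _panel([("p1", 2015, "yield", 10.0), ("p1", 2016, "yield", 14.0)])
        wide = aggregate_panel(panel)
        assert wide.at["p1", "yield"] == pytest.approx(12.0)

    def test_single_year_identity(self):
        panel = _panel([("p1", 2015, "yield", 3.5)])
        assert aggregate_panel(panel).at["p1", "yield"] == 3.5

    def test_year_subset_uses_exactly_requested_years(self):
        rows = [("p1", y, "yield", float(y - 2014)) for y in range(2014, 2021)]
        panel = _panel(rows)
        wide = aggregate_panel(panel, years={"yield": range(2016, 2020)})
        # values for 2016..2019 are 2,3,4,5 -> mean 3.5 over exactly 4 values
        assert wide.at["p1", "yield"] == pytest.approx(3.5)

    def test_missing_function_raises(self):
        panel = _panel(
            [("p1", 2015, "yield", 1.0), ("p2", 2015, "cellulase", 2.0)]
        )
        with pytest.raises(MissingDataError, match="p1|p2"):
            aggregate_panel(panel)

    def test_unknown_function_rejected(self):
        panel = _panel([("p1", 2015, "bogus_function", 1.0)])
        with pytest.raises(ConfigurationError, match="bogus_function"):
            aggregate_panel(panel)

    def test_empty_year_subset_raises(self):
        panel = _panel([("p1", 2015, "yield", 1.0)])
        with pytest.raises(MissingDataError):
            aggregate_panel(panel, years={"yield": [1999]})


class TestMinmaxNormalize:
    def test_increasing(self):
        assert minmax_normalize([2, 4, 6]).tolist() == [0.0, 0.5, 1.0]

    def test_decreasing_reflection(self):
        assert minmax_normalize([2, 4, 6], "decreasing").tolist() == [1.0, 0.5, 0.0]

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateRangeError):
            minmax_normalize([5, 5, 5])

    def test_single_value_raises(self):
        with pytest.raises(DomainError):
            minmax_normalize([1.0])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_reflection_property(self, xs):
        inc = minmax_normalize(xs, "increasing")
        dec = minmax_normalize(xs, "decreasing")
        assert np.allclose(dec, 1.0 - inc)
        assert inc.min() == 0.0 and inc.max() == 1.0

    def test_normalize_table_inverts_n_surplus(self):
        means = pd.DataFrame(
            {"yield": [1.0, 2.0, 3.0], "n_surplus": [10.0, 20.0, 30.0]},
            index=["a", "b", "c"],
        )
        ef = normalize_table(means)
        assert ef["yield"].tolist() == [0.0, 0.5, 1.0]
        assert ef["n_surplus"].tolist() == [1.0, 0.5, 0.0]

    def test_normalize_table_names_degenerate_function(self):
        means = pd.DataFrame({"yield": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(DegenerateRangeError, match="yield"):
            normalize_table(means)


class TestShannon:
    def test_two_equal_taxa(self):
        assert shannon_index([10, 10]) == pytest.approx(math.log(2))

    def test_single_taxon(self):
        assert shannon_index([42]) == 0.0

    def test_hand_computed(self):
        # -sum p ln p with p = 1/6, 2/6, 3/6
        assert shannon_index([1, 2, 3]) == pytest.approx(1.0114, abs=1e-4)

    def test_empty_community(self):
        with pytest.raises(EmptyCommunityError):
            shannon_index([0, 0, 0])

    def test_negative_counts(self):
        with pytest.raises(DomainError):
            shannon_index([3, -1])

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=20).filter(lambda c: sum(c) > 0))
    @settings(max_examples=60, deadline=None)
    def test_bounds(self, counts):
        h = shannon_index(counts)
        k = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= math.log(k) + 1e-12

    def test_uniform_attains_bound(self):
        assert shannon_index([7] * 5) == pytest.approx(math.log(5))


class TestSoilMultidiversity:
    def test_hand_computed(self):
        md = soil_multidiversity(
            {"a": 1.0, "b": 0.5, "c": 0.2}, {"a": 1.0, "b": 1.0, "c": 0.4}
        )
        assert md == pytest.approx(2.0 / 3.0, abs=1e-4)

    def test_all_at_max(self):
        assert soil_multidiversity({"a": 2.0, "b": 3.0}, {"a": 2.0, "b": 3.0}) == 1.0

    def test_all_zero(self):
        assert soil_multidiversity({"a": 0.0}, {"a": 1.0}) == 0.0

    def test_h_above_max_raises(self):
        with pytest.raises(DomainError):
            soil_multidiversity({"a": 2.0}, {"a": 1.0})

    @given(
        hs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_rescale_invariance(self, hs, scale):
        h = {f"g{i}": v for i, v in enumerate(hs)}
        mx = {k: 1.0 for k in h}
        base = soil_multidiversity(h, mx)
        scaled = soil_multidiversity(
            {k: v * scale for k, v in h.items()}, {k: scale for k in h}
        )
        assert scaled == pytest.approx(base, rel=1e-12, abs=1e-12)
        assert 0.0 <= base <= 1.0


class TestComposites:
    def test_simple_mean(self):
        assert composite_mean([0.2, 0.4, 0.6]) == pytest.approx(0.4)

    def test_all_ones(self):
        assert composite_mean([1, 1, 1]) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            composite_mean([0.5, 1.2])

    def test_nested_soil_health(self):
        # microbial 0.6; enzymes mean 0.6; decomposition mean 0.5
        sh = soil_health(0.6, [0.3, 0.6, 0.9], [0.0, 0.5, 1.0])
        assert sh == pytest.approx((0.6 + 0.6 + 0.5) / 3.0)
        assert sh == pytest.approx(0.5667, abs=1e-4)


class TestBaitLamina:
    def test_all_empty(self):
        assert bait_lamina_consumption(["empty"] * 16) == 1.0

    def test_all_filled(self):
        assert bait_lamina_consumption(["filled"] * 16) == 0.0

    def test_mixed(self):
        assert bait_lamina_consumption(["empty", "partly", "filled", "filled"]) == 0.375

    def test_empty_list(self):
        with pytest.raises(MissingDataError):
            bait_lamina_consumption([])

    def test_unknown_state(self):
        with pytest.raises(DomainError):
            bait_lamina_consumption(["empty", "mostly"])


class TestLitterbag:
    @pytest.mark.parametrize(
        "initial,final,expected", [(12, 6, 0.5), (12, 12, 0.0), (12, 9.6, 0.2)]
    )
    def test_values(self, initial, final, expected):
        assert litterbag_mass_loss(initial, final) == pytest.approx(expected)

    def test_mass_gain_flagged(self):
        with pytest.raises(MassGainError):
            litterbag_mass_loss(12.0, 12.5)

    def test_zero_initial(self):
        with pytest.raises(DomainError):
            litterbag_mass_loss(0.0, 0.0)


class TestMicrobialBiomass:
    def test_unit_response(self):
        assert microbial_biomass_from_mirr(1.0) == 38.0

    def test_zero(self):
        assert microbial_biomass_from_mirr(0.0) == 0.0

    def test_scaling(self):
        assert microbial_biomass_from_mirr(2.5) == 95.0

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            microbial_biomass_from_mirr(-0.1)

    def test_overridable_constant(self):
        assert microbial_biomass_from_mirr(1.0, SoilConstants(mirr_factor=40.0)) == 40.0


class TestNitrogenSurplus:
    def test_literal(self):
        assert nitrogen_surplus(10, 100, 60, 5, "literal") == 55.0

    def test_balance(self):
        assert nitrogen_surplus(10, 100, 60, 5, "balance") == 45.0

    def test_zeros(self):
        assert nitrogen_surplus(0, 0, 0, 0) == 0.0

    def test_unknown_variant(self):
        with pytest.raises(ConfigurationError):
            nitrogen_surplus(1, 1, 1, 1, "mystery")

    @given(
        st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3), st.floats(0, 1e3)
    )
    @settings(max_examples=50, deadline=None)
    def test_variants_differ_by_twice_nmin_x1(self, a, b, c, d):
        lit = nitrogen_surplus(a, b, c, d, "literal")
        bal = nitrogen_surplus(a, b, c, d, "balance")
        assert lit - bal == pytest.approx(2 * d, rel=1e-12, abs=1e-9)


class TestUnitConversions:
    def test_one_gram_per_m2(self):
        assert nmin_unit_convert(1.0) == pytest.approx(3.7037, abs=1e-4)

    def test_zero(self):
        assert nmin_unit_convert(0.0) == 0.0

    def test_27_grams_is_100_mg_per_kg(self):
        assert nmin_unit_convert(27.0) == pytest.approx(100.0)

    @given(st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, areal):
        back = nmin_unit_invert(nmin_unit_convert(areal))
        assert back == pytest.approx(areal, rel=1e-12, abs=1e-12)


class TestCarbon:
    def test_factor_rounds_to_366(self):
        assert c_to_co2_factor() == 3.66

    def test_stock_from_two_percent(self):
        assert carbon_stock(2.0) == pytest.approx(81.0)

    def test_flux_zero_when_unchanged(self):
        table = carbon_stock_and_flux({2013: 2.0, 2016: 2.0}, 2013)
        assert table.at[2016, "flux"] == pytest.approx(0.0)

    def test_flux_hand_computed(self):
        # stocks 80 and 83 t/ha correspond to toc 80/40.5 and 83/40.5 percent
        table = carbon_stock_and_flux({2013: 80 / 40.5, 2016: 83 / 40.5}, 2013)
        assert table.at[2013, "stock"] == pytest.approx(80.0)
        assert table.at[2016, "flux"] == pytest.approx(1.0)

    def test_pre_baseline_year_rejected(self):
        with pytest.raises(DomainError):
            carbon_stock_and_flux({2012: 2.0, 2013: 2.0}, 2013)

    def test_missing_baseline(self):
        with pytest.raises(MissingDataError):
            carbon_stock_and_flux({2016: 2.0}, 2013)
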