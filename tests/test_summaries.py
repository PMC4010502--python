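import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracle import naive_spearman
from cascadesim.engine import CapPolicy
from cascadesim.landscape import Landscape, build_landscape
from cascadesim.scenarios import ScenarioSpec
from cascadesim.simulate import run_scenario
from cascadesim.summaries import (extreme_vegtypes,
                                  percent_cleared_by_subcatchment,
                                  percent_cleared_by_vegtype,
                                  single_property_share, spearman_matrix,
                                  summarize_properties)


@pytest.fixture
def singleprop_run(singleprop):
    spec = ScenarioSpec(ordering="random", constrained=False, n_runs=1, seed=0)
    policy = CapPolicy(target_lower=0.5, target_upper=0.5, constrained=False)
    return run_scenario(singleprop, policy, spec)


class TestSummarizeProperties:
    def test_single_run_single_property(self, singleprop, singleprop_run):
        s = summarize_properties(singleprop_run, singleprop)
        assert s.avg_n_properties_with_clearing == 1
        assert s.avg_size_of_clearing_properties_ha == pytest.approx(1000.0)
        assert s.avg_total_new_cleared_ha == pytest.approx(500.0)
        assert s.avg_selected_property_suitability == pytest.approx(200.0)

    def test_average_of_identical_runs_is_single_run(self, singleprop,
                                                     singleprop_run):
        doubled = singleprop_run + singleprop_run
        a = summarize_properties(singleprop_run, singleprop)
        b = summarize_properties(doubled, singleprop)
        assert a == b

    def test_tenure_split_sums_to_total(self, default_landscape, truncate_runs):
        s = summarize_properties(truncate_runs, default_landscape)
        assert s.avg_cleared_aboriginal_ha + s.avg_cleared_nonaboriginal_ha == \
            pytest.approx(s.avg_total_new_cleared_ha, rel=1e-6)

    def test_aboriginal_last_ordering_clears_no_aboriginal_land(
            self, default_landscape):
        # the catchment cap binds long before aboriginal properties get a turn
        spec = ScenarioSpec(ordering="nonaboriginal_large_first",
                            constrained=True, n_runs=3, seed=5)
        res = run_scenario(default_landscape,
                           CapPolicy(overshoot_mode="truncate"), spec)
        s = summarize_properties(res, default_landscape)
        assert s.avg_cleared_aboriginal_ha == 0.0
        assert s.avg_total_new_cleared_ha > 0.0

    def test_invariant_to_run_order(self, default_landscape, truncate_runs):
        a = summarize_properties(truncate_runs, default_landscape)
        b = summarize_properties(list(reversed(truncate_runs)),
                                 default_landscape)
        for field, value in vars(a).items():
            assert getattr(b, field) == pytest.approx(value, rel=1e-12)


class TestSubcatchmentPercentages:
    def test_untouched_subcatchment_reports_current_value(self, capbound):
        spec = ScenarioSpec(ordering="random", n_runs=3, seed=1)
        res = run_scenario(capbound, CapPolicy(overshoot_mode="truncate"), spec)
        df = percent_cleared_by_subcatchment(res, capbound).set_index("sc_id")
        # the grandfathered sub-catchment stays at its initial 60%
        assert df.loc[1, "current_pct"] == pytest.approx(60.0)
        assert df.loc[1, "mean_pct"] == pytest.approx(60.0)

    def test_totals_row_matches_catchment(self, default_landscape,
                                          truncate_runs):
        df = percent_cleared_by_subcatchment(truncate_runs, default_landscape)
        total = df[df["sc_id"] == "Total"].iloc[0]
        mean_frac = np.mean([r.ledger.catchment_fraction()
                             for r in truncate_runs])
        assert total["mean_pct"] == pytest.approx(100 * mean_frac, rel=1e-9)

    def test_subcatchment_decomposition_sums_to_total(self, default_landscape,
                                                      truncate_runs):
        df = percent_cleared_by_subcatchment(truncate_runs, default_landscape)
        body = df[df["sc_id"] != "Total"]
        areas = default_landscape.sub_catchments.set_index("sc_id")["total_area_ha"]
        implied = (body.set_index("sc_id")["mean_pct"] / 100 * areas).sum()
        total = df[df["sc_id"] == "Total"].iloc[0]["mean_pct"] / 100 \
            * areas.sum()
        assert implied == pytest.approx(total, rel=1e-9)


class TestVegtypePercentages:
    def test_untouched_types_report_existing_percentages(self, tiny3):
        spec = ScenarioSpec(ordering="random", n_runs=1, seed=0)
        policy = CapPolicy(target_lower=0.0, target_upper=0.0,
                           overshoot_mode="truncate")
        res = run_scenario(tiny3, policy, spec)
        veg = percent_cleared_by_vegtype(res, tiny3)
        per = veg.per_type.set_index("type_id")
        assert per.loc[1, "mean_pct"] == pytest.approx(100 * 1000 / 5200)
        assert per.loc[2, "mean_pct"] == pytest.approx(0.0)

    def test_fully_cleared_type_reports_100(self):
        units = pd.DataFrame([
            (1, 1, 1, 1, 200, 400.0, 0, 0, 1),
            (2, 1, 1, 2, 200, 600.0, 0, 0, 0),
        ], columns=["unit_id", "prop_id", "sc_id", "type_id", "suitability",
                    "area_ha", "buffered", "protected", "existing_cleared"])
        ls = build_landscape(units, {1: "private"}, {1: 1, 2: 1})
        spec = ScenarioSpec(ordering="random", n_runs=1, seed=0)
        policy = CapPolicy(target_lower=0.0, target_upper=0.0)
        res = run_scenario(ls, policy, spec)
        veg = percent_cleared_by_vegtype(res, ls)
        assert veg.per_type.set_index("type_id").loc[1, "mean_pct"] == \
            pytest.approx(100.0)

    def test_zero_extent_type_excluded_with_warning(self, singleprop):
        ls = build_landscape(singleprop.units, {1: "private"}, {1: 1, 2: 1})
        spec = ScenarioSpec(ordering="random", n_runs=1, seed=0)
        policy = CapPolicy(target_lower=0.0, target_upper=0.0)
        res = run_scenario(ls, policy, spec)
        with pytest.warns(UserWarning, match="zero"):
            veg = percent_cleared_by_vegtype(res, ls)
        assert list(veg.per_type["type_id"]) == [1]

    def test_unconstrained_roughly_doubles_constrained(self, default_landscape,
                                                       truncate_runs):
        spec = ScenarioSpec(ordering="random", constrained=False,
                            n_runs=20, seed=1)
        unc = run_scenario(default_landscape, CapPolicy(), spec)
        m_con = percent_cleared_by_vegtype(truncate_runs,
                                           default_landscape).mean_pct
        m_unc = percent_cleared_by_vegtype(unc, default_landscape).mean_pct
        assert 1.5 < m_unc / m_con < 3.0

    def test_population_vs_sample_sd_switch(self, default_landscape,
                                            truncate_runs):
        pop = percent_cleared_by_vegtype(truncate_runs, default_landscape)
        sam = percent_cleared_by_vegtype(truncate_runs, default_landscape,
                                         population_sd=False)
        n = len(pop.per_type)
        assert sam.sd_pct == pytest.approx(pop.sd_pct * np.sqrt(n / (n - 1)))


class TestSpearman:
    def test_identical_vectors_give_one(self):
        rho, _ = spearman_matrix({"a": [1, 5, 3, 2], "b": [1, 5, 3, 2]})
        assert rho.loc["a", "b"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        rho, _ = spearman_matrix({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert rho.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks (1,2,3,4,5) vs (1,3,2,5,4): d^2 sums to 4, rho = 1-24/120
        rho, p = spearman_matrix({"a": [1, 2, 3, 4, 5], "b": [1, 3, 2, 5, 4]})
        assert rho.loc["a", "b"] == pytest.approx(0.8)
        assert 0 < p.loc["a", "b"] < 1

    def test_constant_vector_reported_missing(self):
        rho, _ = spearman_matrix({"a": [2, 2, 2, 2], "b": [1, 2, 3, 4]})
        assert np.isnan(rho.loc["a", "b"])
        assert rho.loc["a", "a"] == 1.0

    def test_rejects_short_or_ragged_input(self):
        with pytest.raises(ValueError):
            spearman_matrix({"a": [1, 2], "b": [2, 1]})
        with pytest.raises(ValueError):
            spearman_matrix({"a": [1, 2, 3], "b": [1, 2]})

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 9)),
                    min_size=3, max_size=10))
    def test_matches_naive_rank_oracle(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        rho, _ = spearman_matrix({"x": x, "y": y})
        assert rho.loc["x", "y"] == pytest.approx(naive_spearman(x, y),
                                                  abs=1e-9)
        assert rho.loc["y", "x"] == rho.loc["x", "y"]
        assert abs(rho.loc["x", "y"]) <= 1 + 1e-12


class TestExtremeVegtypes:
    def test_k1_is_argmax_argmin(self):
        v = pd.Series({1: 5.0, 2: 9.0, 3: 1.0})
        top, bottom = extreme_vegtypes(v, k=1)
        assert list(top.index) == [2]
        assert list(bottom.index) == [3]

    def test_k_equal_n_returns_everything(self):
        v = pd.Series({i: float(i) for i in range(1, 8)})
        top, bottom = extreme_vegtypes(v, k=7)
        assert len(top) == len(bottom) == 7

    def test_ties_break_by_type_id(self):
        v = pd.Series({3: 5.0, 1: 5.0, 2: 5.0, 4: 0.0})
        top, _ = extreme_vegtypes(v, k=2)
        assert list(top.index) == [1, 2]

    def test_matches_full_sort_oracle(self, default_landscape, truncate_runs):
        veg = percent_cleared_by_vegtype(truncate_runs, default_landscape)
        v = veg.pct_vector()
        top, bottom = extreme_vegtypes(v, k=5)
        ranked = sorted(v.items(), key=lambda kv: (-kv[1], kv[0]))
        assert list(top.index) == [t for t, _ in ranked[:5]]
        ranked_lo = sorted(v.items(), key=lambda kv: (kv[1], kv[0]))
        assert list(bottom.index) == [t for t, _ in ranked_lo[:5]]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            extreme_vegtypes(pd.Series({1: 1.0}), k=2)


class TestSinglePropertyShare:
    def test_whole_catchment_at_full_cap(self):
        pct, of_cap = single_property_share(1000, 1000, 1.0)
        assert pct == pytest.approx(100.0)

    def test_plain_arithmetic(self):
        pct, _ = single_property_share(1_000, 100_000, 0.5)
        assert pct == pytest.approx(0.5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            single_property_share(-1, 100, 0.5)
        with pytest.raises(ValueError):
            single_property_share(1, 100, 0.0)
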