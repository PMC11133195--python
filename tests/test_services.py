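"""Expert-panel aggregation, capacity, multifunctionality, hexagon scores."""

import numpy as np
import pandas as pd
import pytest

from landmetab import build_hex_grid, compute_composition
from landmetab.errors import InvalidArgumentError, ValidationError
from landmetab.services import (
    ServiceMatrix,
    aggregate_panel,
    capacity,
    cover_capacity,
    cover_multifunctionality,
    esc_hex,
    load_service_list,
)
from landmetab.synthetic import PanelScenario, default_legend, generate_expert_panel

from conftest import make_raster


def panel_df(scores):
    """Responses from a list of (expert, service, section, cover, s, d)."""
    return pd.DataFrame(
        scores, columns=["expert_id", "service_code", "section", "cover", "supply", "demand"]
    )


class TestServiceList:
    def test_twenty_one_services_in_three_sections(self):
        services = load_service_list()
        assert len(services) == 21
        counts = services["section"].value_counts()
        assert counts["provisioning"] == 8
        assert counts["regulation_support"] == 9
        assert counts["cultural"] == 4


class TestAggregatePanel:
    def test_unanimous_panel(self):
        df = panel_df([(e, "1.1.1", "provisioning", "forest", 3, 1) for e in range(5)])
        m = aggregate_panel(df)
        assert m.supply.loc["1.1.1", "forest"] == 3.0
        assert m.demand.loc["1.1.1", "forest"] == 1.0
        assert m.count.loc["1.1.1", "forest"] == 5

    def test_extreme_scores_average(self):
        df = panel_df(
            [(1, "1.1.1", "provisioning", "forest", 0, 0),
             (2, "1.1.1", "provisioning", "forest", 5, 5)]
        )
        m = aggregate_panel(df)
        assert m.supply.loc["1.1.1", "forest"] == 2.5

    def test_simulated_panel_matches_mean_oracle(self):
        panel = generate_expert_panel(PanelScenario(seed=5), legend=default_legend())
        m = aggregate_panel(panel)
        # explicit sum/count oracle on a few cells
        for code, cover in [("1.1.1", 4), ("2.3.5", 9), ("3.2.2", 21)]:
            sel = panel[(panel.service_code == code) & (panel.cover == cover)]
            assert m.supply.loc[code, cover] == pytest.approx(
                sel["supply"].sum() / len(sel)
            )
            assert m.count.loc[code, cover] == len(sel)

    def test_out_of_scale_scores_rejected(self):
        df = panel_df([(1, "1.1.1", "provisioning", "forest", 6, 0)])
        with pytest.raises(ValidationError):
            aggregate_panel(df)

    def test_duplicate_responses_rejected(self):
        df = panel_df(
            [(1, "1.1.1", "provisioning", "forest", 3, 0)] * 2
        )
        with pytest.raises(ValidationError):
            aggregate_panel(df)

    def test_identical_experts_equal_single_expert(self):
        one = panel_df(
            [(1, c, s, "forest", 4, 2) for c, s in [("1.1.1", "provisioning"),
                                                    ("2.1.1", "regulation_support")]]
        )
        many = pd.concat(
            [one.assign(expert_id=e) for e in range(1, 11)], ignore_index=True
        )
        m1, mN = aggregate_panel(one), aggregate_panel(many)
        pd.testing.assert_frame_equal(m1.supply, mN.supply)
        pd.testing.assert_frame_equal(m1.demand, mN.demand)


class TestCapacity:
    def test_minimum(self):
        assert capacity(0, 5) == -5.0

    def test_supply_equals_demand(self):
        assert capacity(3.3, 3.3) == 0.0

    def test_arithmetic(self):
        assert capacity(4.2, 1.1) == pytest.approx(3.1)

    @pytest.mark.parametrize("s,d", [(-1, 0), (6, 0), (0, -1), (0, 5.5)])
    def test_out_of_range_rejected(self, s, d):
        if d <= 5:
            with pytest.raises(InvalidArgumentError):
                capacity(s, d)
        else:
            with pytest.raises(InvalidArgumentError):
                capacity(s, d)


def matrix_from(supply: pd.DataFrame, demand: pd.DataFrame) -> ServiceMatrix:
    sections = load_service_list().set_index("code")["section"]
    return ServiceMatrix(
        supply=supply,
        demand=demand,
        count=pd.DataFrame(1, index=supply.index, columns=supply.columns),
        sections=sections.loc[supply.index],
    )


class TestCoverScores:
    def full_index(self):
        return load_service_list()["code"]

    def test_zero_capacity_everywhere(self):
        idx = self.full_index()
        sup = pd.DataFrame(2.0, index=idx, columns=["a"])
        m = matrix_from(sup, sup.copy())
        assert cover_capacity(m)["a"] == 0.0

    def test_symmetric_capacities_cancel(self):
        idx = self.full_index()
        sup = pd.DataFrame(0.0, index=idx, columns=["a"])
        dem = pd.DataFrame(0.0, index=idx, columns=["a"])
        half = len(idx) // 2
        # +5 on ten services, -5 on ten, 0 on the last: mean exactly 0
        sup.iloc[:half] = 5.0
        dem.iloc[half : 2 * half] = 5.0
        m = matrix_from(sup, dem)
        assert cover_capacity(m)["a"] == pytest.approx(0.0, abs=1e-12)

    def test_random_matrix_matches_mean_oracle(self):
        rng = np.random.default_rng(9)
        idx = self.full_index()
        sup = pd.DataFrame(rng.uniform(0, 5, (21, 3)), index=idx, columns=list("abc"))
        dem = pd.DataFrame(rng.uniform(0, 5, (21, 3)), index=idx, columns=list("abc"))
        m = matrix_from(sup, dem)
        esc = cover_capacity(m)
        for cover in "abc":
            expected = np.mean([sup.loc[i, cover] - dem.loc[i, cover] for i in idx])
            assert esc[cover] == pytest.approx(expected)

    def test_multifunctionality_extremes(self):
        idx = self.full_index()
        hi = pd.DataFrame(5.0, index=idx, columns=["a"])
        lo = pd.DataFrame(0.0, index=idx, columns=["a"])
        dem = pd.DataFrame(0.0, index=idx, columns=["a"])
        assert cover_multifunctionality(matrix_from(hi, dem))["a"] == pytest.approx(5.0)
        assert cover_multifunctionality(matrix_from(lo, dem))["a"] == pytest.approx(0.0)

    def test_one_full_section_scores_five_thirds(self):
        services = load_service_list()
        idx = services["code"]
        sup = pd.DataFrame(0.0, index=idx, columns=["a"])
        prov = services.loc[services.section == "provisioning", "code"]
        sup.loc[prov, "a"] = 4.0  # all provisioning offered, others not
        m = matrix_from(sup, pd.DataFrame(0.0, index=idx, columns=["a"]))
        assert cover_multifunctionality(m)["a"] == pytest.approx(5.0 / 3.0)

    def test_threshold_is_inclusive(self):
        idx = self.full_index()
        sup = pd.DataFrame(3.0, index=idx, columns=["a"])
        m = matrix_from(sup, pd.DataFrame(0.0, index=idx, columns=["a"]))
        assert cover_multifunctionality(m, threshold=3.0)["a"] == pytest.approx(5.0)


class TestHexScores:
    def make_composition(self, arr):
        raster = make_raster(arr)
        rows, cols = raster.shape
        grid = build_hex_grid((0, 0, cols * 100.0, rows * 100.0), 20.0)
        return compute_composition(raster, grid, min_valid_fraction=0.0)

    def test_single_cover_hexagon(self):
        comp = self.make_composition(np.full((10, 10), 1))
        esc_i = pd.Series({1: 2.5})
        out = esc_hex(comp, esc_i)
        assert np.allclose(out["esc"], 2.5)

    def test_fifty_fifty_midpoint(self):
        comp = self.make_composition(np.full((10, 10), 1))
        comp.proportions[:] = 0.0
        comp.proportions[1] = 0.5
        comp.proportions[2] = 0.5
        out = esc_hex(comp, pd.Series({1: -2.0, 2: 4.0}))
        assert np.allclose(out["esc"], 1.0)

    def test_matches_brute_force_dot_product(self):
        rng = np.random.default_rng(13)
        comp = self.make_composition(rng.integers(1, 5, size=(20, 20)))
        esc_i = pd.Series({k: rng.uniform(-5, 5) for k in range(1, 5)})
        mf_i = pd.Series({k: rng.uniform(0, 5) for k in range(1, 5)})
        out = esc_hex(comp, esc_i, mf_i)
        props = comp.proportions.loc[comp.included_ids]
        for hid in out.index:
            assert out.loc[hid, "esc"] == pytest.approx(
                sum(props.loc[hid, c] * esc_i[c] for c in props.columns)
            )
            assert out.loc[hid, "mf"] == pytest.approx(
                sum(props.loc[hid, c] * mf_i[c] for c in props.columns)
            )
        # convex-combination bounds
        assert (out["esc"] >= esc_i.min() - 1e-9).all()
        assert (out["esc"] <= esc_i.max() + 1e-9).all()

    def test_missing_cover_named(self):
        comp = self.make_composition(np.full((10, 10), 3))
        with pytest.raises(ValidationError, match="3"):
            esc_hex(comp, pd.Series({1: 0.0}))


def test_adding_mean_expert_leaves_matrix_unchanged():
    base = pd.DataFrame(
        [
            (1, "1.1.1", "provisioning", "forest", 2, 0),
            (2, "1.1.1", "provisioning", "forest", 4, 2),
        ],
        columns=["expert_id", "service_code", "section", "cover", "supply", "demand"],
    )
    m1 = aggregate_panel(base)
    mean_expert = pd.DataFrame(
        [(3, "1.1.1", "provisioning", "forest", 3, 1)], columns=base.columns
    )
    m2 = aggregate_panel(pd.concat([base, mean_expert], ignore_index=True))
    assert m2.supply.loc["1.1.1", "forest"] == m1.supply.loc["1.1.1", "forest"]
    assert m2.demand.loc["1.1.1", "forest"] == m1.demand.loc["1.1.1", "forest"]
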