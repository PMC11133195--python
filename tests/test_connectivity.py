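"""Friction surfaces, accumulated cost and the connectivity transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landmetab.connectivity import (
    AffinityMatrix,
    BarrierClass,
    BarrierSpec,
    FrictionSurface,
    accumulate_cost,
    build_friction,
    eci_b,
    eci_total,
    theoretical_max_cost,
)
from landmetab.errors import (
    EmptyResultError,
    InvalidArgumentError,
    ValidationError,
)
from landmetab.synthetic import default_affinity, default_barriers, default_legend

from _oracles import brute_force_least_cost
from conftest import make_raster


class TestAccumulateCost:
    def test_sources_are_zero(self):
        f = FrictionSurface(np.ones((5, 5)), np.zeros((5, 5), bool), "forest", 100.0)
        src = np.zeros((5, 5), bool)
        src[2, 2] = True
        acc = accumulate_cost(f, src)
        assert acc.cost[2, 2] == 0.0

    def test_uniform_friction_manhattan(self):
        # 4-connectivity on uniform friction f: X_i = f x Manhattan distance
        fval = 2.5
        f = FrictionSurface(np.full((6, 7), fval), np.zeros((6, 7), bool), "forest", 100.0)
        src = np.zeros((6, 7), bool)
        src[0, 0] = True
        acc = accumulate_cost(f, src, connectivity=4)
        for r in range(6):
            for c in range(7):
                assert acc.cost[r, c] == pytest.approx(fval * (r + c))

    @pytest.mark.parametrize("shape", [(2, 2), (3, 3), (3, 4), (4, 4)])
    def test_matches_exhaustive_path_enumeration(self, shape):
        rng = np.random.default_rng(7)
        cost = rng.uniform(0.5, 5.0, size=shape)
        f = FrictionSurface(cost, np.zeros(shape, bool), "forest", 100.0)
        src = np.zeros(shape, bool)
        src[0, 0] = True
        acc = accumulate_cost(f, src, connectivity=8)
        oracle = brute_force_least_cost(cost, src, connectivity=8)
        np.testing.assert_allclose(acc.cost, oracle, rtol=1e-10)

    def test_impermeable_cells_unreachable(self):
        cost = np.ones((3, 3))
        mask = np.zeros((3, 3), bool)
        mask[:, 1] = True  # wall
        cost[:, 1] = np.inf
        f = FrictionSurface(cost, mask, "forest", 100.0)
        src = np.zeros((3, 3), bool)
        src[1, 0] = True
        acc = accumulate_cost(f, src, connectivity=4)
        assert np.isinf(acc.cost[:, 2]).all()
        assert np.isinf(acc.cost[:, 1]).all()

    def test_no_sources_raises(self):
        f = FrictionSurface(np.ones((3, 3)), np.zeros((3, 3), bool), "forest", 100.0)
        with pytest.raises(InvalidArgumentError):
            accumulate_cost(f, np.zeros((3, 3), bool))

    def test_all_sources_masked_raises(self):
        mask = np.zeros((3, 3), bool)
        mask[0, 0] = True
        cost = np.ones((3, 3))
        cost[0, 0] = np.inf
        f = FrictionSurface(cost, mask, "forest", 100.0)
        src = np.zeros((3, 3), bool)
        src[0, 0] = True
        with pytest.raises(EmptyResultError):
            accumulate_cost(f, src)


class TestEciB:
    def test_zero_cost_scores_ten(self):
        assert eci_b(0.0, 100.0) == pytest.approx(10.0)

    def test_max_cost_scores_one(self):
        assert eci_b(100.0, 100.0) == pytest.approx(1.0)

    def test_printed_expression_direct_evaluation(self):
        # independent arithmetic evaluation of 10 - 9 [ln(1+X_i)/ln(1+X_t)]^3
        expected = 10.0 - 9.0 * (math.log(11.0) / math.log(101.0)) ** 3
        assert eci_b(10.0, 100.0) == pytest.approx(expected, rel=1e-12)

    def test_denominator_cubed_variant(self):
        expected = 10.0 - 9.0 * math.log(11.0) / (3.0 * math.log(101.0))
        assert eci_b(10.0, 100.0, exponent="denominator_cubed") == pytest.approx(expected)

    def test_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert eci_b(150.0, 100.0) == pytest.approx(1.0)
        with pytest.raises(InvalidArgumentError):
            eci_b(150.0, 100.0, strict=True)

    @given(
        x=st.floats(0.0, 1.0),
        y=st.floats(0.0, 1.0),
        xt=st.floats(1e-3, 1e6),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_decreasing_and_in_range(self, x, y, xt):
        a, b = sorted((x * xt, y * xt))
        va, vb = eci_b(a, xt), eci_b(b, xt)
        assert va >= vb - 1e-12
        assert 1.0 - 1e-9 <= vb <= va <= 10.0 + 1e-9


class TestTheoreticalMax:
    def test_uniform_grid(self):
        f = FrictionSurface(np.ones((10, 10)), np.zeros((10, 10), bool), "forest", 100.0)
        assert theoretical_max_cost(f) == pytest.approx(math.hypot(9, 9))

    def test_homogeneity(self):
        rng = np.random.default_rng(2)
        cost = rng.uniform(0.5, 3.0, (8, 12))
        f1 = FrictionSurface(cost, np.zeros((8, 12), bool), "forest", 100.0)
        f2 = FrictionSurface(2 * cost, np.zeros((8, 12), bool), "forest", 100.0)
        assert theoretical_max_cost(f2) == pytest.approx(2 * theoretical_max_cost(f1))

    def test_mixed_friction_max_scan(self):
        cost = np.array([[1.0, 4.5], [2.0, 0.5]])
        f = FrictionSurface(cost, np.zeros((2, 2), bool), "forest", 100.0)
        assert theoretical_max_cost(f) == pytest.approx(math.hypot(1, 1) * 4.5)


class TestEciTotal:
    def test_identical_fields(self):
        g = np.full((4, 4), 7.0)
        np.testing.assert_allclose(eci_total([g, g, g]), 7.0)

    def test_two_field_mean(self):
        a, b = np.full((3, 3), 10.0), np.full((3, 3), 1.0)
        np.testing.assert_allclose(eci_total([a, b]), 5.5)

    def test_matches_elementwise_mean(self):
        rng = np.random.default_rng(3)
        fields = [rng.uniform(1, 10, (5, 6)) for _ in range(3)]
        np.testing.assert_allclose(eci_total(fields), np.mean(np.stack(fields), axis=0))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            eci_total([np.ones((2, 2)), np.ones((3, 3))])


class TestBuildFriction:
    def test_affinity_scales_inverse(self):
        raster = make_raster([[10, 10]])  # agroforestry mosaic cells
        aff = default_affinity()
        f = build_friction(raster, default_legend(), aff, BarrierSpec(), "forest")
        expected = 1.0 / aff.affinity("agroforestry_mosaic", "forest")
        np.testing.assert_allclose(f.cost, expected)
        # halving affinity doubles friction
        t = aff.table.copy()
        t.loc["agroforestry_mosaic", "forest"] = t.loc["forest", "agroforestry_mosaic"] = (
            t.loc["agroforestry_mosaic", "forest"] / 2
        )
        f2 = build_friction(
            raster, default_legend(), AffinityMatrix(table=t), BarrierSpec(), "forest"
        )
        np.testing.assert_allclose(f2.cost, 2 * f.cost)

    def test_same_area_no_barrier_costs_base(self):
        raster = make_raster([[4, 4]])  # forest cells, forest target
        f = build_friction(
            raster, default_legend(), default_affinity(), BarrierSpec(), "forest",
            base_cost=1.0,
        )
        np.testing.assert_allclose(f.cost, 1.0)

    def test_halo_matches_hand_computed_grid(self):
        # 10x10 forest with a vertical road at col 4: impact 5 within 2 cells
        arr = np.full((10, 10), 4)
        arr[:, 4] = 23
        raster = make_raster(arr, cell_size=100.0)
        barriers = BarrierSpec(
            classes={23: BarrierClass(23, impact=5.0, halo_m=200.0, impermeable=False)}
        )
        f = build_friction(raster, default_legend(), default_affinity(), barriers, "forest")
        base = 1.0
        oracle = np.empty((10, 10))
        for r in range(10):
            for c in range(10):
                cell_cost = base / 0.1 if c == 4 else base / 1.0
                if abs(c - 4) * 100.0 <= 200.0:
                    cell_cost += 5.0
                oracle[r, c] = cell_cost
        np.testing.assert_allclose(f.cost, oracle)

    def test_impermeable_masked(self):
        arr = np.array([[4, 21]])
        raster = make_raster(arr)
        f = build_friction(
            raster, default_legend(), default_affinity(), default_barriers(), "forest"
        )
        assert not f.mask[0, 0]
        assert f.mask[0, 1]

    def test_unresolvable_class_rejected(self, small_legend):
        raster = make_raster([[5]])  # urban: barrier_flag but no spec needed
        # remove the barrier flag to create an unresolvable class
        from landmetab.legend import Legend, LegendEntry

        legend = Legend(entries={5: LegendEntry(5, "Mystery", "other", "X")})
        with pytest.raises(ValidationError):
            build_friction(raster, legend, default_affinity(), BarrierSpec(), "forest")

    def test_barrier_monotonicity(self):
        # adding a barrier halo never increases ECI_b anywhere
        arr = np.full((12, 12), 4)
        arr[:, 0] = 4  # forest everywhere, sources on the left column patch
        arr[:, 6] = 23  # road
        raster = make_raster(arr)
        legend = default_legend()
        src = np.zeros((12, 12), bool)
        src[:, 0] = True
        no_barrier = BarrierSpec()
        with_barrier = BarrierSpec(
            classes={23: BarrierClass(23, impact=8.0, halo_m=300.0, impermeable=False)}
        )
        # compare at a common X_t: monotonicity concerns the cost field, and
        # the normaliser must not move between the two configurations
        fields = {}
        for name, spec in (("without", no_barrier), ("with", with_barrier)):
            f = build_friction(raster, legend, default_affinity(), spec, "forest")
            fields[name] = (f, accumulate_cost(f, src))
        xt = max(theoretical_max_cost(fields[n][0]) for n in fields)
        vals = {
            n: eci_b(np.minimum(acc.cost, xt), xt) for n, (f, acc) in fields.items()
        }
        assert (vals["with"] <= vals["without"] + 1e-9).all()
        assert (vals["with"] < vals["without"]).any()


def test_cost_scales_linearly_on_uniform_landscape():
    """Multiplying a uniform friction surface by k scales every accumulated
    cost and the theoretical maximum by exactly k, so the cost/maximum ratio
    that drives the connectivity transform is scale-free.

    (The transform itself is logarithmic, so ECI_b is only invariant through
    this ratio at the endpoints X_i = 0 and X_i = X_t; the meaningful
    invariance is in the cost field.)
    """
    cost = np.full((6, 6), 1.7)
    src = np.zeros((6, 6), bool)
    src[0, 0] = True
    f1 = FrictionSurface(cost, np.zeros((6, 6), bool), "forest", 100.0)
    ref = accumulate_cost(f1, src)
    ref_xt = theoretical_max_cost(f1)
    for k in (3.0, 10.0):
        fk = FrictionSurface(k * cost, np.zeros((6, 6), bool), "forest", 100.0)
        acc = accumulate_cost(fk, src)
        np.testing.assert_allclose(acc.cost, k * ref.cost, rtol=1e-12)
        assert theoretical_max_cost(fk) == pytest.approx(k * ref_xt)
        # endpoint invariance of the transform through the ratio
        assert eci_b(0.0, k * ref_xt) == pytest.approx(eci_b(0.0, ref_xt))
        assert eci_b(k * ref_xt, k * ref_xt) == pytest.approx(eci_b(ref_xt, ref_xt))
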