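"""Corridor construction, deviation scoring and discrepancy statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from methbench.consensus_deviation import (
    Corridor,
    build_data_corridor,
    build_gs_corridor,
    deviation,
    deviations,
    discrepancy_score,
    filter_gold_standard_regions,
    inside_fraction,
    mean_absolute_deviation,
)
from methbench.io_calls import RunMeta
from methbench.synthetic_data import blueprint_like_locus_table
from conftest import make_call_set
from oracles import brute_force_data_corridor, brute_force_gs_corridor

beta_values = st.floats(0.0, 1.0, allow_nan=False)


class TestDataCorridor:
    def test_identical_measurements_zero_width(self):
        groups = {p: [0.5] * 5 for p in "ABC"}
        c = build_data_corridor(groups)
        assert (c.lower, c.upper) == (0.5, 0.5)

    def test_short_protocol_is_undefined(self):
        groups = {"A": [0.5] * 5, "B": [0.4] * 4}
        assert build_data_corridor(groups) is None

    def test_empty_protocol_list_rejected(self):
        with pytest.raises(ValueError):
            build_data_corridor({})

    def test_contains_required_counts_post_hoc(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            groups = {p: rng.random(8).tolist() for p in "ABC"}
            c = build_data_corridor(groups)
            for vals in groups.values():
                inside = sum(1 for v in vals if c.lower <= v <= c.upper)
                assert inside >= 5

    @given(st.data())
    def test_matches_exhaustive_search(self, data):
        n_groups = data.draw(st.integers(1, 3))
        groups = {
            f"P{i}": data.draw(
                st.lists(
                    st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 3)),
                    min_size=5, max_size=9,
                )
            )
            for i in range(n_groups)
        }
        got = build_data_corridor(groups, 5)
        want = brute_force_data_corridor(groups, 5)
        assert (got.lower, got.upper) == pytest.approx(want)


class TestGoldStandardCorridor:
    def test_three_technologies_flanked(self):
        c = build_gs_corridor({"A": 0.40, "B": 0.42, "C": 0.44})
        assert (c.lower, c.upper) == pytest.approx((0.35, 0.49))

    def test_flank_clipped_at_zero(self):
        c = build_gs_corridor({"A": 0.0, "B": 0.01, "C": 0.02})
        assert c.lower == 0.0
        assert c.upper == pytest.approx(0.07)

    def test_too_few_technologies_undefined(self):
        assert build_gs_corridor({"A": 0.4, "B": 0.5}) is None

    def test_best_triple_among_five(self):
        techs = {"A": 0.10, "B": 0.80, "C": 0.82, "D": 0.84, "E": 0.30}
        c = build_gs_corridor(techs, flank=0.0)
        assert (c.lower, c.upper) == pytest.approx((0.80, 0.84))

    @given(st.data())
    def test_matches_exhaustive_subset_search(self, data):
        n_tech = data.draw(st.integers(3, 6))
        techs = {
            f"T{i}": data.draw(
                st.lists(
                    st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 3)),
                    min_size=1, max_size=4,
                )
            )
            for i in range(n_tech)
        }
        got = build_gs_corridor(techs, flank=0.0)
        lo, hi = brute_force_gs_corridor(techs, 3)
        assert (got.lower, got.upper) == pytest.approx((lo, hi))


class TestDeviation:
    @pytest.mark.parametrize(
        "m,expected",
        [(0.5, 0.0), (0.7, pytest.approx(0.1)), (0.6, 0.0), (0.4, 0.0),
         (0.1, pytest.approx(0.3))],
    )
    def test_piecewise_formula(self, m, expected):
        c = Corridor(0.4, 0.6, "data_driven", 5)
        assert deviation(m, c) == expected

    def test_undefined_corridor_propagates_missing(self):
        assert np.isnan(deviation(0.5, None))

    @given(m=beta_values, lo=beta_values, hi=beta_values, eps=st.floats(1e-6, 1e-3))
    def test_continuity_near_borders(self, m, lo, hi, eps):
        lo, hi = sorted((lo, hi))
        c = Corridor(lo, hi, "data_driven", 5)
        d0, d1 = deviation(m, c), deviation(min(1.0, m + eps), c)
        assert abs(d1 - d0) <= eps + 1e-12  # 1-Lipschitz, hence continuous

    @given(m=beta_values, lo=beta_values, hi=beta_values,
           wl=st.floats(0, 0.3), wu=st.floats(0, 0.3))
    def test_widening_never_increases_deviation(self, m, lo, hi, wl, wu):
        lo, hi = sorted((lo, hi))
        narrow = Corridor(lo, hi, "data_driven", 5)
        wide = Corridor(max(0.0, lo - wl), min(1.0, hi + wu), "data_driven", 5)
        assert deviation(m, wide) <= deviation(m, narrow) + 1e-12

    @given(m=beta_values, lo=beta_values, hi=beta_values)
    def test_bounded_by_max_border_distance(self, m, lo, hi):
        lo, hi = sorted((lo, hi))
        c = Corridor(lo, hi, "data_driven", 5)
        assert deviation(m, c) <= max(abs(m - lo), abs(m - hi)) + 1e-12

    def test_vectorized_matches_scalar(self):
        c = Corridor(0.3, 0.6, "data_driven", 5)
        ms = np.array([0.0, 0.3, 0.45, 0.6, 0.9, np.nan])
        vec = deviations(ms, c)
        for m, d in zip(ms, vec):
            scalar = deviation(m, c)
            assert (np.isnan(d) and np.isnan(scalar)) or d == scalar


class TestAggregation:
    def test_all_zero(self):
        assert mean_absolute_deviation([0.0, 0.0, 0.0]) == 0.0

    def test_grid_mean(self):
        assert mean_absolute_deviation([0, 0.1, 0.2, 0.1], 2, 2) == pytest.approx(0.1)

    def test_missing_reduces_denominator(self):
        assert mean_absolute_deviation([0.1, 0.2, np.nan, 0.3], 2, 2) == pytest.approx(0.2)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            mean_absolute_deviation([])
        with pytest.raises(ValueError):
            mean_absolute_deviation([np.nan, np.nan])

    @pytest.mark.parametrize(
        "betas,expected",
        [([0.45, 0.5], 1.0), ([0.9, 0.1], 0.0), ([0.45, 0.5, 0.55, 0.9], 0.75)],
    )
    def test_inside_fraction(self, betas, expected):
        corridors = [Corridor(0.4, 0.6, "data_driven", 5)] * len(betas)
        assert inside_fraction(betas, corridors) == expected

    def test_inside_fraction_needs_evaluable_sites(self):
        with pytest.raises(ValueError):
            inside_fraction([np.nan], [Corridor(0.4, 0.6, "data_driven", 5)])


class TestDiscrepancy:
    def _pair(self, b1, b2):
        pos = list(range(10, 10 + 2 * len(b1), 2))
        a = make_call_set(pos, betas=b1, depths=[10] * len(b1),
                          meta=RunMeta("a", "p", "s"))
        b = make_call_set(pos, betas=b2, depths=[10] * len(b2),
                          meta=RunMeta("b", "p", "s"))
        return a, b

    def test_identical_is_zero(self):
        a, b = self._pair([0.2, 0.8], [0.2, 0.8])
        assert discrepancy_score(a, b) == 0.0

    def test_constant_offset(self):
        a, b = self._pair([0.2, 0.5, 0.7], [0.3, 0.6, 0.8])
        assert discrepancy_score(a, b) == pytest.approx(10.0)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(4)
        x, y = rng.random(100), rng.random(100)
        a, b = self._pair(x.tolist(), y.tolist())
        assert discrepancy_score(a, b) == pytest.approx(100 * np.abs(x - y).mean())

    def test_no_common_sites_rejected(self):
        a = make_call_set([10], betas=[0.5], depths=[5], meta=RunMeta("a", "p", "s"))
        b = make_call_set([20], betas=[0.5], depths=[5], meta=RunMeta("b", "p", "s"))
        with pytest.raises(ValueError):
            discrepancy_score(a, b)

    @given(
        triple=st.lists(
            st.tuples(beta_values, beta_values, beta_values), min_size=1, max_size=20
        )
    )
    def test_metric_properties(self, triple):
        """Symmetry, non-negativity and the triangle inequality."""
        x = [t[0] for t in triple]
        y = [t[1] for t in triple]
        z = [t[2] for t in triple]
        a, b = self._pair(x, y)
        _, c = self._pair(x, z)
        d_ab = discrepancy_score(a, b)
        d_ba = discrepancy_score(b, a)
        d_ac = discrepancy_score(a, c)
        d_cb = discrepancy_score(c, b)
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= 0
        assert d_ab <= d_ac + d_cb + 1e-9
        if x == y:
            assert d_ab == 0.0


class TestRegionFilter:
    def test_sparse_regions_dropped(self):
        table = blueprint_like_locus_table(seed=2)
        kept = filter_gold_standard_regions(table)
        regions = set(kept["region"])
        assert len(regions) == 46
        assert {"r29", "r30"}.isdisjoint(regions)


def test_gs_corridor_width_shrinks_to_flank_with_noiseless_techs():
    """With technology noise -> 0 the corridor collapses onto 2 x flank."""
    c = build_gs_corridor({"A": 0.37, "B": 0.37, "C": 0.37}, flank=0.05)
    assert c.width == pytest.approx(0.10)
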