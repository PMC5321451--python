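"""Tests for the t-test/BH/fold-change kernels and hierarchical clustering.

Oracles are independent of the implementation: the t-tail probability is
obtained by numerical quadrature of the Student density written from its
gamma-function definition, and BH is recomputed with an explicit step-up loop.
"""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from lncsig.diffexp import (
    ComparisonResult,
    bh_adjust,
    differential_expression,
    hierarchical_cluster,
    log2_fold_change,
    students_t,
    write_cdt_gtr,
)
from lncsig.errors import ConfigurationError, DataError
from lncsig.expression import Contrast, ExpressionMatrix


def t_two_sided_p_oracle(t: float, df: int) -> float:
    """2 * upper-tail of the Student density, by quadrature from first
    principles (gamma-function form, no scipy.stats)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), np.inf)
    return 2.0 * tail


def bh_oracle(p_values):
    """Explicit Benjamini-Hochberg step-up: sorted q_i = p_i * m / i, then a
    running minimum from the largest rank down, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


class TestStudentsT:
    def test_frozen_example(self):
        t, df, p = students_t([2.0, 4.0, 6.0], [1.0, 3.0, 5.0])
        assert t == pytest.approx(0.6123724357, abs=1e-9)
        assert df == 4.0
        assert p == pytest.approx(t_two_sided_p_oracle(t, 4), abs=1e-10)

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 5), (10, 4)])
    def test_p_matches_quadrature_oracle(self, nx, ny):
        rng = np.random.default_rng(42)
        x, y = rng.normal(0, 1, nx), rng.normal(0.7, 1, ny)
        t, df, p = students_t(x, y)
        assert p == pytest.approx(t_two_sided_p_oracle(t, int(df)), abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=7)
        t_xy, _, p_xy = students_t(x, y)
        t_yx, _, p_yx = students_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_zero_variance_equal_means(self):
        t, df, p = students_t([1.0, 1.0], [1.0, 1.0, 1.0])
        assert (t, df, p) == (0.0, 3.0, 1.0)

    def test_zero_variance_unequal_means(self):
        t, _, p = students_t([2.0, 2.0], [1.0, 1.0])
        assert t == np.inf and p == 0.0
        t, _, p = students_t([1.0, 1.0], [2.0, 2.0])
        assert t == -np.inf and p == 0.0

    def test_too_few_samples(self):
        with pytest.raises(DataError):
            students_t([1.0], [2.0, 3.0])

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=5), rng.normal(size=5)
        t1, _, _ = students_t(x, y)
        t2, _, _ = students_t(x + 100.0, y + 100.0)
        assert t1 == pytest.approx(t2, abs=1e-8)


class TestLog2FoldChange:
    def test_mean_difference(self):
        assert log2_fold_change([3.0, 5.0], [1.0, 1.0]) == 3.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=4), rng.normal(size=6)
        assert log2_fold_change(x, y) == pytest.approx(-log2_fold_change(y, x))


class TestBHAdjust:
    def test_frozen_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @pytest.mark.parametrize(
        "p",
        [
            [0.005, 0.011, 0.02, 0.04, 0.13, 0.35, 0.9],
            [0.5], [1.0, 0.0], [0.03, 0.03, 0.03],
            list(np.random.default_rng(1).random(10)),
        ],
    )
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_properties(self, p):
        adjusted = bh_adjust(p)
        assert np.all(adjusted >= np.asarray(p) - 1e-15)
        assert np.all((adjusted >= 0) & (adjusted <= 1))
        # order-preserving: smaller raw p never gets a larger adjusted p
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adjusted[order]) >= -1e-15)
        np.testing.assert_allclose(adjusted, bh_oracle(p), atol=1e-14)

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(DataError):
            bh_adjust([0.5, np.nan])

    def test_empty_input(self):
        assert bh_adjust([]).size == 0


def _toy_view():
    rng = np.random.default_rng(11)
    samples = [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
    groups = ["A"] * 8 + ["B"] * 8
    values = rng.normal(6.0, 0.3, size=(5, 16))
    values[0, 8:] -= 3.0  # strongly down in A_vs_B? no: B lower -> up in A
    values[1, :8] -= 3.0  # down in A
    frame = pd.DataFrame(values, index=[f"p{i}" for i in range(5)], columns=samples)
    return ExpressionMatrix(values=frame, group_labels=dict(zip(samples, groups)))


class TestDifferentialExpression:
    CONTRAST = Contrast("A_vs_B", "A", "B")

    def test_vectorized_agrees_with_scalar_kernel(self, views):
        lnc_view, _ = views
        contrast = Contrast("PM_vs_N", "PM", "N")
        result = differential_expression(lnc_view, contrast, "lncRNA")
        a, b = lnc_view.group_arrays(contrast)
        for i in [0, 7, 123, 499]:
            t, df, p = students_t(a[i], b[i])
            row = result.table.iloc[i]
            assert row["t_stat"] == pytest.approx(t, rel=1e-12)
            assert row["df"] == df
            assert row["p_raw"] == pytest.approx(p, rel=1e-12)
            assert row["log2fc"] == pytest.approx(log2_fold_change(a[i], b[i]),
                                                  rel=1e-12)

    def test_direction_calls(self):
        view = _toy_view()
        result = differential_expression(view, self.CONTRAST, "lncRNA")
        assert result.table.at["p0", "direction"] == "up"
        assert result.table.at["p1", "direction"] == "down"
        assert set(result.table["direction"][2:]) == {"ns"}
        assert result.counts() == {"up": 1, "down": 1, "total": 2}
        assert result.significant_probes == {"p0", "p1"}

    def test_bh_family_is_the_view(self, views):
        lnc_view, _ = views
        contrast = Contrast("PM_vs_N", "PM", "N")
        result = differential_expression(lnc_view, contrast, "lncRNA")
        np.testing.assert_allclose(
            result.table["p_adj"].to_numpy(),
            bh_oracle(result.table["p_raw"].to_numpy()),
            atol=1e-12,
        )

    def test_strict_fc_cutoff(self):
        # a probe exactly at the cutoff is not called
        samples = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        frame = pd.DataFrame(
            [[1.0, 1.0, 1.0 + 1e-9, 1.0 - 1e-9, 0.0, 0.0, 1e-9, -1e-9]],
            index=["edge"], columns=samples,
        )
        view = ExpressionMatrix(frame, dict(zip(samples, ["A"] * 4 + ["B"] * 4)))
        result = differential_expression(view, self.CONTRAST, "lncRNA")
        assert result.table.at["edge", "direction"] == "ns"

    def test_raw_p_option(self):
        view = _toy_view()
        raw = differential_expression(view, self.CONTRAST, "lncRNA",
                                      use_adjusted_p=False)
        adj = differential_expression(view, self.CONTRAST, "lncRNA")
        assert set(adj.significant.index) <= set(raw.significant.index)

    def test_unknown_molecule_class(self, views):
        with pytest.raises(ConfigurationError):
            differential_expression(views[0], self.CONTRAST, "protein")

    def test_bad_cutoffs(self):
        with pytest.raises(ConfigurationError):
            differential_expression(_toy_view(), self.CONTRAST, "lncRNA",
                                    fc_cutoff=-1.0)


class TestHierarchicalCluster:
    def _matrix(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(6, 10))
        base[1] = base[0] + rng.normal(0, 0.01, 10)  # p1 hugs p0
        return pd.DataFrame(base, index=[f"p{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(10)])

    def test_correlated_rows_merge_first(self):
        tree = hierarchical_cluster(self._matrix())
        first_merge = set(tree.linkage[0, :2].astype(int))
        assert first_merge == {0, 1}
        order = tree.leaf_order
        assert abs(order.index("p0") - order.index("p1")) == 1

    def test_leaf_order_is_permutation(self):
        matrix = self._matrix()
        tree = hierarchical_cluster(matrix, distance_kind="euclidean",
                                    linkage_kind="complete")
        assert sorted(tree.leaf_order) == sorted(matrix.index)

    def test_deterministic(self):
        t1 = hierarchical_cluster(self._matrix())
        t2 = hierarchical_cluster(self._matrix())
        np.testing.assert_array_equal(t1.linkage, t2.linkage)
        assert t1.leaf_order == t2.leaf_order

    def test_constant_row_rejected(self):
        matrix = self._matrix()
        matrix.loc["p5"] = 1.0
        with pytest.raises(DataError, match="p5"):
            hierarchical_cluster(matrix)

    def test_bad_options(self):
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(self._matrix(), distance_kind="manhattan")
        with pytest.raises(ConfigurationError):
            hierarchical_cluster(self._matrix(), linkage_kind="ward")

    def test_cdt_gtr_export(self):
        matrix = self._matrix()
        tree = hierarchical_cluster(matrix)
        cdt, gtr = io.StringIO(), io.StringIO()
        write_cdt_gtr(tree, matrix, cdt, gtr)
        cdt_lines = cdt.getvalue().splitlines()
        gtr_lines = gtr.getvalue().splitlines()
        assert len(cdt_lines) == len(matrix) + 1  # header + one row per item
        assert len(gtr_lines) == len(matrix) - 1  # one line per merge
        assert cdt_lines[0].startswith("GID\tUNIQID\tNAME\tGWEIGHT")
        # data rows follow the leaf order
        assert [line.split("\t")[1] for line in cdt_lines[1:]] == tree.leaf_order
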