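"""Peak expression, curves, detection, co-expression, profiles, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npnets.datamodel import CellAnnotation, ExpressionMatrix, ValidationError
from npnets.expression_stats import (
    area_conservation,
    coexpression_counts,
    cognate_pair_coexpression,
    cv_within_subclass,
    detection_fraction,
    expression_curves,
    nearest_rank_quantile,
    peak_expression,
    peak_rank_table,
    trimmed_mean,
    type_mean_expression,
)


def matrix_from_columns(cols: dict[str, list[float]]) -> ExpressionMatrix:
    genes = list(cols)
    values = np.array(list(cols.values()), dtype=float).T
    return ExpressionMatrix(values, "CPM",
                            [f"c{i}" for i in range(values.shape[0])], genes)


class TestPeakExpression:
    def test_all_zero_gene(self):
        m = matrix_from_columns({"g": [0.0] * 50})
        assert peak_expression(m, "g") == 0.0

    def test_nearest_rank_on_1_to_10000(self):
        m = matrix_from_columns({"g": list(range(1, 10001))})
        assert peak_expression(m, "g", quantile=0.999) == 9990.0

    def test_scalar_scaling(self, rng):
        values = rng.lognormal(1, 2, size=300)
        m1 = matrix_from_columns({"g": values})
        m2 = matrix_from_columns({"g": 3.5 * values})
        assert peak_expression(m2, "g") == pytest.approx(
            3.5 * peak_expression(m1, "g"))

    def test_unknown_gene(self):
        m = matrix_from_columns({"g": [1.0]})
        with pytest.raises(KeyError):
            peak_expression(m, "nope")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1,
                    max_size=200),
           st.floats(0.01, 1.0))
    def test_matches_brute_force_sort_oracle(self, values, q):
        import math
        arr = np.array(values)
        expected = sorted(values)[min(max(math.ceil(q * len(values)), 1),
                                      len(values)) - 1]
        assert nearest_rank_quantile(arr, q) == expected


class TestPeakRankTable:
    def test_single_gene_universe(self):
        m = matrix_from_columns({"g": [5.0, 10.0]})
        t = peak_rank_table(m, ["g"])
        assert t.rank("g") == 1
        assert t.percentile("g") == 100.0

    def test_two_gene_ordering(self):
        m = matrix_from_columns({"a": [10.0] * 4, "b": [5.0] * 4})
        t = peak_rank_table(m, ["a", "b"])
        assert t.rank("a") == 1 and t.rank("b") == 2

    def test_engineered_top_gene(self, rng):
        cols = {f"g{i:04d}": rng.uniform(0, 100, size=30) for i in range(999)}
        cols["winner"] = rng.uniform(500, 600, size=30)
        m = matrix_from_columns(cols)
        t = peak_rank_table(m, list(cols))
        assert t.rank("winner") == 1
        assert t.percentile("winner") == pytest.approx(100.0)

    def test_percentile_monotone_in_rank(self, small_dataset):
        cpm, _, _ = small_dataset
        t = peak_rank_table(cpm, cpm.gene_ids).table.sort_values("absolute_rank")
        assert (np.diff(t["percentile_rank"].to_numpy()) <= 0).all()

    def test_empty_universe_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            peak_rank_table(small_dataset[0], [])

    def test_ties_broken_lexicographically(self):
        m = matrix_from_columns({"b": [7.0], "a": [7.0]})
        t = peak_rank_table(m, ["b", "a"])
        assert t.rank("a") == 1 and t.rank("b") == 2


class TestExpressionCurves:
    def test_single_gene_descending(self):
        m = matrix_from_columns({"g": [5.0, 0.0, 10.0]})
        c = expression_curves(m, ["g"])["g"]
        assert c["value"].tolist() == [10.0, 5.0, 0.0]
        assert c["population_percentile"].tolist() == pytest.approx(
            [100 * 0.5 / 3, 100 * 1.5 / 3, 100 * 2.5 / 3])

    def test_max_over_set(self):
        m = matrix_from_columns({"A": [1.0, 0.0], "B": [0.0, 2.0]})
        c = expression_curves(m, ["A", "B"], mode="max_over_set")
        assert c["max_over_set"]["value"].tolist() == [2.0, 1.0]

    def test_max_curve_dominates_each_gene(self, rng):
        m = matrix_from_columns(
            {f"g{i}": rng.lognormal(0, 2, 100) for i in range(5)})
        genes = m.gene_ids
        maxc = expression_curves(m, genes, "max_over_set")["max_over_set"]
        for g, c in expression_curves(m, genes, "per_gene").items():
            assert (maxc["value"].to_numpy() >= c["value"].to_numpy()).all()

    def test_empty_set_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            expression_curves(small_dataset[0], [])


class TestDetection:
    def test_all_zero(self):
        m = matrix_from_columns({"g": [0.0] * 4})
        assert detection_fraction(m, "g") == 0.0

    def test_strict_threshold(self):
        m = matrix_from_columns({"g": [2.0, 0.5, 3.0, 0.0]})
        assert detection_fraction(m, "g", threshold=1.0) == 0.5

    def test_non_increasing_in_threshold(self, rng):
        m = matrix_from_columns({"g": rng.lognormal(0, 2, 500)})
        fracs = [detection_fraction(m, "g", th) for th in (0.1, 1, 10, 100)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_group_restriction(self, small_dataset):
        cpm, _, ann = small_dataset
        g = cpm.gene_ids[0]
        f_all = detection_fraction(cpm, g, ann=ann)
        f_v = detection_fraction(cpm, g, ann=ann, group={"area": "VISp"})
        f_a = detection_fraction(cpm, g, ann=ann, group={"area": "ALM"})
        n_v = (ann.table["area"] == "VISp").sum()
        n_a = (ann.table["area"] == "ALM").sum()
        assert f_all == pytest.approx((f_v * n_v + f_a * n_a) / (n_v + n_a))


class TestCoexpression:
    def test_all_zero_matrix(self):
        m = matrix_from_columns({"a": [0.0] * 3, "b": [0.0] * 3})
        counts, hist = coexpression_counts(m, ["a", "b"])
        assert counts.tolist() == [0, 0, 0]
        assert hist.tolist() == [3, 0, 0]

    def test_partial_detection(self):
        m = matrix_from_columns({"a": [2.0], "b": [3.0], "c": [0.0]})
        counts, _ = coexpression_counts(m, ["a", "b", "c"])
        assert counts.tolist() == [2]

    def test_histogram_sums_to_group_size(self, small_dataset):
        cpm, _, ann = small_dataset
        genes = cpm.gene_ids[:10]
        _, hist = coexpression_counts(cpm, genes, ann=ann,
                                      group={"area": "ALM"})
        assert hist.sum() == (ann.table["area"] == "ALM").sum()


class TestCognatePairCoexpression:
    def test_disjoint_expressors(self):
        m = matrix_from_columns({"g": [5.0, 0.0], "h": [0.0, 5.0]})
        df = cognate_pair_coexpression(m, [("g", "h")])
        assert df["fraction_both"].iloc[0] == 0.0

    def test_identical_columns(self):
        col = [5.0, 5.0, 0.0, 0.0, 0.0]
        m = matrix_from_columns({"g": col, "h": col})
        df = cognate_pair_coexpression(m, [("g", "h")])
        assert df["fraction_both"].iloc[0] == pytest.approx(0.4)

    def test_bounded_by_min_individual_fraction(self, rng):
        m = matrix_from_columns(
            {f"g{i}": rng.lognormal(0, 2, 200) for i in range(6)})
        pairs = [(f"g{i}", f"g{i+1}") for i in range(5)]
        df = cognate_pair_coexpression(m, pairs)
        assert (df["fraction_both"]
                <= df[["fraction_npp", "fraction_npgpcr"]].min(axis=1)
                + 1e-12).all()


class TestAreaConservation:
    def test_perfect_correlation(self, rng):
        x = rng.uniform(0, 1, 20)
        rho, _ = area_conservation(x, x)
        assert rho == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        x = rng.uniform(0, 1, 20)
        rho, _ = area_conservation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            area_conservation(np.ones(5), np.arange(5.0))

    def test_spearman_option(self, rng):
        x = rng.uniform(0, 1, 30)
        rho, _ = area_conservation(x, x ** 3, method="spearman")
        assert rho == pytest.approx(1.0)


class TestTypeMeanExpression:
    @staticmethod
    def annotated(values_by_type: dict[str, list[float]]):
        """One gene; keys are leaf types, values their cells' expression."""
        cells, vals, rows = [], [], []
        for leaf, vv in values_by_type.items():
            for i, v in enumerate(vv):
                cid = f"{leaf}_c{i}"
                cells.append(cid)
                vals.append([v])
                rows.append({"cell_id": cid, "area": "VISp",
                             "leaf_type": leaf, "subclass": "s",
                             "class": "GABAergic"})
        m = ExpressionMatrix(np.array(vals), "CPM", cells, ["g"])
        return m, CellAnnotation(pd.DataFrame(rows))

    def test_constant_column(self):
        m, ann = self.annotated({"t0": [7.0] * 10})
        prof = type_mean_expression(m, ann)
        assert prof.gene_row("g")[0] == 7.0

    def test_five_percent_trim_removes_single_outlier(self):
        m, ann = self.annotated({"t0": [0.0] * 19 + [1e6]})
        prof = type_mean_expression(m, ann)
        assert prof.gene_row("g")[0] == 0.0

    def test_median_statistic(self):
        m, ann = self.annotated({"t0": [1.0, 2.0, 100.0]})
        prof = type_mean_expression(m, ann, statistic="median")
        assert prof.gene_row("g")[0] == 2.0

    def test_trimmed_mean_within_range_and_untrimmed_limit(self, rng):
        for _ in range(20):
            v = rng.lognormal(0, 2, size=int(rng.integers(1, 40)))
            tm = trimmed_mean(v)
            assert v.min() - 1e-12 <= tm <= v.max() + 1e-12
            if int(0.05 * v.size) == 0:
                assert tm == pytest.approx(v.mean())


class TestCvWithinSubclass:
    @staticmethod
    def profile(values, type_subclasses, taxonomy_builder):
        from npnets.expression_stats import TypeExpressionMatrix
        return TypeExpressionMatrix(np.array([values]), ["g"],
                                    list(type_subclasses), "mean")

    def test_constant_gene_all_cv_zero(self, small_dataset, small_taxonomy):
        from npnets.expression_stats import TypeExpressionMatrix
        leaves = small_taxonomy.leaf_names
        t = TypeExpressionMatrix(np.full((1, len(leaves)), 5.0), ["g"],
                                 leaves, "mean")
        df = cv_within_subclass(t, small_taxonomy)
        cv_cols = [c for c in df.columns if c.startswith("cv_")
                   and c not in ("cv_global", "cv_ratio_mean")]
        assert (df[cv_cols].fillna(0).to_numpy() == 0).all()

    def test_between_subclass_variation_only(self, small_taxonomy):
        from npnets.expression_stats import TypeExpressionMatrix
        leaves = small_taxonomy.leaf_names
        vals = np.array([[10.0 * (1 + hash(small_taxonomy.subclass_of(l)) % 5)
                          for l in leaves]])
        t = TypeExpressionMatrix(vals, ["g"], leaves, "mean")
        df = cv_within_subclass(t, small_taxonomy)
        assert df.loc["g", "cv_global"] > 0
        assert df.loc["g", "cv_ratio_mean"] == pytest.approx(0.0)

    def test_two_type_subclass_cv_value(self):
        # sample sd of [1, 3] is sqrt(2); mean 2 -> CV = 0.7071
        vals = np.array([1.0, 3.0])
        assert vals.std(ddof=1) / vals.mean() == pytest.approx(0.7071, abs=1e-4)

    def test_singleton_subclasses_excluded(self, small_taxonomy):
        from npnets.expression_stats import TypeExpressionMatrix
        # keep one type of the first subclass: it must drop out of the CV table
        leaves = small_taxonomy.leaf_names
        first_sub = small_taxonomy.subclass_of(leaves[0])
        kept = [l for l in leaves
                if small_taxonomy.subclass_of(l) != first_sub] + [leaves[0]]
        t = TypeExpressionMatrix(np.random.default_rng(0).uniform(
            1, 10, (1, len(kept))), ["g"], kept, "mean")
        df = cv_within_subclass(t, small_taxonomy)
        assert f"cv_{first_sub}" not in df.columns
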