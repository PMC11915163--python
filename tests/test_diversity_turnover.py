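import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cryocomm.core_io import CountTable, SampleMetadata, ValidationError
from cryocomm.diversity_turnover import (alpha_group_tests, distance,
                                         gini_simpson, pca, permanova,
                                         pooled_presence, procrustes, shannon,
                                         sorensen_presence, turnover,
                                         venn_partition)
from conftest import make_taxonomy


def table_of(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns, dtype=float)


class TestAlphaDiversity:
    @pytest.mark.parametrize("counts, expected", [
        ([25, 25, 25, 25], np.log(4)),
        ([7, 0, 0], 0.0),
        ([1, 2, 3], 1.01140426),
    ])
    def test_shannon_closed_forms(self, counts, expected):
        h = shannon(table_of({"s": counts}))
        assert h["s"] == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("counts, expected", [
        ([1, 1, 1, 1, 1], 0.8),
        ([1, 3], 0.375),
        ([9], 0.0),
    ])
    def test_gini_simpson_closed_forms(self, counts, expected):
        g = gini_simpson(table_of({"s": counts}))
        assert g["s"] == pytest.approx(expected)

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValidationError):
            shannon(table_of({"s": [0, 0]}))


class TestDistance:
    def test_identical_and_disjoint_columns(self):
        t = table_of({"a": [1, 2, 0, 0], "b": [1, 2, 0, 0], "c": [0, 0, 3, 1]})
        for metric in ("bray_curtis", "sorensen"):
            d = distance(t, metric).to_frame()
            assert d.at["a", "b"] == pytest.approx(0.0)
            assert d.at["a", "c"] == pytest.approx(1.0)

    def test_sorensen_worked_example(self):
        # presence {1,2,3} vs {2,3,4} -> 1 - 4/6
        t = table_of({"a": [1, 1, 1, 0], "b": [0, 1, 1, 1]})
        d = distance(t, "sorensen").to_frame()
        assert d.at["a", "b"] == pytest.approx(1 / 3)
        assert sorensen_presence({1, 2, 3}, {2, 3, 4}) == pytest.approx(1 / 3)

    def test_bounds_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.poisson(3, (12, 8)).astype(float))
        for metric in ("bray_curtis", "sorensen"):
            d = distance(t, metric)
            m = d.matrix
            assert (m >= 0).all() and (m <= 1 + 1e-12).all()
            np.testing.assert_allclose(m, m.T)
            np.testing.assert_allclose(np.diag(m), 0)

    def test_two_all_zero_samples_error(self):
        with pytest.raises(ValidationError):
            distance(table_of({"a": [0, 0], "b": [0, 0]}), "bray_curtis")


class TestPca:
    def test_rank_one_data_loads_on_first_axis(self):
        base = np.array([1.0, 2.0, 3.0])
        t = pd.DataFrame(np.outer(base, [1, 2, 3, 4]))
        res = pca(t, transform="raw")
        assert res.proportions[0] == pytest.approx(1.0)

    def test_identical_samples_flagged_degenerate(self):
        t = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        res = pca(t, transform="raw")
        assert res.degenerate
        assert np.allclose(res.coords.to_numpy(), 0.0)

    def test_proportions_non_increasing_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.random((10, 5)))
        res = pca(t)
        assert np.all(np.diff(res.proportions) <= 1e-12)
        assert res.proportions.sum() == pytest.approx(1.0)


class TestPermanova:
    @pytest.fixture
    def dm(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.random((6, 10)), columns=[f"s{i}" for i in range(10)])
        return distance(t, "bray_curtis")

    def test_matches_skbio_pseudo_f(self, dm):
        import skbio
        groups = {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}
        mine = permanova(dm, groups, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.matrix, list(dm.sample_ids)),
            [groups[s] for s in dm.sample_ids], permutations=9)
        assert mine.f == pytest.approx(ref["test statistic"], rel=1e-9)
        assert 0 <= mine.r2 <= 1

    def test_duplicated_group_gives_near_zero_r2(self):
        base = np.random.default_rng(4).random((5, 4))
        t = pd.DataFrame(np.hstack([base, base]),
                         columns=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("a" if i < 4 else "b") for i in range(8)}
        res = permanova(distance(t, "euclidean"), groups, n_perm=49, seed=1)
        assert res.r2 == pytest.approx(0.0, abs=1e-9)

    def test_strong_separation_is_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, (10, 6))
        b = rng.normal(5, 1, (10, 6))
        t = pd.DataFrame(np.vstack([a, b]).T,
                         columns=[f"s{i}" for i in range(20)])
        groups = {f"s{i}": ("a" if i < 10 else "b") for i in range(20)}
        res = permanova(distance(t, "euclidean"), groups, n_perm=999, seed=2)
        assert res.p_value <= 0.005


class TestProcrustes:
    def test_rotated_scaled_copy_gives_zero_m2(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.random((12, 2)), index=[f"s{i}" for i in range(12)])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = pd.DataFrame(2.0 * X.to_numpy() @ R + 5.0, index=X.index)
        res = procrustes(X, Y, n_perm=9, seed=0)
        assert res.m2 <= 1e-10
        assert res.residuals.max() <= 1e-8

    def test_perturbed_row_has_largest_residual(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.random((10, 2)), index=[f"s{i}" for i in range(10)])
        Y = X.copy()
        Y.iloc[3] += 0.5
        res = procrustes(X, Y, n_perm=9, seed=0)
        assert res.residuals.idxmax() == "s3"

    def test_m2_invariant_to_similarity_transform_of_inputs(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.random((9, 2)), index=[f"s{i}" for i in range(9)])
        Y = pd.DataFrame(rng.random((9, 2)), index=X.index)
        base = procrustes(X, Y, n_perm=9, seed=0).m2
        R = np.array([[0, -1], [1, 0]])
        X2 = pd.DataFrame(3.0 * X.to_numpy() @ R - 1.0, index=X.index)
        assert procrustes(X2, Y, n_perm=9, seed=0).m2 == pytest.approx(base, abs=1e-10)


class TestTurnoverAndVenn:
    @pytest.fixture
    def setup(self, three_period_meta):
        taxa = [f"z{i}" for i in range(1, 5)]
        tax = make_taxonomy({t: "P" for t in taxa})
        # acc pool: z1,z2,z3 ; melt pool: z2,z3,z4
        data = pd.DataFrame(0.0, index=taxa, columns=three_period_meta.periods.index)
        data.loc[["z1", "z2", "z3"], ["acc_1", "acc_2"]] = 1
        data.loc[["z2", "z3", "z4"], ["melt_1", "melt_2"]] = 1
        data.loc[["z2", "z3", "z4"], ["late_1", "late_2"]] = 1
        return data, tax, three_period_meta

    def test_worked_example_rate_half(self, setup):
        data, tax, meta = setup
        res = turnover(data, meta, tax, "phylum", "acc", "melt")["P"]
        assert (res.gained, res.lost, res.shared) == (1, 1, 2)
        assert res.rate == pytest.approx(0.5)

    def test_rate_is_jaccard_distance_of_pooled_sets(self, setup):
        # (gained+lost)/union is the Jaccard distance; it maps to the
        # Sørensen dissimilarity d_s of the pooled sets via 2 d_s/(1 + d_s).
        data, tax, meta = setup
        res = turnover(data, meta, tax, "phylum", "acc", "melt")["P"]
        a = pooled_presence(data, meta, "acc")
        b = pooled_presence(data, meta, "melt")
        jaccard = 1 - len(a & b) / len(a | b)
        d_s = sorensen_presence(a, b)
        assert res.rate == pytest.approx(jaccard)
        assert res.rate == pytest.approx(2 * d_s / (1 + d_s))

    def test_identical_and_disjoint_limits(self, setup):
        data, tax, meta = setup
        assert turnover(data, meta, tax, "phylum", "melt", "late")["P"].rate == 0.0
        data2 = data.copy()
        data2.loc[:, ["melt_1", "melt_2"]] = 0
        data2.loc["z4", ["melt_1", "melt_2"]] = 1
        data2.loc["z4", ["acc_1", "acc_2"]] = 0
        assert turnover(data2, meta, tax, "phylum", "acc", "melt")["P"].rate == 1.0

    def test_venn_worked_example(self):
        out = venn_partition({"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 4, 5}})
        # enumeration: 1 -> A only, 2 -> A&B, 3 -> A&B&C, 4 -> B&C, 5 -> C only
        assert out == {"A": 1, "B": 0, "C": 1, "A&B": 1, "B&C": 1, "A&C": 0,
                       "A&B&C": 1}
        assert sum(out.values()) == 5  # |union|

    @given(st.lists(st.sets(st.integers(0, 20)), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_venn_counts_partition_the_union(self, sets):
        named = {"A": sets[0], "B": sets[1], "C": sets[2]}
        out = venn_partition(named)
        assert sum(out.values()) == len(sets[0] | sets[1] | sets[2])


def test_alpha_group_tests_apply_bh_adjustment(three_period_meta):
    rng = np.random.default_rng(9)
    vals = pd.Series(rng.normal(0, 1, 6), index=three_period_meta.periods.index)
    df = alpha_group_tests(vals, three_period_meta)
    assert set(df.columns) >= {"period_a", "period_b", "t", "p", "p_adjusted"}
    assert len(df) == 3
    assert (df["p_adjusted"] >= df["p"] - 1e-12).all()
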