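"""Diversity indices, distances, PCoA and PERMANOVA against closed forms
and brute-force oracles."""

import io
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from pdbiome.ecology import (
    bray_curtis,
    pcoa,
    permanova,
    richness,
    shannon,
    simpson,
    unifrac,
)
from pdbiome.tables import FeatureTable


def make_table(columns: dict, features=None) -> FeatureTable:
    df = pd.DataFrame(columns)
    if features is not None:
        df.index = features
    return FeatureTable(df)


class TestAlpha:
    def test_uniform_four_taxa(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4), abs=1e-12)
        assert simpson([5, 5, 5, 5]) == pytest.approx(0.75, abs=1e-12)
        assert richness([5, 5, 5, 5]) == 4

    def test_single_taxon(self):
        assert shannon([9]) == 0.0
        assert simpson([9]) == 0.0
        assert richness([9, 0, 0]) == 1

    def test_direct_summation_1234(self):
        # H = -sum p ln p with p = [.1,.2,.3,.4]; 1 - sum p^2 = 0.70
        assert shannon([1, 2, 3, 4]) == pytest.approx(1.27985, abs=1e-4)
        assert simpson([1, 2, 3, 4]) == pytest.approx(0.70, abs=1e-12)

    def test_inverse_simpson_flag(self):
        assert simpson([1, 1], inverse=True) == pytest.approx(2.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = make_table({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert bray_curtis(t)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        t = make_table({"a": [3, 0], "b": [0, 5]})
        assert bray_curtis(t)["a", "b"] == 1.0

    def test_hand_computed_value(self):
        # 1 - 2*min_sum/(sum_u + sum_v) = 1 - 2*2/9 = 5/9
        t = make_table({"u": [1, 2, 0], "v": [0, 2, 4]})
        assert bray_curtis(t)["u", "v"] == pytest.approx(5 / 9, abs=1e-12)

    def test_range_and_symmetry(self, small_cohort):
        dm = bray_curtis(small_cohort.counts)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T, atol=1e-12)


def brute_force_unifrac(tree, counts_a, counts_b, feature_ids, weighted):
    """Explicit branch-by-branch accumulation over the tree."""
    tot_a, tot_b = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        below = {t.name for t in node.tips()} or {node.name}
        a = sum(counts_a.get(f, 0) for f in below)
        b = sum(counts_b.get(f, 0) for f in below)
        if weighted:
            pa, pb = a / tot_a, b / tot_b
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            if (a > 0) != (b > 0):
                num += length
            if a > 0 or b > 0:
                den += length
    return num / den


class TestUniFrac:
    tree_str = "((a:1,b:2):0.5,(c:1,d:1):0.5):0;"

    def tree(self):
        return TreeNode.read(io.StringIO(self.tree_str))

    def test_identical_samples_zero_both_variants(self):
        t = make_table({"s1": [1, 2, 3, 4], "s2": [1, 2, 3, 4]},
                       features=list("abcd"))
        for weighted in (False, True):
            assert unifrac(t, self.tree(), weighted=weighted)["s1", "s2"] == \
                pytest.approx(0.0, abs=1e-12)

    def test_disjoint_subtrees_unweighted_one(self):
        t = make_table({"s1": [3, 1, 0, 0], "s2": [0, 0, 2, 5]},
                       features=list("abcd"))
        assert unifrac(t, self.tree())["s1", "s2"] == pytest.approx(1.0)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_accumulation(self, weighted):
        ca = {"a": 10, "b": 0, "c": 5, "d": 1}
        cb = {"a": 2, "b": 8, "c": 0, "d": 4}
        t = make_table(
            {"s1": [ca[f] for f in "abcd"], "s2": [cb[f] for f in "abcd"]},
            features=list("abcd"),
        )
        expected = brute_force_unifrac(self.tree(), ca, cb, list("abcd"), weighted)
        got = unifrac(t, self.tree(), weighted=weighted)["s1", "s2"]
        assert got == pytest.approx(expected, abs=1e-10)

    def test_missing_feature_errors(self):
        t = make_table({"s1": [1, 1], "s2": [1, 2]}, features=["a", "zzz"])
        with pytest.raises(ValueError, match="zzz"):
            unifrac(t, self.tree())


class TestPcoa:
    def test_equilateral_triangle_eigenstructure(self):
        dm = DistanceMatrix([[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=list("abc"))
        res = pcoa(dm)
        # two equal positive eigenvalues summing to the total SS of 1
        assert res.eigenvalues[0] == pytest.approx(0.5, abs=1e-10)
        assert res.eigenvalues[1] == pytest.approx(0.5, abs=1e-10)
        assert res.eigenvalues[2] == pytest.approx(0.0, abs=1e-10)

    def test_duplicate_sample_coincident(self):
        dm = DistanceMatrix(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0]], ids=list("abc")
        )
        res = pcoa(dm)
        np.testing.assert_allclose(
            res.coordinates.loc["a"], res.coordinates.loc["b"], atol=1e-8
        )

    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_euclidean_distances_reproduced(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        res = pcoa(dm)
        coords = res.coordinates.to_numpy()
        d2 = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_eigenvalue_sum_is_centered_trace(self, small_cohort):
        dm = bray_curtis(small_cohort.counts)
        res = pcoa(dm)
        d2 = np.asarray(dm.data) ** 2
        n = d2.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        trace = np.trace(-0.5 * j @ d2 @ j)
        assert res.eigenvalues.sum() == pytest.approx(trace, abs=1e-8)

    def test_too_many_axes_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=list("ab"))
        with pytest.raises(ValueError):
            pcoa(dm, n_axes=5)


def oracle_f(dm: np.ndarray, groups: np.ndarray) -> float:
    """Classic one-way pseudo-F from within/between squared distances."""
    n = len(groups)
    d2 = dm**2
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    levels = np.unique(groups)
    for g in levels:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(levels)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def two_cloud_data(self, n_per=3, sep=10.0, rng=None):
        rng = rng or np.random.default_rng(0)
        pts = np.vstack(
            [rng.normal(0, 1, (n_per, 2)), rng.normal(sep, 1, (n_per, 2))]
        )
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(2 * n_per)]
        groups = ["A"] * n_per + ["B"] * n_per
        return DistanceMatrix(d, ids=ids), pd.DataFrame({"group": groups}, index=ids)

    def test_equal_distances_f_one_p_one(self):
        n = 6
        d = np.ones((n, n)) - np.eye(n)
        ids = [f"s{i}" for i in range(n)]
        design = pd.DataFrame({"g": ["A"] * 3 + ["B"] * 3}, index=ids)
        res = permanova(DistanceMatrix(d, ids=ids), design, n_permutations=99, seed=0)
        assert res.pseudo_f["g"] == pytest.approx(1.0, abs=1e-10)
        assert res.p_value["g"] == 1.0

    def test_exact_enumeration_matches_brute_force(self):
        """Exact p over all 6!/(3!3!) label splits equals direct
        enumeration with the classic sum-of-squares F."""
        dm, design = self.two_cloud_data(n_per=3, sep=4.0)
        res = permanova(dm, design, exact=True)
        d = np.asarray(dm.data)
        f_obs = oracle_f(d, design["group"].to_numpy())
        assert res.pseudo_f["group"] == pytest.approx(f_obs, rel=1e-9)
        count = total = 0
        for idx in combinations(range(6), 3):
            g = np.array(["B"] * 6)
            g[list(idx)] = "A"
            total += 1
            if oracle_f(d, g) >= f_obs - 1e-12:
                count += 1
        assert res.p_value["group"] == pytest.approx(count / total, abs=1e-12)
        assert res.n_permutations == 20

    def test_one_way_f_matches_skbio(self):
        from skbio.stats.distance import permanova as skbio_permanova

        dm, design = self.two_cloud_data(n_per=4, sep=2.0)
        mine = permanova(dm, design, n_permutations=99, seed=0)
        theirs = skbio_permanova(dm, design["group"].to_numpy(), permutations=0)
        assert mine.pseudo_f["group"] == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_separated_clouds_minimal_p(self):
        rng = np.random.default_rng(1)
        dm, design = self.two_cloud_data(n_per=10, sep=50.0, rng=rng)
        res = permanova(dm, design, n_permutations=99, seed=2)
        assert res.p_value["group"] == pytest.approx(1 / 100)
        assert 0 <= res.r_squared["group"] <= 1

    def test_marginal_mode_adjusts_terms(self):
        rng = np.random.default_rng(3)
        n = 24
        x = rng.normal(size=n)
        group = np.repeat(["A", "B"], n // 2)
        pts = x[:, None] + (group == "A")[:, None] * 1.5 + rng.normal(0, 0.3, (n, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(n)]
        design = pd.DataFrame({"x": x, "group": group}, index=ids)
        res = permanova(DistanceMatrix(d, ids=ids), design,
                        n_permutations=199, marginal=True, seed=0)
        assert set(res.terms) == {"x", "group"}
        assert res.p_value["group"] <= 0.05

    def test_confounded_design_errors(self):
        dm, design = self.two_cloud_data()
        design["dup"] = design["group"]
        with pytest.raises(ValueError, match="confounded"):
            permanova(dm, design, n_permutations=9, marginal=True, seed=0)
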