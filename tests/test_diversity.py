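"""Alpha metrics, Bray–Curtis, UniFrac, PCoA, and ANOSIM."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.stats.distance import anosim as skbio_anosim

import cecomix as cx
from cecomix.diversity import DiversityError


def _table(counts, samples=None, genera=None):
    samples = samples or [f"s{i}" for i in range(np.asarray(counts).shape[1])]
    idx = [f"A{i}" for i in range(np.asarray(counts).shape[0])]
    tax = pd.DataFrame({"phylum": "P", "genus": genera or "g"}, index=idx)
    return cx.FeatureTable(counts=pd.DataFrame(counts, index=idx,
                                               columns=samples), taxonomy=tax)


class TestAlphaDiversity:
    def test_uniform_four_asvs(self):
        res = cx.alpha_diversity(_table([[5], [5], [5], [5]]))
        row = res.iloc[0]
        assert row["shannon_H"] == pytest.approx(2.0)
        assert row["simpson_D"] == pytest.approx(0.75)
        assert row["simpson_E"] == pytest.approx(1.0)

    def test_chao1_hand_value(self):
        # S_obs=6, F1=3, F2=1 -> 6 + 3*2/(2*2) = 7.5
        res = cx.alpha_diversity(_table([[5], [5], [2], [1], [1], [1]]))
        assert res.iloc[0]["chao1"] == pytest.approx(7.5)
        assert res.iloc[0]["observed_asvs"] == 6

    def test_star_tree_faith_pd(self):
        table = _table([[1], [1], [1]])
        tree = TreeNode.read(io.StringIO("(A0:1,A1:1,A2:1);"))
        res = cx.alpha_diversity(table, tree=tree)
        assert res.iloc[0]["faith_pd"] == pytest.approx(3.0)

    def test_missing_tip_names_asv(self):
        table = _table([[1], [1]])
        tree = TreeNode.read(io.StringIO("(A0:1,X:1);"))
        with pytest.raises(DiversityError, match="A1"):
            cx.alpha_diversity(table, tree=tree)

    def test_invariants_on_random_samples(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 30, size=(40, 8))
        counts[:, 0] = 0
        counts[0, 0] = 9  # single-ASV sample: H must be exactly 0
        res = cx.alpha_diversity(_table(counts))
        assert res.iloc[0]["shannon_H"] == 0.0
        assert (res["chao1"] >= res["observed_asvs"] - 1e-9).all()
        assert res["simpson_D"].between(0, 1).all()
        positive = res["observed_asvs"] > 0
        assert res.loc[positive, "simpson_E"].between(0, 1 + 1e-12).all()
        assert (res["shannon_H"] <=
                np.log2(res["observed_asvs"].clip(lower=1)) + 1e-9).all()


class TestBrayCurtis:
    def test_identity_extreme_and_hand_value(self):
        counts = pd.DataFrame({"s1": [6, 0, 2], "s2": [2, 4, 0],
                               "s3": [6, 0, 2], "s4": [0, 7, 0]},
                              index=["a", "b", "c"])
        dm = cx.bray_curtis(counts)
        assert dm["s1", "s3"] == pytest.approx(0.0)
        assert dm["s1", "s4"] == pytest.approx(1.0)          # disjoint support
        assert dm["s1", "s2"] == pytest.approx(1 - 4 / 14)   # hand evaluation

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["a"])
        with pytest.raises(DiversityError, match="s2"):
            cx.bray_curtis(counts)

    def test_matrix_properties(self, study_cohort):
        dm = cx.bray_curtis(cx.relative_abundance(study_cohort["table"].counts))
        D = dm.data
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestUnifrac:
    @pytest.fixture()
    def four_tip(self):
        tree = TreeNode.read(io.StringIO("((A0:1,A1:2):0.5,(A2:3,A3:1):0.25);"))
        table = _table([[4, 0], [2, 0], [0, 5], [0, 1]], samples=["x", "y"])
        return table, tree

    def test_identical_presence_is_zero(self):
        tree = TreeNode.read(io.StringIO("((A0:1,A1:2):0.5,(A2:3,A3:1):0.25);"))
        table = _table([[4, 2], [2, 1], [0, 0], [0, 0]], samples=["x", "y"])
        dm = cx.unifrac(table, tree)
        assert dm["x", "y"] == pytest.approx(0.0)

    def test_disjoint_supports_give_one(self, four_tip):
        table, tree = four_tip
        assert cx.unifrac(table, tree)["x", "y"] == pytest.approx(1.0)

    def test_unweighted_matches_branch_walk_oracle(self):
        tree = TreeNode.read(io.StringIO("((A0:1,A1:2):0.5,(A2:3,A3:1):0.25);"))
        table = _table([[4, 1], [2, 0], [0, 5], [1, 1]], samples=["x", "y"])
        # exhaustive per-branch walk: classify every edge by which sample
        # has a present tip below it
        present = {s: {a for a in table.asv_ids
                       if table.counts.loc[a, s] > 0}
                   for s in ("x", "y")}
        unique = either = 0.0
        for node in tree.postorder(include_self=False):
            below = {t.name for t in node.tips()} or {node.name}
            in_x = bool(below & present["x"])
            in_y = bool(below & present["y"])
            if in_x or in_y:
                either += node.length
                if in_x != in_y:
                    unique += node.length
        dm = cx.unifrac(table, tree)
        assert dm["x", "y"] == pytest.approx(unique / either)

    def test_weighted_matches_formula_oracle(self):
        tree = TreeNode.read(io.StringIO("((A0:1,A1:2):0.5,(A2:3,A3:1):0.25);"))
        table = _table([[4, 1], [2, 0], [0, 5], [1, 1]], samples=["x", "y"])
        cx_total = table.counts.sum()
        num = den = 0.0
        for node in tree.postorder(include_self=False):
            below = {t.name for t in node.tips()} or {node.name}
            px = table.counts.loc[list(below), "x"].sum() / cx_total["x"]
            py = table.counts.loc[list(below), "y"].sum() / cx_total["y"]
            num += node.length * abs(px - py)
            den += node.length * (px + py)
        dm = cx.unifrac(table, tree, weighted=True, normalized=True)
        assert dm["x", "y"] == pytest.approx(num / den)

    def test_unrooted_tree_rejected(self):
        tree = TreeNode.read(io.StringIO("(A0:1,A1:1,A2:1);"))
        table = _table([[1, 0], [0, 1], [1, 1]], samples=["x", "y"])
        with pytest.raises(DiversityError, match="unrooted"):
            cx.unifrac(table, tree)


class TestPCoA:
    def test_three_equidistant_points(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = cx.pcoa(D)
        eig = res.eigenvalues
        assert eig[0] == pytest.approx(eig[1])
        assert eig[0] > 0

    def test_points_on_a_line_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 7.0])
        D = np.abs(pts[:, None] - pts[None, :])
        res = cx.pcoa(D)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        # Euclidean-embeddable input: pairwise distances reproduced
        assert np.allclose(recon, D, atol=1e-8)

    def test_zero_matrix(self):
        res = cx.pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or np.allclose(
            res.coordinates.to_numpy(), 0)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(DiversityError, match="symmetric"):
            cx.pcoa(D)

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean: violates the triangle-embedding into R^n
        D = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1.95],
                      [1, 1, 1.95, 0]])
        res = cx.pcoa(D)
        assert (res.eigenvalues < -1e-12).any()


class TestAnosim:
    def _dm(self, D, ids):
        from skbio import DistanceMatrix
        return DistanceMatrix(D, ids=ids)

    def test_perfect_separation_gives_one(self):
        ids = list("abcdef")
        meta = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        D = np.full((6, 6), 0.9)
        for i, j in itertools.combinations(range(6), 2):
            if (i < 3) == (j < 3):
                D[i, j] = D[j, i] = 0.1
        np.fill_diagonal(D, 0)
        res = cx.anosim(self._dm(D, ids), meta, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.2
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        ids = list("abcdef")
        meta = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        dm = self._dm(D, ids)
        obs = cx.anosim(dm, meta, n_permutations=999, seed=1)
        # exhaustive oracle over all 20 distinct 3/3 label splits
        from scipy.stats import rankdata
        from scipy.spatial.distance import squareform
        ranks = rankdata(squareform(D, checks=False))
        iu, ju = np.triu_indices(6, k=1)
        denom = 6 * 5 / 4

        def r_of(members):
            grp = np.isin(np.arange(6), list(members))
            within = grp[iu] == grp[ju]
            return (ranks[~within].mean() - ranks[within].mean()) / denom

        rs = [r_of(c) for c in itertools.combinations(range(6), 3)]
        p_exact = np.mean([r >= obs.R - 1e-12 for r in rs])
        assert obs.p == pytest.approx(p_exact, abs=0.04)

    def test_matches_skbio_statistic(self, study_cohort):
        dm = cx.bray_curtis(cx.relative_abundance(study_cohort["table"].counts))
        meta = study_cohort["meta"]
        mine = cx.anosim(dm, meta, n_permutations=49, seed=0)
        sk = skbio_anosim(dm, meta.reindex(list(dm.ids)).to_numpy(),
                          permutations=9)
        assert mine.R == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 3))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        ids = [f"s{i}" for i in range(12)]
        dm = self._dm(D, ids)
        from scipy.stats import rankdata
        from scipy.spatial.distance import squareform
        ranks = rankdata(squareform(D, checks=False))
        iu, ju = np.triu_indices(12, k=1)
        denom = 12 * 11 / 4
        codes = np.array([0] * 6 + [1] * 6)
        rs = []
        for _ in range(10_000):
            c = rng.permutation(codes)
            within = c[iu] == c[ju]
            rs.append((ranks[~within].mean() - ranks[within].mean()) / denom)
        assert abs(np.mean(rs)) < 0.02

    def test_deterministic_given_seed(self, study_cohort):
        dm = cx.bray_curtis(cx.relative_abundance(study_cohort["table"].counts))
        meta = study_cohort["meta"]
        a = cx.anosim(dm, meta, n_permutations=199, seed=7)
        b = cx.anosim(dm, meta, n_permutations=199, seed=7)
        assert (a.R, a.p) == (b.R, b.p)

    def test_singleton_group_rejected(self):
        ids = list("abcde")
        meta = pd.Series(["g1"] * 4 + ["g2"], index=ids)
        D = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(DiversityError, match="size"):
            cx.anosim(self._dm(D, ids), meta, n_permutations=9, seed=0)
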