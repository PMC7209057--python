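import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as skbio_faith_pd
from skbio.stats.ordination import pcoa as skbio_pcoa

import phylocomm as pc
from phylocomm.io import ValidationError
from phylocomm.phylometrics import pcoa, unweighted_unifrac

from _oracles import brute_faith_pd, brute_mpd_mntd, brute_unifrac, random_binary
from conftest import make_cm


class TestFaithPD:
    def test_printed_examples(self, toy_tree):
        assert pc.faith_pd(toy_tree, ["A", "B", "C"]) == pytest.approx(5.0)
        assert pc.faith_pd(toy_tree, ["A"]) == pytest.approx(2.0)
        assert pc.faith_pd(toy_tree, ["A", "B"]) == pytest.approx(3.0)

    def test_matches_edge_union_oracle_and_skbio(self):
        rng = np.random.default_rng(0)
        tree = pc.gen_tree(12, seed=5).midpoint_root()
        tips = tree.tip_names
        for _ in range(50):
            k = rng.integers(1, 12)
            subset = list(rng.choice(tips, size=k, replace=False))
            mine = pc.faith_pd(tree, subset)
            assert mine == pytest.approx(brute_faith_pd(tree, subset), abs=1e-9)
            counts = [1 if t in subset else 0 for t in tips]
            ref = skbio_faith_pd(counts, taxa=tips, tree=tree.node)
            assert mine == pytest.approx(float(ref), abs=1e-9)

    def test_monotone_in_taxon_additions(self):
        rng = np.random.default_rng(1)
        tree = pc.gen_tree(15, seed=6)
        tips = list(tree.tip_names)
        rng.shuffle(tips)
        values = [pc.faith_pd(tree, tips[: k + 1]) for k in range(len(tips))]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        assert values[-1] == pytest.approx(tree.total_length)

    def test_unknown_taxon_rejected(self, toy_tree):
        with pytest.raises(ValidationError, match="not in tree"):
            pc.faith_pd(toy_tree, ["A", "zz"])


class TestMpdMntd:
    def test_pair_equals_patristic_distance(self, toy_tree):
        d = toy_tree.patristic_distances()
        assert pc.mpd(d, ["A", "C"]) == pytest.approx(4.0)
        assert pc.mntd(d, ["A", "C"]) == pytest.approx(4.0)

    def test_three_taxon_hand_values(self, toy_tree):
        d = toy_tree.patristic_distances()
        assert pc.mpd(d, ["A", "B", "C"]) == pytest.approx((2 + 4 + 4) / 3)
        assert pc.mntd(d, ["A", "B", "C"]) == pytest.approx((2 + 2 + 4) / 3)

    def test_star_tree_symmetry(self):
        tree = pc.PhyloTree.from_newick("(A:2,B:2,C:2,D:2);")
        d = tree.patristic_distances()
        for subset in (["A", "B"], ["A", "B", "C"], ["A", "B", "C", "D"]):
            assert pc.mpd(d, subset) == pytest.approx(4.0)
            assert pc.mntd(d, subset) == pytest.approx(4.0)

    def test_matches_loop_oracle_with_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        tree = pc.gen_tree(10, seed=7)
        d = tree.patristic_distances()
        subset = list(rng.choice(tree.tip_names, size=6, replace=False))
        ref_mpd, ref_mntd = brute_mpd_mntd(d, subset)
        assert pc.mpd(d, subset) == pytest.approx(ref_mpd)
        assert pc.mntd(d, subset) == pytest.approx(ref_mntd)
        shuffled = d.sample(frac=1, axis=0, random_state=3)
        shuffled = shuffled[shuffled.index]
        assert pc.mpd(shuffled, subset) == pytest.approx(ref_mpd)
        assert pc.mntd(shuffled, subset) == pytest.approx(ref_mntd)

    def test_singleton_is_missing(self, toy_tree):
        d = toy_tree.patristic_distances()
        assert np.isnan(pc.mpd(d, ["A"]))
        assert np.isnan(pc.mntd(d, ["A"]))


class TestUnifrac:
    def test_identical_samples_distance_zero(self, toy_tree):
        cm = make_cm([[1, 1], [1, 1], [0, 0]], taxa=["A", "B", "C"])
        d = unweighted_unifrac(cm, toy_tree)
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_root_clades_distance_one(self):
        tree = pc.PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        cm = make_cm([[1, 0], [1, 0], [0, 1], [0, 1]], taxa=list("ABCD"))
        d = unweighted_unifrac(cm, tree)
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_enumerated_four_tip_case(self):
        tree = pc.PhyloTree.from_newick("((A:1,B:2):1,(C:1,D:3):2);")
        # sample u = {A,C}, v = {A,D}
        # shared: A edge (1) + AB stem (1) + CD stem (2) = 4
        # unique: C (1) + D (3) = 4 -> distance 4/8
        cm = make_cm([[1, 1], [0, 0], [1, 0], [0, 1]], taxa=list("ABCD"),
                     samples=["u", "v"])
        d = unweighted_unifrac(cm, tree)
        assert d.loc["u", "v"] == pytest.approx(0.5)
        assert d.loc["u", "v"] == pytest.approx(
            brute_unifrac(tree, {"A", "C"}, {"A", "D"})
        )

    def test_matches_skbio_and_metric_axioms(self):
        rng = np.random.default_rng(3)
        tree = pc.gen_tree(14, seed=8).midpoint_root()
        m = random_binary(rng, 14, 6, p=0.5)
        m[:, 0] |= m[:, 1]  # avoid empty samples
        m[0, :] = 1
        cm = make_cm(m, taxa=tree.tip_names)
        mine = unweighted_unifrac(cm, tree)
        ref = beta_diversity(
            "unweighted_unifrac",
            m.T,
            ids=cm.sample_ids,
            taxa=tree.tip_names,
            tree=tree.node,
        )
        ref_df = pd.DataFrame(ref.data, index=ref.ids, columns=ref.ids)
        assert np.abs(mine.to_numpy() - ref_df.to_numpy()).max() < 1e-9
        a = mine.to_numpy()
        assert np.allclose(a, a.T)
        for i, j, k in rng.integers(0, 6, size=(100, 3)):
            assert a[i, j] <= a[i, k] + a[k, j] + 1e-12

    def test_empty_sample_flagged_nan(self, toy_tree):
        cm = make_cm([[1, 0], [1, 0], [0, 0]], taxa=["A", "B", "C"])
        d = unweighted_unifrac(cm, toy_tree)
        assert np.isnan(d.iloc[0, 1])


class TestPcoa:
    def test_points_on_a_line(self):
        pts = np.array([0.0, 3.0, 5.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]),
                         index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        recovered = np.abs(axis1[:, None] - axis1[None, :])
        assert np.allclose(recovered, d.to_numpy(), atol=1e-9)
        if res.coordinates.shape[1] > 1:
            assert np.abs(res.coordinates.iloc[:, 1]).max() < 1e-9

    def test_equilateral_metric_two_equal_eigenvalues(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_euclidean_roundtrip_and_skbio_agreement(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        d = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(8)])
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        rec = squareform(pdist(coords))
        assert np.abs(rec - d.to_numpy()).max() < 1e-9
        ref = skbio_pcoa(d.to_numpy(), number_of_dimensions=3)
        assert np.allclose(
            np.sort(res.eigenvalues[:3]), np.sort(ref.eigvals.to_numpy()[:3]),
            atol=1e-8,
        )

    def test_negative_eigenvalues_reported_not_embedded(self):
        # a non-Euclidean metric: star metric with a violation of 4-point condition
        d = np.array(
            [[0, 1, 1, 1], [1, 0, 2, 2], [1, 2, 0, 2], [1, 2, 2, 0]], dtype=float
        )
        d = pd.DataFrame(d, index=list("abcd"), columns=list("abcd"))
        res = pcoa(d)
        assert res.n_negative >= 1
        assert res.coordinates.shape[1] + res.n_negative <= len(res.eigenvalues)

    def test_asymmetric_input_rejected(self):
        d = pd.DataFrame([[0, 1], [2, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError, match="symmetric"):
            pcoa(d)
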