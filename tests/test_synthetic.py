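import numpy as np
import pandas as pd
import pytest

import phylocomm as pc
from phylocomm.synthetic import SynthScenario, assemble_communities, gen_env


class TestGenTree:
    def test_topology_counts(self):
        tree = pc.gen_tree(3, seed=0)
        assert tree.n_tips == 3
        internal = sum(1 for n in tree.node.non_tips(include_self=True))
        assert internal == 2

    @pytest.mark.parametrize("n", [5, 20, 60])
    def test_ultrametric(self, n):
        tree = pc.gen_tree(n, seed=n)
        depths = [t.accumulate_to_ancestor(tree.node) for t in tree.node.tips()]
        assert max(depths) - min(depths) < 1e-9

    def test_yule_growth_rate(self):
        # lineages through time: E[N(t)] = 2 e^(lambda t) from the root split
        lam = 1.0
        target_n = 16
        times = []
        for i in range(400):
            tree = pc.gen_tree(target_n, birth_rate=lam, seed=i)
            depth = max(
                t.accumulate_to_ancestor(tree.node) for t in tree.node.tips()
            )
            times.append(depth)
        # waiting time to n tips: sum of Exp(k*lam) for k=2..n (+ final tail)
        expected = sum(1 / (lam * k) for k in range(2, target_n + 1)) + 1 / (
            lam * target_n
        )
        assert np.mean(times) == pytest.approx(expected, rel=0.1)

    def test_deterministic_under_seed(self):
        assert pc.gen_tree(25, seed=9).to_newick() == pc.gen_tree(25, seed=9).to_newick()


class TestEvolveTrait:
    def test_zero_rate_gives_identical_tips(self):
        tree = pc.gen_tree(10, seed=1)
        traits = pc.evolve_trait(tree, trait_sigma2=0.0, seed=2)
        assert traits.nunique() == 1

    def test_tip_variance_tracks_depth(self):
        tree = pc.gen_tree(6, seed=3)
        depth = max(t.accumulate_to_ancestor(tree.node) for t in tree.node.tips())
        tip = tree.tip_names[0]
        draws = np.array(
            [pc.evolve_trait(tree, 2.0, seed=s)[tip] for s in range(2000)]
        )
        assert draws.var() == pytest.approx(2.0 * depth, rel=0.1)

    def test_sister_tips_covary_through_shared_path(self):
        tree = pc.PhyloTree.from_newick("((A:1,B:1):3,C:4);")
        draws = np.array(
            [pc.evolve_trait(tree, 1.0, seed=s)[["A", "B"]] for s in range(2000)]
        )
        cov = np.cov(draws.T)[0, 1]
        assert cov == pytest.approx(3.0, rel=0.15)  # shared path length


class TestGenEnv:
    def test_mud_always_in_percentage_range(self):
        for s in range(10):
            env = gen_env(seed=s, mud_mean=95, mud_sd=30)
            assert env.data["Mud"].between(0, 100).all()

    def test_gradient_induces_toc_cpe_correlation(self):
        big = {f"A{i}": 4 for i in range(12)}
        r = [gen_env(big, seed=s).variables.corr().loc["TOC", "CPE"] for s in range(10)]
        assert 0.2 < np.mean(r) < 0.95

    def test_design_matches_survey_layout(self):
        env = gen_env(seed=0)
        assert len(env.sample_ids) == 23
        assert env.area.value_counts().to_dict() == pc.PAPER_DESIGN


class TestAssembly:
    def _inputs(self, seed=0, **kw):
        sc = SynthScenario(n_tips=40, richness_per_sample=8, seed=seed, **kw)
        tree = pc.gen_tree(sc.n_tips, seed=seed)
        traits = pc.evolve_trait(tree, sc.trait_sigma2, seed=seed + 1)
        return sc, tree, traits

    def test_huge_bandwidth_weights_are_uniform(self):
        _, tree, traits = self._inputs()
        t = traits.to_numpy()
        w = np.exp(-((t - t.mean()) ** 2) / (2 * 1e9**2))
        assert np.ptp(w) < 1e-6

    def test_filtering_reduces_within_sample_distance(self):
        hits, runs = 0, 20
        for i in range(runs):
            sc, tree, traits = self._inputs(seed=500 + i, assembly="filtering",
                                            endemic_fraction=0.0)
            cm, _ = assemble_communities(tree, traits, sc, seed=600 + i)
            d = tree.patristic_distances()
            pool_mean = d.to_numpy()[np.triu_indices(tree.n_tips, 1)].mean()
            within = [
                pc.mpd(d, list(cm.counts.index[cm.counts[s] > 0]))
                for s in cm.sample_ids
            ]
            if np.nanmean(within) < pool_mean:
                hits += 1
        assert hits >= int(0.95 * runs)

    def test_habitat_blocks_cross_block_pairs_are_checkerboards(self):
        sc, tree, traits = self._inputs(seed=7, assembly="habitat_blocks",
                                        endemic_fraction=0.0)
        cm, truth = assemble_communities(tree, traits, sc, seed=8)
        pa = cm.presence_absence().counts
        blocks = truth["taxon_block"]
        present = pa.sum(axis=1) > 0
        m = pa.to_numpy()
        taxa = list(pa.index)
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                if not (present.iloc[i] and present.iloc[j]):
                    continue
                if blocks[taxa[i]] != blocks[taxa[j]]:
                    assert np.sum((m[i] == 1) & (m[j] == 1)) == 0

    def test_members_always_get_reads(self):
        sc, tree, traits = self._inputs(seed=11)
        cm, truth = assemble_communities(tree, traits, sc, seed=12)
        present = (cm.counts > 0).sum(axis=0)
        assert (present >= 2).all()

    def test_endemics_respect_home_area(self):
        sc, tree, traits = self._inputs(seed=13)
        env = gen_env(sc.areas, seed=14)
        cm, truth = assemble_communities(tree, traits, sc, env=env, seed=15)
        pa = cm.presence_absence().counts
        for taxon, home in truth["endemic_home"].items():
            hit_areas = {env.area[s] for s in pa.columns if pa.loc[taxon, s] > 0}
            assert hit_areas <= {home}


class TestTaxonomy:
    def test_genera_are_monophyletic_clades(self):
        tree = pc.gen_tree(60, seed=9)
        tax = pc.assign_taxonomy(tree, unassigned_fraction=0.0, seed=1)
        genus = {t: l.split(";")[-1] for t, l in tax.items()}
        # every genus's tips must form a clade: their MRCA contains no others
        for g in set(genus.values()):
            members = [t for t, v in genus.items() if v == g]
            mrca = tree.node.lowest_common_ancestor(members)
            below = {t.name for t in mrca.tips()} if not mrca.is_tip() else {mrca.name}
            assert below == set(members)

    def test_unassigned_fraction_controls_truncation(self):
        tree = pc.gen_tree(80, seed=10)
        tax = pc.assign_taxonomy(tree, unassigned_fraction=0.5, seed=2)
        frac = sum(l.endswith("Unassigned") for l in tax.values()) / len(tax)
        assert 0.3 < frac < 0.7
        full = pc.assign_taxonomy(tree, unassigned_fraction=0.0, seed=2)
        assert not any(l.endswith("Unassigned") for l in full.values())


class TestDataset:
    def test_byte_identical_under_seed(self):
        a = pc.generate_dataset(SynthScenario(n_tips=30, richness_per_sample=6, seed=4))
        b = pc.generate_dataset(SynthScenario(n_tips=30, richness_per_sample=6, seed=4))
        pd.testing.assert_frame_equal(a.community.counts, b.community.counts)
        assert a.tree.to_newick() == b.tree.to_newick()
        pd.testing.assert_frame_equal(a.env.data, b.env.data)

    def test_default_design_shape_and_rarity(self):
        ds = pc.generate_dataset(SynthScenario(seed=1))
        assert ds.community.shape[1] == 23
        summary = pc.intersection_summary(
            ds.community, {s: ds.env.area[s] for s in ds.env.sample_ids}
        )
        # endemics (65% of the pool) keep most ASVs confined to one area
        assert summary.unique_fraction() > 0.4

    def test_env_effect_links_richness_to_toc(self):
        sc = SynthScenario(seed=2, env_effect={"TOC": 0.6})
        ds = pc.generate_dataset(sc)
        richness = (ds.community.counts > 0).sum(axis=0)
        toc = ds.env.variables["TOC"]
        assert np.corrcoef(richness, toc.loc[richness.index])[0, 1] > 0.3
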