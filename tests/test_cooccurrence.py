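import numpy as np
import pytest
from scipy import stats

import phylocomm as pc
from phylocomm.io import ValidationError

from _oracles import brute_c_score, random_binary
from conftest import make_cm


class TestCScore:
    def test_identical_rows_score_zero(self):
        st = pc.c_score(make_cm([[1, 1, 0], [1, 1, 0]]))
        assert st.c_score == 0.0
        assert st.n_checkerboard_pairs == 0

    def test_disjoint_rows_form_checkerboard(self):
        # taxon i in sites {1,2}, taxon j in sites {3,4}: (2-0)(2-0) = 4
        st = pc.c_score(make_cm([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert st.c_score == 4.0
        assert st.n_checkerboard_pairs == 1

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            m = random_binary(rng, 6, 5, p=rng.uniform(0.2, 0.8), nonempty_rows=True)
            st = pc.c_score(make_cm(m))
            c_ref, cp_ref = brute_c_score(m)
            assert st.c_score == pytest.approx(c_ref, abs=1e-12)
            assert st.n_checkerboard_pairs == cp_ref
            assert st.n_pairs_evaluated == 15

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        m = random_binary(rng, 7, 6, nonempty_rows=True)
        st = pc.c_score(make_cm(m))
        perm_rows = m[rng.permutation(7)][:, rng.permutation(6)]
        st2 = pc.c_score(make_cm(perm_rows))
        assert st.c_score == pytest.approx(st2.c_score)
        assert st.n_checkerboard_pairs == st2.n_checkerboard_pairs

    def test_single_taxon_rejected(self):
        with pytest.raises(ValidationError, match="two"):
            pc.c_score(make_cm([[1, 0]]))

    def test_nonbinary_rejected(self, small_cm):
        with pytest.raises(ValidationError, match="presence-absence"):
            pc.c_score(small_cm)


class TestSim2:
    def test_row_sums_conserved_every_draw(self):
        rng = np.random.default_rng(2)
        m = random_binary(rng, 8, 6)
        for draw in pc.sim2_null(m, n_reps=200, seed=0):
            assert (draw.sum(axis=1) == m.sum(axis=1)).all()

    def test_full_row_returned_unchanged(self):
        m = np.array([[1, 1, 1], [1, 0, 0]])
        for draw in pc.sim2_null(m, n_reps=50, seed=1):
            assert draw[0].tolist() == [1, 1, 1]

    def test_row_arrangements_uniform(self):
        # row (1,1,0): the 3 arrangements should each appear ~1/3
        m = np.array([[1, 1, 0]])
        counts = {}
        for draw in pc.sim2_null(m, n_reps=30_000, seed=3):
            counts[tuple(draw[0])] = counts.get(tuple(draw[0]), 0) + 1
        freqs = np.array(list(counts.values()))
        assert len(freqs) == 3
        assert np.all(np.abs(freqs / 30_000 - 1 / 3) < 0.01)
        assert stats.chisquare(freqs).pvalue > 0.001


class TestCooccurrenceTest:
    def test_identical_rows_aggregated(self):
        m = np.tile(np.array([[1, 0, 1, 0, 1]]), (4, 1))
        res = pc.cooccurrence_test(make_cm(m), n_reps=300, seed=0)
        assert res.observed == 0.0
        assert res.ses <= 0

    def test_tail_probabilities_tie_inclusive(self):
        rng = np.random.default_rng(4)
        res = pc.cooccurrence_test(
            make_cm(random_binary(rng, 6, 5, nonempty_rows=True)),
            n_reps=200,
            seed=5,
        )
        assert res.p_upper + res.p_lower >= 1.0
        assert 0 < res.p_upper <= 1 and 0 < res.p_lower <= 1

    def test_type_i_error_under_true_null(self):
        # data drawn from sim2 itself: two-tailed rejections near 0.05
        rng = np.random.default_rng(6)
        template = random_binary(rng, 10, 8, p=0.4, nonempty_rows=True)
        gen = pc.sim2_null(template, n_reps=400, seed=7)
        rejections = 0
        for i, data in enumerate(gen):
            res = pc.cooccurrence_test(data, n_reps=199, seed=100 + i)
            if 2 * min(res.p_upper, res.p_lower) <= 0.05:
                rejections += 1
        assert abs(rejections / 400 - 0.05) < 0.03

    def test_segregated_blocks_positive_ses(self):
        # two site-blocks with block-confined taxa: segregation, ses > 0
        m = np.zeros((10, 8), dtype=int)
        rng = np.random.default_rng(8)
        for i in range(10):
            block = slice(0, 4) if i < 5 else slice(4, 8)
            m[i, block] = rng.random(4) < 0.8
            if m[i].sum() == 0:
                m[i, block.start] = 1
        res = pc.cooccurrence_test(make_cm(m), n_reps=500, seed=9)
        assert res.ses > 0

    def test_shared_block_negative_ses(self):
        # all taxa crowd the same half of the sites: aggregation, ses < 0
        m = np.zeros((10, 8), dtype=int)
        rng = np.random.default_rng(10)
        m[:, :4] = rng.random((10, 4)) < 0.8
        m[m.sum(axis=1) == 0, 0] = 1
        res = pc.cooccurrence_test(make_cm(m), n_reps=500, seed=11)
        assert res.ses < 0


class TestScales:
    AREAS = dict(pc.PAPER_DESIGN)

    def _sample_map(self):
        return {
            f"{a}.{r}": a for a, n in self.AREAS.items() for r in range(1, n + 1)
        }

    def test_design_column_counts(self):
        mapping = self._sample_map()
        rng = np.random.default_rng(12)
        m = random_binary(rng, 15, 23, p=0.4, nonempty_rows=True)
        cm = make_cm(m, samples=list(mapping))
        pooled = pc.pool_by_area(cm, mapping)
        assert cm.shape[1] == 23
        assert pooled.shape[1] == 6

    def test_pooling_is_union_of_presences(self):
        mapping = {"a.1": "a", "a.2": "a"}
        cm = make_cm([[1, 0], [0, 1], [0, 0]], samples=["a.1", "a.2"])
        pooled = pc.pool_by_area(cm, mapping)
        assert pooled.counts["a"].tolist() == [1, 1, 0]

    def test_identical_replicates_pool_to_themselves(self):
        mapping = {"a.1": "a", "a.2": "a"}
        cm = make_cm([[1, 1], [0, 0], [1, 1]], samples=["a.1", "a.2"])
        pooled = pc.pool_by_area(cm, mapping)
        assert pooled.counts["a"].tolist() == cm.counts["a.1"].tolist()

    def test_run_scales_table(self):
        mapping = self._sample_map()
        rng = np.random.default_rng(13)
        m = random_binary(rng, 12, 23, p=0.45, nonempty_rows=True)
        cm = make_cm(m, samples=list(mapping))
        table = pc.run_scales(cm, mapping, n_reps=99, seed=14)
        scopes = set(table["scope"])
        assert {"regional_replicates", "regional_areas"} <= scopes
        assert {f"local:{a}" for a in self.AREAS} <= scopes
        assert set(table["statistic"]) == {"c_score", "checker_pairs"}
        assert ((table["p_upper"] > 0) & (table["p_upper"] <= 1)).all()

    def test_single_replicate_area_skipped(self):
        mapping = {"a.1": "a", "a.2": "a", "b.1": "b"}
        cm = make_cm([[1, 0, 1], [0, 1, 1], [1, 1, 0]], samples=list(mapping))
        with pytest.warns(UserWarning, match="<2 replicates"):
            table = pc.run_scales(cm, mapping, n_reps=49, seed=0)
        assert "local:b" not in set(table["scope"])
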