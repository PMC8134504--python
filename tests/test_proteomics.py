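"""Proteomic-screen statistics: preprocessing, Welch differentials,
q-values, clustering, stage classification, group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist

import mammoquant as mq
from mammoquant.errors import ParameterError
from mammoquant.proteomics import AbundanceMatrix


def _matrix(values, groups, original_zero=None):
    values = np.asarray(values, float)
    n_prot, n_samp = values.shape
    return AbundanceMatrix(
        values=values,
        protein_ids=[f"P{i}" for i in range(n_prot)],
        sample_ids=[f"s{i}" for i in range(n_samp)],
        group_labels=list(groups),
        original_zero=original_zero)


class TestPreprocessing:
    def test_impute_half_global_minimum(self):
        m = _matrix([[10, 0, 20], [30, 40, 0]], ["a", "a", "b"])
        out = mq.impute_zeros(m)
        assert out.values[0, 1] == 5.0
        assert out.values[1, 2] == 5.0
        assert out.original_zero[0, 1] and out.original_zero[1, 2]

    def test_impute_idempotent_and_no_zero_noop(self):
        m = _matrix([[1, 2], [3, 4]], ["a", "b"])
        once = mq.impute_zeros(m)
        assert np.array_equal(once.values, m.values)
        twice = mq.impute_zeros(mq.impute_zeros(
            _matrix([[0, 2], [3, 4]], ["a", "b"])))
        assert np.array_equal(
            twice.values,
            mq.impute_zeros(_matrix([[0, 2], [3, 4]], ["a", "b"])).values)

    def test_filter_uses_original_zeros_not_values(self):
        # protein 0: 3 zeros in group a -> dropped; protein 1: 2+2 -> kept
        vals = np.array([[0, 0, 0, 1, 1, 5, 5, 5, 5, 5],
                         [0, 0, 1, 1, 1, 0, 0, 5, 5, 5]], float)
        groups = ["a"] * 5 + ["b"] * 5
        m = mq.impute_zeros(_matrix(vals, groups))
        out = mq.filter_group_zeros(m, max_zeros_per_group=2)
        assert out.protein_ids == ["P1"]

    def test_eic_normalize_columns_sum_to_one(self):
        m = _matrix([[2, 1], [3, 1], [5, 2]], ["a", "b"])
        out = mq.eic_normalize(m)
        assert np.allclose(out.values.sum(axis=0), 1.0, atol=1e-12)
        assert out.values[:, 0] == pytest.approx([0.2, 0.3, 0.5])

    def test_zero_column_rejected(self):
        with pytest.raises(ParameterError):
            mq.eic_normalize(_matrix([[0, 1], [0, 2]], ["a", "b"]))

    def test_tsv_roundtrip(self, tmp_path):
        p = mq.AbundanceGenParams(n_proteins=20, dropout_prob=0.1, seed=0)
        m, _ = mq.generate_abundance_matrix(p)
        m.to_tsv(tmp_path / "m.tsv", tmp_path / "g.json")
        back = AbundanceMatrix.from_tsv(tmp_path / "m.tsv",
                                        tmp_path / "g.json")
        assert np.allclose(back.values, m.values)
        assert back.group_labels == m.group_labels


class TestDifferential:
    def test_identical_groups_not_significant(self):
        vals = np.tile([[4.0, 5.0, 6.0]], (3, 2)).reshape(3, 6)
        m = _matrix(vals, ["a"] * 3 + ["b"] * 3)
        res = mq.differential(m.subset_group("a"), m.subset_group("b"))
        assert (res.table.log2_ratio == 0).all()
        assert not res.table.significant.any()

    def test_welch_worked_example(self):
        m = _matrix([[1, 2, 3, 2, 3, 4]], ["a"] * 3 + ["b"] * 3)
        res = mq.differential(m.subset_group("a"), m.subset_group("b"))
        row = res.table.iloc[0]
        assert row.t == pytest.approx(-1.2247, abs=1e-4)
        assert row.p == pytest.approx(0.2879, abs=1e-3)

    def test_unique_observation_sentinel(self):
        vals = np.array([[5, 6, 7, 0, 0, 0],
                         [0, 0, 0, 5, 6, 7],
                         [5, 6, 7, 5, 6, 7]], float)
        m = mq.impute_zeros(_matrix(vals, ["a"] * 3 + ["b"] * 3))
        res = mq.differential(m.subset_group("a"), m.subset_group("b"))
        by_id = res.table.set_index("protein_id")
        assert by_id.loc["P0", "log2_ratio"] == 10.0
        assert by_id.loc["P1", "log2_ratio"] == -10.0
        assert by_id.loc["P0", "significant"]

    def test_min_obs_excludes_sparse_proteins(self):
        vals = np.array([[5, 0, 0, 0, 0, 0],
                         [5, 6, 7, 5, 6, 7]], float)
        m = mq.impute_zeros(_matrix(vals, ["a"] * 3 + ["b"] * 3))
        res = mq.differential(m.subset_group("a"), m.subset_group("b"),
                              min_obs=3)
        assert res.table.protein_id.tolist() == ["P1"]

    def test_type_one_error_on_null_generator(self):
        """Welch test holds its nominal 5% size on null matrices."""
        p = mq.AbundanceGenParams(n_proteins=2000,
                                  groups=[("a", 5), ("b", 5)],
                                  dropout_prob=0.0, seed=42)
        m, _ = mq.generate_abundance_matrix(p)
        res = mq.differential(m.subset_group("a"), m.subset_group("b"))
        assert (res.table.p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestQvalues:
    def test_all_ones(self):
        assert mq.qvalues([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_hand_bh_example(self):
        assert mq.qvalues([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_p_equals_p(self):
        assert mq.qvalues([0.2]).tolist() == [0.2]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_brute_force_bh(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(2, 40))
        q = mq.qvalues(p)
        # brute-force step-up: q_i = min over j with p_j >= p_i of p_j*m/rank_j
        m_ = len(p)
        order = np.argsort(p)
        brute = np.empty(m_)
        running = 1.0
        for rank in range(m_, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m_ / rank)
            brute[i] = running
        assert q == pytest.approx(brute)
        # monotone in the p ordering
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_below_bh_under_signal(self):
        rng = np.random.default_rng(0)
        p = np.concatenate([rng.uniform(0, 0.001, 300),
                            rng.uniform(0, 1, 700)])
        qs = mq.qvalues(p, method="storey")
        qb = mq.qvalues(p, method="bh")
        assert (qs <= qb + 1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            mq.qvalues([0.5, 1.2])


def _brute_force_average_linkage(X):
    """Enumerate agglomerative average-linkage merges on correlation
    distance; returns the sequence of merged index sets."""
    d = {}
    n = len(X)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = np.corrcoef(X[i], X[j])[0, 1]
            dm[i, j] = dm[j, i] = 1 - r
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = np.mean([dm[i, j] for i in a for j in b])
            if best is None or avg < best[0] - 1e-12:
                best = (avg, a, b)
        _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append(a | b)
    return merges


class TestCorrelationCluster:
    def test_identical_profiles_merge_first(self):
        X = np.array([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1],
                      [2, 2, 3, 1]], float).T
        m = _matrix(X, ["a", "a", "b", "b"])
        dend = mq.correlation_cluster(m)
        first = dend.linkage[0]
        assert sorted(first[:2]) == [0, 1]
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        X = np.array([[1, 2, 3], [3, 2, 1]], float).T
        m = _matrix(X, ["a", "b"])
        dend = mq.correlation_cluster(m)
        assert dend.linkage[0, 2] == pytest.approx(2.0)

    def test_merge_order_matches_enumeration(self):
        """Four toy profiles: merges equal brute-force average linkage."""
        rng = np.random.default_rng(1)
        X = rng.uniform(0.5, 5.0, (4, 30))
        m = _matrix(X.T, list("abcd"))
        dend = mq.correlation_cluster(m)
        brute = _brute_force_average_linkage(X)
        # decode scipy merge sets
        sets = {i: frozenset([i]) for i in range(4)}
        got = []
        for k, row in enumerate(dend.linkage):
            s = sets[int(row[0])] | sets[int(row[1])]
            sets[4 + k] = s
            got.append(s)
        assert got == brute

    def test_newick_has_all_leaves(self):
        p = mq.AbundanceGenParams(n_proteins=50, dropout_prob=0.0, seed=2)
        m, _ = mq.generate_abundance_matrix(p)
        nwk = mq.correlation_cluster(m).to_newick()
        for sid in m.sample_ids:
            assert sid in nwk

    def test_constant_profile_rejected(self):
        m = _matrix(np.array([[1, 1], [1, 2]], float), ["a", "b"])
        with pytest.raises(ParameterError):
            mq.correlation_cluster(m)


class TestStageClassifier:
    def _separable(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (50, 5))
        b = rng.normal(10, 1, (50, 5))
        extra_a = rng.normal(0, 1, (50, 3))
        extra_b = rng.normal(10, 1, (50, 3))
        train = _matrix(np.abs(np.hstack([a, b])) + 1e-9,
                        ["g1"] * 5 + ["g2"] * 5)
        score = _matrix(np.abs(np.hstack([extra_a, extra_b])) + 1e-9,
                        ["g1"] * 3 + ["g2"] * 3)
        return train, score

    def test_separable_data_confident(self):
        train, score = self._separable()
        rep = mq.rf_stage_classify(train, score, n_trees=1000, seed=0)
        for sid, label in zip(score.sample_ids, score.group_labels):
            assert rep.probabilities.loc[sid, label] > 0.9
        assert rep.oob_accuracy == 1.0

    def test_null_scores_near_half(self):
        """Pure-noise features give ~0.5 class probability."""
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            train = _matrix(np.abs(rng.normal(5, 1, (50, 10))),
                            ["g1"] * 5 + ["g2"] * 5)
            rep = mq.rf_stage_classify(train, train, n_trees=1000, seed=seed)
            means.append(rep.probabilities["g1"].mean())
        assert np.mean(means) == pytest.approx(0.5, abs=0.15)

    def test_deterministic_for_seed(self):
        train, score = self._separable()
        r1 = mq.rf_stage_classify(train, score, n_trees=200, seed=7)
        r2 = mq.rf_stage_classify(train, score, n_trees=200, seed=7)
        pd.testing.assert_frame_equal(r1.probabilities, r2.probabilities)

    def test_single_class_rejected(self):
        train, score = self._separable()
        bad = _matrix(train.values, ["g1"] * 10)
        with pytest.raises(ParameterError):
            mq.rf_stage_classify(bad, score)


class TestGroupCompare:
    def test_anova_worked_example(self):
        res = mq.group_compare([(1, 2, 3), (2, 3, 4), (5, 6, 7)],
                               "anova_tukey")
        assert res["F"] == pytest.approx(13.0)
        assert res["p"] == pytest.approx(0.0066, abs=5e-4)
        assert len(res["pairwise"]) == 3

    def test_identical_groups_f_zero(self):
        res = mq.group_compare([(2, 2, 2), (2, 2, 2)], "anova_tukey")
        assert res["F"] == 0.0 and res["p"] == 1.0

    def test_wilcoxon_exact_enumeration(self):
        res = mq.group_compare([(1, 2), (3, 4)], "wilcoxon")
        assert res["p"] == pytest.approx(1 / 3)

    def test_kruskal_dunn_shapes(self):
        res = mq.group_compare([(1, 2, 3), (2, 3, 4), (5, 6, 7)],
                               "kruskal_dunn")
        assert res["p"] < 0.05
        assert set(res["pairwise"].columns) >= {"z", "p", "p_bonferroni"}
        assert len(res["pairwise"]) == 3

    def test_unknown_design_rejected(self):
        with pytest.raises(ParameterError):
            mq.group_compare([(1, 2), (3, 4)], "bogus")


class TestStageSignatureQualitative:
    def test_delayed_group_classified_as_early(self):
        """A mutant group whose profile matches the younger stage clusters
        with it and is scored as the earlier stage by the forest."""
        effects = [mq.PlantedEffect(i, "4wk_wt", "5wk_wt",
                                    4.0 if i % 2 else 0.25)
                   for i in range(60)]
        p = mq.AbundanceGenParams(n_proteins=400, dropout_prob=0.05,
                                  planted_effects=effects, seed=7)
        m, _ = mq.generate_abundance_matrix(p)
        mn = mq.eic_normalize(mq.filter_group_zeros(mq.impute_zeros(m)))

        # clustering: delayed (5wk_mut) samples sit nearer 4wk than 5wk
        dend = mq.correlation_cluster(mn)
        coph = cophenet(dend.linkage)
        n = len(mn.sample_ids)
        cm = np.zeros((n, n))
        cm[np.triu_indices(n, 1)] = coph
        cm += cm.T
        idx = {g: [i for i, l in enumerate(mn.group_labels) if l == g]
               for g in mn.groups}
        d_mut_4wk = cm[np.ix_(idx["5wk_mut"], idx["4wk_wt"])].mean()
        d_mut_5wk = cm[np.ix_(idx["5wk_mut"], idx["5wk_wt"])].mean()
        assert d_mut_4wk < d_mut_5wk

        # forest scores the delayed group as the earlier stage
        cols = idx["4wk_wt"] + idx["5wk_wt"]
        train = AbundanceMatrix(
            values=mn.values[:, cols], protein_ids=list(mn.protein_ids),
            sample_ids=[mn.sample_ids[i] for i in cols],
            group_labels=[mn.group_labels[i] for i in cols],
            original_zero=mn.original_zero[:, cols])
        rep = mq.rf_stage_classify(train, mn.subset_group("5wk_mut"),
                                   n_trees=1000, seed=1)
        assert (rep.probabilities["4wk_wt"] > 0.5).all()
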