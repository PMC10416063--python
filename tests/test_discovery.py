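import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from phosmod.discovery import (ClusteringCandidate, ModuleDiscovery,
                               adjusted_rand_index, calculate_module_scores,
                               drop_incoherent_modules, impute_missing,
                               export_module_tables, mean_pairwise_ari,
                               pairwise_correlation, run_clustering_sweep,
                               select_consensus_labels)


def series(values, keys=None):
    keys = keys or [f"k{i}" for i in range(len(values))]
    return pd.Series(values, index=keys)


def block_correlation_fixture(block_sizes=(6, 5, 4), seed=0):
    """Sites drawn from independent latent factors: block-diagonal corr."""
    rng = np.random.default_rng(seed)
    rows, keys = [], []
    for b, size in enumerate(block_sizes):
        latent = rng.normal(size=40)
        for i in range(size):
            rows.append(latent + rng.normal(0, 0.1, size=40))
            keys.append(f"b{b}_{i}")
    m = pd.DataFrame(rows, index=keys)
    return pairwise_correlation(m), keys, block_sizes


class TestPairwiseCorrelation:
    def test_identical_rows_correlate_to_one(self):
        m = pd.DataFrame([[1, 2, 3, 4, 5.0]] * 2, index=["a", "b"])
        corr = pairwise_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_row_correlates_to_minus_one(self):
        m = pd.DataFrame([[1, 2, 3, 4, 5.0], [-1, -2, -3, -4, -5.0]],
                         index=["a", "b"])
        assert pairwise_correlation(m).loc["a", "b"] == pytest.approx(-1.0)

    def test_low_overlap_pairs_zeroed(self):
        a = [1.0, 2, 3, np.nan, np.nan, np.nan]
        b = [2.0, 4, 6.5, np.nan, np.nan, np.nan]
        c = [1.0, 5, 2, 4, 3, 6]
        m = pd.DataFrame([a, b, c], index=["a", "b", "c"])
        corr = pairwise_correlation(m, min_overlap=5)
        assert corr.loc["a", "b"] == 0.0  # only 3 shared samples
        assert corr.loc["a", "a"] == 1.0

    def test_zero_variance_site_warns_and_zeroes(self):
        m = pd.DataFrame([[1.0, 1, 1, 1, 1], [1.0, 2, 3, 4, 5]],
                         index=["flat", "var"])
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pairwise_correlation(m)
        assert corr.loc["flat", "var"] == 0.0
        assert corr.loc["flat", "flat"] == 1.0


class TestAdjustedRandIndex:
    def test_label_permutation_gives_one(self):
        a = series([0, 0, 1, 1])
        b = series([1, 1, 0, 0])
        assert adjusted_rand_index(a, b) == pytest.approx(1.0)

    def test_identical_gives_one(self):
        a = series([0, 1, 2, 2, 1])
        assert adjusted_rand_index(a, a.copy()) == pytest.approx(1.0)

    def test_crossed_partition_worked_example(self):
        # contingency table all ones: (0 - 2/3) / (2 - 2/3) = -0.5
        a = series([0, 0, 1, 1])
        b = series([0, 1, 0, 1])
        assert adjusted_rand_index(a, b) == pytest.approx(-0.5)

    def test_matches_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 50)
            a = series(rng.integers(0, 5, n))
            b = series(rng.integers(0, 5, n))
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )

    def test_noise_sites_become_singletons(self):
        # one partition discards everything: far from credit for agreement
        a = series([-1, -1, -1, -1])
        b = series([0, 0, 1, 1])
        assert adjusted_rand_index(a, b) < 0.5

    def test_domain_mismatch_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            adjusted_rand_index(series([0, 1]), series([0, 1], ["x", "y"]))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        a = series(rng.integers(-1, 4, n))
        b = series(rng.integers(-1, 4, n))
        assert adjusted_rand_index(a, b) == pytest.approx(
            adjusted_rand_index(b, a)
        )
        relabeled = a.map({-1: -1, 0: 7, 1: 3, 2: 9, 3: 0})
        assert adjusted_rand_index(relabeled, b) == pytest.approx(
            adjusted_rand_index(a, b)
        )


class TestSweepAndConsensus:
    def test_density_sweep_recovers_planted_blocks(self):
        corr, keys, sizes = block_correlation_fixture()
        cands = run_clustering_sweep(
            corr, [("hdbscan", {"min_cluster_size": 4})]
        )
        assert len(cands) == 1
        assert cands[0].n_modules == 3

    def test_min_cluster_size_above_largest_block_yields_all_noise(self):
        corr, keys, sizes = block_correlation_fixture()
        cands = run_clustering_sweep(
            corr, [("hdbscan", {"min_cluster_size": max(sizes) + 1})]
        )
        assert cands[0].n_labeled == 0

    def test_duplicate_grid_entries_are_deterministic(self):
        corr, _, _ = block_correlation_fixture()
        entry = ("kmeans", {"n_clusters": 3})
        c1, c2 = run_clustering_sweep(corr, [entry, entry])
        pd.testing.assert_series_equal(c1.labels, c2.labels)

    def test_failing_grid_entry_skipped(self):
        corr, _, _ = block_correlation_fixture()
        cands = run_clustering_sweep(
            corr, [("kmeans", {"n_clusters": -2}),
                   ("kmeans", {"n_clusters": 3})]
        )
        assert len(cands) == 1

    def cand(self, labels, name="x"):
        return ClusteringCandidate(name, {}, series(labels))

    def test_identical_pair_beats_random_candidate(self):
        rng = np.random.default_rng(0)
        good = [0] * 10 + [1] * 10
        cands = [self.cand(good, "a"), self.cand(good, "b"),
                 self.cand(list(rng.integers(0, 5, 20)), "noise")]
        chosen = select_consensus_labels(cands)
        assert chosen.algorithm in ("a", "b")

    def test_mean_ari_tie_broken_by_n_labeled(self):
        a = self.cand([0, 0, 1, 1, -1, -1], "few")
        b = self.cand([0, 0, 1, 1, 2, 2], "many")
        # symmetric two-candidate mean ARI is equal for both
        chosen = select_consensus_labels([a, b])
        assert chosen.algorithm == "many"

    def test_single_candidate_returned_with_warning(self):
        a = self.cand([0, 0, 1, 1], "only")
        with pytest.warns(UserWarning, match="single candidate"):
            assert select_consensus_labels([a]) is a

    def test_selection_invariant_to_candidate_order(self):
        rng = np.random.default_rng(3)
        good = [0] * 8 + [1] * 8
        cands = [self.cand(good, "a"), self.cand(good, "b"),
                 self.cand(list(rng.integers(0, 4, 16)), "noise")]
        first = select_consensus_labels(cands)
        second = select_consensus_labels(cands[::-1])
        pd.testing.assert_series_equal(first.labels, second.labels)


class TestModuleScores:
    def test_mean_of_members_per_sample(self):
        m = pd.DataFrame([[1.0, 3.0], [3.0, 5.0]], index=["a", "b"],
                         columns=["s1", "s2"])
        scores = calculate_module_scores(m, series([0, 0], ["a", "b"]))
        np.testing.assert_allclose(scores.loc[0], [2.0, 4.0])

    def test_single_member_module_equals_its_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["a"])
        scores = calculate_module_scores(m, series([5], ["a"]))
        np.testing.assert_allclose(scores.loc[5], m.loc["a"])

    def test_missing_member_excluded_from_mean(self):
        m = pd.DataFrame([[1.0, np.nan], [3.0, 5.0]], index=["a", "b"])
        scores = calculate_module_scores(m, series([0, 0], ["a", "b"]))
        assert scores.loc[0].tolist() == [2.0, 5.0]

    def test_sample_order_invariance(self, small_cohort):
        m = small_cohort.phospho.iloc[:20]
        labels = series([0] * 10 + [1] * 10, list(m.index))
        base = calculate_module_scores(m, labels)
        shuffled = calculate_module_scores(m[m.columns[::-1]], labels)
        pd.testing.assert_frame_equal(base, shuffled[base.columns])


class TestImputeMissing:
    def test_identical_neighbor_supplies_value(self):
        m = pd.DataFrame([[1.0, 2.0, np.nan], [1.0, 2.0, 3.0]],
                         index=["a", "b"])
        out = impute_missing(m, k=1)
        assert out.loc["a"].iloc[2] == pytest.approx(3.0)

    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4))
        pd.testing.assert_frame_equal(impute_missing(m), m)

    def test_equidistant_neighbors_average(self):
        m = pd.DataFrame([
            [0.0, 1.0, np.nan],
            [0.1, 1.0, 2.0],
            [-0.1, 1.0, 4.0],
        ], index=["target", "n1", "n2"])
        out = impute_missing(m, k=2)
        assert out.loc["target"].iloc[2] == pytest.approx(3.0)

    def test_all_missing_row_is_an_error(self):
        m = pd.DataFrame([[np.nan, np.nan], [1.0, 2.0]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            impute_missing(m)


class TestCuration:
    def test_incoherent_module_demoted(self):
        corr, keys, sizes = block_correlation_fixture()
        labels = series([0] * 6 + [1] * 5 + [2] * 4, keys)
        # artificial incoherent module: mix across blocks
        mixed = series([0, 1, 0, 1, 0, 1] + [2] * 5 + [3] * 4, keys)
        kept = drop_incoherent_modules(labels, corr, 0.25)
        assert set(kept) == {0, 1, 2}
        # build an incoherent group out of anti/un-correlated sites
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(6, 40)),
                         index=[f"r{i}" for i in range(6)])
        c2 = pairwise_correlation(m)
        demoted = drop_incoherent_modules(
            series([0] * 6, list(m.index)), c2, 0.25
        )
        assert set(demoted) == {-1}


class TestExportModuleTables:
    def test_one_table_per_module_in_leaf_order(self, tmp_path, small_cohort):
        m = small_cohort.phospho.iloc[:12].fillna(0.0)
        labels = series([0] * 6 + [1] * 6, list(m.index))
        written = export_module_tables(m, labels, tmp_path)
        assert len(written) == 2
        table = pd.read_csv(written[0], sep="\t", index_col=0)
        block = m.loc[labels.index[labels == 0]]
        order = leaves_list(linkage(pdist(block.to_numpy()), "average"))
        expected = ["_".join(k) for k in block.iloc[order].index]
        assert list(table.index) == expected

    def test_annotations_appended_when_given(self, tmp_path, small_cohort):
        m = small_cohort.phospho.iloc[:4]
        labels = series([0, 0, 1, 1], list(m.index))
        written = export_module_tables(
            m, labels, tmp_path, annotations=small_cohort.annotations
        )
        table = pd.read_csv(written[0], sep="\t", index_col=0)
        assert "subtype" in table.index


def test_module_discovery_estimator_end_to_end(small_cohort, reduced_grid):
    from phosmod.normalize import normalize_phospho_by_protein
    from phosmod.preprocess import filter_rows

    resid, _ = normalize_phospho_by_protein(
        small_cohort.phospho, small_cohort.protein
    )
    filtered = filter_rows(resid)
    disco = ModuleDiscovery(grid=reduced_grid, seed=0).fit(filtered)
    assert disco.labels_.shape[0] == len(filtered)
    assert disco.module_scores_.shape[1] == filtered.shape[1]
    assert set(disco.sweep_report_.columns) >= {
        "algorithm", "n_modules", "n_labeled", "mean_ari"
    }
    truth = small_cohort.truth.site_modules.loc[filtered.index]
    assert adjusted_rand_index(disco.label_series_, truth) >= 0.8
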