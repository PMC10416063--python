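import numpy as np
import pandas as pd
import pytest

from phosmod.discovery import calculate_module_scores
from phosmod.normalize import normalize_phospho_by_protein
from phosmod.regulators import (calculate_regulator_association,
                                collect_possible_regulators,
                                correlate_activation_loops, filter_druggable,
                                sigmoid_transform)


def protein_frame(rows):
    return pd.DataFrame(
        {g: np.asarray(v, dtype=float) for g, v in rows.items()}
    ).T.rename_axis("gene").set_axis(
        [f"s{i}" for i in range(len(next(iter(rows.values()))))], axis=1
    )


def phospho_frame(rows):
    idx = pd.MultiIndex.from_tuples(list(rows), names=["gene", "site"])
    values = np.asarray(list(rows.values()), dtype=float)
    return pd.DataFrame(values, index=idx,
                        columns=[f"s{i}" for i in range(values.shape[1])])


EMPTY_PHOSPHO = pd.DataFrame(
    np.empty((0, 8)),
    index=pd.MultiIndex.from_arrays([[], []], names=["gene", "site"]),
    columns=[f"s{i}" for i in range(8)],
)


class TestCollect:
    def test_identical_rows_collapse_to_one_feature(self):
        v = np.arange(8, dtype=float)
        protein = protein_frame({"A": v, "B": v})
        feats = collect_possible_regulators(["A", "B"], protein,
                                            EMPTY_PHOSPHO)
        assert len(feats) == 1
        assert feats[0].source == "collapsed"
        np.testing.assert_allclose(feats[0].values, v)

    def test_correlation_chain_merges_via_connected_components(self):
        rng = np.random.default_rng(0)
        a = np.linspace(0, 10, 50)
        b = a + rng.normal(0, 0.12, 50)
        c = b + rng.normal(0, 0.12, 50)
        protein = protein_frame({"A": a, "B": b, "C": c})
        corr = protein.T.corr()
        # fixture sanity: A-B and B-C above threshold, A-C possibly below
        assert corr.loc["A", "B"] > 0.95 and corr.loc["B", "C"] > 0.95
        feats = collect_possible_regulators(["A", "B", "C"], protein,
                                            EMPTY_PHOSPHO)
        assert len(feats) == 1
        assert set(feats[0].genes) == {"A", "B", "C"}

    def test_threshold_above_one_disables_collapsing(self):
        v = np.arange(8, dtype=float)
        protein = protein_frame({"A": v, "B": v, "C": -v})
        feats = collect_possible_regulators(
            ["A", "B", "C"], protein, EMPTY_PHOSPHO, corr_threshold=1.5
        )
        assert len(feats) == 3

    def test_anticorrelated_features_never_merge(self):
        v = np.arange(8, dtype=float)
        protein = protein_frame({"A": v, "B": -v})
        feats = collect_possible_regulators(["A", "B"], protein,
                                            EMPTY_PHOSPHO)
        assert len(feats) == 2

    def test_gathers_raw_phospho_rows_and_imputes(self):
        v = np.arange(8, dtype=float)
        w = v[::-1].copy()
        w[3] = np.nan
        protein = protein_frame({"A": v})
        phospho = phospho_frame({("A", "S5"): w, ("ZZ", "S1"): v})
        feats = collect_possible_regulators(["A"], protein, phospho)
        ids = {f.feature_id for f in feats}
        assert ids == {"A-protein", "A-S5-phospho"}
        for f in feats:
            assert not f.values.isna().any()

    def test_absent_gene_warns_and_skips(self):
        protein = protein_frame({"A": np.arange(8, dtype=float)})
        with pytest.warns(UserWarning, match="GHOST"):
            feats = collect_possible_regulators(["A", "GHOST"], protein,
                                                EMPTY_PHOSPHO)
        assert len(feats) == 1


class TestSigmoid:
    def scores(self, rows):
        return pd.DataFrame(np.asarray(rows, dtype=float),
                            index=range(len(rows)),
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_rank_preserving_per_module(self):
        rng = np.random.default_rng(2)
        scores = self.scores([rng.normal(size=20)])
        out = sigmoid_transform(scores)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(scores.iloc[0], out.iloc[0])
        assert rho == pytest.approx(1.0)

    def test_symmetric_inputs_map_symmetrically_around_half(self):
        scores = self.scores([[-2, -1, 0, 1, 2]])
        out = sigmoid_transform(scores).iloc[0].to_numpy()
        assert out[2] == pytest.approx(0.5)
        np.testing.assert_allclose(out + out[::-1], 1.0)

    def test_zero_variance_module_becomes_half_with_warning(self):
        scores = self.scores([[1, 1, 1, 1]])
        with pytest.warns(UserWarning, match="zero variance"):
            out = sigmoid_transform(scores)
        np.testing.assert_allclose(out.iloc[0], 0.5)


class TestAssociation:
    def setup_features(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        driver = rng.normal(size=n)
        protein = protein_frame({
            "REG": driver + rng.normal(0, 0.2, n),
            "DEC1": rng.normal(size=n),
            "DEC2": rng.normal(size=n),
        })
        feats = collect_possible_regulators(["REG", "DEC1", "DEC2"],
                                            protein, EMPTY_PHOSPHO)
        scores = pd.DataFrame([driver], index=pd.Index([0], name="module"),
                              columns=protein.columns)
        return feats, scores

    def test_identical_feature_scores_give_coefficient_one(self):
        feats, scores = self.setup_features()
        scores.iloc[0] = feats[0].values
        out = calculate_regulator_association(feats, scores)
        row = out[out["feature"] == feats[0].feature_id].iloc[0]
        assert row["statistic"] == pytest.approx(1.0)

    def test_true_driver_tops_both_modes(self):
        feats, scores = self.setup_features()
        for mode in ("correlation", "linear_model"):
            out = calculate_regulator_association(feats, scores, mode=mode)
            best = out.loc[out["statistic"].abs().idxmax()]
            assert best["feature"].startswith("REG")

    def test_sigmoid_leaves_spearman_results_unchanged(self):
        feats, scores = self.setup_features(seed=5)
        plain = calculate_regulator_association(feats, scores, sigmoid=False)
        curved = calculate_regulator_association(feats, scores, sigmoid=True)
        pd.testing.assert_frame_equal(plain, curved)

    def test_permuted_null_is_calibrated(self):
        """Features independent of scores: p roughly uniform, coefficients
        centered on zero."""
        rng = np.random.default_rng(7)
        n = 40
        stats, ps = [], []
        for _ in range(100):
            protein = protein_frame({"X": rng.normal(size=n)})
            feats = collect_possible_regulators(["X"], protein,
                                                EMPTY_PHOSPHO)
            scores = pd.DataFrame([rng.normal(size=n)],
                                  index=pd.Index([0], name="module"),
                                  columns=protein.columns)
            out = calculate_regulator_association(feats, scores)
            stats.append(out["statistic"].iloc[0])
            ps.append(out["p"].iloc[0])
        assert abs(np.mean(stats)) < 0.1
        # uniform p-values: mean near 0.5, not piled near 0
        assert 0.35 < np.mean(ps) < 0.65
        assert np.mean(np.array(ps) < 0.05) < 0.15

    def test_linear_model_mode_reports_no_p(self):
        feats, scores = self.setup_features()
        out = calculate_regulator_association(feats, scores,
                                              mode="linear_model")
        assert out["p"].isna().all()


class TestActivationLoops:
    def test_loop_identical_to_scores_correlates_perfectly(self):
        v = np.linspace(-1, 1, 12)
        phospho = phospho_frame({("KIN", "T200"): v})
        scores = pd.DataFrame([v, -v], index=pd.Index([0, 1], name="module"),
                              columns=phospho.columns)
        out = correlate_activation_loops(scores, [("KIN", "T200")], phospho)
        by_mod = out.set_index("module")
        assert by_mod.loc[0, "statistic"] == pytest.approx(1.0)
        assert by_mod.loc[1, "statistic"] == pytest.approx(-1.0)

    def test_absent_sites_reported_and_empty_list_warns(self):
        phospho = phospho_frame({("KIN", "T200"): np.arange(6, dtype=float)})
        scores = pd.DataFrame([np.arange(6, dtype=float)],
                              index=pd.Index([0], name="module"),
                              columns=phospho.columns)
        with pytest.warns(UserWarning, match="no activation-loop"):
            out = correlate_activation_loops(scores, [("GHOST", "S1")],
                                             phospho)
        assert (out["status"] == "absent").all()


class TestDruggabilityFilter:
    def associations(self):
        return pd.DataFrame({
            "module": [0, 0], "feature": ["A-protein", "B-protein|C-protein"],
            "mode": ["correlation"] * 2, "statistic": [0.9, 0.8],
            "p": [0.01, 0.02], "adj_p": [0.02, 0.02],
        })

    def features(self):
        from phosmod.regulators import RegulatorFeature

        mk = lambda fid, genes: RegulatorFeature(
            fid, "protein", (fid,), tuple(genes),
            pd.Series(np.zeros(3), index=["s0", "s1", "s2"]),
        )
        return [mk("A-protein", ["A"]), mk("B-protein|C-protein", ["B", "C"])]

    def test_all_flagged_is_identity_none_flagged_is_empty(self):
        assoc, feats = self.associations(), self.features()
        drug = pd.DataFrame({"gene": ["A", "B", "C"],
                             "druggable": ["yes"] * 3})
        assert len(filter_druggable(assoc, feats, drug)) == 2
        none = pd.DataFrame({"gene": ["Z"], "druggable": ["yes"]})
        assert filter_druggable(assoc, feats, none).empty

    def test_collapsed_feature_kept_if_any_member_druggable(self):
        assoc, feats = self.associations(), self.features()
        drug = pd.DataFrame({"gene": ["C"], "druggable": ["kinase"]})
        out = filter_druggable(assoc, feats, drug)
        assert list(out["feature"]) == ["B-protein|C-protein"]
        assert out["druggable"].iloc[0] == "kinase"


def test_collapsing_preserves_samples_and_shrinks_features(small_cohort):
    feats = collect_possible_regulators(
        small_cohort.regulator_candidates, small_cohort.protein,
        small_cohort.phospho,
    )
    n_rows = (small_cohort.protein.index.isin(
        small_cohort.regulator_candidates).sum()
        + small_cohort.phospho.index.get_level_values(0).isin(
            small_cohort.regulator_candidates).sum())
    assert 0 < len(feats) <= n_rows
    for f in feats:
        assert len(f.values) == small_cohort.phospho.shape[1]
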