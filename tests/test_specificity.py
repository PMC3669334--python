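"""Tissue means, the two ratio specificity scores, and ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuespec import (
    TissueSampleMap,
    ValidationError,
    compute_tissue_means,
    rank_by_specificity,
    score_specificity,
)
from tissuespec.fixtures import reference_mean_matrix
from conftest import make_dataset, random_mean_matrix


def naive_scores(means: pd.DataFrame, target: str):
    """Direct transcription of the two score definitions, used as oracle:
    score_i = mean over non-target tissues of (tissue mean / target mean);
    score_v = target mean / mean of non-target tissue means."""
    others = [c for c in means.columns if c != target]
    score_i, score_v = {}, {}
    for fid, row in means.iterrows():
        ratios = [row[t] / row[target] for t in others]
        score_i[fid] = sum(ratios) / len(ratios)
        score_v[fid] = row[target] / (sum(row[t] for t in others) / len(others))
    return score_i, score_v


class TestComputeTissueMeans:
    def test_simple_average(self, tiny_dataset, tiny_map):
        mm = compute_tissue_means(tiny_dataset, tiny_map)
        assert mm.means.loc["probe0", "kidney"] == 15.0  # (10+20)/2
        assert mm.means.loc["probe1", "liver"] == 200.0

    def test_missing_replicate_skipped(self, tiny_dataset, tiny_map):
        # probe2 kidney: [5, NaN] -> mean 5, n=1
        mm = compute_tissue_means(tiny_dataset, tiny_map)
        assert mm.means.loc["probe2", "kidney"] == 5.0
        assert mm.n_replicates.loc["probe2", "kidney"] == 1
        assert mm.n_replicates.loc["probe0", "kidney"] == 2

    def test_all_missing_yields_undefined_mean(self):
        ds = make_dataset({"GSM1": [np.nan], "GSM2": [np.nan], "GSM3": [1.0]},
                          symbols=["G"])
        mm = compute_tissue_means(ds, TissueSampleMap(
            {"kidney": ["GSM1", "GSM2"], "liver": ["GSM3"]}))
        assert np.isnan(mm.means.loc["probe0", "kidney"])
        assert mm.n_replicates.loc["probe0", "kidney"] == 0

    def test_human_kidney_fxyd2_reconstructed_replicates(self):
        """Two replicate intensities averaging to the published human kidney
        FXYD2 value (mean 11852250, SEM 272891 with n=2 => values differ by
        2*SEM*sqrt(2)/sqrt(2) = 545782)."""
        ds = make_dataset({"GSM18955": [12125141.0], "GSM18956": [11579359.0]},
                          symbols=["FXYD2"])
        mm = compute_tissue_means(ds, TissueSampleMap({"kidney": ["GSM18955", "GSM18956"]}))
        assert mm.means.loc["probe0", "kidney"] == 11852250.0

    def test_replicate_permutation_invariance(self, tiny_dataset, tiny_map):
        flipped = TissueSampleMap({"kidney": ["GSM2", "GSM1"], "liver": ["GSM4", "GSM3"]})
        a = compute_tissue_means(tiny_dataset, tiny_map)
        b = compute_tissue_means(tiny_dataset, flipped)
        pd.testing.assert_frame_equal(a.means, b.means)


class TestScoreSpecificity:
    def test_equal_means_score_one(self):
        rng = np.random.default_rng(0)
        mm = random_mean_matrix(rng, n_features=5)
        mm.means.loc[:, :] = 7.0
        res = score_specificity(mm, "t1")
        assert np.allclose(res["score_i"], 1.0)
        assert np.allclose(res["score_v"], 1.0)

    def test_mouse_fxyd2_worked_example(self):
        """Published mouse kidney FXYD2 row: kidney 9786 vs 76/99/113/106/215
        gives score_v = 9786/121.8 = 80.345 and score_i its reciprocal."""
        mm = reference_mean_matrix("mouse", "kidney")
        res = score_specificity(mm, "kidney").set_index("gene_symbol")
        assert res.loc["FXYD2", "score_v"] == pytest.approx(80.344828, rel=1e-6)
        assert res.loc["FXYD2", "score_i"] == pytest.approx(0.0124463, rel=1e-4)
        assert res.loc["FXYD2", "ratio_kidney"] == 1.0
        assert res.loc["FXYD2", "ratio_adipose"] == pytest.approx(215 / 9786)

    def test_mouse_acvr1c_worked_example(self):
        """Published mouse adipose ACVR1C row: 776 vs 58/61/63/60/68 -> 12.516."""
        mm = reference_mean_matrix("mouse", "adipose")
        res = score_specificity(mm, "adipose").set_index("gene_symbol")
        assert res.loc["ACVR1C", "score_v"] == pytest.approx(12.516129, rel=1e-6)

    def test_zero_target_mean_excluded(self):
        rng = np.random.default_rng(1)
        mm = random_mean_matrix(rng, n_features=3)
        mm.means.iloc[0, 0] = 0.0
        res = score_specificity(mm, "t1")
        assert res.loc[0, "excluded_reason"] == "nonpositive target mean"
        assert np.isnan(res.loc[0, "score_i"])

    def test_undefined_means_excluded(self):
        rng = np.random.default_rng(2)
        mm = random_mean_matrix(rng, n_features=3)
        mm.means.iloc[0, 0] = np.nan
        mm.means.iloc[1, 2] = np.nan
        res = score_specificity(mm, "t1")
        assert res.loc[0, "excluded_reason"] == "undefined target mean"
        assert res.loc[1, "excluded_reason"] == "undefined non-target mean"
        assert res.loc[2, "excluded_reason"] == ""

    def test_unknown_target_rejected(self):
        mm = random_mean_matrix(np.random.default_rng(3))
        with pytest.raises(ValidationError, match="unknown target"):
            score_specificity(mm, "brain")

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(42)
        mm = random_mean_matrix(rng, n_features=50)
        res = score_specificity(mm, "t3").set_index("feature_id")
        oi, ov = naive_scores(mm.means, "t3")
        for fid in mm.feature_ids:
            assert res.loc[fid, "score_i"] == pytest.approx(oi[fid], rel=1e-12)
            assert res.loc[fid, "score_v"] == pytest.approx(ov[fid], rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 1000.0))
    def test_reciprocity_and_scale_invariance(self, seed, scale):
        """score_v * score_i = 1, and a global positive rescaling of the
        expression matrix leaves both scores unchanged."""
        rng = np.random.default_rng(seed)
        mm = random_mean_matrix(rng, n_features=20)
        res = score_specificity(mm, "t1")
        assert np.allclose(res["score_i"] * res["score_v"], 1.0, rtol=1e-9)
        mm.means *= scale
        res2 = score_specificity(mm, "t1")
        assert np.allclose(res["score_i"], res2["score_i"], rtol=1e-9)
        assert np.allclose(res["score_v"], res2["score_v"], rtol=1e-9)

    def test_monotone_in_target_mean(self):
        rng = np.random.default_rng(7)
        mm = random_mean_matrix(rng, n_features=10)
        before = score_specificity(mm, "t2")
        mm.means["t2"] *= 3.0
        after = score_specificity(mm, "t2")
        assert (after["score_i"] < before["score_i"]).all()
        assert (after["score_v"] > before["score_v"]).all()


class TestRankBySpecificity:
    def test_basic_order_and_ranks(self):
        rng = np.random.default_rng(5)
        mm = random_mean_matrix(rng, n_features=2)
        mm.means.loc["p0", "t1"] = mm.means.loc["p0"].drop("t1").mean() * 10  # score_i 0.1
        mm.means.loc["p1", "t1"] = mm.means.loc["p1"].drop("t1").mean() * 2   # score_i 0.5
        ranked = rank_by_specificity(score_specificity(mm, "t1"))
        assert ranked["feature_id"].tolist() == ["p0", "p1"]
        assert ranked["rank"].tolist() == [1, 2]

    def test_two_sort_orders_coincide(self):
        """Ascending score_i equals descending score_v, exactly."""
        rng = np.random.default_rng(6)
        mm = random_mean_matrix(rng, n_features=40)
        res = score_specificity(mm, "t4")
        by_i = rank_by_specificity(res)["feature_id"].tolist()
        by_v = res.sort_values(["score_v", "gene_symbol", "feature_id"],
                               ascending=[False, True, True],
                               kind="mergesort")["feature_id"].tolist()
        assert by_i == by_v

    def test_ties_break_by_symbol_then_feature(self):
        mm = random_mean_matrix(np.random.default_rng(8), n_features=3)
        mm.means.loc[:, :] = 5.0  # all scores equal 1
        mm.gene_symbols[:] = ["ZZZ", "AAA", "AAA"]
        ranked = rank_by_specificity(score_specificity(mm, "t1"))
        assert ranked["gene_symbol"].tolist() == ["AAA", "AAA", "ZZZ"]
        assert ranked["feature_id"].tolist() == ["p1", "p2", "p0"]

    def test_gene_level_keeps_best_probe(self):
        mm = random_mean_matrix(np.random.default_rng(9), n_features=4)
        mm.gene_symbols[:] = ["G1", "G1", "G2", ""]
        ranked = rank_by_specificity(score_specificity(mm, "t1"), level="gene")
        assert len(ranked) == 2  # one row per symbol; unannotated dropped
        assert set(ranked["gene_symbol"]) == {"G1", "G2"}

    def test_excluded_after_scored(self):
        mm = random_mean_matrix(np.random.default_rng(10), n_features=4)
        mm.means.iloc[1, 0] = np.nan
        ranked = rank_by_specificity(score_specificity(mm, "t1"))
        assert ranked["excluded_reason"].iloc[-1] != ""
        assert (ranked["excluded_reason"].iloc[:-1] == "").all()
        assert ranked["rank"].tolist() == [1, 2, 3, 4]

    def test_mixed_targets_rejected(self):
        mm = random_mean_matrix(np.random.default_rng(11), n_features=4)
        res = pd.concat([score_specificity(mm, "t1"), score_specificity(mm, "t2")])
        with pytest.raises(ValidationError, match="mixed target"):
            rank_by_specificity(res)

    def test_mouse_kidney_published_order(self):
        """Hand arithmetic over the ten published mouse-kidney rows puts
        FXYD2 (80.34) above SLC34A1 (76.04) at the top."""
        mm = reference_mean_matrix("mouse", "kidney")
        ranked = rank_by_specificity(score_specificity(mm, "kidney"), level="gene")
        assert ranked["gene_symbol"].tolist()[:2] == ["FXYD2", "SLC34A1"]
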