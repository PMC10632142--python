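"""Marker classification, FISH dot counting, and the transcriptomic screen."""

import numpy as np
import pandas as pd
import pytest

from retinads import classify, synth


def _two_blob_table(n=1000, sep_sd=6.0, seed=0):
    return synth.generate_marker_table(
        n,
        {"pRGC10-like": 0.7, "pRGC16-like": 0.3},
        {
            "pRGC10-like": {"bnc2": 100 + 10 * sep_sd, "foxp2": 100.0},
            "pRGC16-like": {"bnc2": 100.0, "foxp2": 100 + 10 * sep_sd},
        },
        {
            "pRGC10-like": {"bnc2": 10.0, "foxp2": 10.0},
            "pRGC16-like": {"bnc2": 10.0, "foxp2": 10.0},
        },
        seed=seed,
    )


class TestZscore:
    def test_two_point_standardization(self):
        df = pd.DataFrame({"ch": [0.0, 2.0], "batch_id": "b"})
        out = classify.zscore_channels(df, ["ch"])
        assert np.allclose(sorted(out["z_ch"]), [-1.0, 1.0])  # population sd

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"ch": rng.normal(size=100), "batch_id": "b"})
        once = classify.zscore_channels(df, ["ch"])
        twice = classify.zscore_channels(
            once.rename(columns={"z_ch": "ch2"})[["ch2", "batch_id"]].rename(
                columns={"ch2": "ch"}
            ),
            ["ch"],
        )
        assert np.allclose(once["z_ch"], twice["z_ch"], atol=1e-12)

    def test_gain_invariance_across_batches(self):
        """Two batches with different gains give identical z-distributions."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        df = pd.DataFrame(
            {
                "ch": np.concatenate([base, 5.0 * base + 30.0]),
                "batch_id": ["a"] * 200 + ["b"] * 200,
            }
        )
        out = classify.zscore_channels(df, ["ch"])
        za = out.loc[out.batch_id == "a", "z_ch"].to_numpy()
        zb = out.loc[out.batch_id == "b", "z_ch"].to_numpy()
        assert np.allclose(za, zb, atol=1e-9)

    def test_zero_variance_names_channel_and_batch(self):
        df = pd.DataFrame({"ch": [1.0, 1.0], "batch_id": "b7"})
        with pytest.raises(ValueError, match="'ch'.*'b7'"):
            classify.zscore_channels(df, ["ch"])


class TestKmeans:
    def test_separated_blobs_recover_truth(self):
        res = classify.kmeans_classify(_two_blob_table(), ["bnc2", "foxp2"], seed=0)
        agree = classify.label_agreement(
            res.table["assigned_label"], res.table["true_label"]
        )
        assert agree >= 0.99
        assert not res.degenerate

    def test_k1_gives_single_label(self):
        res = classify.kmeans_classify(
            _two_blob_table(100), ["bnc2", "foxp2"], k=1, seed=0
        )
        assert res.table["assigned_label"].nunique() == 1

    def test_label_assignment_invariant_to_seed(self):
        """The BNC2-high cluster is always the pRGC10-like label regardless of
        k-means cluster indexing."""
        t = _two_blob_table(400)
        a = classify.kmeans_classify(t, ["bnc2", "foxp2"], seed=0)
        b = classify.kmeans_classify(t, ["bnc2", "foxp2"], seed=12345)
        assert (a.table["assigned_label"] == b.table["assigned_label"]).all()

    def test_single_class_flags_degenerate(self):
        df = synth.generate_marker_table(
            200, {"only": 1.0}, {"only": {"bnc2": 100.0, "foxp2": 100.0}},
            {"only": {"bnc2": 10.0, "foxp2": 10.0}}, seed=1,
        )
        res = classify.kmeans_classify(df, ["bnc2", "foxp2"], seed=0)
        assert res.degenerate

    def test_class_fractions_recovered_within_binomial_error(self):
        n = 1000
        res = classify.kmeans_classify(_two_blob_table(n), ["bnc2", "foxp2"], seed=0)
        frac = (res.table["assigned_label"] == "pRGC10-like").mean()
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / n)

    def test_affine_batch_transform_invariance(self):
        """z-scoring then k-means is invariant to per-batch affine intensity
        transforms (gain/offset drift between imaging days)."""
        t = _two_blob_table(500, seed=3)
        t2 = t.copy()
        t2["bnc2"] = 3.0 * t2["bnc2"] + 17.0
        t2["foxp2"] = 0.5 * t2["foxp2"] - 4.0
        a = classify.kmeans_classify(t, ["bnc2", "foxp2"], seed=0)
        b = classify.kmeans_classify(t2, ["bnc2", "foxp2"], seed=0)
        assert (a.table["assigned_label"] == b.table["assigned_label"]).all()


class TestThreshold:
    def test_threshold_extremes(self):
        t = classify.zscore_channels(_two_blob_table(100), ["bnc2"])
        low = classify.threshold_classify(t, "bnc2", z_threshold=-100.0)
        high = classify.threshold_classify(t, "bnc2", z_threshold=100.0)
        assert (low["assigned_label"] == "positive").all()
        assert (high["assigned_label"] == "negative").all()

    def test_midpoint_threshold_matches_kmeans(self):
        t = _two_blob_table(1000)
        km = classify.kmeans_classify(t, ["bnc2", "foxp2"], seed=0)
        midpoint = float(km.centroids_z[:, 0].mean())  # between the blob centres
        th = classify.threshold_classify(km.table, "bnc2", z_threshold=midpoint)
        km_pos = km.table["assigned_label"] == "pRGC10-like"
        th_pos = th["assigned_label"] == "positive"
        assert (km_pos == th_pos).mean() >= 0.99


class TestDotCounting:
    def test_worked_example(self):
        # (5000 - 1*1000) / 40 = 100 dots
        assert classify.count_dots(5000.0, 1000.0, 1.0, 40.0) == pytest.approx(100.0)

    def test_background_equal_integrated_gives_zero(self):
        assert classify.count_dots(1000.0, 500.0, 2.0, 40.0) == 0.0

    def test_negative_numerator_floored(self):
        assert classify.count_dots(100.0, 500.0, 2.0, 40.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify.count_dots(100.0, 500.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            classify.count_dots(100.0, 0.0, 1.0, 40.0)

    @pytest.mark.parametrize(
        "dots,probe,expected",
        [
            (40.0, "BNC2", False),  # strictly more than 40
            (41.0, "BNC2", True),
            (80.0, "FSTL4", False),
            (80.5, "FSTL4", True),
        ],
    )
    def test_strict_probe_thresholds(self, dots, probe, expected):
        assert classify.call_probe_positive(dots, probe) is expected

    def test_unknown_probe_rejected(self):
        with pytest.raises(ValueError, match="unknown probe"):
            classify.call_probe_positive(10.0, "NOPE")

    def test_table_applies_artifact_exclusion(self):
        cells = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "integrated_intensity": [5000.0, 5000.0],
                "area_px": [1000.0, 1000.0],
                "background_per_px": [1.0, 1.0],
                "single_dot_intensity": [40.0, 40.0],
                "probe": ["BNC2", "BNC2"],
                "artifact": [False, True],
            }
        )
        out = classify.dot_count_table(cells)
        assert out["positive"].tolist() == [True, False]


class TestMarkerScreen:
    def _matrix(self, fold=0.0, n=200, seed=0):
        return synth.generate_expression_matrix(
            30, {"f": n, "p": n}, [("f", "p")],
            fold_changes={("g0000", "p"): fold} if fold else None, seed=seed,
        )

    def test_identical_distributions_not_excluded(self):
        counts, labels = self._matrix()
        res = classify.marker_screen(counts, labels, [("f", "p")], ["g0000", "g0001"])
        assert res.excluded_pairs == []

    def test_three_log_fold_drop_excluded(self):
        counts, labels = self._matrix(fold=-3.0)
        res = classify.marker_screen(counts, labels, [("f", "p")], ["g0000"])
        assert res.excluded_pairs == [("f", "p")]
        assert res.table["log_fold_change"].iloc[0] < -2.0

    def test_underpowered_pair_not_excluded(self):
        """A 3-log drop with n=2 per cluster cannot reach p<0.05 by exact
        rank-sum (minimum two-sided p for 2 vs 2 is 1/3)."""
        counts, labels = self._matrix(fold=-3.0, n=2, seed=1)
        res = classify.marker_screen(counts, labels, [("f", "p")], ["g0000"])
        assert res.excluded_pairs == []
        assert res.table["p_value"].iloc[0] > 0.05

    def test_absent_gene_rejected(self):
        counts, labels = self._matrix()
        with pytest.raises(ValueError, match="absent"):
            classify.marker_screen(counts, labels, [("f", "p")], ["GABRA2"])

    def test_type_one_error_controlled(self):
        """No true fold change: exclusion rate over 200 simulated pairs stays
        near the nominal level (<= 7.5%)."""
        excluded = 0
        for i in range(200):
            counts, labels = synth.generate_expression_matrix(
                10, {"f": 50, "p": 50}, [("f", "p")], seed=2000 + i
            )
            res = classify.marker_screen(
                counts, labels, [("f", "p")], ["g0000", "g0001"]
            )
            excluded += bool(res.excluded_pairs)
        assert excluded / 200 <= 0.075


class TestDotplotStats:
    def test_all_zero_gene(self):
        counts = pd.DataFrame([[0, 0, 0]], index=["g"], columns=["c1", "c2", "c3"])
        labels = pd.Series(["cl"] * 3, index=counts.columns)
        out = classify.dotplot_stats(counts, labels, ["g"])
        assert out["pct_expressing"].iloc[0] == 0.0
        assert np.isnan(out["mean_in_expressing"].iloc[0])

    def test_all_express(self):
        counts = pd.DataFrame([[5, 5, 5]], index=["g"], columns=["c1", "c2", "c3"])
        labels = pd.Series(["cl"] * 3, index=counts.columns)
        out = classify.dotplot_stats(counts, labels, ["g"])
        assert out["pct_expressing"].iloc[0] == 100.0
        assert out["mean_in_expressing"].iloc[0] == 5.0

    def test_half_express(self):
        counts = pd.DataFrame([[4, 0, 4, 0]], index=["g"], columns=list("abcd"))
        labels = pd.Series(["cl"] * 4, index=counts.columns)
        out = classify.dotplot_stats(counts, labels, ["g"])
        assert out["pct_expressing"].iloc[0] == 50.0
        assert out["mean_in_expressing"].iloc[0] == 4.0
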