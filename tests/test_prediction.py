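"""Feature construction, PCA summary, and the direction-of-change forest."""

import numpy as np
import pandas as pd
import pytest

from methylaging.prediction import (
    breadth_of_coverage,
    build_feature_table,
    pca_summary,
    train_evaluate_rf,
)


def _genes(rows):
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    plus = frame["strand"] == "+"
    frame["tss"] = np.where(plus, frame["start"], frame["end"] - 1)
    frame["tes"] = np.where(plus, frame["end"] - 1, frame["start"])
    return frame.set_index("gene_id", drop=False)


class TestBreadth:
    def test_summed_peak_width_over_gene_length(self):
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        peaks = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1_100, 1_500], "end": [1_300, 1_800]}
        )
        assert breadth_of_coverage(genes, peaks)["G1"] == pytest.approx(0.5)

    def test_no_peaks_gives_zero(self):
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        assert breadth_of_coverage(genes, pd.DataFrame(columns=["chrom", "start", "end"]))[
            "G1"
        ] == 0.0

    def test_partial_overlap_clipped_to_gene(self):
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1_250]})
        assert breadth_of_coverage(genes, peaks)["G1"] == pytest.approx(0.25)

    def test_overlapping_peaks_merged_so_breadth_bounded(self):
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        peaks = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [1_000, 1_000], "end": [2_000, 2_000]}
        )
        assert breadth_of_coverage(genes, peaks)["G1"] == pytest.approx(1.0)


class TestFeatureTable:
    def _inputs(self):
        genes = _genes(
            [("G1", "chr1", "+", 0, 1_000), ("G2", "chr1", "+", 5_000, 7_000),
             ("G3", "chr1", "+", 10_000, 12_000)]
        )
        body = pd.DataFrame(
            {"m_young": [0.8, 0.2, 0.5], "m_old": [0.8, 0.25, 0.5]},
            index=["G1", "G2", "G3"],
        )
        prom = body.copy()
        degs = pd.DataFrame(
            {"direction": ["up", "down", "ns"], "log2fc": [1, -1, 0]},
            index=["G1", "G2", "G3"],
        )
        expr = pd.Series([100.0, 50.0, 10.0], index=["G1", "G2", "G3"])
        peaks = {"mark": pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})}
        return body, prom, degs, genes, peaks, expr

    def test_only_labelled_genes_enter(self):
        table = build_feature_table(*self._inputs())
        assert set(table.index) == {"G1", "G2"}
        assert table.loc["G1", "breadth_mark"] == pytest.approx(0.5)
        assert table.loc["G2", "gene_size"] == 2_000

    def test_gene_missing_methylation_dropped(self):
        body, prom, degs, genes, peaks, expr = self._inputs()
        body = body.drop("G2")
        table = build_feature_table(body, prom, degs, genes, peaks, expr)
        assert set(table.index) == {"G1"}
        assert table.attrs["n_dropped_missing"] == 1

    def test_no_labelled_genes_rejected(self):
        body, prom, degs, genes, peaks, expr = self._inputs()
        degs["direction"] = "ns"
        with pytest.raises(ValueError, match="labelled"):
            build_feature_table(body, prom, degs, genes, peaks, expr)


def _toy_table(n=60, seed=0, separation=0.6, extra_noise=0):
    rng = np.random.default_rng(seed)
    label = np.array(["up"] * (n // 2) + ["down"] * (n - n // 2))
    signal = np.where(label == "up", 0.5 + separation / 2, 0.5 - separation / 2)
    table = pd.DataFrame(
        {
            "label": label,
            "meth_body_young": signal + 0.05 * rng.normal(size=n),
            "meth_prom_young": signal + 0.05 * rng.normal(size=n),
            "gene_size": rng.integers(1_000, 5_000, n).astype(float),
        },
        index=[f"g{i}" for i in range(n)],
    )
    for j in range(extra_noise):
        table[f"noise_{j}"] = rng.normal(size=n)
    return table


class TestPCA:
    def test_single_axis_of_variation_dominates(self):
        rng = np.random.default_rng(1)
        axis = rng.normal(size=30)
        table = pd.DataFrame(
            {
                "label": ["up", "down"] * 15,
                "meth_body_young": axis,
                "other": 2.0 * axis + 1.0,  # collinear: one latent axis
            }
        )
        summary = pca_summary(table)
        assert summary.variance_fraction[0] > 0.999
        assert abs(summary.feature_correlations.loc["PC1", "meth_body_young"]) > 0.999

    def test_pc1_sign_follows_gene_body_methylation(self):
        summary = pca_summary(_toy_table())
        assert summary.feature_correlations.loc["PC1", "meth_body_young"] > 0

    def test_two_cluster_table_separates_labels_on_pc1(self):
        table = _toy_table(separation=0.8)
        summary = pca_summary(table)
        up = summary.scores.loc[table["label"] == "up", "PC1"]
        down = summary.scores.loc[table["label"] == "down", "PC1"]
        assert up.min() > down.max()

    def test_duplicate_features_get_equal_correlations(self):
        table = _toy_table()
        table["meth_prom_young"] = table["meth_body_young"]
        summary = pca_summary(table)
        corr = summary.feature_correlations
        assert corr.loc["PC1", "meth_body_young"] == pytest.approx(
            corr.loc["PC1", "meth_prom_young"], abs=1e-12
        )

    def test_constant_feature_dropped_with_warning(self):
        table = _toy_table()
        table["flat"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            summary = pca_summary(table)
        assert "flat" in summary.dropped_features
        assert "flat" not in summary.feature_correlations.columns

    def test_variance_fractions_are_valid(self):
        summary = pca_summary(_toy_table(), n_components=3)
        assert (summary.variance_fraction >= 0).all()
        assert summary.variance_fraction.sum() <= 1.0 + 1e-12


class TestRandomForest:
    def test_separable_feature_gives_perfect_auc(self):
        table = _toy_table(separation=0.6, seed=2)
        report = train_evaluate_rf(table, seed=0, n_trees=100)
        assert report.auc == 1.0

    def test_split_is_stratified_and_partitions_genes(self):
        table = _toy_table(n=40, seed=3)
        report = train_evaluate_rf(table, seed=1, n_trees=50)
        train, val = set(report.train_genes), set(report.validation_genes)
        assert train.isdisjoint(val)
        assert train | val == set(table.index)
        assert len(train) == round(0.7 * len(table))
        val_labels = table.loc[report.validation_genes, "label"]
        assert set(val_labels) == {"up", "down"}

    def test_same_seed_reproduces_report(self):
        table = _toy_table(seed=4)
        a = train_evaluate_rf(table, seed=9, n_trees=60)
        b = train_evaluate_rf(table, seed=9, n_trees=60)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        pd.testing.assert_frame_equal(a.importance, b.importance)

    def test_feature_subset_restricts_model(self):
        table = _toy_table(seed=5)
        report = train_evaluate_rf(
            table, seed=0, n_trees=50, feature_subset=["meth_body_young"]
        )
        assert report.features == ["meth_body_young"]
        with pytest.raises(ValueError, match="unknown features"):
            train_evaluate_rf(table, seed=0, feature_subset=["nope"])

    def test_single_label_rejected(self):
        table = _toy_table()
        table["label"] = "up"
        with pytest.raises(ValueError, match="both up and down"):
            train_evaluate_rf(table)

    def test_noise_features_do_not_collapse_auc(self):
        base = _toy_table(seed=6, separation=0.5)
        noisy = _toy_table(seed=6, separation=0.5, extra_noise=5)
        auc_base = np.mean(
            [train_evaluate_rf(base, seed=s, n_trees=100).auc for s in range(5)]
        )
        auc_noisy = np.mean(
            [train_evaluate_rf(noisy, seed=s, n_trees=100).auc for s in range(5)]
        )
        assert auc_base - auc_noisy <= 0.05
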