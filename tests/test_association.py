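"""Region methylation, methylation-expression association, the resampling
null, and the gene-set screen."""

import warnings

import numpy as np
import pandas as pd
import pytest

import methylaging as ma
from methylaging.association import (
    binned_profiles,
    dmr_expression_correlation,
    geneset_correlation_screen,
    methylation_level_association,
    random_set_null,
    region_methylation,
)


def _sites(rows, samples=("a", "b")):
    data = {"chrom": [], "pos": [], "strand": [], "context": []}
    for s in samples:
        data[f"M_{s}"] = []
        data[f"U_{s}"] = []
    for chrom, pos, context, counts in rows:
        data["chrom"].append(chrom)
        data["pos"].append(pos)
        data["strand"].append("+")
        data["context"].append(context)
        for s in samples:
            m, u = counts.get(s, (0, 0))
            data[f"M_{s}"].append(m)
            data[f"U_{s}"].append(u)
    return pd.DataFrame(data)


def _genes(rows):
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    plus = frame["strand"] == "+"
    frame["tss"] = np.where(plus, frame["start"], frame["end"] - 1)
    frame["tes"] = np.where(plus, frame["end"] - 1, frame["start"])
    return frame.set_index("gene_id", drop=False)


DESIGN = pd.DataFrame({"group": ["g", "g"]}, index=["a", "b"])
GROUPS = {"g": ["a", "b"]}


class TestRegionMethylation:
    def test_pooled_fraction(self):
        sites = _sites(
            [("chr1", 1_100, "CG", {"a": (8, 2)}), ("chr1", 1_200, "CG", {"b": (2, 8)})]
        )
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        summary = region_methylation(sites, DESIGN, genes, region="gene_body", groups=GROUPS)
        assert summary.loc["G1", "m_g"] == pytest.approx(0.5)
        assert summary.loc["G1", "n_sites"] == 2

    def test_pooled_equals_coverage_weighted_site_mean(self):
        rng = np.random.default_rng(0)
        rows = []
        for pos in range(1_000, 2_000, 50):
            rows.append(("chr1", pos, "CG", {"a": tuple(rng.integers(0, 20, 2))}))
        sites = _sites(rows, samples=("a",))
        genes = _genes([("G1", "chr1", "+", 900, 2_100)])
        summary = region_methylation(
            sites, pd.DataFrame({"group": ["g"]}, index=["a"]), genes,
            region="gene_body", groups={"g": ["a"]},
        )
        m = sites["M_a"].to_numpy()
        cov = m + sites["U_a"].to_numpy()
        frac = np.where(cov > 0, m / np.maximum(cov, 1), 0.0)
        weighted = (frac * cov).sum() / cov.sum()
        assert summary.loc["G1", "m_g"] == pytest.approx(weighted, abs=1e-12)

    def test_uncovered_gene_omitted(self):
        sites = _sites([("chr1", 1_100, "CG", {"a": (1, 1)})])
        genes = _genes(
            [("G1", "chr1", "+", 1_000, 2_000), ("G2", "chr1", "+", 5_000, 6_000)]
        )
        summary = region_methylation(sites, DESIGN, genes, region="gene_body", groups=GROUPS)
        assert "G2" not in summary.index

    def test_context_filter(self):
        sites = _sites(
            [("chr1", 1_100, "CG", {"a": (10, 0)}), ("chr1", 1_200, "CH", {"a": (0, 10)})]
        )
        genes = _genes([("G1", "chr1", "+", 1_000, 2_000)])
        cg = region_methylation(sites, DESIGN, genes, context="CG", groups=GROUPS)
        ch = region_methylation(sites, DESIGN, genes, context="CH", groups=GROUPS)
        assert cg.loc["G1", "m_g"] == pytest.approx(1.0)
        assert ch.loc["G1", "m_g"] == pytest.approx(0.0)

    def test_promoter_region_is_strand_aware(self):
        sites = _sites([("chr1", 8_500, "CG", {"a": (4, 0)})])
        genes = _genes([("G1", "chr1", "-", 5_000, 9_000)])  # tss = 8999
        summary = region_methylation(sites, DESIGN, genes, region="promoter", groups=GROUPS)
        assert summary.loc["G1", "m_g"] == pytest.approx(1.0)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            region_methylation(_sites([]), DESIGN, _genes([]), region="exon")

    def test_binned_profiles_are_strand_oriented(self):
        # methylated only near the gene start: on the minus strand the
        # signal must appear at the downstream end of the profile
        rows = [("chr1", p, "CG", {"a": (5, 0)}) for p in range(1_000, 1_200, 20)]
        rows += [("chr1", p, "CG", {"a": (0, 5)}) for p in range(1_800, 2_000, 20)]
        sites = _sites(rows, samples=("a",))
        design = pd.DataFrame({"group": ["g"]}, index=["a"])
        plus = binned_profiles(sites, design, _genes([("G", "chr1", "+", 1_000, 2_000)]),
                               samples=["a"], n_bins=10, flank_bins=2, flank=100)
        minus = binned_profiles(sites, design, _genes([("G", "chr1", "-", 1_000, 2_000)]),
                                samples=["a"], n_bins=10, flank_bins=2, flank=100)
        body_plus = plus.iloc[0, 2:12].to_numpy(dtype=float)
        body_minus = minus.iloc[0, 2:12].to_numpy(dtype=float)
        assert np.nanmean(body_plus[:3]) > np.nanmean(body_plus[-3:])
        assert np.allclose(body_minus, body_plus[::-1], equal_nan=True)


class TestLevelAssociation:
    def _table(self):
        genes = [f"g{i}" for i in range(30)]
        direction = ["up"] * 10 + ["down"] * 10 + ["ns"] * 10
        m = np.concatenate([np.linspace(0.75, 0.85, 10),
                            np.linspace(0.15, 0.25, 10),
                            np.linspace(0.45, 0.55, 10)])
        fc = np.concatenate([np.linspace(1.0, 2.0, 10),
                             np.linspace(-2.0, -1.0, 10),
                             np.linspace(-0.1, 0.1, 10)])
        summary = pd.DataFrame({"m_young": m}, index=genes)
        degs = pd.DataFrame({"direction": direction, "log2fc": fc}, index=genes)
        return summary, degs

    def test_separated_groups_give_positive_r_and_tiny_kw_p(self):
        summary, degs = self._table()
        results = methylation_level_association(summary, degs, "young")
        assert results["DEG"].r > 0.9
        assert results["DEG"].kw_p < 0.001
        assert results["DEG"].trend_grid is not None
        assert len(results["DEG"].pairwise) == 3

    def test_constant_fold_change_flagged(self):
        summary, degs = self._table()
        degs["log2fc"] = 1.0
        results = methylation_level_association(summary, degs, "young")
        assert np.isnan(results["DEG"].r)
        assert results["DEG"].note == "constant_input"

    def test_missing_group_column_rejected(self):
        summary, degs = self._table()
        with pytest.raises(ValueError, match="no methylation column"):
            methylation_level_association(summary, degs, "elderly")


class TestDmrCorrelation:
    def test_perfect_anticorrelation(self):
        genes = _genes([(f"G{i}", "chr1", "+", i * 10_000, i * 10_000 + 2_000)
                        for i in range(1, 4)])
        dmrs = pd.DataFrame(
            {"chrom": "chr1",
             "start": [10_500, 20_500, 30_500],
             "end": [11_000, 21_000, 31_000],
             "delta": [-0.2, 0.0, 0.2]}
        )
        degs = pd.DataFrame(
            {"direction": ["up", "up", "up"], "log2fc": [1.0, 0.0, -1.0]},
            index=["G1", "G2", "G3"],
        )
        results = dmr_expression_correlation(dmrs, degs, genes, region="gene_body")
        assert results["DEG"].r == pytest.approx(-1.0)

    def test_multiple_dmrs_use_mean_delta(self):
        genes = _genes([("G1", "chr1", "+", 10_000, 14_000)])
        dmrs = pd.DataFrame(
            {"chrom": "chr1", "start": [10_500, 12_000], "end": [11_000, 12_500],
             "delta": [0.4, -0.2]}
        )
        degs = pd.DataFrame({"direction": ["up"], "log2fc": [1.0]}, index=["G1"])
        results = dmr_expression_correlation(dmrs, degs, genes, region="gene_body")
        assert results["DEG"].note == "insufficient_pairs"  # < 3 pairs still reported

    def test_enhancer_maps_to_nearest_tss(self):
        genes = _genes([("G1", "chr1", "+", 10_000, 14_000),
                        ("G2", "chr1", "+", 80_000, 84_000)])
        enhancers = pd.DataFrame({"chrom": ["chr1"], "start": [16_000], "end": [17_000]})
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [16_200], "end": [16_700],
                             "delta": [0.3]})
        degs = pd.DataFrame({"direction": ["up", "down"], "log2fc": [1.0, -1.0]},
                            index=["G1", "G2"])
        results = dmr_expression_correlation(
            dmrs, degs, genes, region="enhancer", enhancers=enhancers
        )
        # only G1 receives a delta: not enough pairs for r, but the mapping held
        assert results["DEG"].n == 1

    def test_planted_anticorrelation_recovered_across_seeds(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            params = ma.SimulationParams(
                seed=100 + seed, n_chrom=1, chrom_length=1_200_000, n_genes=300,
                n_cpg=20_000, n_islands=40, n_planted_dmrs=20, n_planted_degs=80,
                coverage_mean=8, dmr_in_deg_fraction=1.0, dmr_deg_coupling=1.0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ann = ma.simulate_annotation(params)
                meth, truth = ma.simulate_methylome(ann, params)
                counts = ma.simulate_expression(ann, truth, params)
            design = meth.design[meth.design["sex"] == "male"]
            dmr_result = ma.call_dmrs(meth.sites, design)
            degs = ma.call_degs(counts).per_sex["male"]
            results = dmr_expression_correlation(
                dmr_result.dmrs, degs, ann.genes, region="gene_body"
            )
            res = results["DEG"]
            if np.isfinite(res.r) and res.r < 0 and res.p < 0.05:
                hits += 1
        assert hits >= n_seeds - 1


class TestResamplingNull:
    def _data(self, n=600, seed=0, rho=0.0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        m = rng.normal(0.6, 0.15, n)
        fc = rho * (m - m.mean()) / m.std() + np.sqrt(1 - rho**2) * rng.normal(size=n)
        return pd.Series(m, index=genes), pd.Series(fc, index=genes)

    def test_same_seed_reproduces_draws(self):
        m, fc = self._data()
        a = random_set_null(m, fc, set_size=100, n_draws=200, seed=5)
        b = random_set_null(m, fc, set_size=100, n_draws=200, seed=5)
        assert np.array_equal(a.draws, b.draws)

    def test_null_mean_tracks_pool_correlation(self):
        # resampled sets inherit the pool-level association: under
        # independence the null mean matches the (near-zero) pool r
        m, fc = self._data(seed=1)
        pool_r = np.corrcoef(m, fc)[0, 1]
        null = random_set_null(m, fc, set_size=100, n_draws=1_000, seed=2)
        assert null.draws.mean() == pytest.approx(pool_r, abs=0.02)
        assert abs(null.draws.mean()) < 0.1

    def test_extreme_observed_r_has_extreme_percentile(self):
        m, fc = self._data(seed=2)
        null = random_set_null(m, fc, set_size=100, n_draws=200, seed=3, observed_r=0.99)
        assert null.percentile == 1.0
        null = random_set_null(m, fc, set_size=100, n_draws=200, seed=3, observed_r=-0.99)
        assert null.percentile == 0.0

    def test_oversized_set_rejected(self):
        m, fc = self._data(n=50)
        with pytest.raises(ValueError, match="set_size"):
            random_set_null(m, fc, set_size=100, n_draws=10, seed=0)


class TestGeneSetScreen:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(2_000)]
        m = pd.Series(rng.normal(0.6, 0.15, len(genes)), index=genes)
        fc = pd.Series(rng.normal(size=len(genes)), index=genes)
        planted = genes[:80]
        z = (m[planted] - m[planted].mean()) / m[planted].std()
        fc[planted] = 0.6 * z + 0.8 * rng.normal(size=len(planted))
        return m, fc, planted

    def test_small_sets_excluded(self):
        m, fc, _ = self._data()
        gmt = {"tiny": list(m.index[:49]), "ok": list(m.index[:50])}
        screen = geneset_correlation_screen(m, fc, gmt, min_size=50)
        assert screen["set"].tolist() == ["ok"]

    def test_planted_set_flagged_null_set_not(self):
        m, fc, planted = self._data(seed=3)
        gmt = {"planted": planted, "null": list(m.index[1_000:1_080])}
        screen = geneset_correlation_screen(m, fc, gmt, min_size=50, r_cutoff=0.4)
        flags = screen.set_index("set")["met_cutoff"]
        assert flags["planted"] and not flags["null"]

    def test_cutoff_boundary_is_inclusive_only_at_threshold(self):
        m = pd.Series(np.linspace(0, 1, 60), index=[f"g{i}" for i in range(60)])
        rng = np.random.default_rng(0)
        # craft fold changes with r just below 0.4
        fc = pd.Series(0.39 * (m - m.mean()) / m.std() + rng.normal(size=60), index=m.index)
        screen = geneset_correlation_screen(m, fc, {"s": list(m.index)}, min_size=50)
        r = screen.loc[0, "r"]
        assert screen.loc[0, "met_cutoff"] == (r >= 0.4)

    def test_absolute_mode_flags_negative_correlations(self):
        m = pd.Series(np.linspace(0, 1, 60), index=[f"g{i}" for i in range(60)])
        fc = pd.Series(-m.to_numpy(), index=m.index)
        signed = geneset_correlation_screen(m, fc, {"s": list(m.index)}, min_size=50)
        absolute = geneset_correlation_screen(m, fc, {"s": list(m.index)}, min_size=50,
                                              absolute=True)
        assert not signed.loc[0, "met_cutoff"]
        assert absolute.loc[0, "met_cutoff"]
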