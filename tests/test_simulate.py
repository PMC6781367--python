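"""Properties of the synthetic-study generator."""

import io as stdio
import warnings

import numpy as np
import pandas as pd
import pytest

import methylaging as ma
from methylaging import io as mio
from methylaging.simulate import simulate_annotation, simulate_expression, simulate_methylome

TINY = dict(
    n_chrom=1, chrom_length=400_000, n_genes=100, n_cpg=6_000, n_islands=15,
    n_planted_dmrs=6, n_planted_degs=30, coverage_mean=8,
)


def _params(seed=0, **overrides):
    return ma.SimulationParams(seed=seed, **{**TINY, **overrides})


def _global_cg_mean(sites):
    cg = sites[sites["context"] == "CG"]
    m_cols = [c for c in cg.columns if c.startswith("M_")]
    u_cols = [c for c in cg.columns if c.startswith("U_")]
    m = cg[m_cols].to_numpy().sum()
    return m / (m + cg[u_cols].to_numpy().sum())


def _simulate(params):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        annotation = simulate_annotation(params)
        methylome, truth = simulate_methylome(annotation, params)
    return annotation, methylome, truth


class TestAnnotation:
    def test_seed_determinism(self):
        a = simulate_annotation(_params(seed=4))
        b = simulate_annotation(_params(seed=4))
        pd.testing.assert_frame_equal(a.genes, b.genes)
        pd.testing.assert_frame_equal(a.cpgs, b.cpgs)
        pd.testing.assert_frame_equal(a.islands, b.islands)

    def test_no_genes_leaves_background_cpgs(self):
        ann = simulate_annotation(_params(n_genes=0, n_planted_dmrs=0, n_planted_degs=0))
        assert len(ann.genes) == 0
        assert len(ann.cpgs) > 0

    def test_islands_contain_at_least_ten_cpgs(self):
        ann = simulate_annotation(_params(seed=2))
        pos = {c: g["pos"].to_numpy() for c, g in ann.cpgs.groupby("chrom")}
        for _, island in ann.islands.iterrows():
            p = pos[island["chrom"]]
            inside = ((p >= island["start"]) & (p < island["end"])).sum()
            assert inside >= 10

    def test_genes_do_not_overlap(self):
        ann = simulate_annotation(_params(seed=3))
        for _, chunk in ann.genes.groupby("chrom"):
            chunk = chunk.sort_values("start")
            assert (chunk["start"].to_numpy()[1:] >= chunk["end"].to_numpy()[:-1]).all()

    def test_genome_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_annotation(_params(chrom_length=50_000, n_genes=100))


class TestMethylome:
    def test_same_seed_gives_byte_identical_coverage_files(self):
        frames = []
        for _ in range(2):
            _, meth, _ = _simulate(_params(seed=9))
            buf = stdio.StringIO()
            sample = meth.samples[0]
            frame = meth.sample_frame(sample)
            frame.to_csv(buf, sep="\t", index=False)
            frames.append(buf.getvalue())
        assert frames[0] == frames[1]

    def test_global_mean_converges_to_target(self):
        # law-of-large-numbers check at 50k sites, no planted shift
        params = ma.SimulationParams(
            seed=5, n_chrom=1, chrom_length=2_500_000, n_genes=500, n_cpg=50_000,
            n_islands=75, n_planted_dmrs=0, dmr_delta=0.0, n_planted_degs=100,
        )
        _, meth, _ = _simulate(params)
        assert _global_cg_mean(meth.sites) == pytest.approx(0.74, abs=0.02)

    def test_planted_hyper_dmrs_shift_old_up(self):
        params = _params(seed=6, dmr_delta=0.3)
        ann, meth, truth = _simulate(params)
        young = [f"M_{s}" for s in meth.design.index[meth.design["age"] == "young"]]
        young_u = [f"U_{s}" for s in meth.design.index[meth.design["age"] == "young"]]
        old = [f"M_{s}" for s in meth.design.index[meth.design["age"] == "old"]]
        old_u = [f"U_{s}" for s in meth.design.index[meth.design["age"] == "old"]]
        hyper = truth.dmrs[truth.dmrs["direction"] == "hyper"]
        assert len(hyper) > 0
        for _, dmr in hyper.iterrows():
            sel = meth.sites[
                (meth.sites["chrom"] == dmr["chrom"])
                & (meth.sites["pos"] >= dmr["start"])
                & (meth.sites["pos"] < dmr["end"])
            ]
            m_y = sel[young].to_numpy().sum() / sel[young + young_u].to_numpy().sum()
            m_o = sel[old].to_numpy().sum() / sel[old + old_u].to_numpy().sum()
            assert m_o > m_y

    def test_zero_delta_plants_no_dmrs(self):
        _, _, truth = _simulate(_params(dmr_delta=0.0))
        assert truth.dmrs.empty

    def test_planted_dmrs_are_disjoint_and_degs_exist(self):
        ann, _, truth = _simulate(_params(seed=8))
        truth.validate(ann)  # raises on overlap/unknown ids
        assert len(truth.dmrs) == 6
        assert len(truth.degs) == 30

    def test_outputs_parse_through_io(self, tmp_path):
        ann, meth, _ = _simulate(_params(seed=1, ch_fraction=0.1))
        sample = meth.samples[0]
        path = tmp_path / "s.cx"
        mio.write_methylome(meth.sample_frame(sample), path, dialect="cx")
        back = mio.read_methylome(path)
        assert (back["context"] == "CH").sum() > 0
        bed = tmp_path / "islands.bed"
        mio.write_bed(ann.islands, bed)
        assert len(mio.read_bed(bed)) == len(ann.islands)


class TestExpression:
    def test_direction_follows_promoter_methylation_when_rho_is_one(self):
        params = _params(seed=3, association_strength=1.0)
        ann, meth, truth = _simulate(params)
        prom = truth.gene_meth.loc[truth.degs["gene_id"], "promoter_young"]
        median = prom.median()
        up = truth.degs["direction"] == "up"
        assert (prom[up.to_numpy()] > median).all()
        assert (prom[~up.to_numpy()] <= median).all()

    def test_direction_uninformative_when_rho_is_zero(self):
        rs = []
        for seed in range(20):
            params = _params(seed=seed, association_strength=0.0, n_cpg=3_000, n_islands=5)
            ann, meth, truth = _simulate(params)
            prom = truth.gene_meth.loc[truth.degs["gene_id"], "promoter_young"].to_numpy()
            sign = np.where(truth.degs["direction"] == "up", 1.0, -1.0)
            rs.append(np.corrcoef(prom, sign)[0, 1])
        assert abs(np.mean(rs)) < 0.08

    def test_zero_fold_change_empties_truth(self):
        params = _params(deg_log2fc=0.0)
        ann, meth, truth = _simulate(params)
        counts = simulate_expression(ann, truth, params)
        assert truth.degs.empty
        assert counts.counts.shape == (len(ann.genes), 24)

    def test_counts_deterministic(self):
        params = _params(seed=12)
        ann, meth, truth = _simulate(params)
        c1 = simulate_expression(ann, truth, params)
        c2 = simulate_expression(ann, truth, params)
        pd.testing.assert_frame_equal(c1.counts, c2.counts)


class TestPeaks:
    def test_peaks_disjoint_within_mark_and_deterministic(self):
        params = _params(seed=2)
        ann, meth, truth = _simulate(params)
        peaks1 = ma.simulate_peaks(ann, truth, params)
        peaks2 = ma.simulate_peaks(ann, truth, params)
        for mark, track in peaks1.items():
            pd.testing.assert_frame_equal(track, peaks2[mark])
            for _, chunk in track.groupby("chrom"):
                chunk = chunk.sort_values("start")
                assert (chunk["start"].to_numpy()[1:] >= chunk["end"].to_numpy()[:-1]).all()

    def test_active_mark_breadth_anticorrelates_with_promoter_methylation(self):
        from methylaging.prediction import breadth_of_coverage

        params = _params(seed=7)
        ann, meth, truth = _simulate(params)
        peaks = ma.simulate_peaks(ann, truth, params)
        breadth = breadth_of_coverage(ann.genes, peaks["H3K27ac"])
        prom = truth.gene_meth.loc[breadth.index, "promoter_young"]
        assert np.corrcoef(breadth, prom)[0, 1] < -0.3
        rep = breadth_of_coverage(ann.genes, peaks["H3K9me3"])
        assert np.corrcoef(rep, prom)[0, 1] > 0.3
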