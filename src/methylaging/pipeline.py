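"""End-to-end orchestration: simulate (or load) -> DMRs -> DEGs ->
enrichment -> association -> prediction.

A single global seed deterministically derives a per-stage seed by hashing
the stage name, so identical configs produce byte-identical outputs and
any stage can be re-run in isolation.  Every output file is recorded in a
manifest with a SHA-256 content checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import dmr as dmrmod
from . import enrichment as enrich
from . import expression as expr
from . import io as mio
from . import prediction as pred
from .simulate import SimulatedMethylome, SimulationParams, simulate_all
from .stats import derive_seed

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "methylaging_run"
    simulate: dict | None = None  # SimulationParams overrides; None => load inputs
    inputs: dict | None = None
    dmr: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    prediction: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' block or an 'inputs' block")
        if self.simulate is not None and self.inputs is not None:
            raise ValueError("config cannot have both 'simulate' and 'inputs'")
        if self.inputs is not None:
            required = {"methylomes", "design", "counts", "meta", "genes", "islands"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"inputs block missing: {sorted(missing)}")


_DMR_DEFAULTS = dict(window_size=500, min_cpg=10, min_site_cov=5.0, min_cpg_cov=3, alpha=0.05)
_EXPR_DEFAULTS = dict(alpha=0.05, fc_min=1.25, screen_alpha=0.05, contrast_method="conover")
_ASSOC_DEFAULTS = dict(
    null_draws=2_000, set_size=500, min_set_size=50, r_cutoff=0.4, poly_degree=2,
    n_random_sets=100, enhancer_mark="H3K27ac",
)
_PRED_DEFAULTS = dict(train_frac=0.70, n_trees=500, min_labelled=10)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Writer:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[Path] = []
        self.log_lines: list[str] = []

    def path(self, *parts) -> Path:
        target = self.outdir.joinpath(*parts)
        target.parent.mkdir(parents=True, exist_ok=True)
        self.files.append(target)
        return target

    def frame(self, frame: pd.DataFrame, *parts, index=False, index_label=None):
        frame.to_csv(
            self.path(*parts), sep="\t", index=index, index_label=index_label,
            float_format=FLOAT_FMT,
        )

    def log(self, message: str) -> None:
        self.log_lines.append(message)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage in dependency order; returns the manifest."""
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    w = _Writer(out)
    w.log(f"seed: {config.seed}")

    data = _obtain_data(config, w)
    dmr_results = _stage_dmrs(config, data, w)
    deg_results = _stage_expression(config, data, w)
    _stage_enrichment(config, data, dmr_results, deg_results, w)
    assoc_summaries = _stage_association(config, data, dmr_results, deg_results, w)
    _stage_prediction(config, data, deg_results, assoc_summaries, w)

    log_path = w.path("pipeline.log")
    log_path.write_text("\n".join(w.log_lines) + "\n")
    manifest = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(set(w.files)) if p.exists()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


@dataclass
class _Data:
    methylome: SimulatedMethylome
    counts: object  # CountsMatrix
    genes: pd.DataFrame
    islands: pd.DataFrame
    peaks: dict[str, pd.DataFrame]
    chrom_sizes: dict[str, int]
    gmt: dict[str, list[str]]
    truth: object | None = None


def _obtain_data(config: PipelineConfig, w: _Writer) -> _Data:
    if config.simulate is not None:
        params = SimulationParams(
            **{**config.simulate, "seed": derive_seed(config.seed, "simulate")}
        )
        w.log(f"simulate: {params}")
        study = simulate_all(params)
        meth = study.methylome
        # materialize the simulated inputs in their external formats
        for sample in meth.samples:
            mio.write_methylome(
                meth.sample_frame(sample), w.path("inputs", f"{sample}.cov"), dialect="cov"
            )
        design_out = meth.design.reset_index()
        w.frame(design_out, "inputs", "methylome_design.tsv")
        mio.write_counts(
            study.counts, w.path("inputs", "counts.tsv"), w.path("inputs", "meta.tsv")
        )
        mio.write_gene_models(study.annotation.genes, w.path("inputs", "genes.tsv"))
        mio.write_bed(study.annotation.islands, w.path("inputs", "islands.bed"))
        for mark, track in study.peaks.items():
            mio.write_bed(track, w.path("inputs", "peaks", f"{mark}.bed"))
        w.frame(study.truth.dmrs, "truth", "planted_dmrs.tsv")
        w.frame(study.truth.degs, "truth", "planted_degs.tsv")
        w.frame(study.truth.gene_meth, "truth", "gene_methylation_levels.tsv")
        gmt = _random_gene_sets(
            list(study.annotation.genes.index), derive_seed(config.seed, "gene_sets"),
            n_sets=_assoc_cfg(config)["n_random_sets"],
        )
        mio.write_gmt(gmt, w.path("inputs", "gene_sets.gmt"))
        return _Data(
            meth, study.counts, study.annotation.genes, study.annotation.islands,
            study.peaks, study.annotation.chrom_sizes, gmt, study.truth,
        )

    paths = config.inputs
    frames = {
        sample: mio.read_methylome(path, sample_id=sample)
        for sample, path in paths["methylomes"].items()
    }
    sites = mio.combine_methylomes(frames)
    design = pd.read_csv(paths["design"], sep="\t").set_index("sample")
    meth = SimulatedMethylome(sites, design)
    counts = mio.read_counts(paths["counts"], paths["meta"])
    genes = mio.read_gene_models(paths["genes"])
    islands = mio.read_bed(paths["islands"], class_label="island")
    peaks = {
        mark: mio.read_bed(path, class_label=mark)
        for mark, path in paths.get("peaks", {}).items()
    }
    gmt = mio.read_gmt(paths["gmt"]) if "gmt" in paths else {}
    chrom_sizes = _infer_chrom_sizes(sites, genes, islands, peaks)
    return _Data(meth, counts, genes, islands, peaks, chrom_sizes, gmt)


def _infer_chrom_sizes(sites, genes, islands, peaks) -> dict[str, int]:
    sizes: dict[str, int] = {}

    def bump(chrom, value):
        sizes[chrom] = max(sizes.get(chrom, 0), int(value))

    for chrom, chunk in sites.groupby("chrom"):
        bump(chrom, chunk["pos"].max() + 1)
    for frame in [genes, islands, *peaks.values()]:
        for chrom, chunk in frame.groupby("chrom"):
            bump(chrom, chunk["end"].max())
    return {c: v + 10_000 for c, v in sizes.items()}


def _random_gene_sets(genes: list[str], seed: int, n_sets: int) -> dict[str, list[str]]:
    """A pathway-database stand-in: random gene sets of realistic sizes."""
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(30, 160))
        size = min(size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False))
        sets[f"SET_{i:03d}"] = members
    return sets


def _dmr_cfg(config):
    return {**_DMR_DEFAULTS, **config.dmr}


def _expr_cfg(config):
    return {**_EXPR_DEFAULTS, **config.expression}


def _assoc_cfg(config):
    return {**_ASSOC_DEFAULTS, **config.association}


def _pred_cfg(config):
    return {**_PRED_DEFAULTS, **config.prediction}


def _sex_samples(design: pd.DataFrame, sex: str) -> list[str]:
    return list(design.index[design["sex"] == sex])


def _stage_dmrs(config, data, w) -> dict[str, dmrmod.DMRResult]:
    cfg = _dmr_cfg(config)
    w.log(f"dmr: {cfg}")
    results = {}
    for sex in ("male", "female"):
        samples = _sex_samples(data.methylome.design, sex)
        design = data.methylome.design.loc[samples]
        result = dmrmod.call_dmrs(data.methylome.sites, design, **cfg)
        results[sex] = result
        w.frame(result.windows, "dmr", f"windows_{sex}.tsv")
        mio.write_bed(dmrmod.dmrs_to_bed(result.dmrs), w.path("dmr", f"dmrs_{sex}.bed"),
                      extra_cols=["score"])
        w.log(f"dmr[{sex}]: {len(result.windows)} windows tested, {len(result.dmrs)} DMRs")
    common = dmrmod.common_dmrs(results["male"].dmrs, results["female"].dmrs)
    w.frame(common, "dmr", "common_dmrs.tsv")
    return results


def _stage_expression(config, data, w) -> expr.DEGTables:
    cfg = _expr_cfg(config)
    w.log(f"expression: {cfg}")
    result = expr.call_degs(data.counts, **cfg)
    w.frame(result.size_factors.to_frame().reset_index(names="sample"),
            "expression", "size_factors.tsv")
    for sex, table in result.per_sex.items():
        w.frame(table, "expression", f"degs_{sex}.tsv")
        n = int((table["direction"] != "ns").sum())
        w.log(f"expression[{sex}]: {n} DEGs")
    w.frame(result.overlap.reset_index(names="direction"), "expression", "overlap.tsv")
    w.log(f"expression overlap chi2 p: {result.chi2_p:.6g}")
    return result


def _stage_enrichment(config, data, dmr_results, deg_results, w) -> None:
    classes = enrich.derive_feature_classes(
        data.genes, data.islands, data.chrom_sizes, data.peaks
    )
    for label, intervals in classes.items():
        mio.write_bed(intervals, w.path("enrichment", "classes", f"{label}.bed"))
    for sex, result in dmr_results.items():
        if result.windows.empty:
            continue
        for direction in (None, "hyper", "hypo"):
            tag = direction or "all"
            table = enrich.feature_enrichment(
                result.windows, result.dmrs, classes, direction=direction
            )
            w.frame(table, "enrichment", f"features_{sex}_{tag}.tsv")
        if data.gmt:
            dmr_genes = enrich.genes_with_dmr_in_body(result.dmrs, data.genes)
            table = enrich.geneset_enrichment(dmr_genes, set(data.genes.index), data.gmt)
            w.frame(table, "enrichment", f"gene_sets_{sex}.tsv")


def _region_summaries(data, sex: str) -> dict[str, pd.DataFrame]:
    design = data.methylome.design
    groups = {
        "young": list(design.index[(design["sex"] == sex) & (design["age"] == "young")]),
        "old": list(design.index[(design["sex"] == sex) & (design["age"] == "old")]),
    }
    return {
        region: assoc.region_methylation(
            data.methylome.sites, design, data.genes, region=region, groups=groups
        )
        for region in ("gene_body", "promoter")
    }


def _stage_association(config, data, dmr_results, deg_results, w):
    cfg = _assoc_cfg(config)
    w.log(f"association: {cfg}")
    summaries = {}
    for sex in ("male", "female"):
        summaries[sex] = _region_summaries(data, sex)
        deg_table = deg_results.per_sex[sex]
        rows = []
        for region in ("gene_body", "promoter"):
            summary = summaries[sex][region]
            w.frame(summary.reset_index(names="gene_id"),
                    "association", f"methylation_{region}_{sex}.tsv")
            for group in ("young", "old"):
                results = assoc.methylation_level_association(
                    summary, deg_table, group, poly_degree=cfg["poly_degree"]
                )
                for scope, res in results.items():
                    rows.append((region, group, scope, res.n, res.r, res.p,
                                 res.kw_h, res.kw_p))
        # DMR-delta vs log2FC correlations by class
        dmrs = dmr_results[sex].dmrs
        for region in ("promoter", "gene_body", "enhancer"):
            try:
                enhancers = data.peaks.get(cfg["enhancer_mark"])
                results = assoc.dmr_expression_correlation(
                    dmrs, deg_table, data.genes, region=region, enhancers=enhancers
                )
            except ValueError:
                continue
            for scope, res in results.items():
                rows.append((f"dmr_{region}", "delta", scope, res.n, res.r, res.p,
                             np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["region", "group", "scope", "n", "r", "p", "kw_h", "kw_p"]
        )
        w.frame(table, "association", f"correlations_{sex}.tsv")

        # resampling null against the DEG-set correlation
        body = summaries[sex]["gene_body"]
        meth = body["m_young"]
        fc = deg_table["log2fc"]
        deg_genes = deg_table.index[deg_table["direction"] != "ns"]
        eligible = meth.dropna().index.intersection(fc.dropna().index)
        set_size = min(cfg["set_size"], len(eligible))
        if set_size >= 10:
            obs_idx = deg_genes.intersection(eligible)
            obs_r, _ = assoc.pearson_r(
                meth.loc[obs_idx].to_numpy(), fc.loc[obs_idx].to_numpy()
            ) if len(obs_idx) >= 3 else (np.nan, np.nan)
            null = assoc.random_set_null(
                meth, fc, set_size=set_size, n_draws=cfg["null_draws"],
                seed=derive_seed(config.seed, f"null:{sex}"),
                observed_r=obs_r if np.isfinite(obs_r) else None,
            )
            w.frame(pd.DataFrame({"r": null.draws}), "association", f"null_draws_{sex}.tsv")
            w.log(
                f"association[{sex}]: observed DEG r={null.observed_r:.4f}, "
                f"null mean={null.draws.mean():.4f}, percentile={null.percentile:.4f}"
            )
        if data.gmt:
            screen = assoc.geneset_correlation_screen(
                meth, fc, data.gmt, min_size=cfg["min_set_size"],
                r_cutoff=cfg["r_cutoff"],
            )
            w.frame(screen, "association", f"geneset_screen_{sex}.tsv")
    return summaries


def _stage_prediction(config, data, deg_results, summaries, w) -> None:
    cfg = _pred_cfg(config)
    w.log(f"prediction: {cfg}")
    _, normalized, _ = expr.estimate_size_factors(data.counts)
    for sex in ("male", "female"):
        deg_table = deg_results.per_sex[sex]
        n_labelled = int(deg_table["direction"].isin(["up", "down"]).sum())
        if n_labelled < cfg["min_labelled"]:
            w.log(f"prediction[{sex}]: skipped ({n_labelled} labelled genes)")
            continue
        meta = data.counts.meta
        young = [s for s in meta.index if meta.loc[s, "sex"] == sex and meta.loc[s, "age"] == "young"]
        base_expression = normalized[young].mean(axis=1)
        table = pred.build_feature_table(
            summaries[sex]["gene_body"], summaries[sex]["promoter"],
            deg_table, data.genes, data.peaks, base_expression,
        )
        w.frame(table.reset_index(names="gene_id"), "prediction", f"features_{sex}.tsv")
        pca = pred.pca_summary(table)
        w.frame(pca.scores.reset_index(names="gene_id"), "prediction", f"pca_scores_{sex}.tsv")
        w.frame(pca.feature_correlations.reset_index(names="component"),
                "prediction", f"pca_feature_correlations_{sex}.tsv")
        report = pred.train_evaluate_rf(
            table, train_frac=cfg["train_frac"], n_trees=cfg["n_trees"],
            seed=derive_seed(config.seed, f"rf:{sex}"),
        )
        w.frame(report.importance.reset_index(names="feature"),
                "prediction", f"importance_{sex}.tsv")
        payload = {
            "sex": sex,
            "accuracy": round(report.accuracy, 6),
            "auc": round(report.auc, 6),
            "n_train": len(report.train_genes),
            "n_validation": len(report.validation_genes),
            "pca_variance_fraction": [round(float(v), 6) for v in pca.variance_fraction],
        }
        w.path("prediction", f"report_{sex}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        w.log(f"prediction[{sex}]: accuracy={report.accuracy:.4f} auc={report.auc:.4f}")
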