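"""Seeded synthetic study generator.

Emulates the statistical structure of a paired WGBS + RNA-seq aging study
of both sexes:

* a small genome with non-overlapping genes, CpG islands (dense, lowly
  methylated CpG clusters), dispersed background CpGs, and dense CpG
  clusters reserved for planted differentially methylated regions (DMRs);
* per-sample cytosine counts: site-level methylation drawn from a beta
  distribution centred on the regional mean (overdispersion across sites),
  read coverage Poisson, methylated reads binomial;
* a negative-binomial count matrix with planted differentially expressed
  genes (DEGs) whose direction of change can be coupled, with tunable
  strength ``association_strength``, to the gene's early-life (young)
  promoter/gene-body methylation level;
* histone-mark peak tracks whose breadth over a gene correlates with its
  promoter methylation (negatively for active marks, positively for
  repressive marks);
* a truth table recording every planted effect, used by recovery tests.

Every stage derives its random stream from ``params.seed`` and a fixed
stage tag, so stages are individually reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .stats import derive_seed

METH_GROUPS = ("FY", "FO", "MY", "MO")  # female/male x young/old
_GROUP_META = {
    "FY": ("young", "female"),
    "FO": ("old", "female"),
    "MY": ("young", "male"),
    "MO": ("old", "male"),
}

ACTIVE_MARKS = ("H3K27ac", "H3K4me3")
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")


@dataclass
class SimulationParams:
    """All knobs of the generator.  Defaults describe the emulated study:
    ~74% global CpG methylation, ~5x mean coverage, 3 methylome and 6
    transcriptome replicates per age x sex group, a desk-scale genome of
    2 chromosomes x 5 Mb with 2,000 genes and 100,000 cytosines."""

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 2_000
    n_cpg: int = 100_000
    n_islands: int = 150
    island_cpg_mean: float = 30.0  # mean CpGs per island; every island has >= 10
    island_mean_methylation: float = 0.20
    global_mean_methylation: float = 0.74
    beta_dispersion: float = 0.02
    coverage_mean: float = 5.0
    n_meth_samples_per_group: int = 3
    n_expr_samples_per_group: int = 6
    window_size: int = 500
    n_planted_dmrs: int = 20
    cpgs_per_dmr: int = 25
    dmr_delta: float = 0.3
    hyper_fraction: float = 0.5
    dmr_in_deg_fraction: float = 0.5  # fraction of planted DMRs placed in DEG gene bodies
    dmr_deg_coupling: float = 0.7  # P(in-gene DMR delta opposes the host gene's direction)
    n_planted_degs: int = 200
    deg_log2fc: float = 1.0
    association_strength: float = 0.8  # rho: P(direction follows young promoter methylation)
    nb_dispersion: float = 0.05
    ch_fraction: float = 0.0
    ch_mean_methylation: float = 0.05

    def validate(self) -> None:
        positives = [
            "n_chrom", "chrom_length", "n_cpg", "window_size",
            "n_meth_samples_per_group", "n_expr_samples_per_group", "cpgs_per_dmr",
        ]
        for name in positives:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_genes", "n_islands", "n_planted_dmrs", "n_planted_degs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = [
            "island_mean_methylation", "global_mean_methylation", "hyper_fraction",
            "dmr_in_deg_fraction", "dmr_deg_coupling", "association_strength",
            "ch_fraction", "ch_mean_methylation",
        ]
        for name in probs:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if not 0.0 < self.beta_dispersion < 1.0:
            raise ValueError("beta_dispersion must lie in (0, 1)")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if abs(self.dmr_delta) > 1.0:
            raise ValueError("dmr_delta must lie in [-1, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_planted_degs > self.n_genes:
            raise ValueError("n_planted_degs cannot exceed n_genes")

    def replace(self, **overrides) -> "SimulationParams":
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        values.update(overrides)
        return SimulationParams(**values)


@dataclass
class Annotation:
    """Simulated gene models, cytosine positions, islands, and the dense
    candidate windows reserved for DMR planting."""

    genes: pd.DataFrame  # gene_id-indexed: chrom, strand, start, end, tss, tes
    cpgs: pd.DataFrame  # chrom, pos, strand, context
    islands: pd.DataFrame  # chrom, start, end, name
    dmr_candidates: pd.DataFrame  # chrom, start, end, host_gene
    chrom_sizes: dict[str, int]


@dataclass
class TruthTable:
    """Planted effects: the oracle for recovery tests."""

    dmrs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start", "end", "direction", "delta", "host_gene"]
        )
    )
    degs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "direction", "log2fc"])
    )
    gene_meth: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "promoter_young", "body_young"]
        )
    )

    def validate(self, annotation: Annotation) -> None:
        dmrs = self.dmrs.sort_values(["chrom", "start"])
        for _, group in dmrs.groupby("chrom"):
            if (group["start"].to_numpy()[1:] < group["end"].to_numpy()[:-1]).any():
                raise ValueError("planted DMRs overlap")
        unknown = set(self.degs["gene_id"]) - set(annotation.genes.index)
        if unknown:
            raise ValueError(f"planted DEGs not in gene set: {sorted(unknown)[:5]}")


@dataclass
class SimulatedMethylome:
    """Site-by-sample count table plus the sample design."""

    sites: pd.DataFrame  # chrom, pos, strand, context, M_<sample>, U_<sample>
    design: pd.DataFrame  # sample-indexed: group, age, sex

    @property
    def samples(self) -> list[str]:
        return list(self.design.index)

    def sample_frame(self, sample: str) -> pd.DataFrame:
        """One sample's methylome in the per-sample long layout."""
        frame = self.sites[["chrom", "pos", "strand", "context"]].copy()
        frame["m_count"] = self.sites[f"M_{sample}"]
        frame["u_count"] = self.sites[f"U_{sample}"]
        return frame


def _rng(params: SimulationParams, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(params.seed, f"simulate:{stage}"))


def simulate_annotation(params: SimulationParams) -> Annotation:
    """Place non-overlapping genes, islands, background CpGs, and the dense
    clusters reserved for planted DMRs.  Deterministic given the seed."""
    params.validate()
    rng = _rng(params, "annotation")
    chroms = [f"chr{i + 1}" for i in range(params.n_chrom)]
    chrom_sizes = {c: params.chrom_length for c in chroms}

    genes = _place_genes(params, rng, chroms)

    # Dense candidate windows for planted DMRs: a fraction sit inside gene
    # bodies (their hosts will be planted as DEGs), the rest are intergenic.
    candidates = _place_dmr_candidates(params, rng, genes, chroms)

    island_rows = []
    cpg_chunks = []
    n_island_cpgs = 0
    if params.n_islands > 0:
        tss_pool = genes.sample(
            n=min(params.n_islands // 2, len(genes)), random_state=int(rng.integers(2**31))
        ) if len(genes) else genes
        anchors = []
        for _, gene in tss_pool.iterrows():
            anchors.append((gene["chrom"], int(gene["tss"])))
        while len(anchors) < params.n_islands:
            chrom = chroms[int(rng.integers(len(chroms)))]
            anchors.append((chrom, int(rng.integers(5_000, params.chrom_length - 5_000))))
        for idx, (chrom, center) in enumerate(anchors):
            n_sites = 10 + int(rng.poisson(max(params.island_cpg_mean - 10, 0)))
            gaps = rng.integers(2, 25, size=n_sites)
            offsets = np.cumsum(gaps)
            start = max(1, center - int(offsets[-1] // 2))
            positions = start + offsets - offsets[0]
            positions = positions[positions < params.chrom_length - 1]
            if len(positions) == 0:
                continue
            island_rows.append(
                (chrom, int(positions[0]), int(positions[-1]) + 2, f"island_{idx}")
            )
            cpg_chunks.append(pd.DataFrame({"chrom": chrom, "pos": positions}))
            n_island_cpgs += len(positions)
    islands = pd.DataFrame(island_rows, columns=["chrom", "start", "end", "name"])

    # Candidate DMR clusters.
    n_dmr_cpgs = 0
    for _, cand in candidates.iterrows():
        positions = np.sort(
            rng.choice(
                np.arange(cand["start"], cand["end"]), size=params.cpgs_per_dmr, replace=False
            )
        )
        cpg_chunks.append(pd.DataFrame({"chrom": cand["chrom"], "pos": positions}))
        n_dmr_cpgs += len(positions)

    # Background CpGs spread uniformly, split across chromosomes.
    n_background = max(params.n_cpg - n_island_cpgs - n_dmr_cpgs, 0)
    per_chrom = np.full(len(chroms), n_background // len(chroms))
    per_chrom[: n_background % len(chroms)] += 1
    for chrom, count in zip(chroms, per_chrom):
        positions = np.sort(rng.choice(params.chrom_length - 2, size=count, replace=False)) + 1
        cpg_chunks.append(pd.DataFrame({"chrom": chrom, "pos": positions}))

    cpgs = pd.concat(cpg_chunks, ignore_index=True)
    cpgs = cpgs.drop_duplicates(["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    cpgs["strand"] = np.where(rng.random(len(cpgs)) < 0.5, "+", "-")
    cpgs["context"] = "CG"
    if params.ch_fraction > 0:
        is_ch = rng.random(len(cpgs)) < params.ch_fraction
        cpgs.loc[is_ch, "context"] = "CH"
    return Annotation(genes, cpgs, islands, candidates, chrom_sizes)


def _place_genes(params: SimulationParams, rng, chroms) -> pd.DataFrame:
    if params.n_genes == 0:
        empty = pd.DataFrame(columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes"])
        return empty.set_index(pd.Index([], name=None))
    per_chrom = np.full(params.n_chrom, params.n_genes // params.n_chrom)
    per_chrom[: params.n_genes % params.n_chrom] += 1
    min_len, max_len = 1_500, 4_000
    rows = []
    gene_idx = 0
    for chrom, count in zip(chroms, per_chrom):
        if count == 0:
            continue
        slot = params.chrom_length // count
        if slot < min_len + 2_200:  # room for the gene plus promoter flank
            raise ValueError(
                f"genome too small to place {params.n_genes} genes of >= {min_len} bp"
            )
        for i in range(count):
            slot_start = i * slot
            length = int(rng.integers(min_len, min(max_len, slot - 2_200)))
            start = slot_start + 1_100 + int(rng.integers(0, slot - length - 2_200))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene_{gene_idx:05d}", chrom, strand, start, start + length))
            gene_idx += 1
    frame = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    plus = frame["strand"] == "+"
    frame["tss"] = np.where(plus, frame["start"], frame["end"] - 1)
    frame["tes"] = np.where(plus, frame["end"] - 1, frame["start"])
    return frame.set_index("gene_id", drop=False)


def _place_dmr_candidates(params: SimulationParams, rng, genes, chroms) -> pd.DataFrame:
    w = params.window_size
    rows = []
    taken: set[tuple[str, int]] = set()
    if params.n_planted_dmrs == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "host_gene"])
    n_in_gene = int(round(params.n_planted_dmrs * params.dmr_in_deg_fraction))
    n_in_gene = min(n_in_gene, params.n_planted_degs, len(genes))
    if n_in_gene > 0:
        # hosts need a window-aligned tile fully inside the gene body
        roomy = genes[(genes["end"] // w) * w - ((genes["start"] // w) + 1) * w >= w]
        hosts = roomy.sample(
            n=min(n_in_gene, len(roomy)), random_state=int(rng.integers(2**31))
        )
        for _, gene in hosts.iterrows():
            first = (gene["start"] // w) + 1
            last = gene["end"] // w - 1
            tile = int(rng.integers(first, last + 1))
            key = (gene["chrom"], tile)
            if key in taken:
                continue
            taken.add(key)
            rows.append((gene["chrom"], tile * w, (tile + 1) * w, gene["gene_id"]))
    while len(rows) < params.n_planted_dmrs:
        chrom = chroms[int(rng.integers(len(chroms)))]
        tile = int(rng.integers(2, params.chrom_length // w - 2))
        key = (chrom, tile)
        if key in taken:
            continue
        taken.add(key)
        rows.append((chrom, tile * w, (tile + 1) * w, ""))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "host_gene"])


def _assign_site_means(
    annotation: Annotation, params: SimulationParams, rng
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Per-site young methylation means, per-gene truth levels, and per-DMR
    baseline levels.  Background sites are calibrated so the pooled CpG mean
    hits ``global_mean_methylation``."""
    cpgs = annotation.cpgs
    n = len(cpgs)
    means = np.full(n, np.nan)
    pos_by_chrom = {c: g["pos"].to_numpy() for c, g in cpgs.groupby("chrom")}
    offset_by_chrom = {c: g.index[0] for c, g in cpgs.groupby("chrom")}

    def assign(chrom, start, end, value):
        pos = pos_by_chrom.get(chrom)
        if pos is None:
            return
        i0 = np.searchsorted(pos, start, side="left")
        i1 = np.searchsorted(pos, end, side="left")
        base = offset_by_chrom[chrom]
        means[base + i0 : base + i1] = value

    genes = annotation.genes
    # One latent axis drives both promoter and gene-body level, giving the
    # positive promoter/body correlation seen in real methylomes.
    z = rng.normal(size=len(genes))
    promoter_level = np.clip(0.72 + 0.16 * z, 0.05, 0.97)
    body_level = np.clip(0.75 + 0.08 * z + 0.05 * rng.normal(size=len(genes)), 0.30, 0.95)
    gene_meth = pd.DataFrame(
        {
            "gene_id": genes.index,
            "promoter_young": promoter_level,
            "body_young": body_level,
        }
    ).set_index("gene_id", drop=False)

    for (gene_id, gene), body in zip(genes.iterrows(), body_level):
        assign(gene["chrom"], gene["start"], gene["end"], body)
    for (gene_id, gene), prom in zip(genes.iterrows(), promoter_level):
        tss = gene["tss"]
        assign(gene["chrom"], max(tss - 1_000, 0), tss + 1_000, prom)
    for _, island in annotation.islands.iterrows():
        assign(island["chrom"], island["start"], island["end"], params.island_mean_methylation)

    # DMR clusters: mid-range baseline so a +/- delta stays inside [0, 1].
    dmr_base = rng.uniform(0.35, 0.60, size=len(annotation.dmr_candidates))
    dmr_levels = annotation.dmr_candidates.copy()
    dmr_levels["young_mean"] = dmr_base
    for (_, cand), base in zip(annotation.dmr_candidates.iterrows(), dmr_base):
        assign(cand["chrom"], cand["start"], cand["end"], base)

    # Solve the background level so the genome-wide CpG mean matches target.
    is_cg = (cpgs["context"] == "CG").to_numpy()
    unassigned = np.isnan(means)
    n_bg = int((unassigned & is_cg).sum())
    assigned_sum = np.nansum(np.where(is_cg, means, 0.0))
    if n_bg > 0:
        background = (params.global_mean_methylation * is_cg.sum() - assigned_sum) / n_bg
        if not 0.02 <= background <= 0.98:
            warnings.warn(
                "background methylation level clipped while calibrating the "
                f"global mean (solved {background:.3f})"
            )
            background = float(np.clip(background, 0.02, 0.98))
    else:
        background = params.global_mean_methylation
    means[unassigned] = background
    means[~is_cg] = params.ch_mean_methylation
    return means, gene_meth, dmr_levels


def simulate_methylome(
    annotation: Annotation, params: SimulationParams
) -> tuple[SimulatedMethylome, TruthTable]:
    """Draw per-sample cytosine counts for the four age x sex groups and
    record every planted effect in a truth table.

    Site methylation is beta-distributed around the regional mean (shared
    across animals: replicate variability is binomial read sampling); old
    groups are shifted by ``+/- dmr_delta`` inside planted DMR windows.
    Planted DEG identities and directions are decided here, because in-gene
    DMR deltas are coupled to their host gene's direction of change.
    """
    params.validate()
    rng = _rng(params, "methylome")
    cpgs = annotation.cpgs
    n = len(cpgs)

    means, gene_meth, dmr_levels = _assign_site_means(annotation, params, rng)
    kappa = 1.0 / params.beta_dispersion - 1.0
    clipped = np.clip(means, 1e-3, 1.0 - 1e-3)
    site_young = rng.beta(clipped * kappa, (1.0 - clipped) * kappa)

    truth = TruthTable(gene_meth=gene_meth)
    truth.degs = _plant_degs(annotation, gene_meth, params, rng)

    site_old = site_young.copy()
    if params.n_planted_dmrs > 0 and params.dmr_delta != 0:
        truth.dmrs = _plant_dmrs(annotation, truth.degs, params, rng)
        pos_by_chrom = {c: g["pos"].to_numpy() for c, g in cpgs.groupby("chrom")}
        offset_by_chrom = {c: g.index[0] for c, g in cpgs.groupby("chrom")}
        any_clipped = False
        for _, dmr in truth.dmrs.iterrows():
            pos = pos_by_chrom[dmr["chrom"]]
            base = offset_by_chrom[dmr["chrom"]]
            i0 = base + np.searchsorted(pos, dmr["start"], side="left")
            i1 = base + np.searchsorted(pos, dmr["end"], side="left")
            shifted = site_young[i0:i1] + dmr["delta"]
            if (shifted < 0.005).any() or (shifted > 0.995).any():
                any_clipped = True
            site_old[i0:i1] = np.clip(shifted, 0.005, 0.995)
        if any_clipped:
            warnings.warn("dmr_delta pushed site means outside [0, 1]; clipped")

    sites = cpgs[["chrom", "pos", "strand", "context"]].copy()
    design_rows = []
    for group in METH_GROUPS:
        age, sex = _GROUP_META[group]
        group_mean = site_old if age == "old" else site_young
        for rep in range(params.n_meth_samples_per_group):
            sample = f"{group}{rep + 1}"
            coverage = rng.poisson(params.coverage_mean, size=n)
            m = rng.binomial(coverage, group_mean)
            sites[f"M_{sample}"] = m
            sites[f"U_{sample}"] = coverage - m
            design_rows.append((sample, group, age, sex))
    design = pd.DataFrame(design_rows, columns=["sample", "group", "age", "sex"]).set_index(
        "sample"
    )
    methylome = SimulatedMethylome(sites, design)
    truth.validate(annotation)
    return methylome, truth


def _plant_degs(annotation, gene_meth, params, rng) -> pd.DataFrame:
    if params.n_planted_degs == 0 or params.deg_log2fc == 0 or len(annotation.genes) == 0:
        return pd.DataFrame(columns=["gene_id", "direction", "log2fc"])
    hosts = [g for g in annotation.dmr_candidates["host_gene"] if g]
    pool = [g for g in annotation.genes.index if g not in set(hosts)]
    n_extra = params.n_planted_degs - len(hosts)
    extra = list(rng.choice(pool, size=max(n_extra, 0), replace=False)) if n_extra > 0 else []
    planted = hosts + extra
    prom = gene_meth.loc[planted, "promoter_young"].to_numpy()
    median = np.median(prom)
    follows = rng.random(len(planted)) < params.association_strength
    informed = np.where(prom > median, 1.0, -1.0)
    random_dir = np.where(rng.random(len(planted)) < 0.5, 1.0, -1.0)
    sign = np.where(follows, informed, random_dir)
    return pd.DataFrame(
        {"gene_id": planted, "direction": np.where(sign > 0, "up", "down"),
         "log2fc": sign * params.deg_log2fc}
    ).set_index("gene_id", drop=False)


def _plant_dmrs(annotation, degs, params, rng) -> pd.DataFrame:
    rows = []
    deg_dir = degs["direction"] if len(degs) else pd.Series(dtype=object)
    for _, cand in annotation.dmr_candidates.iterrows():
        host = cand["host_gene"]
        if host and host in deg_dir.index and rng.random() < params.dmr_deg_coupling:
            # anti-correlated with the host gene's expression change
            sign = -1.0 if deg_dir.loc[host] == "up" else 1.0
        else:
            sign = 1.0 if rng.random() < params.hyper_fraction else -1.0
        rows.append(
            (cand["chrom"], cand["start"], cand["end"],
             "hyper" if sign > 0 else "hypo", sign * abs(params.dmr_delta), host)
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "delta", "host_gene"])


def simulate_expression(
    annotation: Annotation, truth: TruthTable, params: SimulationParams
):
    """Negative-binomial count matrix for 4 age x sex groups.

    Planted DEGs (recorded in ``truth.degs``) have their old-group mean
    scaled by ``2**log2fc`` in both sexes; per-sample library-size factors
    exercise the normalization downstream.  Returns a
    :class:`~methylaging.types.CountsMatrix`.
    """
    from .types import CountsMatrix

    params.validate()
    rng = _rng(params, "expression")
    genes = annotation.genes
    if params.n_planted_degs > len(genes):
        raise ValueError("n_planted_degs cannot exceed the number of genes")
    n_genes = len(genes)
    if params.deg_log2fc == 0:
        truth.degs = pd.DataFrame(columns=["gene_id", "direction", "log2fc"])

    base_mean = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)
    log2fc = pd.Series(0.0, index=genes.index)
    if len(truth.degs):
        log2fc.loc[truth.degs["gene_id"]] = truth.degs["log2fc"].to_numpy()
    old_mean = base_mean * np.power(2.0, log2fc.to_numpy())

    phi = params.nb_dispersion
    counts = {}
    meta_rows = []
    for group in METH_GROUPS:
        age, sex = _GROUP_META[group]
        mu_group = old_mean if age == "old" else base_mean
        for rep in range(params.n_expr_samples_per_group):
            sample = f"{group}_r{rep + 1}"
            lib = rng.uniform(0.7, 1.4)
            mu = np.maximum(mu_group * lib, 1e-8)
            if phi > 0:
                shape = 1.0 / phi
                counts[sample] = rng.negative_binomial(shape, shape / (shape + mu))
            else:
                counts[sample] = rng.poisson(mu)
            meta_rows.append((sample, age, sex))
    frame = pd.DataFrame(counts, index=genes.index)
    meta = pd.DataFrame(meta_rows, columns=["sample", "age", "sex"]).set_index("sample")
    return CountsMatrix(frame.astype(np.int64), meta)


def simulate_peaks(
    annotation: Annotation, truth: TruthTable, params: SimulationParams,
    marks: tuple[str, ...] = ACTIVE_MARKS + REPRESSIVE_MARKS,
) -> dict[str, pd.DataFrame]:
    """Per-mark peak tracks (BED-style frames, disjoint within a mark).

    A gene's peak breadth is drawn around a linear function of its young
    promoter methylation: decreasing for active marks, increasing for
    repressive ones.
    """
    params.validate()
    rng = _rng(params, "peaks")
    genes = annotation.genes
    prom = truth.gene_meth.loc[genes.index, "promoter_young"].to_numpy() if len(genes) else np.array([])
    tracks: dict[str, pd.DataFrame] = {}
    for mark in marks:
        if mark in ACTIVE_MARKS:
            target = 0.70 - 0.60 * prom
        elif mark in REPRESSIVE_MARKS:
            target = 0.05 + 0.55 * prom
        else:
            target = np.full(len(genes), 0.3)
        breadth = np.clip(target + 0.12 * rng.normal(size=len(genes)), 0.0, 0.95)
        rows = []
        for (gene_id, gene), b in zip(genes.iterrows(), breadth):
            width = int(round(b * (gene["end"] - gene["start"])))
            if width < 20:
                continue
            slack = (gene["end"] - gene["start"]) - width
            offset = int(rng.integers(0, slack + 1))
            start = gene["start"] + offset
            rows.append((gene["chrom"], start, start + width, f"{mark}_{gene_id}"))
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        tracks[mark] = track.sort_values(["chrom", "start"], kind="mergesort").reset_index(
            drop=True
        )
    return tracks


@dataclass
class SimulatedStudy:
    params: SimulationParams
    annotation: Annotation
    methylome: SimulatedMethylome
    counts: "object"  # CountsMatrix
    peaks: dict[str, pd.DataFrame]
    truth: TruthTable


def simulate_all(params: SimulationParams) -> SimulatedStudy:
    """Run every generator stage in dependency order."""
    annotation = simulate_annotation(params)
    methylome, truth = simulate_methylome(annotation, params)
    counts = simulate_expression(annotation, truth, params)
    peaks = simulate_peaks(annotation, truth, params)
    return SimulatedStudy(params, annotation, methylome, counts, peaks, truth)
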