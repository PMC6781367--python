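"""Relationships between methylation and expression change with age.

Covers four analyses:

* pooled region methylation (gene body TSS-TES, or promoter +/- 1 kb of
  the TSS) per gene and age group, as the count-weighted fraction
  sum(M) / sum(M + U) over the region's cytosines;
* correlation of per-gene DMR methylation change (delta) with expression
  log2 fold change, by region class (promoter, gene body, enhancer),
  separately for DEGs and non-DEGs;
* association of absolute (young or old) region methylation with the
  expression fold change: Pearson r, a polynomial trend with a pointwise
  95% band, and a Kruskal-Wallis contrast of methylation across
  up / unchanged / down genes;
* the resampling null (correlation over random gene sets) and the
  gene-set correlation screen with a minimum set size and an r cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import merge_intervals
from .stats import conover_two_sample, kruskal_groups, pearson_r

REGIONS = ("gene_body", "promoter")
PROMOTER_FLANK = 1_000


def _region_bounds(genes: pd.DataFrame, region: str) -> pd.DataFrame:
    if region == "gene_body":
        return pd.DataFrame(
            {"chrom": genes["chrom"], "start": genes["start"], "end": genes["end"]},
            index=genes.index,
        )
    if region == "promoter":
        return pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": np.maximum(genes["tss"] - PROMOTER_FLANK, 0),
                "end": genes["tss"] + PROMOTER_FLANK,
            },
            index=genes.index,
        )
    raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def region_methylation(
    sites: pd.DataFrame,
    design: pd.DataFrame,
    genes: pd.DataFrame,
    region: str = "gene_body",
    context: str = "CG",
    groups: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Pooled methylation fraction per gene x group.

    ``groups`` maps a group label to its sample ids; by default one group
    per distinct ``group`` value in the design.  Genes with no covered
    cytosine in the region are omitted.  Returns a frame indexed by gene
    with ``m_<group>`` fraction columns and ``n_sites``.
    """
    if groups is None:
        col = "group" if "group" in design.columns else "age"
        groups = {g: list(idx) for g, idx in design.groupby(col).groups.items()}
    if context is not None and "context" in sites.columns:
        sites = sites[sites["context"] == context]
    bounds = _region_bounds(genes, region)

    # prefix sums of pooled counts per chromosome: each gene's region is a
    # contiguous slice of the sorted site positions
    out: dict[str, np.ndarray] = {}
    n_sites = np.zeros(len(bounds), dtype=int)
    cum_by_chrom = {}
    for chrom, chunk in sites.groupby("chrom", sort=False):
        chunk = chunk.sort_values("pos", kind="mergesort")
        pos = chunk["pos"].to_numpy()
        sums = {}
        for label, members in groups.items():
            m = chunk[[f"M_{s}" for s in members]].to_numpy().sum(axis=1)
            u = chunk[[f"U_{s}" for s in members]].to_numpy().sum(axis=1)
            sums[label] = (
                np.concatenate([[0], np.cumsum(m)]),
                np.concatenate([[0], np.cumsum(m + u)]),
            )
        covered = np.concatenate(
            [[0], np.cumsum((chunk[[c for c in chunk.columns if c.startswith("M_") or c.startswith("U_")]].sum(axis=1) > 0).to_numpy().astype(int))]
        )
        cum_by_chrom[chrom] = (pos, sums, covered)

    for label in groups:
        out[f"m_{label}"] = np.full(len(bounds), np.nan)
    for chrom, gene_chunk in bounds.groupby("chrom", sort=False):
        if chrom not in cum_by_chrom:
            continue
        pos, sums, covered = cum_by_chrom[chrom]
        i0 = np.searchsorted(pos, gene_chunk["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos, gene_chunk["end"].to_numpy(), side="left")
        rows = bounds.index.get_indexer(gene_chunk.index)
        n_sites[rows] = covered[i1] - covered[i0]
        for label in groups:
            cm, ct = sums[label]
            m = cm[i1] - cm[i0]
            t = ct[i1] - ct[i0]
            with np.errstate(invalid="ignore", divide="ignore"):
                out[f"m_{label}"][rows] = np.where(t > 0, m / np.maximum(t, 1), np.nan)

    frame = pd.DataFrame(out, index=bounds.index)
    frame["n_sites"] = n_sites
    frame["region"] = region
    frame["context"] = context if context is not None else "all"
    keep = frame[[f"m_{g}" for g in groups]].notna().any(axis=1) & (frame["n_sites"] > 0)
    return frame[keep]


def binned_profiles(
    sites: pd.DataFrame,
    design: pd.DataFrame,
    genes: pd.DataFrame,
    samples: list[str] | None = None,
    n_bins: int = 100,
    flank: int = 2_000,
    flank_bins: int = 20,
    context: str = "CG",
) -> pd.DataFrame:
    """Per-gene binned methylation profile (heatmap export).

    The gene body is divided into ``n_bins`` equal bins TSS to TES, with
    ``flank_bins`` fixed-width bins over each ``flank`` bp flank; profiles
    of minus-strand genes are reversed so bin 0 is always upstream of the
    TSS.  Values are pooled fractions over the listed samples.
    """
    if samples is None:
        samples = list(design.index)
    if context is not None and "context" in sites.columns:
        sites = sites[sites["context"] == context]
    total_bins = n_bins + 2 * flank_bins
    profile = np.full((len(genes), total_bins), np.nan)
    by_chrom = {}
    for chrom, chunk in sites.groupby("chrom", sort=False):
        chunk = chunk.sort_values("pos", kind="mergesort")
        m = chunk[[f"M_{s}" for s in samples]].to_numpy().sum(axis=1)
        u = chunk[[f"U_{s}" for s in samples]].to_numpy().sum(axis=1)
        by_chrom[chrom] = (
            chunk["pos"].to_numpy(),
            np.concatenate([[0], np.cumsum(m)]),
            np.concatenate([[0], np.cumsum(m + u)]),
        )
    for row, (gene_id, gene) in enumerate(genes.iterrows()):
        if gene["chrom"] not in by_chrom:
            continue
        pos, cm, ct = by_chrom[gene["chrom"]]
        left = np.linspace(gene["start"] - flank, gene["start"], flank_bins + 1)[:-1]
        body = np.linspace(gene["start"], gene["end"], n_bins + 1)[:-1]
        right = np.linspace(gene["end"], gene["end"] + flank, flank_bins + 1)
        edges = np.concatenate([left, body, right])
        idx = np.searchsorted(pos, edges, side="left")
        m = cm[idx[1:]] - cm[idx[:-1]]
        t = ct[idx[1:]] - ct[idx[:-1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(t > 0, m / np.maximum(t, 1), np.nan)
        if gene["strand"] == "-":
            values = values[::-1]
        profile[row] = values
    return pd.DataFrame(profile, index=genes.index)


@dataclass
class AssociationResult:
    scope: str
    n: int
    r: float
    p: float
    trend_coeffs: np.ndarray | None = None
    trend_grid: pd.DataFrame | None = None
    kw_h: float = float("nan")
    kw_p: float = float("nan")
    pairwise: pd.DataFrame | None = None
    note: str = ""


def dmr_expression_correlation(
    dmrs: pd.DataFrame,
    deg_table: pd.DataFrame,
    genes: pd.DataFrame,
    region: str = "gene_body",
    enhancers: pd.DataFrame | None = None,
    max_enhancer_distance: int = 100_000,
) -> dict[str, AssociationResult]:
    """Pearson correlation of per-gene mean DMR delta with log2 fold
    change, separately for DEGs and non-DEGs.

    ``region`` selects how DMRs are assigned to genes: overlap with the
    promoter or gene body, or via enhancer intervals mapped to the gene
    with the nearest TSS within ``max_enhancer_distance``.
    """
    if region in REGIONS:
        bounds = _region_bounds(genes, region)
        gene_delta = _mean_delta_by_overlap(dmrs, bounds)
    elif region == "enhancer":
        if enhancers is None or enhancers.empty:
            raise ValueError("enhancer correlation requires an enhancer track")
        gene_delta = _mean_delta_via_enhancers(dmrs, enhancers, genes, max_enhancer_distance)
    else:
        raise ValueError(f"unknown region {region!r}")

    merged = deg_table.join(gene_delta.rename("delta"), how="inner").dropna(
        subset=["delta", "log2fc"]
    )
    results = {}
    for scope, subset in (
        ("DEG", merged[merged["direction"] != "ns"]),
        ("nonDEG", merged[merged["direction"] == "ns"]),
    ):
        if len(subset) < 3:
            results[scope] = AssociationResult(scope, len(subset), float("nan"),
                                               float("nan"), note="insufficient_pairs")
            continue
        r, p = pearson_r(subset["delta"].to_numpy(), subset["log2fc"].to_numpy())
        note = "constant_input" if np.isnan(r) else ""
        results[scope] = AssociationResult(scope, len(subset), r, p, note=note)
    return results


def _mean_delta_by_overlap(dmrs: pd.DataFrame, bounds: pd.DataFrame) -> pd.Series:
    values: dict[str, list[float]] = {}
    if dmrs.empty:
        return pd.Series(dtype=float)
    dmr_by_chrom = {c: g.sort_values("start") for c, g in dmrs.groupby("chrom")}
    for gene_id, iv in bounds.iterrows():
        group = dmr_by_chrom.get(iv["chrom"])
        if group is None:
            continue
        hits = group[(group["start"] < iv["end"]) & (group["end"] > iv["start"])]
        if len(hits):
            values[gene_id] = hits["delta"].mean()
    return pd.Series(values, dtype=float)


def _mean_delta_via_enhancers(dmrs, enhancers, genes, max_distance) -> pd.Series:
    # DMR -> overlapping enhancer -> gene with the nearest TSS
    enhancers = merge_intervals(enhancers)
    assigned: dict[str, list[float]] = {}
    tss_by_chrom = {
        c: (g["tss"].to_numpy(), g.index.to_numpy()) for c, g in genes.groupby("chrom")
    }
    for chrom, enh_chunk in enhancers.groupby("chrom"):
        if chrom not in tss_by_chrom:
            continue
        tss, gene_ids = tss_by_chrom[chrom]
        order = np.argsort(tss)
        tss, gene_ids = tss[order], gene_ids[order]
        dmr_chunk = dmrs[dmrs["chrom"] == chrom]
        for _, enh in enh_chunk.iterrows():
            hits = dmr_chunk[
                (dmr_chunk["start"] < enh["end"]) & (dmr_chunk["end"] > enh["start"])
            ]
            if hits.empty:
                continue
            center = (enh["start"] + enh["end"]) // 2
            i = np.searchsorted(tss, center)
            best, best_d = None, max_distance + 1
            for j in (i - 1, i):
                if 0 <= j < len(tss) and abs(tss[j] - center) < best_d:
                    best, best_d = gene_ids[j], abs(tss[j] - center)
            if best is None or best_d > max_distance:
                continue
            assigned.setdefault(best, []).extend(hits["delta"].tolist())
    return pd.Series({g: float(np.mean(v)) for g, v in assigned.items()}, dtype=float)


def methylation_level_association(
    summary: pd.DataFrame,
    deg_table: pd.DataFrame,
    group: str,
    poly_degree: int = 2,
) -> dict[str, AssociationResult]:
    """Association between region methylation in one age group and log2FC.

    Returns results for DEGs (with the polynomial trend and the
    Kruskal-Wallis contrast of methylation across up/ns/down) and for
    non-DEGs.
    """
    col = f"m_{group}"
    if col not in summary.columns:
        raise ValueError(f"summary has no methylation column for group {group!r}")
    merged = deg_table.join(summary[[col]], how="inner").dropna(subset=[col, "log2fc"])

    by_dir = {d: merged.loc[merged["direction"] == d, col].to_numpy() for d in ("up", "ns", "down")}
    kw_h, kw_p = kruskal_groups([by_dir["up"], by_dir["ns"], by_dir["down"]])
    pairwise_rows = []
    for a, b in (("up", "ns"), ("up", "down"), ("ns", "down")):
        if len(by_dir[a]) and len(by_dir[b]):
            t, p = conover_two_sample(by_dir[a], by_dir[b])
            pairwise_rows.append((a, b, t, p))
    pairwise = pd.DataFrame(pairwise_rows, columns=["group_a", "group_b", "t", "p"])

    results = {}
    for scope, subset in (
        ("DEG", merged[merged["direction"] != "ns"]),
        ("nonDEG", merged[merged["direction"] == "ns"]),
    ):
        m = subset[col].to_numpy()
        fc = subset["log2fc"].to_numpy()
        if len(subset) < 3:
            results[scope] = AssociationResult(scope, len(subset), float("nan"),
                                               float("nan"), note="insufficient_pairs")
            continue
        r, p = pearson_r(m, fc)
        note = "constant_input" if np.isnan(r) else ""
        coeffs, grid = _polynomial_trend(m, fc, poly_degree)
        res = AssociationResult(scope, len(subset), r, p, coeffs, grid, note=note)
        if scope == "DEG":
            res.kw_h, res.kw_p, res.pairwise = kw_h, kw_p, pairwise
        results[scope] = res
    return results


def _polynomial_trend(x: np.ndarray, y: np.ndarray, degree: int):
    """Least-squares polynomial fit of y on x with a pointwise 95% band."""
    if np.ptp(x) == 0 or len(x) <= degree + 1:
        return None, None
    X = np.vander(x, degree + 1, increasing=True)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(x) - (degree + 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    grid_x = np.linspace(x.min(), x.max(), 50)
    G = np.vander(grid_x, degree + 1, increasing=True)
    fit = G @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", G, cov, G), 0.0))
    t_crit = sps.t.ppf(0.975, dof)
    grid = pd.DataFrame(
        {"x": grid_x, "fit": fit, "lo": fit - t_crit * se, "hi": fit + t_crit * se}
    )
    return beta, grid


@dataclass
class NullDistribution:
    """Correlation coefficients of randomly resampled gene sets."""

    draws: np.ndarray
    set_size: int
    seed: int
    observed_r: float = float("nan")
    percentile: float = float("nan")  # empirical percentile of observed_r

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def random_set_null(
    methylation: pd.Series,
    fold_changes: pd.Series,
    set_size: int = 500,
    n_draws: int = 10_000,
    seed: int = 0,
    observed_r: float | None = None,
) -> NullDistribution:
    """Null distribution of the methylation-log2FC Pearson r over random
    gene sets drawn without replacement (independently across draws)."""
    common = methylation.dropna().index.intersection(fold_changes.dropna().index)
    if set_size > len(common):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(common)} eligible genes"
        )
    x = methylation.loc[common].to_numpy(dtype=float)
    y = fold_changes.loc[common].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = np.empty((n_draws, set_size), dtype=np.int64)
    for i in range(n_draws):
        idx[i] = rng.choice(len(common), size=set_size, replace=False)
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        draws = (xs * ys).sum(axis=1) / np.sqrt(
            (xs**2).sum(axis=1) * (ys**2).sum(axis=1)
        )
    null = NullDistribution(draws, set_size, seed)
    if observed_r is not None:
        null.observed_r = float(observed_r)
        null.percentile = float(np.mean(draws <= observed_r))
    return null


def geneset_correlation_screen(
    methylation: pd.Series,
    fold_changes: pd.Series,
    gmt: dict[str, list[str]],
    min_size: int = 50,
    r_cutoff: float = 0.4,
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-gene-set correlation between region methylation and log2FC.

    Sets are intersected with the genes carrying both values; sets smaller
    than ``min_size`` after intersection are excluded.  A set is flagged
    when r >= r_cutoff (or |r| >= r_cutoff with ``absolute=True``).
    """
    common = methylation.dropna().index.intersection(fold_changes.dropna().index)
    rows = []
    for name, members in gmt.items():
        genes = [g for g in members if g in common]
        if len(genes) < min_size:
            continue
        r, p = pearson_r(
            methylation.loc[genes].to_numpy(), fold_changes.loc[genes].to_numpy()
        )
        stat = abs(r) if absolute else r
        rows.append((name, len(genes), r, p, bool(stat >= r_cutoff)))
    frame = pd.DataFrame(rows, columns=["set", "n", "r", "p", "met_cutoff"])
    return frame.sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
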