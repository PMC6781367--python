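"""Feature-class derivation and over/under-representation testing.

Feature classes are derived from gene models and CpG islands the standard
way: promoters are +/- 1 kb around the strand-aware TSS, gene bodies span
TSS to TES, CpG shores are the 2 kb flanks of (merged) islands, and
shelves the 2 kb flanks beyond the shores.  Derived shores/shelves are
subtracted so islands, shores, and shelves are pairwise disjoint.

Representation of DMRs within a class is tested with the exact
hypergeometric distribution, conditioning on the universe of windows that
passed the coverage filters and were actually tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import clip_to_chroms, merge_intervals, overlaps_any, subtract_intervals
from .stats import bh_adjust, hypergeom_tails

SHORE_FLANK = 2_000
SHELF_FLANK = 2_000
PROMOTER_FLANK = 1_000


def derive_feature_classes(
    genes: pd.DataFrame,
    islands: pd.DataFrame,
    chrom_sizes: dict[str, int],
    peak_tracks: dict[str, pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the feature-class map.

    Returns interval frames for ``island``, ``shore``, ``shelf``,
    ``promoter``, ``promoter_island``, ``promoter_non_island``,
    ``gene_body``, plus one class per loaded peak track.
    """
    classes: dict[str, pd.DataFrame] = {}
    merged_islands = merge_intervals(islands)
    classes["island"] = merged_islands

    shores_raw = pd.concat(
        [
            merged_islands.assign(
                start=merged_islands["start"] - SHORE_FLANK, end=merged_islands["start"]
            ),
            merged_islands.assign(
                start=merged_islands["end"], end=merged_islands["end"] + SHORE_FLANK
            ),
        ],
        ignore_index=True,
    ) if not merged_islands.empty else pd.DataFrame(columns=["chrom", "start", "end"])
    shores_raw = _drop_empty(shores_raw)
    shores = subtract_intervals(clip_to_chroms(shores_raw, chrom_sizes), merged_islands)
    classes["shore"] = shores

    shelves_raw = pd.concat(
        [
            merged_islands.assign(
                start=merged_islands["start"] - SHORE_FLANK - SHELF_FLANK,
                end=merged_islands["start"] - SHORE_FLANK,
            ),
            merged_islands.assign(
                start=merged_islands["end"] + SHORE_FLANK,
                end=merged_islands["end"] + SHORE_FLANK + SHELF_FLANK,
            ),
        ],
        ignore_index=True,
    ) if not merged_islands.empty else pd.DataFrame(columns=["chrom", "start", "end"])
    shelves_raw = _drop_empty(shelves_raw)
    shelves = subtract_intervals(clip_to_chroms(shelves_raw, chrom_sizes), merged_islands)
    shelves = subtract_intervals(shelves, shores)
    classes["shelf"] = shelves

    if len(genes):
        promoters = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["tss"] - PROMOTER_FLANK,
                "end": genes["tss"] + PROMOTER_FLANK,
                "name": genes.index,
            }
        )
        promoters = clip_to_chroms(promoters, chrom_sizes)
        with_island = overlaps_any(promoters, merged_islands)
        classes["promoter"] = promoters.reset_index(drop=True)
        classes["promoter_island"] = promoters[with_island].reset_index(drop=True)
        classes["promoter_non_island"] = promoters[~with_island].reset_index(drop=True)
        bodies = pd.DataFrame(
            {
                "chrom": genes["chrom"],
                "start": genes["start"],
                "end": genes["end"],
                "name": genes.index,
            }
        )
        classes["gene_body"] = clip_to_chroms(bodies, chrom_sizes).reset_index(drop=True)
    else:
        for label in ("promoter", "promoter_island", "promoter_non_island", "gene_body"):
            classes[label] = pd.DataFrame(columns=["chrom", "start", "end", "name"])

    for mark, track in (peak_tracks or {}).items():
        classes[mark] = clip_to_chroms(track, chrom_sizes).reset_index(drop=True)
    return classes


def _drop_empty(frame: pd.DataFrame) -> pd.DataFrame:
    if frame.empty:
        return frame
    return frame[frame["start"] < frame["end"]].reset_index(drop=True)


def feature_enrichment(
    windows: pd.DataFrame,
    dmrs: pd.DataFrame,
    class_map: dict[str, pd.DataFrame],
    direction: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric over/under-representation of DMR windows per class.

    The universe is all tested windows (N); K of them overlap the class by
    >= 1 bp; among the n DMR windows, k overlap.  ``direction`` optionally
    restricts the DMRs to hyper or hypo.
    """
    if direction is not None:
        dmrs = dmrs[dmrs["direction"] == direction]
    N = len(windows)
    n = len(dmrs)
    rows = []
    for label, intervals in class_map.items():
        if intervals.empty:
            rows.append((label, N, 0, n, 0, np.nan, np.nan, np.nan, "empty_class"))
            continue
        K = int(overlaps_any(windows, intervals).sum())
        if K == 0:
            rows.append((label, N, 0, n, 0, np.nan, np.nan, np.nan, "no_universe_overlap"))
            continue
        k = int(overlaps_any(dmrs, intervals).sum()) if n else 0
        p_over, p_under = hypergeom_tails(k, N, K, n)
        fold = (k / n) / (K / N) if n else np.nan
        rows.append((label, N, K, n, k, fold, float(p_over), float(p_under), ""))
    return pd.DataFrame(
        rows,
        columns=["class_label", "N", "K", "n", "k", "fold", "p_over", "p_under", "note"],
    )


def geneset_enrichment(
    dmr_genes: set[str] | list[str],
    universe_genes: set[str] | list[str],
    gmt: dict[str, list[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of DMR-containing genes in each
    gene set, with BH q across the tested sets."""
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty gene universe")
    hits = set(dmr_genes) & universe
    N, n = len(universe), len(hits)
    rows = []
    for name, members in gmt.items():
        in_universe = set(members) & universe
        if not in_universe:
            continue  # set does not intersect the universe
        K = len(in_universe)
        k = len(in_universe & hits)
        p_over, _ = hypergeom_tails(k, N, K, n)
        fold = (k / n) / (K / N) if n else np.nan
        rows.append((name, N, K, n, k, fold, float(p_over)))
    frame = pd.DataFrame(rows, columns=["set", "N", "K", "n", "k", "fold", "p_over"])
    if len(frame):
        frame["q"] = bh_adjust(frame["p_over"].to_numpy())
    else:
        frame["q"] = pd.Series(dtype=float)
    return frame.sort_values("p_over", kind="mergesort").reset_index(drop=True)


def genes_with_dmr_in_body(dmrs: pd.DataFrame, genes: pd.DataFrame) -> set[str]:
    """Gene ids whose body (TSS to TES span) overlaps >= 1 DMR."""
    if dmrs.empty or genes.empty:
        return set()
    bodies = pd.DataFrame(
        {"chrom": genes["chrom"], "start": genes["start"], "end": genes["end"]},
        index=genes.index,
    )
    hit = overlaps_any(bodies.reset_index(drop=True), dmrs)
    return set(genes.index[hit])
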