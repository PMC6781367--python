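"""Small interval algebra on BED-style frames (chrom, start, end).

All operations assume 0-based half-open coordinates and return frames
sorted by (chrom, start).  Intervals are merged where the operation
requires disjointness.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_EMPTY = ["chrom", "start", "end"]


def merge_intervals(frame: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or touching intervals are merged."""
    if frame.empty:
        return pd.DataFrame(columns=_EMPTY)
    rows = []
    for chrom, group in frame.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=_EMPTY)


def subtract_intervals(frame: pd.DataFrame, remove: pd.DataFrame) -> pd.DataFrame:
    """Set difference ``frame \\ remove`` (both merged first)."""
    frame = merge_intervals(frame)
    remove = merge_intervals(remove)
    if frame.empty or remove.empty:
        return frame
    by_chrom = {c: g for c, g in remove.groupby("chrom")}
    rows = []
    for _, iv in frame.iterrows():
        cuts = by_chrom.get(iv["chrom"])
        pos = iv["start"]
        if cuts is not None:
            sub = cuts[(cuts["end"] > iv["start"]) & (cuts["start"] < iv["end"])]
            for _, cut in sub.iterrows():
                if cut["start"] > pos:
                    rows.append((iv["chrom"], pos, cut["start"]))
                pos = max(pos, cut["end"])
        if pos < iv["end"]:
            rows.append((iv["chrom"], pos, iv["end"]))
    return pd.DataFrame(rows, columns=_EMPTY).sort_values(["chrom", "start"]).reset_index(
        drop=True
    )


def clip_to_chroms(frame: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Clip intervals to [0, chrom_length); intervals falling entirely
    outside are dropped."""
    if frame.empty:
        return frame
    out = frame.copy()
    sizes = out["chrom"].map(chrom_sizes)
    if sizes.isna().any():
        missing = out.loc[sizes.isna(), "chrom"].unique().tolist()
        raise ValueError(f"unknown chromosomes: {missing}")
    out["start"] = np.maximum(out["start"], 0)
    out["end"] = np.minimum(out["end"], sizes.astype(int))
    return out[out["start"] < out["end"]].reset_index(drop=True)


def overlaps_any(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each query interval share >= 1 bp with any
    reference interval?"""
    if query.empty:
        return np.zeros(0, dtype=bool)
    reference = merge_intervals(reference)
    mask = np.zeros(len(query), dtype=bool)
    ref_by_chrom = {c: g for c, g in reference.groupby("chrom")}
    q = query.reset_index(drop=True)
    for chrom, group in q.groupby("chrom"):
        ref = ref_by_chrom.get(chrom)
        if ref is None:
            continue
        ref_starts = ref["start"].to_numpy()
        ref_ends = ref["end"].to_numpy()
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        idx = np.searchsorted(ref_starts, ends, side="left") - 1
        valid = idx >= 0
        hit = np.zeros(len(group), dtype=bool)
        hit[valid] = ref_ends[idx[valid]] > starts[valid]
        mask[group.index.to_numpy()] = hit
    return mask


def overlap_width(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Per-query total overlapping width with the merged reference set."""
    if query.empty:
        return np.zeros(0, dtype=int)
    reference = merge_intervals(reference)
    widths = np.zeros(len(query), dtype=int)
    ref_by_chrom = {c: g for c, g in reference.groupby("chrom")}
    q = query.reset_index(drop=True)
    for chrom, group in q.groupby("chrom"):
        ref = ref_by_chrom.get(chrom)
        if ref is None:
            continue
        ref_starts = ref["start"].to_numpy()
        ref_ends = ref["end"].to_numpy()
        cum = np.concatenate([[0], np.cumsum(ref_ends - ref_starts)])
        for row_idx, (s, e) in zip(group.index, zip(group["start"], group["end"])):
            i0 = np.searchsorted(ref_ends, s, side="right")
            i1 = np.searchsorted(ref_starts, e, side="left")
            if i1 <= i0:
                continue
            total = cum[i1] - cum[i0]
            total -= max(0, s - ref_starts[i0])
            total -= max(0, ref_ends[i1 - 1] - e)
            widths[row_idx] = total
    return widths
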