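"""Window-based differentially methylated region (DMR) calling.

The genome is tiled into consecutive, non-overlapping fixed-width windows
(default 500 bp, anchored at coordinate 0 of each chromosome).  Replicates
within each age group are pooled by summing read counts, each window's
pooled 2x2 table (methylated/unmethylated x young/old) is tested with a
two-sided Fisher exact test, and Benjamini-Hochberg adjusted p-values are
thresholded to call DMRs.

Filters, applied in order:

1. site filter: CpGs whose mean per-sample coverage within either group is
   below ``min_site_cov`` are removed;
2. tiling: surviving CpGs are assigned to the window containing them;
   windows with fewer than ``min_cpg`` CpGs are dropped;
3. window coverage filter: windows where any retained CpG has pooled group
   coverage below ``min_cpg_cov`` (in either group) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_adjust, fisher_exact_many

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_cpg",
    "m_young", "u_young", "m_old", "u_old",
    "frac_young", "frac_old", "delta",
]


@dataclass
class DMRResult:
    """All tested windows plus the subset called significant."""

    windows: pd.DataFrame  # WINDOW_COLUMNS + p, q
    dmrs: pd.DataFrame  # significant windows + direction
    alpha: float
    excluded: pd.DataFrame  # windows dropped before testing, with reasons


def make_windows(
    sites: pd.DataFrame,
    design: pd.DataFrame,
    window_size: int = 500,
    min_cpg: int = 10,
    min_site_cov: float = 5.0,
    min_cpg_cov: int = 3,
    context: str = "CG",
) -> pd.DataFrame:
    """Pool filtered CpG counts into genome tiles, pre-test.

    ``sites`` is a combined site-by-sample table (``chrom, pos`` plus
    ``M_<sample>``/``U_<sample>`` columns); ``design`` maps each sample to a
    ``group`` of ``young`` or ``old``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    groups = design["age"] if "age" in design.columns else design["group"]
    young = [s for s in groups.index if groups.loc[s] == "young"]
    old = [s for s in groups.index if groups.loc[s] == "old"]
    if not young or not old:
        raise ValueError("both young and old groups must be non-empty")

    if "context" in sites.columns and context is not None:
        sites = sites[sites["context"] == context]
    if sites.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)

    m_y = sites[[f"M_{s}" for s in young]].to_numpy().sum(axis=1)
    u_y = sites[[f"U_{s}" for s in young]].to_numpy().sum(axis=1)
    m_o = sites[[f"M_{s}" for s in old]].to_numpy().sum(axis=1)
    u_o = sites[[f"U_{s}" for s in old]].to_numpy().sum(axis=1)

    # site filter: mean per-sample coverage within each group
    keep = ((m_y + u_y) / len(young) >= min_site_cov) & ((m_o + u_o) / len(old) >= min_site_cov)

    frame = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[keep],
            "tile": sites["pos"].to_numpy()[keep] // window_size,
            "m_young": m_y[keep],
            "u_young": u_y[keep],
            "m_old": m_o[keep],
            "u_old": u_o[keep],
        }
    )
    if frame.empty:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    frame["cov_young"] = frame["m_young"] + frame["u_young"]
    frame["cov_old"] = frame["m_old"] + frame["u_old"]

    grouped = frame.groupby(["chrom", "tile"], sort=True)
    agg = grouped.agg(
        n_cpg=("m_young", "size"),
        m_young=("m_young", "sum"),
        u_young=("u_young", "sum"),
        m_old=("m_old", "sum"),
        u_old=("u_old", "sum"),
        min_cov_young=("cov_young", "min"),
        min_cov_old=("cov_old", "min"),
    ).reset_index()

    # window filters: enough CpGs, and every retained CpG adequately covered
    # by the pooled counts of both groups
    agg = agg[agg["n_cpg"] >= min_cpg]
    agg = agg[(agg["min_cov_young"] >= min_cpg_cov) & (agg["min_cov_old"] >= min_cpg_cov)]

    agg["start"] = agg["tile"] * window_size
    agg["end"] = (agg["tile"] + 1) * window_size
    cov_y = agg["m_young"] + agg["u_young"]
    cov_o = agg["m_old"] + agg["u_old"]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["frac_young"] = agg["m_young"] / cov_y
        agg["frac_old"] = agg["m_old"] / cov_o
    agg["delta"] = agg["frac_old"] - agg["frac_young"]
    return agg[WINDOW_COLUMNS].reset_index(drop=True)


def pooled_window_test(windows: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided Fisher exact test of each window's pooled 2x2 table.

    Windows with zero total coverage in either group cannot be tested and
    are returned separately with a reason code.
    """
    if windows.empty:
        empty = windows.copy()
        empty["p"] = pd.Series(dtype=float)
        return empty, pd.DataFrame(columns=list(windows.columns) + ["reason"])
    cov_y = windows["m_young"] + windows["u_young"]
    cov_o = windows["m_old"] + windows["u_old"]
    testable = (cov_y > 0) & (cov_o > 0)
    excluded = windows[~testable].copy()
    excluded["reason"] = "zero_group_coverage"
    tested = windows[testable].copy()
    tables = tested[["m_young", "u_young", "m_old", "u_old"]].to_numpy()
    tested["p"] = fisher_exact_many(tables)
    return tested, excluded


def adjust_and_call(windows: pd.DataFrame, alpha: float = 0.05) -> DMRResult:
    """BH-adjust the window p-values jointly and call DMRs at q < alpha,
    labelling each hyper (delta > 0) or hypo (delta < 0)."""
    if windows.empty:
        empty = windows.copy()
        for col in ("p", "q"):
            if col not in empty.columns:
                empty[col] = pd.Series(dtype=float)
        dmrs = empty.copy()
        dmrs["direction"] = pd.Series(dtype=object)
        return DMRResult(empty, dmrs, alpha, pd.DataFrame())
    out = windows.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    called = out[(out["q"] < alpha) & (out["delta"] != 0)].copy()
    called["direction"] = np.where(called["delta"] > 0, "hyper", "hypo")
    return DMRResult(out, called, alpha, pd.DataFrame())


def call_dmrs(
    sites: pd.DataFrame,
    design: pd.DataFrame,
    window_size: int = 500,
    min_cpg: int = 10,
    min_site_cov: float = 5.0,
    min_cpg_cov: int = 3,
    alpha: float = 0.05,
    context: str = "CG",
) -> DMRResult:
    """End-to-end window construction, testing, and calling."""
    windows = make_windows(
        sites, design,
        window_size=window_size, min_cpg=min_cpg,
        min_site_cov=min_site_cov, min_cpg_cov=min_cpg_cov, context=context,
    )
    tested, excluded = pooled_window_test(windows)
    result = adjust_and_call(tested, alpha=alpha)
    return DMRResult(result.windows, result.dmrs, alpha, excluded)


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """DMRs as a BED4+1 frame: name = direction, score = -log10 q."""
    if dmrs.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score"])
    score = -np.log10(np.maximum(dmrs["q"].to_numpy(), 1e-300))
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["direction"],
            "score": np.round(score, 4),
        }
    ).reset_index(drop=True)


def common_dmrs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Windows significant in both of two contrasts (identical coordinates),
    with each contrast's direction retained."""
    if a.empty or b.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "direction_a", "direction_b"])
    merged = a.merge(b, on=["chrom", "start", "end"], suffixes=("_a", "_b"))
    return merged[["chrom", "start", "end", "direction_a", "direction_b"]]
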