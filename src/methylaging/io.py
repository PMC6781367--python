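"""Readers and writers for the external formats the pipeline touches.

Supported formats:

* Bismark-style ``.cov`` coverage files (6 tab-separated columns: chrom,
  start 1-based, end, %methylation, count methylated, count unmethylated).
  The %methylation column is derived, never authoritative: fractions are
  always recomputed from the counts.
* Bismark-style cytosine reports (7 columns: chrom, pos 1-based, strand,
  count methylated, count unmethylated, context, trinucleotide), used when
  strand/context labels need to survive a round trip.
* BED3/BED4 interval tracks, gene-model TSVs, raw count TSVs with a sample
  metadata TSV, and GMT gene sets.

Internally everything is 0-based half-open; the two coverage dialects are
converted at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import METHYLOME_COLUMNS, CountsMatrix, GeneModel

_COV_COLUMNS = ["chrom", "start", "end", "pct", "m_count", "u_count"]
_CX_COLUMNS = ["chrom", "pos1", "strand", "m_count", "u_count", "context", "tri"]


class ParseError(ValueError):
    """Malformed input file."""


def _read_table(path: str | os.PathLike, n_fields: int, names: list[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", header=None, names=names, comment="#", dtype=str
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ParseError(f"{path}: {exc}") from exc
    # too-few-column rows come back as NaN padding rather than a parser error
    bad = frame[names[n_fields - 1]].isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: expected {n_fields} tab-separated fields")
    return frame


def _sniff_columns(path: str | os.PathLike) -> int:
    with open(path) as handle:
        for line in handle:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 0


def read_methylome(path: str | os.PathLike, sample_id: str | None = None) -> pd.DataFrame:
    """Read one sample's cytosine-level counts.

    The dialect is detected from the column count: 6 columns is a ``.cov``
    coverage file (CpG context, + strand assumed), 7 columns a cytosine
    report.  Returns a frame with columns ``chrom, pos, strand, context,
    m_count, u_count`` sorted by (chrom, pos); positions are 0-based.
    """
    n_cols = _sniff_columns(path)
    if n_cols == 0:
        frame = pd.DataFrame(columns=METHYLOME_COLUMNS)
        frame.attrs["sample_id"] = sample_id
        return frame
    if n_cols == 6:
        raw = _read_table(path, 6, _COV_COLUMNS)
        frame = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": _to_int(raw["start"], path, "position") - 1,
                "strand": "+",
                "context": "CG",
                "m_count": _to_int(raw["m_count"], path, "methylated count"),
                "u_count": _to_int(raw["u_count"], path, "unmethylated count"),
            }
        )
    elif n_cols == 7:
        raw = _read_table(path, 7, _CX_COLUMNS)
        frame = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": _to_int(raw["pos1"], path, "position") - 1,
                "strand": raw["strand"],
                "context": raw["context"],
                "m_count": _to_int(raw["m_count"], path, "methylated count"),
                "u_count": _to_int(raw["u_count"], path, "unmethylated count"),
            }
        )
    else:
        raise ParseError(f"{path}: expected 6 (coverage) or 7 (cytosine report) columns, found {n_cols}")
    if (frame["m_count"] < 0).any() or (frame["u_count"] < 0).any():
        raise ParseError(f"{path}: negative read counts")
    if (frame["pos"] < 0).any():
        raise ParseError(f"{path}: non-positive 1-based positions")
    bad_strand = ~frame["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(f"{path}: invalid strand {frame.loc[bad_strand, 'strand'].iloc[0]!r}")
    frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    frame.attrs["sample_id"] = sample_id
    return frame


def _to_int(series: pd.Series, path, what: str) -> pd.Series:
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.isna().any():
        line = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {line}: non-numeric {what} {series.iloc[line - 1]!r}")
    if (numeric != numeric.astype(np.int64)).any():
        bad = int(np.flatnonzero((numeric != numeric.astype(np.int64)).to_numpy())[0]) + 1
        raise ParseError(f"{path}: line {bad}: non-integer {what} {series.iloc[bad - 1]!r}")
    return numeric.astype(np.int64)


def write_methylome(frame: pd.DataFrame, path: str | os.PathLike, dialect: str = "cov") -> None:
    """Write a methylome frame as a ``.cov`` file or a cytosine report.

    The ``cov`` dialect drops strand/context (CpG + strand is assumed on
    re-read); use ``cx`` when those labels must round-trip.
    """
    if dialect == "cov":
        cov = frame["m_count"] + frame["u_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * frame["m_count"] / cov.replace(0, 1), 0.0)
        out = pd.DataFrame(
            {
                "chrom": frame["chrom"],
                "start": frame["pos"] + 1,
                "end": frame["pos"] + 1,
                "pct": pct,
                "m": frame["m_count"],
                "u": frame["u_count"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
    elif dialect == "cx":
        out = pd.DataFrame(
            {
                "chrom": frame["chrom"],
                "pos1": frame["pos"] + 1,
                "strand": frame["strand"],
                "m": frame["m_count"],
                "u": frame["u_count"],
                "context": frame["context"],
                "tri": np.where(frame["context"] == "CG", "CGN", "CHN"),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown methylome dialect {dialect!r}")


def combine_methylomes(samples: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample methylomes into one site-by-sample count table.

    Returns a frame with ``chrom, pos, strand, context`` plus ``M_<sample>``
    and ``U_<sample>`` columns.  Sites absent from a sample get zero counts
    (no coverage).
    """
    if not samples:
        raise ValueError("no samples to combine")
    pieces = []
    for sample, frame in samples.items():
        piece = frame.set_index(["chrom", "pos"])
        pieces.append(
            piece[["m_count", "u_count"]].rename(
                columns={"m_count": f"M_{sample}", "u_count": f"U_{sample}"}
            )
        )
    merged = pd.concat(pieces, axis=1).fillna(0).astype(np.int64)
    # strand/context: take from the first sample that covers the site
    meta = pd.concat(
        [f.set_index(["chrom", "pos"])[["strand", "context"]] for f in samples.values()]
    )
    meta = meta[~meta.index.duplicated(keep="first")]
    merged = merged.join(meta)
    merged = merged.reset_index().sort_values(["chrom", "pos"], kind="mergesort")
    merged.attrs["samples"] = list(samples)
    return merged.reset_index(drop=True)


def read_gene_models(path: str | os.PathLike) -> pd.DataFrame:
    """Read a 5-column gene-model TSV (gene_id, chrom, strand, start, end).

    A header row is optional.  Returns a frame indexed by gene_id with
    derived strand-aware ``tss``/``tes`` columns.
    """
    frame = _read_table(path, 5, ["gene_id", "chrom", "strand", "start", "end"])
    if len(frame) and frame.iloc[0]["gene_id"] == "gene_id":
        frame = frame.iloc[1:].reset_index(drop=True)
    if frame.empty:
        return pd.DataFrame(
            columns=["gene_id", "chrom", "strand", "start", "end", "tss", "tes"]
        ).set_index(pd.Index([], name=None))
    frame["start"] = _to_int(frame["start"], path, "gene start")
    frame["end"] = _to_int(frame["end"], path, "gene end")
    if frame["gene_id"].duplicated().any():
        dup = frame.loc[frame["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    if (frame["start"] >= frame["end"]).any():
        bad = frame[frame["start"] >= frame["end"]].iloc[0]
        raise ValueError(f"{path}: gene {bad['gene_id']}: start >= end")
    bad_strand = ~frame["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"{path}: invalid strand for gene {frame.loc[bad_strand, 'gene_id'].iloc[0]}")
    plus = frame["strand"] == "+"
    frame["tss"] = np.where(plus, frame["start"], frame["end"] - 1)
    frame["tes"] = np.where(plus, frame["end"] - 1, frame["start"])
    return frame.set_index("gene_id", drop=False)


def write_gene_models(genes: pd.DataFrame | Iterable[GeneModel], path) -> None:
    if not isinstance(genes, pd.DataFrame):
        from .types import genes_to_frame

        genes = genes_to_frame(list(genes))
    genes[["gene_id", "chrom", "strand", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | os.PathLike, class_label: str = "") -> pd.DataFrame:
    """Read BED3/BED4 intervals (0-based half-open) into a frame."""
    n_cols = _sniff_columns(path)
    if n_cols == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "class_label"])
    names = ["chrom", "start", "end", "name", "score", "strand"][: max(n_cols, 3)]
    frame = _read_table(path, 3, names)
    frame["start"] = _to_int(frame["start"], path, "interval start")
    frame["end"] = _to_int(frame["end"], path, "interval end")
    if (frame["start"] >= frame["end"]).any():
        bad = frame[frame["start"] >= frame["end"]].iloc[0]
        raise ValueError(f"{path}: interval with start >= end at {bad['chrom']}:{bad['start']}")
    if "name" not in frame:
        frame["name"] = ""
    frame["name"] = frame["name"].fillna("")
    frame["class_label"] = class_label
    return frame[["chrom", "start", "end", "name", "class_label"]].sort_values(
        ["chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


def write_bed(frame: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"]
    if "name" in frame.columns:
        cols.append("name")
    if extra_cols:
        cols.extend(extra_cols)
    frame[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def read_annotation(
    gene_path: str | os.PathLike, bed_paths: Mapping[str, str | os.PathLike] | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Read gene models plus BED interval tracks keyed by feature class."""
    genes = read_gene_models(gene_path)
    tracks = {
        label: read_bed(path, class_label=label) for label, path in (bed_paths or {}).items()
    }
    return genes, tracks


def read_counts(path: str | os.PathLike, metadata_path: str | os.PathLike) -> CountsMatrix:
    """Read a raw count TSV (first column gene_id, header row of sample ids)
    and a metadata TSV with columns sample, age, sex."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: counts must be numeric")
    if (values < 0).any():
        raise ValueError(f"{path}: negative count entries")
    if not (values == values.astype(np.int64)).all():
        gene = counts.index[np.argwhere(values != values.astype(np.int64))[0][0]]
        raise ValueError(f"{path}: non-integer count for gene {gene}")
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample" not in meta.columns:
        raise ValueError(f"{metadata_path}: missing 'sample' column")
    meta = meta.set_index("sample")
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return CountsMatrix(counts.astype(np.int64), meta.loc[counts.columns])


def write_counts(matrix: CountsMatrix, counts_path, meta_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    matrix.meta.to_csv(meta_path, sep="\t", index_label="sample")


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i}: GMT rows need name, description, >= 1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as handle:
        for name, genes in sets.items():
            handle.write("\t".join([name, name] + list(genes)) + "\n")
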