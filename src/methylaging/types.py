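"""Shared genomic data model and coordinate conventions.

All internal coordinates are 0-based, half-open ``[start, end)``.  The only
1-based dialect in the code base is the Bismark-style coverage format, which
is converted at the I/O boundary (see :mod:`methylaging.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

VALID_CONTEXTS = ("CG", "CH")
VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with an optional feature class label."""

    chrom: str
    start: int
    end: int
    name: str = ""
    class_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS/TES.

    ``tss`` is ``start`` on the + strand and ``end - 1`` on the - strand;
    ``tes`` is the opposite terminus.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CpGSiteRecord:
    """One cytosine's methylated/unmethylated read counts for one sample."""

    chrom: str
    pos: int
    m_count: int
    u_count: int
    strand: str = "+"
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("position must be >= 0")
        if self.m_count < 0 or self.u_count < 0:
            raise ValueError("read counts must be >= 0")
        if self.context not in VALID_CONTEXTS:
            raise ValueError(f"context must be one of {VALID_CONTEXTS}")

    @property
    def coverage(self) -> int:
        return self.m_count + self.u_count

    @property
    def fraction(self) -> float | None:
        """Methylation fraction M/(M+U); ``None`` for zero-coverage sites."""
        cov = self.coverage
        return None if cov == 0 else self.m_count / cov


# Column layout of a per-sample methylome frame.
METHYLOME_COLUMNS = ["chrom", "pos", "strand", "context", "m_count", "u_count"]


@dataclass
class CountsMatrix:
    """Raw RNA-seq counts (genes x samples) with per-sample age/sex metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        counts, meta = self.counts, self.meta
        if not counts.columns.equals(pd.Index(meta.index)):
            missing = set(counts.columns) - set(meta.index)
            extra = set(meta.index) - set(counts.columns)
            raise ValueError(
                "counts columns and metadata samples differ "
                f"(missing metadata for {sorted(missing)}, unused metadata for {sorted(extra)})"
            )
        if not counts.index.is_unique:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in counts matrix: {dup}")
        values = counts.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not (values == values.astype(int)).all():
            raise ValueError("counts must be integers")
        for col in ("age", "sex"):
            if col not in meta.columns:
                raise ValueError(f"sample metadata is missing the {col!r} column")
        bad_age = set(meta["age"]) - {"young", "old"}
        if bad_age:
            raise ValueError(f"age labels must be young/old, got {sorted(bad_age)}")
        bad_sex = set(meta["sex"]) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"sex labels must be male/female, got {sorted(bad_sex)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, samples: list[str]) -> "CountsMatrix":
        return CountsMatrix(self.counts[samples].copy(), self.meta.loc[samples].copy())


def genes_to_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Tabulate gene models with derived TSS/TES, indexed by gene_id."""
    frame = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "tss": [g.tss for g in genes],
            "tes": [g.tes for g in genes],
        }
    )
    return frame.set_index("gene_id", drop=False)
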