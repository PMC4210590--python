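"""Genomic intervals, UCR catalogs and genomic-context classification.

Ultra-conserved regions (UCRs) are genomic segments of at least 200 bp with
100% identity across the human, mouse and rat genomes.  This module handles
their coordinates and classifies each UCR by its transcriptional context:

* ``exonic`` — the UCR overlaps a confirmed exon;
* ``putative_exonic`` — it overlaps only EST-level transcript evidence;
* ``non_exonic`` — it overlaps neither.

Coordinates are 1-based and fully closed in memory (``chr10:50,604,757-
50,605,033`` spans 277 nt); on disk the standard BED convention (0-based,
half-open) is used, with conversion at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

GENOMIC_CLASSES = ("exonic", "putative_exonic", "non_exonic")

__all__ = [
    "GENOMIC_CLASSES",
    "GenomicInterval",
    "AnnotationTracks",
    "UCRCatalog",
    "region_length",
    "overlaps",
    "classify_context",
    "classify_catalog",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A named interval on a chromosome, 1-based and fully closed."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end < self.start:
            raise ValueError(
                f"invalid interval {self.name!r}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise ValueError(f"invalid interval {self.name!r}: start must be >= 1 (1-based)")


@dataclass
class AnnotationTracks:
    """Annotation evidence used for context classification.

    ``exons`` carry confirmed exon intervals; ``ests`` carry EST/mRNA-level
    (uncertain) transcript evidence.
    """

    exons: list[GenomicInterval] = field(default_factory=list)
    ests: list[GenomicInterval] = field(default_factory=list)


@dataclass
class UCRCatalog:
    """Catalog of UCR loci with an optional genomic-context class per record."""

    records: pd.DataFrame  # columns: ucr_id, chrom, start, end, genomic_class

    REQUIRED = ("ucr_id", "chrom", "start", "end", "genomic_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"catalog is missing columns: {missing}")
        if self.records["ucr_id"].duplicated().any():
            dup = self.records.loc[self.records["ucr_id"].duplicated(), "ucr_id"].iloc[0]
            raise ValueError(f"duplicate ucr_id in catalog: {dup!r}")
        bad = self.records["end"] < self.records["start"]
        if bad.any():
            raise ValueError("catalog contains intervals with end < start")

    @property
    def ucr_ids(self) -> list[str]:
        return self.records["ucr_id"].tolist()

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.ucr_id)
            for r in self.records.itertuples(index=False)
        ]

    def __len__(self) -> int:
        return len(self.records)


def region_length(iv: GenomicInterval) -> int:
    """Number of nucleotides spanned by a 1-based closed interval.

    ``chr10:50,604,757-50,605,033`` → 277.
    """
    return iv.end - iv.start + 1


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two closed intervals share at least one base.

    Adjacent intervals (``a.end + 1 == b.start``) do not overlap.
    """
    return a.chrom == b.chrom and max(a.start, b.start) <= min(a.end, b.end)


def classify_context(ucr: GenomicInterval, tracks: AnnotationTracks) -> str:
    """Classify a UCR by transcript evidence, with strict precedence.

    ``exonic`` (any confirmed-exon overlap) beats ``putative_exonic`` (EST-only
    overlap) beats ``non_exonic``; a single overlapping base suffices.  Strand
    is ignored: genomic context is a property of the locus, not of the probe.
    """
    if any(overlaps(ucr, exon) for exon in tracks.exons):
        return "exonic"
    if any(overlaps(ucr, est) for est in tracks.ests):
        return "putative_exonic"
    return "non_exonic"


def classify_catalog(catalog: UCRCatalog, tracks: AnnotationTracks) -> pd.DataFrame:
    """Classify every catalog record; returns ucr_id → genomic_class."""
    rows = [
        {"ucr_id": iv.name, "genomic_class": classify_context(iv, tracks)}
        for iv in catalog.intervals()
    ]
    return pd.DataFrame(rows, columns=["ucr_id", "genomic_class"])


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open on disk <-> 1-based closed in memory)
# ---------------------------------------------------------------------------

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed(intervals: Iterable[GenomicInterval] | UCRCatalog, path: str | Path) -> None:
    """Write intervals as 6-column BED; a UCRCatalog gains a 7th class column."""
    path = Path(path)
    if isinstance(intervals, UCRCatalog):
        df = intervals.records.copy()
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"] - 1,  # to 0-based half-open
                "end": df["end"],
                "name": df["ucr_id"],
                "score": 0,
                "strand": ".",
                "genomic_class": df["genomic_class"],
            }
        )
    else:
        ivs = list(intervals)
        out = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in ivs],
                "start": [iv.start - 1 for iv in ivs],
                "end": [iv.end for iv in ivs],
                "name": [iv.name for iv in ivs],
                "score": 0,
                "strand": ".",
            }
        )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path, *, as_catalog: bool = False) -> list[GenomicInterval] | UCRCatalog:
    """Read a BED file written by :func:`write_bed` (or any 4+ column BED)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = _BED6[:ncol] if ncol <= 6 else _BED6 + ["genomic_class"] + list(range(ncol - 7))
    df.columns = names[:ncol]
    df["start"] = df["start"].astype(int) + 1  # to 1-based closed
    df["end"] = df["end"].astype(int)
    if as_catalog:
        if "genomic_class" not in df.columns:
            df["genomic_class"] = "non_exonic"
        rec = df.rename(columns={"name": "ucr_id"})[
            ["ucr_id", "chrom", "start", "end", "genomic_class"]
        ]
        return UCRCatalog(rec.reset_index(drop=True))
    if "name" not in df.columns:
        df["name"] = ""
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.name))
        for r in df.itertuples(index=False)
    ]
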