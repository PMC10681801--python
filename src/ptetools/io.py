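"""Reading and writing of the standard genomic formats the pipeline touches.

All coordinates are 0-based half-open internally.  Coverage tracks are dense
per-base vectors (one ``numpy`` array per chromosome) — the fixtures and
analysis windows here are desk-scale, so a dense representation (~8 bytes/bp)
is simpler and faster than interval trees.  Chromosome names are passed
through verbatim; a mismatch between a file and the declared chromosome
sizes raises an explicit error listing the offending names.

Files whose path ends in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "GeneRecord",
    "read_bedgraph",
    "write_bedgraph",
    "read_regions",
    "write_regions",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
]


class FormatError(ValueError):
    """A file violated the expected format."""


def _open(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).  ``name`` and
    ``score`` carry the optional BED columns 4 and 5.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance(self, other: "GenomicInterval") -> int | None:
        """Gap between closest edges; 0 if overlapping; None across chromosomes."""
        if self.chrom != other.chrom:
            return None
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class CoverageTrack:
    """Per-chromosome non-negative signal at 1-bp resolution.

    Values are depth-normalized, RPKM-like units.  Missing positions are 0.
    """

    def __init__(self, data: dict[str, np.ndarray]):
        self.data = {}
        for chrom, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"track for {chrom} must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"track for {chrom} has negative values")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n) for c, n in chrom_sizes.items()})

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.data.items()}

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.data[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.data

    def chroms(self) -> list[str]:
        return list(self.data)

    def values(self, interval: GenomicInterval) -> np.ndarray:
        """Signal over an interval (view into the per-chromosome vector)."""
        arr = self.data[interval.chrom]
        if interval.end > len(arr):
            raise ValueError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(arr)}"
            )
        return arr[interval.start : interval.end]

    def total(self) -> float:
        return float(sum(a.sum() for a in self.data.values()))

    def mean_with(self, other: "CoverageTrack") -> "CoverageTrack":
        if set(self.data) != set(other.data):
            raise ValueError("chromosome sets differ")
        return CoverageTrack(
            {c: (self.data[c] + other.data[c]) / 2.0 for c in self.data}
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene reduced to its TSS, strand and expression level (RNA count)."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    count: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.count < 0:
            raise ValueError(f"gene {self.gene_id}: negative count")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> CoverageTrack:
    """Read a 4-column bedGraph into a dense per-bp track.

    Run-length records are expanded; overlapping records are an error (they
    would make the per-bp value ambiguous).  Records on chromosomes absent
    from ``chrom_sizes`` raise a :class:`FormatError`.
    """
    track = CoverageTrack.zeros(chrom_sizes)
    covered: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()
    }
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if chrom not in track.data:
                raise FormatError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in declared "
                    f"sizes {sorted(chrom_sizes)}"
                )
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise FormatError(
                    f"{path}:{lineno}: interval {start}-{end} outside "
                    f"[0, {chrom_sizes[chrom]})"
                )
            if covered[chrom][start:end].any():
                raise FormatError(f"{path}:{lineno}: overlapping records")
            covered[chrom][start:end] = True
            track.data[chrom][start:end] = value
    return track


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write run-length-encoded bedGraph; zero runs and empty tails omitted."""
    with _open(path, "wt") as fh:
        for chrom in track.chroms():
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            vals = arr[starts]
            keep = vals != 0
            if not keep.any():
                continue
            df = pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[keep],
                    "end": ends[keep],
                    "value": vals[keep],
                }
            )
            df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED regions


def read_regions(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals, sorted by (chrom, start).

    Columns 4 (name), 5 (score) and 6 (strand) are kept when present;
    strand defaults to ``'.'``.
    """
    out: list[GenomicInterval] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            if s >= e:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else None
            score = None
            if len(parts) > 4 and parts[4] != ".":
                score = float(parts[4])
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, s, e, strand, name, score))
    out.sort()
    return out


def write_regions(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (name '.', score 0 when absent)."""
    with _open(path, "wt") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            name = iv.name if iv.name is not None else "."
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id, uppercased; N is allowed."""
    with _open(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return seqs


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# gene tables


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "count"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a TSV with header gene_id, chrom, tss, strand, count."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"{path}: duplicate gene_id {dups}")
    return [
        GeneRecord(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            count=float(r.count),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.tss, g.strand, g.count) for g in genes],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
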