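"""Readers and writers for the external formats the pipeline touches.

Coordinates are 0-based half-open everywhere (BED/bedGraph/chain native).
Every reader reports how many records it dropped; nothing is silently
discarded or imputed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ProbeSignal",
    "GeneRecord",
    "IntervalValue",
    "GenomeAssembly",
    "ReadReport",
    "read_probe_table",
    "merge_replicates",
    "read_genes_bed",
    "read_expression_tsv",
    "attach_expression",
    "read_interval_values",
    "read_chrom_sizes",
    "write_bedgraph",
    "write_chrom_sizes",
    "write_tsv",
]

# value formatting used by every writer; round-trips to 6 significant digits
_FLOAT_FMT = "%.6g"


@dataclass(frozen=True, slots=True)
class ProbeSignal:
    """One microarray probe carrying a log2(IP/input) value."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"probe {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def midpoint(self) -> int:
        """Point representation used for all membership tests."""
        return (self.start + self.end) // 2


@dataclass(slots=True)
class GeneRecord:
    """A gene with a strand-aware transcription span.

    ``expression`` is mean log2 normalized expression over replicates;
    ``genic_signal`` is the mean probe value inside [tx_start, tx_end).
    Either may be None when unavailable.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    expression: float | None = None
    genic_signal: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.tx_start >= self.tx_end:
            raise ValidationError(f"gene {self.gene_id}: tx_start must be < tx_end")

    @property
    def five_prime(self) -> int:
        """Strand-aware 5' position (the base of the transcription start)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True, slots=True)
class IntervalValue:
    """A genomic interval carrying one value (bedGraph record)."""

    chrom: str
    start: int
    end: int
    value: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered (chromosome, length) pairs, i.e. a chrom.sizes file."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValidationError("assembly chromosome names must be unique")
        for name, length in self.chroms:
            if length <= 0:
                raise ValidationError(f"chromosome {name}: length must be > 0")
        object.__setattr__(self, "_lengths", dict(self.chroms))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)


@dataclass
class ReadReport:
    """Row accounting for a reader: rows in = records out + dropped."""

    n_rows: int = 0
    n_dropped: int = 0
    dropped_reasons: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.n_dropped += 1
        self.dropped_reasons[reason] = self.dropped_reasons.get(reason, 0) + 1


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_int(text: str, path: Path, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad {what} {text!r}") from None


def _parse_float(text: str, path: Path, lineno: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: bad {what} {text!r}") from None


def read_probe_table(
    path: str | Path, mode: str = "ratio"
) -> tuple[list[ProbeSignal], ReadReport]:
    """Read a per-probe signal table (TSV with header).

    ``ratio`` mode expects columns chrom,start,end,value; ``two_channel``
    expects chrom,start,end,ip,input and computes value = log2(ip/input).
    Rows with non-finite values (or non-positive channel intensities in
    two_channel mode) are dropped and counted. Output is sorted by
    (chrom, start).
    """
    if mode not in ("ratio", "two_channel"):
        raise ValidationError(f"unknown probe table mode {mode!r}")
    path = Path(path)
    required = ["chrom", "start", "end"] + (
        ["value"] if mode == "ratio" else ["ip", "input"]
    )
    report = ReadReport()
    probes: list[ProbeSignal] = []
    with _open_text(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise ParseError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        try:
            cols = {name: header.index(name) for name in required}
        except ValueError as exc:
            raise ParseError(f"{path}:1: header missing column: {exc}") from None
        width = max(cols.values()) + 1
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < width:
                raise ParseError(f"{path}:{lineno}: expected >= {width} columns")
            report.n_rows += 1
            chrom = fields[cols["chrom"]]
            start = _parse_int(fields[cols["start"]], path, lineno, "start")
            end = _parse_int(fields[cols["end"]], path, lineno, "end")
            if mode == "ratio":
                value = _parse_float(fields[cols["value"]], path, lineno, "value")
            else:
                ip = _parse_float(fields[cols["ip"]], path, lineno, "ip")
                inp = _parse_float(fields[cols["input"]], path, lineno, "input")
                if ip <= 0 or inp <= 0:
                    report.drop("non_positive_channel")
                    continue
                value = math.log2(ip / inp)
            if not math.isfinite(value):
                report.drop("non_finite_value")
                continue
            probes.append(ProbeSignal(chrom, start, end, value))
    if report.n_rows == 0:
        raise ParseError(f"{path}: no data rows")
    probes.sort(key=lambda p: (p.chrom, p.start, p.end))
    return probes, report


def merge_replicates(
    tracks: Sequence[Sequence[ProbeSignal]],
) -> tuple[list[ProbeSignal], int]:
    """Per-probe arithmetic mean across replicate tracks.

    Probes are matched by (chrom, start, end); probes absent from any
    replicate are dropped. Returns (merged sorted probes, n_dropped).
    """
    if len(tracks) == 0:
        raise ValidationError("merge_replicates requires at least one track")
    keyed = [
        {(p.chrom, p.start, p.end): p.value for p in track} for track in tracks
    ]
    common = set(keyed[0])
    union = set(keyed[0])
    for k in keyed[1:]:
        common &= set(k)
        union |= set(k)
    merged = [
        ProbeSignal(c, s, e, sum(k[(c, s, e)] for k in keyed) / len(keyed))
        for (c, s, e) in common
    ]
    merged.sort(key=lambda p: (p.chrom, p.start, p.end))
    return merged, len(union) - len(common)


def read_genes_bed(path: str | Path) -> list[GeneRecord]:
    """Read gene spans from a BED6(+) file. Duplicate gene ids are an error."""
    path = Path(path)
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom = fields[0]
            start = _parse_int(fields[1], path, lineno, "start")
            end = _parse_int(fields[2], path, lineno, "end")
            name = fields[3]
            strand = fields[5]
            if name in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            genes.append(GeneRecord(name, chrom, strand, start, end))
    if not genes:
        raise ParseError(f"{path}: no gene records")
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.tx_end))
    return genes


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Read a log2 expression table (gene_id + one column per replicate).

    Returns gene_id -> mean over replicate columns.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need gene_id plus >=1 replicate column")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    means = df.iloc[:, 1:].mean(axis=1)
    return dict(zip(ids, means.astype(float)))


def attach_expression(
    genes: Sequence[GeneRecord], expression: dict[str, float]
) -> tuple[list[GeneRecord], int]:
    """Attach expression values to genes; returns (genes, n_missing)."""
    out: list[GeneRecord] = []
    n_missing = 0
    for g in genes:
        if g.gene_id in expression:
            out.append(replace_gene(g, expression=expression[g.gene_id]))
        else:
            n_missing += 1
            out.append(replace_gene(g, expression=None))
    return out, n_missing


def replace_gene(gene: GeneRecord, **kwargs) -> GeneRecord:
    """Copy a GeneRecord with some fields replaced."""
    data = dict(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        tx_start=gene.tx_start,
        tx_end=gene.tx_end,
        expression=gene.expression,
        genic_signal=gene.genic_signal,
    )
    data.update(kwargs)
    return GeneRecord(**data)


def read_interval_values(path: str | Path) -> list[IntervalValue]:
    """Read a bedGraph-dialect file (4 columns, 0-based half-open).

    Input may be unsorted; output is sorted. Overlapping intervals are an
    error naming the first offending pair.
    """
    path = Path(path)
    records: list[IntervalValue] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: bedGraph requires 4 columns")
            records.append(
                IntervalValue(
                    fields[0],
                    _parse_int(fields[1], path, lineno, "start"),
                    _parse_int(fields[2], path, lineno, "end"),
                    _parse_float(fields[3], path, lineno, "value"),
                )
            )
    if not records:
        raise ParseError(f"{path}: no interval records")
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    _check_non_overlapping(records, str(path))
    return records


def _check_non_overlapping(records: Sequence[IntervalValue], origin: str) -> None:
    for prev, cur in zip(records, records[1:]):
        if prev.chrom == cur.chrom and cur.start < prev.end:
            raise ValidationError(
                f"{origin}: overlapping intervals "
                f"{prev.chrom}:{prev.start}-{prev.end} and "
                f"{cur.chrom}:{cur.start}-{cur.end}"
            )


def read_chrom_sizes(path: str | Path) -> GenomeAssembly:
    """Read a 2-column chrom.sizes TSV."""
    path = Path(path)
    chroms: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: chrom.sizes requires 2 columns")
            chroms.append((fields[0], _parse_int(fields[1], path, lineno, "length")))
    if not chroms:
        raise ParseError(f"{path}: no chromosomes")
    return GenomeAssembly(tuple(chroms))


def write_bedgraph(track: Iterable[IntervalValue], path: str | Path) -> None:
    """Write a sorted, non-overlapping bedGraph file."""
    records = sorted(track, key=lambda r: (r.chrom, r.start, r.end))
    _check_non_overlapping(records, f"write_bedgraph({path})")
    with open(path, "wt") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{_FLOAT_FMT % r.value}\n")


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for name, length in assembly.items():
            fh.write(f"{name}\t{length}\n")


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as TSV with header, 6-significant-digit floats."""
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
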