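"""Non-overlapping genomic binning and the gene-density association summary.

Chromosomes are tiled from 0 with a fixed bin size; the terminal partial bin
is kept and flagged. Probes are assigned to bins by midpoint, genes by their
strand-aware 5' start (default) or by span overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io_formats import GeneRecord, GenomeAssembly, ProbeSignal

__all__ = [
    "GenomeBin",
    "BinGrid",
    "DensityAssociation",
    "make_bins",
    "mean_signal_per_bin",
    "count_genes_per_bin",
    "density_association",
    "bins_to_dataframe",
]


@dataclass(slots=True)
class GenomeBin:
    chrom: str
    start: int
    end: int
    partial: bool = False
    n_probes: int = 0
    mean_signal: float | None = None
    gene_count: int = 0
    lamin: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BinGrid:
    """Fixed-size tiling of an assembly; supports O(1) position lookup."""

    assembly: GenomeAssembly
    bin_size: int
    bins: list[GenomeBin]
    _offsets: dict[str, int] = field(default_factory=dict, repr=False)

    def __iter__(self) -> Iterator[GenomeBin]:
        return iter(self.bins)

    def __len__(self) -> int:
        return len(self.bins)

    def locate(self, chrom: str, pos: int) -> GenomeBin | None:
        """Bin containing (chrom, pos), or None for unknown chrom / out of range."""
        if chrom not in self._offsets:
            return None
        if pos < 0 or pos >= self.assembly.length(chrom):
            return None
        return self.bins[self._offsets[chrom] + pos // self.bin_size]

    def bins_overlapping(self, chrom: str, start: int, end: int) -> list[GenomeBin]:
        if chrom not in self._offsets or end <= 0:
            return []
        length = self.assembly.length(chrom)
        start = max(start, 0)
        end = min(end, length)
        if start >= end:
            return []
        first = start // self.bin_size
        last = (end - 1) // self.bin_size
        off = self._offsets[chrom]
        return self.bins[off + first : off + last + 1]


def make_bins(assembly: GenomeAssembly, bin_size: int) -> BinGrid:
    """Tile every chromosome from 0; keep (and flag) the final partial bin."""
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    bins: list[GenomeBin] = []
    offsets: dict[str, int] = {}
    for chrom, length in assembly.items():
        offsets[chrom] = len(bins)
        for start in range(0, length, bin_size):
            end = min(start + bin_size, length)
            bins.append(GenomeBin(chrom, start, end, partial=(end - start) < bin_size))
    return BinGrid(assembly, bin_size, bins, offsets)


def mean_signal_per_bin(
    grid: BinGrid, probes: Sequence[ProbeSignal], min_probes: int = 1
) -> BinGrid:
    """Average probe values per bin (assignment by probe midpoint).

    Bins holding fewer than ``min_probes`` probes get mean_signal None.
    Probes on chromosomes absent from the grid are ignored (not counted).
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for p in probes:
        b = grid.locate(p.chrom, p.midpoint)
        if b is None:
            continue
        key = id(b)
        sums[key] = sums.get(key, 0.0) + p.value
        counts[key] = counts.get(key, 0) + 1
    for b in grid:
        n = counts.get(id(b), 0)
        b.n_probes = n
        b.mean_signal = (sums[id(b)] / n) if n >= min_probes and n > 0 else None
    return grid


def count_genes_per_bin(
    grid: BinGrid, genes: Sequence[GeneRecord], rule: str = "tss"
) -> int:
    """Count genes per bin; returns the number of skipped genes.

    ``tss``: each gene counted once, in the bin holding its strand-aware 5'
    start. ``overlap``: counted in every bin its span intersects. Genes on
    chromosomes missing from the assembly are skipped with a warning.
    """
    if rule not in ("tss", "overlap"):
        raise ValidationError(f"unknown gene counting rule {rule!r}")
    for b in grid:
        b.gene_count = 0
    n_skipped = 0
    for g in genes:
        if g.chrom not in grid.assembly:
            n_skipped += 1
            continue
        if rule == "tss":
            b = grid.locate(g.chrom, g.five_prime)
            if b is None:
                n_skipped += 1
                continue
            b.gene_count += 1
        else:
            hit = grid.bins_overlapping(g.chrom, g.tx_start, g.tx_end)
            if not hit:
                n_skipped += 1
                continue
            for b in hit:
                b.gene_count += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} genes outside the assembly were skipped")
    return n_skipped


@dataclass(frozen=True)
class GroupSummary:
    n_bins: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class DensityAssociation:
    """Per-gene-count signal summaries plus the (uncapped) Pearson r."""

    groups: dict[int, GroupSummary]
    pearson_r: float
    r_pvalue: float
    cap: int
    n_bins: int
    degenerate: bool = False


def density_association(grid: BinGrid, cap: int = 10) -> DensityAssociation:
    """Summarize mean signal by gene count over bins with defined signal.

    Gene counts >= ``cap`` are pooled for the group summaries; the Pearson
    correlation always uses the uncapped counts.
    """
    usable = [b for b in grid if b.mean_signal is not None]
    if len(usable) < 3:
        raise ValidationError("density_association needs >=3 bins with signal")
    counts = np.array([b.gene_count for b in usable], dtype=float)
    signal = np.array([b.mean_signal for b in usable], dtype=float)
    degenerate = np.ptp(counts) == 0 or np.ptp(signal) == 0
    if degenerate:
        r, p = float("nan"), float("nan")
    else:
        r, p = stats.pearsonr(counts, signal)
    groups: dict[int, GroupSummary] = {}
    capped = np.minimum(counts.astype(int), cap)
    for c in sorted(set(capped)):
        vals = signal[capped == c]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        groups[int(c)] = GroupSummary(len(vals), float(med), float(q1), float(q3))
    return DensityAssociation(groups, float(r), float(p), cap, len(usable), degenerate)


def bins_to_dataframe(grid: BinGrid) -> pd.DataFrame:
    """Per-bin export table."""
    return pd.DataFrame(
        {
            "chrom": [b.chrom for b in grid],
            "start": [b.start for b in grid],
            "end": [b.end for b in grid],
            "partial": [int(b.partial) for b in grid],
            "n_probes": [b.n_probes for b in grid],
            "mean_signal": [b.mean_signal for b in grid],
            "gene_count": [b.gene_count for b in grid],
            "lamin": [b.lamin for b in grid],
        }
    )
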