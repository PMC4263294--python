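"""Chain-file based interval remapping between assemblies.

Implements UCSC chain parsing and region-style interval conversion with a
minimum mapped-fraction criterion (``min_blocks``). An interval maps through
a single chain to the envelope (min..max) of the destination positions of
its aligned bases; negative destination strand is handled by coordinate
reflection. When two or more chains satisfy the criterion the interval
fails as ambiguous unless best-chain selection is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .io_formats import IntervalValue, _open_text

__all__ = [
    "Chain",
    "ChainSet",
    "LiftoverParams",
    "MapResult",
    "MapReport",
    "parse_chain",
    "parse_chain_text",
    "map_interval",
    "map_profile",
]

DELETED = "deleted"
PARTIALLY_DELETED = "partially_deleted"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LiftoverParams:
    min_blocks: float = 0.1
    best_chain: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.min_blocks <= 1:
            raise ValidationError("min_blocks must be in (0, 1]")


@dataclass
class Chain:
    """One chain: colinear gapped alignment of a source (t) to a destination (q) region.

    Block arrays: ``sizes[i]`` aligned bases, then ``dt[i]``/``dq[i]`` gap
    bases on t/q before the next block (0 for the final block). Coordinates
    follow the chain format: t strand is always '+'; q coordinates are on
    the q strand and reflect through q_size when q_strand is '-'.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    sizes: np.ndarray
    dt: np.ndarray
    dq: np.ndarray
    t_block_starts: np.ndarray = field(init=False, repr=False)
    q_block_starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.q_strand not in ("+", "-"):
            raise ParseError(f"chain {self.chain_id}: bad q strand {self.q_strand!r}")
        if np.any(self.sizes < 1):
            raise ParseError(f"chain {self.chain_id}: block sizes must be >= 1")
        t_span = int(np.sum(self.sizes + self.dt))
        q_span = int(np.sum(self.sizes + self.dq))
        if t_span != self.t_end - self.t_start:
            raise ParseError(
                f"chain {self.chain_id}: block sums span {t_span} t-bases, "
                f"header says {self.t_end - self.t_start}"
            )
        if q_span != self.q_end - self.q_start:
            raise ParseError(
                f"chain {self.chain_id}: block sums span {q_span} q-bases, "
                f"header says {self.q_end - self.q_start}"
            )
        t_starts = self.t_start + np.concatenate(
            ([0], np.cumsum(self.sizes + self.dt)[:-1])
        )
        q_starts = self.q_start + np.concatenate(
            ([0], np.cumsum(self.sizes + self.dq)[:-1])
        )
        self.t_block_starts = t_starts.astype(np.int64)
        self.q_block_starts = q_starts.astype(np.int64)


@dataclass
class ChainSet:
    chains: list[Chain]
    _by_t: dict[str, list[Chain]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_t = {}
        for c in self.chains:
            self._by_t.setdefault(c.t_name, []).append(c)

    def __len__(self) -> int:
        return len(self.chains)

    def on_source(self, t_name: str) -> list[Chain]:
        return self._by_t.get(t_name, [])


def parse_chain(path: str | Path) -> ChainSet:
    """Parse a UCSC chain file (gzip accepted by extension)."""
    with _open_text(path) as fh:
        return parse_chain_text(fh.read(), origin=str(path))


def parse_chain_text(text: str, origin: str = "<string>") -> ChainSet:
    chains: list[Chain] = []
    header: list[str] | None = None
    sizes: list[int] = []
    dts: list[int] = []
    dqs: list[int] = []

    def finish() -> None:
        nonlocal header
        if header is None:
            return
        if not sizes:
            raise ParseError(f"{origin}: chain {header[12]} has no blocks")
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = header
        if t_strand != "+":
            raise ParseError(f"{origin}: chain {chain_id}: t strand must be '+'")
        chains.append(
            Chain(
                score=float(score),
                t_name=t_name,
                t_size=int(t_size),
                t_start=int(t_start),
                t_end=int(t_end),
                q_name=q_name,
                q_size=int(q_size),
                q_strand=q_strand,
                q_start=int(q_start),
                q_end=int(q_end),
                chain_id=int(chain_id),
                sizes=np.array(sizes, dtype=np.int64),
                dt=np.array(dts, dtype=np.int64),
                dq=np.array(dqs, dtype=np.int64),
            )
        )
        header = None
        sizes.clear()
        dts.clear()
        dqs.clear()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if fields[0] == "chain":
            finish()
            if len(fields) != 13:
                raise ParseError(f"{origin}:{lineno}: chain header needs 13 fields")
            header = fields
        else:
            if header is None:
                raise ParseError(f"{origin}:{lineno}: block line outside a chain")
            try:
                nums = [int(x) for x in fields]
            except ValueError:
                raise ParseError(f"{origin}:{lineno}: bad block line {line!r}") from None
            if len(nums) == 1:
                sizes.append(nums[0])
                dts.append(0)
                dqs.append(0)
            elif len(nums) == 3:
                sizes.append(nums[0])
                dts.append(nums[1])
                dqs.append(nums[2])
            else:
                raise ParseError(f"{origin}:{lineno}: block line needs 1 or 3 fields")
    finish()
    if not chains:
        raise ParseError(f"{origin}: no chains found")
    return ChainSet(chains)


@dataclass(frozen=True)
class MapResult:
    ok: bool
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    reason: str | None = None
    chain_id: int | None = None
    mapped_fraction: float = 0.0


def _chain_overlap(chain: Chain, start: int, end: int):
    """Aligned bases of [start, end) within one chain.

    Returns (n_aligned, plus_start, plus_end) with destination coordinates
    on the q plus strand, or None when no base aligns.
    """
    tb = chain.t_block_starts
    qb = chain.q_block_starts
    lo = np.maximum(start, tb)
    hi = np.minimum(end, tb + chain.sizes)
    lens = hi - lo
    mask = lens > 0
    if not np.any(mask):
        return None
    n_aligned = int(lens[mask].sum())
    q_lo = qb[mask] + (lo[mask] - tb[mask])
    q_hi = qb[mask] + (hi[mask] - tb[mask])
    q_min = int(q_lo.min())
    q_max = int(q_hi.max())
    if chain.q_strand == "-":
        return n_aligned, chain.q_size - q_max, chain.q_size - q_min
    return n_aligned, q_min, q_max


def map_interval(
    chrom: str,
    start: int,
    end: int,
    chains: ChainSet,
    params: LiftoverParams | None = None,
) -> MapResult:
    """Map one source interval; see module docstring for semantics."""
    params = params or LiftoverParams()
    if start >= end:
        raise ValidationError(f"interval {chrom}:{start}-{end}: start must be < end")
    length = end - start
    candidates = []  # (fraction, n_aligned, chain, plus_start, plus_end)
    for chain in chains.on_source(chrom):
        hit = _chain_overlap(chain, start, end)
        if hit is None:
            continue
        n_aligned, p_start, p_end = hit
        candidates.append((n_aligned / length, n_aligned, chain, p_start, p_end))
    if not candidates:
        return MapResult(False, reason=DELETED)
    eligible = [c for c in candidates if c[0] >= params.min_blocks]
    if not eligible:
        best = max(c[0] for c in candidates)
        return MapResult(False, reason=PARTIALLY_DELETED, mapped_fraction=best)
    if len(eligible) > 1:
        if not params.best_chain:
            return MapResult(
                False, reason=AMBIGUOUS, mapped_fraction=max(c[0] for c in eligible)
            )
        # score desc, then more aligned bases, then lowest chain id
        eligible.sort(key=lambda c: (-c[2].score, -c[1], c[2].chain_id))
    frac, _, chain, p_start, p_end = eligible[0]
    return MapResult(
        True,
        chrom=chain.q_name,
        start=p_start,
        end=p_end,
        chain_id=chain.chain_id,
        mapped_fraction=frac,
    )


@dataclass
class MapReport:
    n_input: int = 0
    n_mapped: int = 0
    failures: dict[str, int] = field(default_factory=dict)
    n_collided: int = 0
    unmapped: list[tuple[IntervalValue, str]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv, _ in self.unmapped],
                "start": [iv.start for iv, _ in self.unmapped],
                "end": [iv.end for iv, _ in self.unmapped],
                "value": [iv.value for iv, _ in self.unmapped],
                "reason": [r for _, r in self.unmapped],
            }
        )


def map_profile(
    track: Sequence[IntervalValue],
    chains: ChainSet,
    params: LiftoverParams | None = None,
) -> tuple[list[IntervalValue], MapReport]:
    """Map a non-overlapping valued profile interval by interval.

    Values are carried unchanged. Mapped intervals that overlap an earlier
    (input-order) mapped interval on the destination are dropped and
    counted as collisions. Output is sorted by (chrom, start).
    """
    params = params or LiftoverParams()
    report = MapReport(n_input=len(track))
    kept: dict[str, list[tuple[int, int]]] = {}  # chrom -> sorted (start, end)
    out: list[IntervalValue] = []
    import bisect

    for iv in track:
        res = map_interval(iv.chrom, iv.start, iv.end, chains, params)
        if not res.ok:
            report.failures[res.reason] = report.failures.get(res.reason, 0) + 1
            report.unmapped.append((iv, res.reason))
            continue
        spans = kept.setdefault(res.chrom, [])
        i = bisect.bisect_right(spans, (res.start, res.end))
        collides = (i > 0 and spans[i - 1][1] > res.start) or (
            i < len(spans) and spans[i][0] < res.end
        )
        if collides:
            report.n_collided += 1
            report.unmapped.append((iv, "collision"))
            continue
        spans.insert(i, (res.start, res.end))
        out.append(IntervalValue(res.chrom, res.start, res.end, iv.value))
        report.n_mapped += 1
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out, report
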