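"""Sliding-window smoothing of probe-level signal.

Two views of the same operation: a per-probe smooth (each probe replaced by
the mean of all probes within ``halfwidth`` bases of its midpoint, in both
directions) and a fixed-step window track for export/plotting. Windows never
cross chromosome boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import GenomeAssembly, IntervalValue, ProbeSignal

__all__ = ["SmoothingParams", "smooth_per_probe", "window_track"]


@dataclass(frozen=True)
class SmoothingParams:
    halfwidth: int = 500_000
    min_probes: int = 1

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValidationError("halfwidth must be > 0")
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")


def _chrom_groups(probes: Sequence[ProbeSignal]):
    """Yield (chrom, slice) for runs of consecutive equal chromosomes."""
    start = 0
    for i in range(1, len(probes) + 1):
        if i == len(probes) or probes[i].chrom != probes[start].chrom:
            yield probes[start].chrom, slice(start, i)
            start = i


def _require_sorted(mids: np.ndarray, chrom: str) -> None:
    if np.any(np.diff(mids) < 0):
        raise ValidationError(f"probes on {chrom} are not sorted by position")


def smooth_per_probe(
    probes: Sequence[ProbeSignal], params: SmoothingParams | None = None
) -> np.ndarray:
    """Per-probe window mean, |mid_j - mid_i| <= halfwidth, boundary inclusive.

    Input must be sorted by position within each chromosome; output is
    aligned with the input order and has the same length. O(n) per
    chromosome via cumulative sums.
    """
    params = params or SmoothingParams()
    out = np.empty(len(probes), dtype=float)
    for chrom, sl in _chrom_groups(probes):
        mids = np.array([p.midpoint for p in probes[sl]], dtype=np.int64)
        vals = np.array([p.value for p in probes[sl]], dtype=float)
        _require_sorted(mids, chrom)
        lo = np.searchsorted(mids, mids - params.halfwidth, side="left")
        hi = np.searchsorted(mids, mids + params.halfwidth, side="right")
        csum = np.concatenate(([0.0], np.cumsum(vals)))
        out[sl] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def window_track(
    probes: Sequence[ProbeSignal],
    window: int = 1_000_000,
    step: int | None = None,
    min_probes: int = 1,
    assembly: GenomeAssembly | None = None,
) -> list[IntervalValue]:
    """Mean probe value per window of fixed size placed every ``step`` bases.

    A probe belongs to a window when its midpoint lies in
    [start, start + window). Windows holding fewer than ``min_probes``
    probes emit no record. With an assembly, windows tile up to the
    chromosome length and are clipped to it; otherwise they stop at the
    last probe.
    """
    step = window if step is None else step
    if step <= 0 or window <= 0:
        raise ValidationError("window and step must be > 0")
    if step > window:
        raise ValidationError("step must be <= window")
    track: list[IntervalValue] = []
    for chrom, sl in _chrom_groups(probes):
        mids = np.array([p.midpoint for p in probes[sl]], dtype=np.int64)
        vals = np.array([p.value for p in probes[sl]], dtype=float)
        _require_sorted(mids, chrom)
        limit = assembly.length(chrom) if assembly is not None else int(mids[-1]) + 1
        starts = np.arange(0, limit, step, dtype=np.int64)
        lo = np.searchsorted(mids, starts, side="left")
        hi = np.searchsorted(mids, starts + window, side="left")
        csum = np.concatenate(([0.0], np.cumsum(vals)))
        for s, l, h in zip(starts, lo, hi):
            n = h - l
            if n < min_probes:
                continue
            end = int(s) + window
            if assembly is not None:
                end = min(end, assembly.length(chrom))
            track.append(IntervalValue(chrom, int(s), end, (csum[h] - csum[l]) / n))
    return track
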