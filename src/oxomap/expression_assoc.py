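"""Genic signal averaging and expression-group comparisons.

A gene's signal is the mean of probe values whose midpoints fall inside its
transcription span. Genes are split by expression (at the median, or into
top/bottom quantile fractions) and the groups compared with a two-sided
pooled-variance Student's t-test (Welch optional).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticError, ValidationError
from .io_formats import GeneRecord, ProbeSignal, replace_gene

__all__ = [
    "GroupComparison",
    "genic_signal",
    "split_by_expression",
    "compare_groups",
    "histogram_export",
]


@dataclass(frozen=True)
class GroupComparison:
    group_a_n: int
    group_b_n: int
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float


def genic_signal(
    genes: Sequence[GeneRecord], probes: Sequence[ProbeSignal]
) -> list[GeneRecord]:
    """Attach the mean probe value within [tx_start, tx_end) to each gene.

    Overlapping genes each average their own probes independently. Genes
    whose span contains no probe midpoint get genic_signal None.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in probes}:
        sub = [p for p in probes if p.chrom == chrom]
        mids = np.array([p.midpoint for p in sub], dtype=np.int64)
        if np.any(np.diff(mids) < 0):
            raise ValidationError(f"probes on {chrom} are not sorted by position")
        vals = np.array([p.value for p in sub], dtype=float)
        by_chrom[chrom] = (mids, np.concatenate(([0.0], np.cumsum(vals))))
    out: list[GeneRecord] = []
    for g in genes:
        if g.chrom not in by_chrom:
            out.append(replace_gene(g, genic_signal=None))
            continue
        mids, csum = by_chrom[g.chrom]
        lo = int(np.searchsorted(mids, g.tx_start, side="left"))
        hi = int(np.searchsorted(mids, g.tx_end, side="left"))
        if hi > lo:
            out.append(replace_gene(g, genic_signal=(csum[hi] - csum[lo]) / (hi - lo)))
        else:
            out.append(replace_gene(g, genic_signal=None))
    return out


def split_by_expression(
    genes: Sequence[GeneRecord], mode: str = "median", q: float = 0.25
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split genes into (high, low) expression groups.

    Only genes with both expression and genic_signal participate. ``median``
    mode assigns expression > median to high and <= median (ties included)
    to low. ``top_bottom`` keeps the top and bottom q-fractions by
    expression rank and discards the middle.
    """
    usable = [g for g in genes if g.expression is not None and g.genic_signal is not None]
    if len(usable) < 4:
        raise ValidationError("need >=4 genes with expression and genic signal")
    expr = np.array([g.expression for g in usable], dtype=float)
    if mode == "median":
        med = float(np.median(expr))
        high = [g for g, e in zip(usable, expr) if e > med]
        low = [g for g, e in zip(usable, expr) if e <= med]
    elif mode == "top_bottom":
        if not 0 < q < 0.5:
            raise ValidationError("top_bottom fraction q must be in (0, 0.5)")
        k = max(1, int(len(usable) * q))
        order = np.argsort(expr, kind="stable")
        low = [usable[i] for i in order[:k]]
        high = [usable[i] for i in order[-k:]]
    else:
        raise ValidationError(f"unknown split mode {mode!r}")
    if not high or not low:
        raise ValidationError("expression split produced an empty group")
    return high, low


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sided Student's t-test (pooled variance unless welch=True)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >=2 values")
    pooled_ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    if not welch and pooled_ss == 0:
        raise DegenerateStatisticError("zero pooled variance: t undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group_a_n=len(a),
        group_b_n=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def histogram_export(
    values: Sequence[float], n_bins: int = 30, range_: tuple[float, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(edges, counts) for a plain histogram export."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=n_bins, range=range_)
    return edges, counts
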