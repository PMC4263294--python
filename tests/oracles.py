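"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized/block-arithmetic code paths of the
package: smoothing is checked by an O(n^2) scan, chain mapping by walking
every base through the block layout.
"""

from __future__ import annotations

import numpy as np

from oxomap.liftover import Chain, ChainSet


def brute_smooth(probes, halfwidth: int) -> np.ndarray:
    """O(n^2) per-probe window mean."""
    out = np.empty(len(probes))
    for i, p in enumerate(probes):
        vals = [
            q.value
            for q in probes
            if q.chrom == p.chrom and abs(q.midpoint - p.midpoint) <= halfwidth
        ]
        out[i] = sum(vals) / len(vals)
    return out


def random_chain(
    rng: np.random.Generator,
    chain_id: int,
    t_name: str = "chrT",
    q_strand: str | None = None,
) -> Chain:
    """A small random but internally consistent chain."""
    n_blocks = int(rng.integers(1, 6))
    sizes = rng.integers(1, 60, n_blocks).astype(np.int64)
    dt = rng.integers(0, 40, n_blocks).astype(np.int64)
    dq = rng.integers(0, 40, n_blocks).astype(np.int64)
    dt[-1] = dq[-1] = 0
    t_start = int(rng.integers(0, 300))
    q_start = int(rng.integers(0, 300))
    t_end = t_start + int((sizes + dt).sum())
    q_end = q_start + int((sizes + dq).sum())
    strand = q_strand if q_strand is not None else ("-" if rng.random() < 0.5 else "+")
    return Chain(
        score=float(rng.integers(1, 1000)),
        t_name=t_name,
        t_size=t_end + int(rng.integers(0, 100)),
        t_start=t_start,
        t_end=t_end,
        q_name="chrQ",
        q_size=q_end + int(rng.integers(0, 100)),
        q_strand=strand,
        q_start=q_start,
        q_end=q_end,
        chain_id=chain_id,
        sizes=sizes,
        dt=dt,
        dq=dq,
    )


def walk_chain_bases(chain: Chain):
    """Yield (t_pos, q_plus_pos) for every aligned base of a chain."""
    t = chain.t_start
    q = chain.q_start
    for size, dt_, dq_ in zip(chain.sizes, chain.dt, chain.dq):
        for k in range(int(size)):
            qq = q + k
            plus = chain.q_size - 1 - qq if chain.q_strand == "-" else qq
            yield t + k, plus
        t += int(size + dt_)
        q += int(size + dq_)


def oracle_map_interval(
    chrom: str,
    start: int,
    end: int,
    chains: ChainSet,
    min_blocks: float,
    best_chain: bool = False,
):
    """Per-base reference for map_interval.

    Returns ("mapped", (q_name, q_start, q_end)) or (reason, None).
    """
    cands = []
    for chain in chains.chains:
        if chain.t_name != chrom:
            continue
        plus_positions = [
            plus for t_pos, plus in walk_chain_bases(chain) if start <= t_pos < end
        ]
        if plus_positions:
            cands.append(
                (
                    len(plus_positions) / (end - start),
                    len(plus_positions),
                    chain,
                    min(plus_positions),
                    max(plus_positions) + 1,
                )
            )
    if not cands:
        return "deleted", None
    eligible = [c for c in cands if c[0] >= min_blocks]
    if not eligible:
        return "partially_deleted", None
    if len(eligible) > 1 and not best_chain:
        return "ambiguous", None
    eligible.sort(key=lambda c: (-c[2].score, -c[1], c[2].chain_id))
    _, _, chain, lo, hi = eligible[0]
    return "mapped", (chain.q_name, lo, hi)
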