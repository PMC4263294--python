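"""Ground-truth simulator for every stage of the pipeline.

Generates a toy genome with lamina-associated domains (LADs), a bimodal
lamin profile with sharp domain borders, probe-level damage signal with an
additive in-LAD effect, gene annotations depleted in LAD interiors, an
expression table, and a derived second assembly with a chain file carrying
indels and an optional inversion. All randomness flows from one seed
through named, splittable substreams so each artifact is reproducible in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    GeneRecord,
    GenomeAssembly,
    IntervalValue,
    ProbeSignal,
    write_bedgraph,
    write_chrom_sizes,
    write_tsv,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Dataset",
    "ChainPair",
    "simulate_dataset",
    "simulate_chain_pair",
    "simulate_derived_lamin",
]

# named substreams carved off the master seed (order is part of the contract)
_STREAMS = ("lads", "lamin", "probes", "genes", "expression", "chain", "derived_lamin")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_lengths: tuple[int, ...] = (20_000_000,)
    probe_spacing: int = 6_000
    probe_length: int = 60
    lad_length_range: tuple[int, int] = (100_000, 10_000_000)
    lad_genome_fraction: float = 0.4
    lamin_mu: float = 2.0
    lamin_sd: float = 0.5
    lamin_tile: int = 10_000
    oxo_delta: float = 0.38
    oxo_baseline: float = 0.0
    oxo_sd: float = 0.5
    gene_density_ratio: float = 5.0
    n_genes: int = 300
    gene_edge_scale: int = 100_000
    gene_length_log_mean: float = float(np.log(20_000))
    gene_length_log_sd: float = 0.8
    expression_log2_mean: float = 6.0
    expression_log2_sd: float = 2.0
    expression_replicates: int = 2
    expression_replicate_sd: float = 0.25
    chain_event_rate: float = 1.0
    chain_indel_range: tuple[int, int] = (1_000, 50_000)
    chain_inversion: bool = True

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be > 0")
        if not 0 < self.lad_genome_fraction < 1:
            raise ValidationError("lad_genome_fraction must be in (0, 1)")
        if self.oxo_sd <= 0:
            raise ValidationError("oxo_sd must be > 0")
        if self.probe_spacing <= 0 or self.lamin_tile <= 0:
            raise ValidationError("spacings must be > 0")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]

    @property
    def assembly(self) -> GenomeAssembly:
        return GenomeAssembly(tuple(zip(self.chrom_names, self.chrom_lengths)))


@dataclass
class GroundTruth:
    lads: dict[str, list[tuple[int, int]]]
    probe_in_lad: np.ndarray
    gene_in_lad: np.ndarray
    true_delta: float
    true_baseline: float
    realized_lad_fraction: float
    p_gene_in_lad: float

    def to_json_dict(self) -> dict:
        return {
            "lads": {c: [[int(s), int(e)] for s, e in ivs] for c, ivs in self.lads.items()},
            "probe_in_lad": [int(x) for x in self.probe_in_lad],
            "gene_in_lad": [int(x) for x in self.gene_in_lad],
            "true_delta": self.true_delta,
            "true_baseline": self.true_baseline,
            "realized_lad_fraction": self.realized_lad_fraction,
            "p_gene_in_lad": self.p_gene_in_lad,
        }


class _LadIndex:
    """Point-membership lookup over per-chromosome LAD intervals."""

    def __init__(self, lads: dict[str, list[tuple[int, int]]]):
        self._starts = {c: np.array([s for s, _ in ivs], dtype=np.int64) for c, ivs in lads.items()}
        self._ends = {c: np.array([e for _, e in ivs], dtype=np.int64) for c, ivs in lads.items()}

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos), dtype=bool)
        ends = self._ends[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < ends[idx[ok]]
        return out


def _draw_lads(
    rng: np.random.Generator, length: int, config: SimulationConfig
) -> list[tuple[int, int]]:
    """Draw LADs covering ~lad_genome_fraction of one chromosome.

    Lengths are log-uniform on the configured range, truncated to hit the
    coverage target exactly; gaps between LADs follow a Dirichlet split of
    the remaining sequence so the realized fraction is tight.
    """
    target = int(round(config.lad_genome_fraction * length))
    lo, hi = config.lad_length_range
    lens: list[int] = []
    total = 0
    while total < target:
        l = int(round(np.exp(rng.uniform(np.log(lo), np.log(min(hi, length))))))
        l = min(l, target - total)
        l = max(l, 1)
        lens.append(l)
        total += l
    n = len(lens)
    gap_total = length - total
    weights = rng.dirichlet(np.ones(n + 1))
    gaps = np.floor(weights * gap_total).astype(int)
    gaps[-1] += gap_total - gaps.sum()
    lads: list[tuple[int, int]] = []
    cursor = 0
    for gap, l in zip(gaps[:-1], lens):
        cursor += int(gap)
        lads.append((cursor, cursor + l))
        cursor += l
    return lads


@dataclass
class Dataset:
    config: SimulationConfig
    assembly: GenomeAssembly
    probes: list[ProbeSignal]
    lamin: list[IntervalValue]
    genes: list[GeneRecord]
    expression_table: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts as plain-text files; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "chrom_sizes": outdir / "chrom.sizes",
            "probes_tsv": outdir / "probes.tsv",
            "probes_bedgraph": outdir / "probes.bedgraph",
            "lamin": outdir / "lamin.bedgraph",
            "genes": outdir / "genes.bed",
            "expression": outdir / "expression.tsv",
            "truth": outdir / "truth.json",
        }
        write_chrom_sizes(self.assembly, paths["chrom_sizes"])
        probe_df = pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.probes],
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "value": [p.value for p in self.probes],
            }
        )
        write_tsv(probe_df, paths["probes_tsv"])
        write_bedgraph(
            [IntervalValue(p.chrom, p.start, p.end, p.value) for p in self.probes],
            paths["probes_bedgraph"],
        )
        write_bedgraph(self.lamin, paths["lamin"])
        with open(paths["genes"], "wt") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.tx_start)):
                fh.write(
                    f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\n"
                )
        write_tsv(self.expression_table, paths["expression"])
        with open(paths["truth"], "wt") as fh:
            json.dump(self.truth.to_json_dict(), fh)
            fh.write("\n")
        return paths


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path | None = None
) -> Dataset:
    """Generate a full synthetic dataset (optionally written to ``outdir``)."""
    rngs = config.rngs()
    assembly = config.assembly

    lads: dict[str, list[tuple[int, int]]] = {}
    for chrom, length in assembly.items():
        lads[chrom] = _draw_lads(rngs["lads"], length, config)
    index = _LadIndex(lads)
    lad_bp = sum(e - s for ivs in lads.values() for s, e in ivs)
    realized_fraction = lad_bp / assembly.total_length

    lamin = _simulate_lamin_tiles(assembly, index, config, rngs["lamin"])
    probes, probe_in_lad = _simulate_probes(assembly, index, config, rngs["probes"])
    genes, gene_in_lad, p_gene_in_lad = _simulate_genes(
        assembly, lads, config, rngs["genes"]
    )
    genes, expr_table = _simulate_expression(genes, config, rngs["expression"])

    truth = GroundTruth(
        lads=lads,
        probe_in_lad=probe_in_lad,
        gene_in_lad=gene_in_lad,
        true_delta=config.oxo_delta,
        true_baseline=config.oxo_baseline,
        realized_lad_fraction=realized_fraction,
        p_gene_in_lad=p_gene_in_lad,
    )
    dataset = Dataset(config, assembly, probes, lamin, genes, expr_table, truth)
    if outdir is not None:
        dataset.write(outdir)
    return dataset


def _simulate_lamin_tiles(assembly, index, config, rng) -> list[IntervalValue]:
    out: list[IntervalValue] = []
    for chrom, length in assembly.items():
        starts = np.arange(0, length, config.lamin_tile, dtype=np.int64)
        ends = np.minimum(starts + config.lamin_tile, length)
        mids = (starts + ends) // 2
        in_lad = index.contains(chrom, mids)
        mu = np.where(in_lad, config.lamin_mu, -config.lamin_mu)
        vals = rng.normal(mu, config.lamin_sd)
        out.extend(
            IntervalValue(chrom, int(s), int(e), float(v))
            for s, e, v in zip(starts, ends, vals)
        )
    return out


def _simulate_probes(assembly, index, config, rng):
    probes: list[ProbeSignal] = []
    membership: list[np.ndarray] = []
    half = config.probe_length // 2
    for chrom, length in assembly.items():
        base = np.arange(config.probe_spacing // 2, length, config.probe_spacing)
        jitter = rng.integers(
            -config.probe_spacing // 4, config.probe_spacing // 4 + 1, size=len(base)
        )
        mids = np.clip(base + jitter, half, max(length - half, half + 1))
        mids = np.sort(mids)
        in_lad = index.contains(chrom, mids)
        vals = (
            config.oxo_baseline
            + config.oxo_delta * in_lad
            + rng.normal(0.0, config.oxo_sd, size=len(mids))
        )
        membership.append(in_lad)
        probes.extend(
            ProbeSignal(chrom, int(m - half), int(m + half), float(v))
            for m, v in zip(mids, vals)
        )
    return probes, np.concatenate(membership) if membership else np.array([], bool)


def _complement(lad_list: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    cursor = 0
    for s, e in lad_list:
        if s > cursor:
            out.append((cursor, s))
        cursor = e
    if cursor < length:
        out.append((cursor, length))
    return out


def _simulate_genes(assembly, lads, config, rng):
    """Place genes with density odds gene_density_ratio : 1 (inter-LAD : LAD).

    LAD genes concentrate near domain borders (exponential distance from
    the nearest edge) so LAD interiors form gene deserts, matching the
    depleted-interior structure the generator is meant to emulate.
    """
    if config.n_genes * 200 > assembly.total_length:
        raise ValidationError("n_genes cannot fit in the genome")
    lad_iv = [(c, s, e) for c, ivs in lads.items() for s, e in ivs]
    inter_iv = [
        (c, s, e)
        for c, _len in assembly.items()
        for s, e in _complement(lads[c], _len)
    ]
    lad_bp = sum(e - s for _, s, e in lad_iv)
    inter_bp = sum(e - s for _, s, e in inter_iv)
    p_lad = lad_bp / (lad_bp + config.gene_density_ratio * inter_bp)
    lad_weights = np.array([e - s for _, s, e in lad_iv], dtype=float)
    inter_weights = np.array([e - s for _, s, e in inter_iv], dtype=float)
    genes: list[GeneRecord] = []
    in_lad_flags = np.zeros(config.n_genes, dtype=bool)
    for i in range(config.n_genes):
        in_lad = bool(lad_iv) and rng.random() < p_lad
        if in_lad:
            j = rng.choice(len(lad_iv), p=lad_weights / lad_weights.sum())
            chrom, s, e = lad_iv[j]
            d = int(rng.exponential(config.gene_edge_scale))
            pos = s + d if rng.random() < 0.5 else e - 1 - d
            pos = int(np.clip(pos, s, e - 1))
        else:
            j = rng.choice(len(inter_iv), p=inter_weights / inter_weights.sum())
            chrom, s, e = inter_iv[j]
            pos = int(rng.integers(s, e))
        in_lad_flags[i] = in_lad
        strand = "+" if rng.random() < 0.5 else "-"
        glen = max(200, int(rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd)))
        chrom_len = assembly.length(chrom)
        if strand == "+":
            tx_start, tx_end = pos, min(pos + glen, chrom_len)
        else:
            tx_start, tx_end = max(pos + 1 - glen, 0), pos + 1
        if tx_end - tx_start < 2:
            tx_end = min(tx_start + 2, chrom_len)
            tx_start = tx_end - 2
        genes.append(GeneRecord(f"g{i:05d}", chrom, strand, tx_start, tx_end))
    return genes, in_lad_flags, p_lad


def _simulate_expression(genes, config, rng):
    base = rng.normal(config.expression_log2_mean, config.expression_log2_sd, len(genes))
    reps = base[:, None] + rng.normal(
        0.0, config.expression_replicate_sd, (len(genes), config.expression_replicates)
    )
    table = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes]}
        | {f"rep{j + 1}": reps[:, j] for j in range(config.expression_replicates)}
    )
    out = []
    for g, mean_expr in zip(genes, reps.mean(axis=1)):
        g.expression = float(mean_expr)
        out.append(g)
    return out, table


# ---------------------------------------------------------------------------
# paired assembly + chain file


@dataclass(frozen=True)
class ChainSegment:
    """A colinear match between the primary (a1) and derived (a2) assembly.

    ``inverted`` segments pair a2 position a2_start+k with a1 position
    a1_end-1-k; otherwise a2_start+k pairs with a1_start+k.
    """

    chrom: str
    a1_start: int
    a1_end: int
    a2_start: int
    a2_end: int
    inverted: bool = False

    @property
    def length(self) -> int:
        return self.a1_end - self.a1_start


@dataclass
class ChainPair:
    assembly1: GenomeAssembly
    assembly2: GenomeAssembly
    segments: dict[str, list[ChainSegment]]

    def chain_text(self) -> str:
        """Chain file mapping derived (t = a2) coordinates onto primary (q = a1)."""
        lines: list[str] = []
        chain_id = 0
        for chrom, _ in self.assembly2.items():
            segs = self.segments.get(chrom, [])
            plus = [s for s in segs if not s.inverted]
            q_size = self.assembly1.length(chrom)
            t_size = self.assembly2.length(chrom)
            if plus:
                chain_id += 1
                score = sum(s.length for s in plus)
                head = (
                    f"chain {score} {chrom} {t_size} + {plus[0].a2_start} "
                    f"{plus[-1].a2_end} {chrom} {q_size} + {plus[0].a1_start} "
                    f"{plus[-1].a1_end} {chain_id}"
                )
                lines.append(head)
                for a, b in zip(plus, plus[1:]):
                    lines.append(f"{a.length} {b.a2_start - a.a2_end} {b.a1_start - a.a1_end}")
                lines.append(f"{plus[-1].length}")
                lines.append("")
            for s in segs:
                if not s.inverted:
                    continue
                chain_id += 1
                head = (
                    f"chain {s.length} {chrom} {t_size} + {s.a2_start} {s.a2_end} "
                    f"{chrom} {q_size} - {q_size - s.a1_end} {q_size - s.a1_start} "
                    f"{chain_id}"
                )
                lines.append(head)
                lines.append(f"{s.length}")
                lines.append("")
        return "\n".join(lines) + "\n"

    def write_chain(self, path: str | Path) -> None:
        Path(path).write_text(self.chain_text())

    def project_intervals(
        self, chrom: str, intervals: list[tuple[int, int]]
    ) -> list[tuple[int, int]]:
        """Project primary-assembly intervals onto the derived assembly."""
        out: list[tuple[int, int]] = []
        for seg in self.segments.get(chrom, []):
            for s, e in intervals:
                lo, hi = max(s, seg.a1_start), min(e, seg.a1_end)
                if lo >= hi:
                    continue
                if seg.inverted:
                    out.append(
                        (seg.a2_start + (seg.a1_end - hi), seg.a2_start + (seg.a1_end - lo))
                    )
                else:
                    out.append(
                        (seg.a2_start + (lo - seg.a1_start), seg.a2_start + (hi - seg.a1_start))
                    )
        out.sort()
        merged: list[tuple[int, int]] = []
        for s, e in out:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def map_base(self, chrom: str, pos: int) -> int | None:
        """Per-base a2 -> a1 lookup (independent arithmetic for truth/oracles)."""
        for seg in self.segments.get(chrom, []):
            if seg.a2_start <= pos < seg.a2_end:
                k = pos - seg.a2_start
                return seg.a1_end - 1 - k if seg.inverted else seg.a1_start + k
        return None


def simulate_chain_pair(
    config: SimulationConfig, outdir: str | Path | None = None
) -> ChainPair:
    """Derive a second assembly by seeded indels plus one optional inversion."""
    rng = config.rngs()["chain"]
    assembly1 = config.assembly
    segments: dict[str, list[ChainSegment]] = {}
    a2_lengths: list[tuple[str, int]] = []
    lo, hi = config.chain_indel_range
    for chrom, length in assembly1.items():
        n_events = rng.poisson(config.chain_event_rate * length / 1e6)
        positions = np.sort(rng.integers(1, max(length, 2), size=n_events))
        segs: list[ChainSegment] = []
        a1 = a2 = 0
        for pos in positions:
            pos = int(pos)
            if pos <= a1:
                continue
            segs.append(ChainSegment(chrom, a1, pos, a2, a2 + (pos - a1)))
            a2 += pos - a1
            a1 = pos
            size = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            if rng.random() < 0.5:  # deletion: present only in a1
                a1 = min(a1 + size, length)
            else:  # insertion: present only in a2
                a2 += size
        if a1 < length:
            segs.append(ChainSegment(chrom, a1, length, a2, a2 + (length - a1)))
            a2 += length - a1
        segments[chrom] = segs
        a2_lengths.append((chrom, a2))
    if config.chain_inversion and config.chain_event_rate > 0:
        _plant_inversion(segments, rng)
    pair = ChainPair(assembly1, GenomeAssembly(tuple(a2_lengths)), segments)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pair.write_chain(outdir / "toy.chain")
        write_chrom_sizes(pair.assembly2, outdir / "chrom2.sizes")
    return pair


def _plant_inversion(segments: dict[str, list[ChainSegment]], rng) -> None:
    """Invert a sub-segment of the longest match segment, if long enough."""
    best = None
    for chrom, segs in segments.items():
        for i, s in enumerate(segs):
            if best is None or s.length > best[2].length:
                best = (chrom, i, s)
    if best is None:
        return
    chrom, i, seg = best
    if seg.length < 600_000:
        return
    inv_len = int(rng.integers(200_000, min(seg.length // 2, 2_000_000)))
    off = int(rng.integers(1, seg.length - inv_len))
    left = ChainSegment(
        chrom, seg.a1_start, seg.a1_start + off, seg.a2_start, seg.a2_start + off
    )
    mid = ChainSegment(
        chrom,
        seg.a1_start + off,
        seg.a1_start + off + inv_len,
        seg.a2_start + off,
        seg.a2_start + off + inv_len,
        inverted=True,
    )
    right = ChainSegment(
        chrom,
        seg.a1_start + off + inv_len,
        seg.a1_end,
        seg.a2_start + off + inv_len,
        seg.a2_end,
    )
    segments[chrom][i : i + 1] = [left, mid, right]


def simulate_derived_lamin(
    pair: ChainPair,
    lads: dict[str, list[tuple[int, int]]],
    config: SimulationConfig,
) -> list[IntervalValue]:
    """Lamin tile profile on the derived assembly, from projected LADs.

    Bases present only in the derived assembly (insertions) fall outside
    every projected LAD and read as inter-LAD signal.
    """
    rng = config.rngs()["derived_lamin"]
    projected = {
        chrom: pair.project_intervals(chrom, lads.get(chrom, []))
        for chrom, _ in pair.assembly2.items()
    }
    index = _LadIndex(projected)
    return _simulate_lamin_tiles(pair.assembly2, index, config, rng)
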