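# oxomap

A tested, reusable pipeline for genome-wide oxidative DNA damage (8-oxoG)
microarray profiles: per-probe log2(IP/input) signal processing, sliding-window
smoothing, gene-density association in megabase bins, expression-group
comparison, chain-file interval remapping between assemblies (liftOver-style,
with a minimum mapped-fraction criterion), and lamina-associated-domain (LAD)
association statistics including a permutation z-score test. A first-class
synthetic-data module generates toy genomes with known ground truth so every
stage is exercisable end-to-end without downloads.

## Layout

| module | role |
| --- | --- |
| `oxomap.io_formats` | readers/writers: probe tables (ratio or two-channel), BED6 genes, expression TSV, bedGraph, chrom.sizes; replicate merging |
| `oxomap.smoothing` | per-probe ±halfwidth window means (O(n)); fixed-step window tracks |
| `oxomap.binning_density` | non-overlapping genomic bins, probe/gene assignment, gene-density association (Pearson r + per-count quartile summaries) |
| `oxomap.expression_assoc` | genic signal averaging, median / top-bottom expression splits, pooled-variance Student's t (Welch optional) |
| `oxomap.liftover` | UCSC chain parsing and interval/profile remapping with `min_blocks`, ambiguity and deletion failure labels |
| `oxomap.lad_assoc` | 200 kb fragment profiles (signal + coverage-weighted lamin), cutoff split, group stats, permutation z-score, 2-D density grid |
| `oxomap.synthetic_data` | seeded generator: LAD architecture, bimodal lamin tiles, probe signal with an in-LAD offset, LAD-depleted genes, expression table, derived assembly + chain file with indels and an inversion |
| `oxomap.cli` | `oxomap` command with one subcommand per stage plus `all` |

Conventions: 0-based half-open coordinates everywhere; probes are represented
by their midpoint for membership tests; nothing is dropped silently — every
reader and stage reports counts.

## CLI

Generate a synthetic dataset (including a second toy assembly, a chain file
and a lamin profile in the foreign coordinates):

```sh
oxomap simulate --seed 1 --outdir sim/
```

Run the whole pipeline from a YAML config:

```sh
oxomap all --config pipeline.yaml
```

with e.g.

```yaml
probes: sim/probes.tsv          # one path, or a list of replicate tables
genes: sim/genes.bed
expression: sim/expression.tsv
lamin_source: sim/lamin_derived.bedgraph   # foreign-assembly coordinates
chain: sim/toy.chain
chrom_sizes: sim/chrom.sizes
outdir: out/
seed: 1
# optional overrides (defaults shown)
probe_mode: ratio      # or two_channel (columns ip/input)
halfwidth: 500000
window: 1000000
step: 200000
bin_size: 1000000
fragment_size: 200000
cutoff: 0.0
min_blocks: 0.1
best_chain: false
gene_rule: tss         # or overlap
welch: false
n_iter: 1000
```

CLI flags override config values, which override the defaults. Individual
stages are also available (`oxomap smooth|bins|expression|liftover|lads|
permtest`). Exit codes: 0 success, 1 data error (partial outputs are
removed), 2 usage error. Every stage writes a `runlog_<stage>.json` with the
version, a config hash, the seed and record counts; reruns with the same
inputs and seed are byte-identical.

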