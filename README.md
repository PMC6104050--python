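# hetna — heterogeneous network alignment

Global pairwise alignment of *colored* (heterogeneous) networks.  Nodes
(and optionally edges) carry type labels; node signatures are built from
colored graphlets, edge conservation is scored with a color-aware S³
measure, and three alignment strategies — seed-and-extend (WAVE-style),
simulated annealing (SANA-style), and genetic search (MAGNA-style) — can
consume either the homogeneous or the heterogeneous versions of both
measures.  A synthetic-network module reproduces the standard
noise-robustness evaluation protocol (geometric / scale-free networks,
balanced random colorings, x%-edge rewiring with known true mappings).

## Components

| module | what it does |
|---|---|
| `hetna.netmodel` | colored networks, alignments, similarity matrices, TSV I/O |
| `hetna.graphlets` | 2–5-node graphlet/orbit catalog (30 graphlets, 73 orbits); GDV / NCGDV / ECGDV counting with a numba ESU kernel |
| `hetna.similarity` | stacked-signature PCA (r ≥ 2, ≥ 90 % variance) + cosine similarity scaled to [0, 1]; NoPCA variant |
| `hetna.conservation` | conserved-edge classification, homogeneous & heterogeneous S³ (weights 1, 2/3, 1/3), incremental delta-objective for search aligners |
| `hetna.aligners` | `wave_align`, `sana_align` (swap/change annealing, numba-accelerated), `magna_align` (elitist GA with crossover + repair) |
| `hetna.synth` | geometric & scale-free generators with exact node/edge counts, balanced random and membership-list colorings, noise rewiring |
| `hetna.evaluate` | node correctness, the full factor sweep (`run_sweep`), rank-frequency summaries |
| `hetna.cli` | `hetna` command with `count / similarity / score / align / generate / noise / evaluate / sweep` subcommands |

## CLI quick start

```bash
# 2-colored geometric network, 1000 nodes / 6000 edges
hetna generate --model geo --nodes 1000 --edges 6000 --colors 2 --seed 1 --out-prefix net

# 25%-rewired noisy counterpart + true node mapping
hetna noise --edge-list net.edges.tsv --node-colors net.colors.tsv \
      --level 0.25 --seed 2 --out-prefix noisy

# colored-graphlet signatures and PCA+cosine similarity
hetna count --edge-list net.edges.tsv   --node-colors net.colors.tsv   --mode ncgdv --out net.sig.tsv
hetna count --edge-list noisy.edges.tsv --node-colors noisy.colors.tsv --mode ncgdv --out noisy.sig.tsv
hetna similarity --sig-g net.sig.tsv --sig-h noisy.sig.tsv --out sim.tsv

# align (heterogeneous NC + heterogeneous S3) and score against the truth
hetna align --method sana --g net.edges.tsv --h noisy.edges.tsv \
      --node-colors-g net.colors.tsv --node-colors-h noisy.colors.tsv \
      --sim sim.tsv --ec hets3 --budget 2000000 --seed 3 --out aln.tsv
hetna evaluate --alignment aln.tsv --truth noisy.truth.tsv
```

All formats are plain whitespace-separated text: edge lists and
alignments are 2 columns, node colors 2 columns, edge colors 3 columns
(node1 node2 color), similarities 3 columns (node1 node2 value∈[0,1]).
Outputs carry a `#`-comment metadata header with version, seed, and
parameters; every stochastic routine is deterministic given its seed.

## Notes

- Counting and annealing have numba-compiled kernels with pure-Python
  fallbacks (`engine="python"`); both paths are tested against each
  other and against an independent brute-force enumerator.
- `SweepConfig` defaults run the desk-scale experiment
  (n = 300, m = 1800, k ∈ {1, 2, 4}, noise ∈ {0, 0.25, 0.5}); scale up
  `n`, `m`, `replicates`, and `sana_budget` for full-size runs.
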