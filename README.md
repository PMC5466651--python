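# knetdist

Order-`k` node equivalence, network reduction, and the `k`th-distance on
rooted phylogenetic networks (single-rooted, leaf-labelled DAGs).

The package computes a chain of equivalence relations over a network's nodes
— order 1 and odd orders compare nodes by their children, even orders by
their parents, anchored at leaf labels and the root — and from it:

- a membership test and projection (`reduce`) for the space of order-`k`
  reduced networks (every node equivalent only to itself, no
  in-degree-1/out-degree-1 nodes);
- the `k`th-distance between two networks: per order, joint equivalence
  classes of the two networks' disjoint union are compared by class size, and
  the one-sided discordances are summed and normalized by `k * (n1 + n2)`.
  The value is kept as an exact rational.

Two independent routes are implemented for the equivalence relations — fast
partition refinement and a naive memoized recursion that follows the defining
clauses literally (exhaustive bipartite matching of children/parents) — and
cross-validated against each other in the test suite, together with a
VF2-based isomorphism oracle.

## Layout

| module | contents |
|---|---|
| `knetdist.network` | `PhyloNetwork` model, validation, height/depth/category index, eNewick and edge-list I/O, origin-tagged disjoint union |
| `knetdist.equivalence` | `partition_order1`, `refine_step`, `equivalence_chain`, the naive oracle `naive_equivalent` |
| `knetdist.reduction` | `is_kth_order_reduced`, `suppress_unary`, `reduce` |
| `knetdist.metric` | `class_tables`, `kth_distance` (exact `Fraction`), `brute_force_isomorphic` |
| `knetdist.generator` | seeded random network generator for property testing |
| `knetdist.fixtures` | transcribed figure networks (`fig1_n1` … `fig7_n`) with self-verifying documented facts |
| `knetdist.cli` | `knetdist` command-line tool |

## CLI

Network arguments are file paths (`.edges`/`.txt` edge lists, anything else
eNewick with `#H` hybrid tags) or bundled fixture names:

```sh
knetdist distance --k 3 fig1_n1 fig1_n2          # d_3 = 1/13 (...)
knetdist distance --k 3 --json fig2_n1 fig2_n2   # full breakdown, 16/21
knetdist check-reduced --k 2 fig7_n              # "not reduced"
knetdist reduce --k 2 fig7_n -o reduced.edges
knetdist equivalence --k 3 fig1_n1 --two fig1_n2 # joint classes as TSV
knetdist generate --leaves 6 --reticulations 2 --seed 7 -o net.edges
knetdist matrix --k 2 somedir/ -o dist.tsv
```

Exit codes: 0 success, 1 usage error, 2 validation/parse error.

## Formats

- **eNewick**: standard extended Newick; every occurrence of a reticulate
  node carries the same `#H<id>` tag and is merged on parsing. Serialization
  is canonical (children ordered by the leaf-label set below them, hybrid
  numbers in first-encounter order) and stable under reparse.
- **edge list**: `edge <parent> <child>` / `leaf <node> <label>` lines,
  `#` comments, `node <id>` for the degenerate one-node network. Lossless.

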