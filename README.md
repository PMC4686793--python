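# gadp — inside/outside dynamic programming over strings and sets

`gadp` is a toolkit for ensemble dynamic programming built around one idea:
a DP algorithm is a *decomposition grammar* (how the state space splits)
plus an *evaluation algebra* (how parts are scored and chosen), and the
outside (backward) recursion of any such algorithm — the part needed for
posterior probabilities — can be derived **mechanically** from the inside
grammar. A production `A → α B β` contributes `B* → α A* β`; start rules
`S → A` become terminations `A* → S*`; stop rules `A → ε` become the
outside start `ε* → A*`. Because each derived rule inherits the scoring
slot of the rule that generated it, one algebra evaluates both directions,
and inside×outside products yield exact posteriors.

The same formalism covers ordered and unordered data. The package ships
four complete engines:

| engine | inside quantity | outside quantity | posterior |
|---|---|---|---|
| `gadp.hmm` | forward `f±[i]` over prefixes | backward `b±[i]` over suffixes | P(position i in the CpG "+" state) |
| `gadp.alignment` | Gotoh `M/D/I[i][j]` over prefix alignments | gap-*closing* tables `M*/D*/I*` | P(xᵢ aligned to yⱼ) |
| `gadp.rna` | `U/B[i][j]` over substructures | `U*/B*` over contexts | base-pair probabilities P(i,j) |
| `gadp.set_dp` | punctuated-set tables `Z([p,A,i])` | complement tables `Z([j,A*,q])` | path adjacency / endpoint probabilities |

For sets, the index type is the *punctuated set* `[i, A, j]` — an unordered
vertex subset with distinguished path endpoints — and the single rule
`A → Av` (split off a boundary vertex) gives the Held–Karp TSP recursion,
exact shortest Hamiltonian paths, and Boltzmann ensembles of paths weighted
by `exp(−ℓ(π)/RT)` with `R = (n−1)·d̄`.

The flagship application (`gadp.hox`) analyses gene clusters that grew by
serial duplication (such as HOX clusters): when genetic distance grows
monotonically with genomic distance (the Robinson property), the shortest
Hamiltonian path through the distance matrix recovers the genomic gene
order, and the path ensemble quantifies its robustness — endpoint
probabilities mark the cluster ends, interior endpoint mass hints at
rearrangements.

## Worked example

Analyse a synthetic 8-gene serial-duplication cluster (seeded, zero noise):

```python
from gadp.hox import synthesize_cluster, run_cluster_analysis

dm = synthesize_cluster(8, noise=0.0, seed=7)
report = run_cluster_analysis(dm, temperatures=[0.1, 1.0])
print(" -> ".join(report.optimal_path))
for label, p in report.endpoint_table(0.1).items():
    print(f"{label}\t{p:.3f}")
```

prints

```
g1 -> g2 -> g3 -> g4 -> g5 -> g6 -> g7 -> g8
g1      0.398
g2      0.254
g3      0.213
g4      0.193
g5      0.191
g6      0.202
g7      0.252
g8      0.297
```

The optimal path is the true gene order (the zero-noise matrix is exactly
Robinson), and at the low temperature `T = 0.1` the two genomic ends `g1`
and `g8` carry the largest endpoint probabilities (0.398 and 0.297 against
a uniform baseline of 2/8 = 0.25). The adjacency posterior concentrates on
true neighbours: `P(g1~g2) = 0.705` versus `P(g1~g8) = 0.062`. Raising the
temperature flattens everything towards uniform (`T = 1` already gives
endpoint values within 0.24–0.27).

The string engines work the same way; e.g. RNA base-pair probabilities for
a hairpin-forming sequence:

```python
from gadp.rna import RnaInput, rna_inside, rna_outside, basepair_probabilities
inp = RnaInput("GGGAAACCC")
tables = rna_outside(inp, rna_inside(inp, "partition"))
P = basepair_probabilities(inp, tables=tables)   # P[0, 8] = 0.172
```

## Command line

```bash
gadp hmm     --fasta in.fa --params params.yaml --out posteriors.tsv
gadp align   --fasta pair.fa --mode partition --gap-open -2 --gap-extend -1 --out matchprobs.tsv
gadp rna     --fasta in.fa --mode partition --rt 1.0 --out bpp.tsv
gadp shp     --matrix d.phylip --temperature 0.1 --out report/
gadp hox     --fasta hoxa.fa --metric hamming --temperatures 0.1,0.5,1,10 --out report/
gadp hox     --synthetic 11 --noise 0.5 --seed 1 --out report/
gadp grammar --in rna.json --out rna_outside.json
```

`gadp grammar` reads a grammar description (JSON: `symbols[]`,
`productions[]`, `start`, `stop`, `tapes`), emits its mechanically derived
outside grammar and prints the rule listing.

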