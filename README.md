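# motifclique

Exact discovery of planted (l, d) DNA motifs by recursive
reference-vertex clique search.

## The problem

Transcription-factor binding sites appear in promoter sequences as short,
mutated copies of an unknown common pattern. The planted (l, d) motif
problem formalises this: given m DNA sequences, each containing exactly
one instance of an unknown length-l motif with at most d substitutions
(one occurrence per sequence, "OOPS"), recover the motif and the instance
positions. The classical challenge setting is l=15, d=4, m=20, n=600.

Since every instance is within Hamming distance d of the true motif, any
two instances are within 2d of each other (triangle inequality). The set
of planted instances therefore forms an **m-clique** in the graph whose
vertices are all l-mers of the input and whose edges join pairs at
distance ≤ 2d. `motifclique` enumerates *every* such clique exactly — so
the planted solution is guaranteed to be among the output — by a
depth-first reference-vertex search: each l-mer of sequence 0 in turn
filters the candidate sets of all later sequences down to its
2d-neighbours, the survivors of sequence 1 filter the rest again, and so
on; a path is abandoned as soon as any remaining sequence has no
compatible vertex. Candidate sets are filtered freshly per level, so peak
memory is O(m²n).

The difficulty of an instance is summarised by the weakness probability

    p(l, d) = Σ_{i=0}^{2d} C(l, i) (3/4)^i (1/4)^(l-i),

the chance that two random background l-mers look like a motif pair.
Larger p means more spurious cliques and a harder search; p for (15, 4)
is 0.057.

## Worked example

Generate a small planted benchmark, search it, and score the result:

```
$ motifclique simulate -m 5 -n 40 -l 7 -d 1 --mode exact_d --seed 3 -o bench
INFO motifclique: simulated m=5 n=40 (l=7, d=1, exact_d, seed=3): true motif TAAAATT

$ motifclique search bench.fasta -l 7 -d 1 -o cliques.tsv --consensus-report consensus.txt
INFO motifclique: search: m=5, n=40..40, l=7, d=1, weakness p=0.013
INFO motifclique.search: clique search: m=5 l=7 d=1 -> 1 clique(s), 33 dead end(s), 2255 distance evaluations, 0.00s

$ cat cliques.tsv
clique	seq0	seq1	seq2	seq3	seq4
0	seq0:30:TACAATT	seq1:11:TAAAATG	seq2:5:TAAAACT	seq3:27:TAAAATG	seq4:30:TACAATT
# cliques	1

$ motifclique evaluate --truth bench.truth.tsv --cliques cliques.tsv -l 7
cliques	1
best_clique_recall	1.000
union_recall	1.000
seq_id	planted_start	hit_by_best
seq0	30	yes
...
```

The single clique found is exactly the planted tuple: every instance
start matches the ground truth, so the base-level recall rate is 1.000.
The consensus report aligns the clique members column by column; here the
per-column majority reconstructs the true motif `TAAAATT` exactly (a
column without a dominant base would be shown as `x`). On the classical
(15, 4), m=20, n=600 setting a search takes a few seconds and the planted
tuple is always among the reported cliques.

The same machinery is importable as a library:

```python
from motifclique import MotifModel, generate_planted, find_cliques

model = MotifModel(15, 4)
ds = generate_planted(20, 600, model, mode="exact_d", seed=1)
result = find_cliques(ds.sequences, model)
assert ds.planted_starts in {c.starts for c in result.cliques}
```

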