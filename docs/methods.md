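# Methods

## Model and search procedure

The planted (l, d) motif model assumes m DNA sequences over {A, C, G, T},
each carrying exactly one instance of an unknown length-l motif, each
instance differing from it in at most d positions. Because two strings
within d of a common centre are within 2d of each other, the m planted
instances form a clique under the pairwise-distance threshold 2d. The
search enumerates *all* m-cliques of l-mers (one vertex per sequence,
every pair within 2d); completeness of that enumeration is what
guarantees the planted tuple is always reported. The output may also
contain spurious cliques assembled from background coincidences — their
expected number grows with the weakness probability p (below) — and no
deduplication across cliques is attempted: each valid position tuple is
reported once, in lexicographic order of (j_0, …, j_{m−1}).

The enumeration is a depth-first reference-vertex search. At depth i the
chosen vertex of sequence i filters the candidate pool of every later
sequence down to its 2d-neighbours; the path is abandoned the moment any
later pool becomes empty, and the search backtracks to substitute the
previous reference. Depth m emits the accumulated references as a
clique. The recursion is realised as an explicit stack so m is not
bounded by the interpreter call depth, and pools are index arrays
filtered freshly at each level, keeping peak memory O(m²n). Sequence 0,
as read, is always the first reference sequence; no reordering is
applied, which keeps runs reproducible.

Distances are computed on byte-encoded sequence windows with vectorised
comparison; the unit tests pin exact agreement between this packed
representation and a per-character loop.

## Weakness probability

For two independent uniform random l-mers each position differs with
probability 3/4, so the probability that they lie within 2d is the
binomial tail

p(l, d) = Σ_{i=0}^{min(2d, l)} C(l, i) (3/4)^i (1/4)^(l−i),

computed in exact integer arithmetic and rounded half-up to 3 decimals
for reporting. p saturates at 1 when 2d ≥ l and is non-decreasing in d.
It predicts search difficulty: the expected candidate-pool sizes shrink
geometrically with depth as (n−l+1)p^i, so small p means early dead ends
and a fast search, while p above roughly 0.25 (e.g. the (18, 6) model)
makes sample-driven clique search impractically slow regardless of
implementation.

## Recall rate

Predictions are scored at base resolution: the known set is the m·l base
positions covered by the planted windows, the predicted set is the union
of bases covered by a reported clique's windows, and the recall rate is
|known ∩ predicted| / |known|. Partial window overlap earns partial
credit. Because spurious cliques can coexist with the planted one, the
evaluator reports both the best single clique's recall and the recall of
the union of all reported cliques.

## Consensus derivation

A clique's members are already aligned, so the consensus is per-column:
the plurality base is emitted when its frequency strictly exceeds the
dominance threshold (default 0.5 — a strict majority, which also makes
the emitted base unique), otherwise the column is written as `x`. The
threshold is a parameter rather than a hidden constant. For the validity
flag, `x` columns are resolved to the plurality base (ties broken
alphabetically) and every member is checked to lie within d of the
resolved string.

## Synthetic benchmark generator

The generator emulates the classical challenge protocol: i.i.d. uniform
background bases, a uniform random true motif, one instance per sequence
at a uniform random start in {0, …, n−l}, overwriting the background.
Mutated positions are sampled without replacement and each mutated base
is replaced by a uniformly chosen different base, so the realised
distance to the motif equals the mutation count. Two modes: `up_to_d`
(default; the mutation count is uniform on {0, …, d}, the literal
"up to d mutations" model) and `exact_d` (exactly d, the convention of
the published challenge benchmarks; used for the challenge-recall tests
here). Everything is drawn from a single seeded generator, so a seed
reproduces the dataset — FASTA bytes included. Planted instances are not
protected from colliding with background near-motifs, and the background
is strictly uniform i.i.d.: no GC skew, no Markov structure, no repeats.
Passing tests on this generator therefore demonstrate correctness of the
combinatorial search under the model's own assumptions, not robustness
to the compositional biases of real genomic sequence.

## Validation strategy

Two independent brute-force references check the search from both
directions on small instances: full product-space enumeration of
position tuples (the definition of the output, without any filtering
logic), and pattern-driven enumeration of the d-neighbourhood of every
l-mer of sequence 0, whose witness tuples must all appear among the
cliques. The abstract-graph variant of the search runs the identical
engine on labelled vertices with an arbitrary symmetric compatibility
predicate, which lets the four-part worked example (parts {A,B,C},
{Z,E,F,G}, {H,I,J,K,L}, {M,N,O,Q,R,T}) pin the exact traversal order,
output [(A,Z,J,M), (A,Z,J,T)], and the recorded dead end where reference
H leaves the last part empty. One listed compatibility relation in that
example (R–H) appears in only one direction; the fixture uses the
symmetric closure, which provably does not affect the reachable paths.

Scale choices: the challenge-recall test runs ten seeded (15, 4), m=20,
n=600 datasets (a few seconds each); oracle equivalence runs twenty
m=4, n=20, l=5, d=1 instances (65 536-tuple product space each) and ten
planted (7, 1), m=5, n=40 instances. Published-table agreement for p
covers all 42 (l, d) entries; four of the published roundings differ
from the exact tail by one unit in the last printed digit, and the test
asserts exact agreement for the other 38 and last-digit agreement for
those four.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| l | motif length (bases) | required, ≥ 1 |
| d | max mutations per instance (bases) | required, 0 ≤ d < l |
| 2d | pairwise clique threshold | derived, never set directly |
| mutation mode | `up_to_d` or `exact_d` | `up_to_d` |
| dominance threshold | column frequency a base must exceed in the consensus | 0.5 |
| `--first-k` | stop after k cliques (result flagged incomplete) | unlimited |
| `--max-seconds` | soft wall-clock limit, partial results flagged | none |
| `--skip-ambiguous` | keep IUPAC-coded records, skip affected windows | off (strict A/C/G/T) |

## Known limitations

Single-strand search only (no reverse-complement scanning); strictly
OOPS inputs — a sequence without an instance empties the candidate pools
and yields zero cliques rather than a partial motif; weak models with
large p (e.g. (18, 6) at n=600) are beyond practical reach of any
sample-driven clique enumeration, including this one; and the consensus
is a plurality call, not a position-weight-matrix or information-content
model.
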