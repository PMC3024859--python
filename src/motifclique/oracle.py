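"""Brute-force references for validating the clique search on tiny inputs.

Two independent routes to the same ground truth:

* :func:`exhaustive_cliques` walks the full product space of
  one-vertex-per-sequence tuples and keeps those passing the pairwise-2d
  test — the definition of the search's output, computed without any
  filtering or backtracking.
* :func:`exhaustive_pattern_search` enumerates candidate motif *strings*
  (the d-neighbourhood of every l-mer of sequence 0) and keeps those
  with a witness within d in every sequence — the pattern-driven
  formulation of the planted problem.  Anchoring on sequence 0 is sound
  for one-occurrence-per-sequence data: the true motif is within d of
  sequence 0's instance.

Both refuse instances whose enumeration would exceed an explicit budget;
they exist to check correctness, not to be fast.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np

from .sequences import ALPHABET, MotifModel, SequenceSet


class BudgetExceededError(RuntimeError):
    """The instance is too large for exhaustive enumeration."""


def exhaustive_cliques(
    S: SequenceSet, model: MotifModel, *, budget: int = 10**6
) -> set[tuple[int, ...]]:
    """All position tuples (j_0, ..., j_{m-1}) whose l-mers are pairwise
    within 2d, by full product-space enumeration."""
    m = S.m
    l = model.length
    counts = [n - l + 1 for n in S.lengths]
    space = 1
    for c in counts:
        space *= c
    if space > budget:
        raise BudgetExceededError(
            f"product space {space} exceeds budget {budget}"
        )

    windows = [S.windows(i, l) for i in range(m)]
    # pairwise compatibility lookup tables, one per sequence pair
    compat: dict[tuple[int, int], np.ndarray] = {}
    for a, b in combinations(range(m), 2):
        dist = (windows[a][:, None, :] != windows[b][None, :, :]).sum(axis=2)
        compat[(a, b)] = dist <= model.threshold

    out: set[tuple[int, ...]] = set()
    for tup in product(*(range(c) for c in counts)):
        if all(compat[(a, b)][tup[a], tup[b]] for a, b in combinations(range(m), 2)):
            out.add(tup)
    return out


def _neighborhood(lmer: str, d: int):
    """Every string within Hamming distance d of ``lmer`` (inclusive)."""
    l = len(lmer)
    yield lmer
    for k in range(1, d + 1):
        for positions in combinations(range(l), k):
            alternatives = [
                [b for b in ALPHABET if b != lmer[p]] for p in positions
            ]
            for subst in product(*alternatives):
                chars = list(lmer)
                for p, b in zip(positions, subst):
                    chars[p] = b
                yield "".join(chars)


def exhaustive_pattern_search(
    S: SequenceSet, model: MotifModel, *, budget: int = 10**6
) -> set[str]:
    """All l-mer strings within d of at least one window of *every*
    sequence, enumerated from the d-neighbourhoods of sequence 0's
    windows."""
    l, d = model.length, model.max_mutations
    n_windows0 = S.lengths[0] - l + 1
    neighborhood_size = sum(
        _ncr(l, k) * 3**k for k in range(d + 1)
    )
    if n_windows0 * neighborhood_size > budget:
        raise BudgetExceededError(
            f"{n_windows0} anchor l-mers x {neighborhood_size} neighbours "
            f"exceeds budget {budget}"
        )

    windows = [S.windows(i, l) for i in range(S.m)]
    seen: set[str] = set()
    hits: set[str] = set()
    for j in range(n_windows0):
        anchor = S.sequence(0)[j : j + l]
        for cand in _neighborhood(anchor, d):
            if cand in seen:
                continue
            seen.add(cand)
            row = np.frombuffer(cand.encode(), dtype=np.uint8)
            enc = _encode_row(row)
            if all(
                int((w != enc).sum(axis=1).min()) <= d for w in windows
            ):
                hits.add(cand)
    return hits


def _encode_row(ascii_row: np.ndarray) -> np.ndarray:
    from .sequences import _ENCODE

    return _ENCODE[ascii_row]


def _ncr(n: int, r: int) -> int:
    from math import comb

    return comb(n, r)


def witness_tuples(
    S: SequenceSet, model: MotifModel, motif: str
) -> list[tuple[int, ...]]:
    """For a motif string, one tuple combining, per sequence, the first
    window within d of it (empty list if some sequence has none)."""
    l, d = model.length, model.max_mutations
    enc = _encode_row(np.frombuffer(motif.encode(), dtype=np.uint8))
    tup = []
    for i in range(S.m):
        dist = (S.windows(i, l) != enc).sum(axis=1)
        js = np.flatnonzero(dist <= d)
        if js.size == 0:
            return []
        tup.append(int(js[0]))
    return [tuple(tup)]
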