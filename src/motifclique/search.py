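"""Exact clique search over l-mer vertices by recursive reference filtering.

The planted (l, d) problem: every input sequence carries one instance of
an unknown motif, each instance within ``d`` mutations of it.  By the
triangle inequality any two instances are within ``2d`` of each other, so
the tuple of instances is an m-clique in the graph whose vertices are all
l-mers and whose edges join pairs at Hamming distance <= 2d.

The search anchors on sequence 0: each of its vertices in turn becomes
the *reference vertex* and filters every later sequence's candidate set
down to the vertices within 2d of it.  The surviving set of sequence 1
supplies the next reference, filtering sequences 2..m-1 again, and so on.
The path continues only while every remaining sequence keeps at least one
compatible vertex; otherwise the search backtracks and substitutes the
last reference.  Reaching depth m emits the accumulated reference tuple
as a clique.  Every m-clique is enumerated exactly once, so the planted
tuple is always among the output (completeness), and every output tuple
is pairwise within 2d by construction (soundness).

Depth-first traversal in ascending start order makes the output order
lexicographic in the position tuple (j_0, ..., j_{m-1}) and fully
deterministic.  The recursion is realised as an explicit stack, so m is
not limited by the interpreter call depth.  Candidate sets are filtered
freshly at each level (peak memory stays O(m^2 n): at most m levels of at
most m candidate index arrays of at most n entries each).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np

from .sequences import (
    InstanceTooShortError,
    MotifModel,
    SequenceSet,
    VertexRef,
    enumerate_vertices,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Clique:
    """One vertex per sequence, pairwise Hamming distance <= 2d.

    ``members[t]`` comes from sequence ``t``; ``strings[t]`` is its l-mer.
    """

    members: tuple[VertexRef, ...]
    strings: tuple[str, ...]

    @property
    def starts(self) -> tuple[int, ...]:
        return tuple(v.start for v in self.members)


@dataclass(frozen=True)
class DeadEnd:
    """A rejected search path: after choosing ``ref`` at depth ``level``,
    sequence ``empty_k`` retained no compatible vertex."""

    level: int
    ref: Hashable
    empty_k: int


@dataclass
class SearchResult:
    """Outcome of a clique search.

    ``complete`` is False when the search stopped early (clique cap or
    soft time limit); the cliques found up to that point are still valid.
    """

    cliques: list[Clique]
    complete: bool = True
    dead_ends: int = 0
    distance_evaluations: int = 0
    elapsed_seconds: float = 0.0

    def __len__(self) -> int:
        return len(self.cliques)

    def __iter__(self):
        return iter(self.cliques)


def _search_engine(
    initial: list[Sequence],
    filter_pool: Callable[[int, object, int, Sequence], Sequence],
    emit: Callable[[list], None],
    *,
    trace: list | None = None,
    max_cliques: int | None = None,
    max_seconds: float | None = None,
) -> tuple[bool, int]:
    """Depth-first reference-vertex search, generic over the vertex type.

    ``initial[k]`` is the level-0 candidate pool of part ``k``;
    ``filter_pool(level, ref, k, pool)`` returns the members of ``pool``
    (part ``k``) compatible with the reference chosen at ``level``.
    ``emit`` receives each completed m-tuple.  Returns (complete,
    dead-end count).
    """
    m = len(initial)
    deadline = None if max_seconds is None else time.monotonic() + max_seconds
    emitted = 0
    dead_ends = 0

    # Stack frame per depth: (candidate pools for parts i..m-1, cursor into
    # the pool of part i).  `chosen[t]` is the reference selected at depth t.
    frames: list[list] = [[{k: initial[k] for k in range(m)}, 0]]
    chosen: list = []

    while frames:
        pools, pos = frames[-1]
        i = len(frames) - 1
        own = pools[i]
        if pos >= len(own):
            frames.pop()
            if chosen:
                chosen.pop()
            continue
        frames[-1][1] = pos + 1
        ref = own[pos]

        if i == m - 1:
            emit(chosen + [ref])
            emitted += 1
            if max_cliques is not None and emitted >= max_cliques:
                return False, dead_ends
            continue

        if deadline is not None and time.monotonic() > deadline:
            return False, dead_ends

        new_pools: dict[int, Sequence] = {}
        valid = True
        for k in range(i + 1, m):
            kept = filter_pool(i, ref, k, pools[k])
            if len(kept) == 0:
                valid = False
                dead_ends += 1
                if trace is not None:
                    trace.append(DeadEnd(level=i, ref=ref, empty_k=k))
                logger.debug(
                    "dead end at depth %d: reference %r leaves part %d empty",
                    i, ref, k,
                )
                break
            new_pools[k] = kept
        if valid:
            chosen.append(ref)
            frames.append([new_pools, 0])

    return True, dead_ends


def filter_candidates(
    S: SequenceSet,
    model: MotifModel,
    ref: VertexRef,
    pool: Sequence[VertexRef],
) -> list[VertexRef]:
    """Subset of ``pool`` within threshold 2d of ``ref``, order preserved.

    This is the single filtering step of the search, exposed for direct
    use; the search itself runs the same comparison on packed windows.
    """
    l = model.length
    ref_row = S.windows(ref.seq_index, l)[ref.start]
    out = []
    for v in pool:
        row = S.windows(v.seq_index, l)[v.start]
        if int(np.count_nonzero(row != ref_row)) <= model.threshold:
            out.append(v)
    return out


def find_cliques(
    S: SequenceSet,
    model: MotifModel,
    *,
    max_cliques: int | None = None,
    max_seconds: float | None = None,
    trace: list | None = None,
) -> SearchResult:
    """Enumerate every m-clique of l-mers with pairwise distance <= 2d.

    Parameters
    ----------
    S
        Input sequences; sequence 0 anchors the search.
    model
        The (l, d) model; the pairwise threshold is ``2d``.
    max_cliques
        Stop after this many cliques (result flagged incomplete).
    max_seconds
        Soft wall-clock limit; on expiry the cliques found so far are
        returned with ``complete=False``.
    trace
        Optional list collecting :class:`DeadEnd` records for rejected
        paths (used for debugging and didactic runs).

    Returns
    -------
    SearchResult
        Cliques in lexicographic order of their position tuples.
    """
    m = S.m
    l = model.length
    for i, n_i in enumerate(S.lengths):
        if n_i < l:
            raise InstanceTooShortError(
                f"sequence {S.ids[i]!r} has length {n_i} < motif length {l}"
            )
    windows = [S.windows(i, l) for i in range(m)]
    threshold = model.threshold

    # Candidate pools are index arrays into each sequence's window matrix;
    # ambiguous windows (IUPAC codes) are excluded up front.
    initial = [
        np.array([v.start for v in enumerate_vertices(S, k, l)], dtype=np.intp)
        for k in range(m)
    ]

    evals = 0

    def filter_pool(level: int, ref_j: int, k: int, pool: np.ndarray) -> np.ndarray:
        nonlocal evals
        evals += len(pool)
        ref_row = windows[level][ref_j]
        dist = np.count_nonzero(windows[k][pool] != ref_row, axis=1)
        return pool[dist <= threshold]

    cliques: list[Clique] = []

    def emit(starts: list[int]) -> None:
        members = tuple(VertexRef(t, int(j)) for t, j in enumerate(starts))
        cliques.append(
            Clique(members=members, strings=tuple(S.lmer(v, l) for v in members))
        )

    t0 = time.monotonic()
    complete, dead_ends = _search_engine(
        initial, filter_pool, emit,
        trace=trace, max_cliques=max_cliques, max_seconds=max_seconds,
    )
    elapsed = time.monotonic() - t0
    logger.info(
        "clique search: m=%d l=%d d=%d -> %d clique(s), %d dead end(s), "
        "%d distance evaluations, %.2fs%s",
        m, l, model.max_mutations, len(cliques), dead_ends, evals, elapsed,
        "" if complete else " [INCOMPLETE]",
    )
    return SearchResult(
        cliques=cliques,
        complete=complete,
        dead_ends=dead_ends,
        distance_evaluations=evals,
        elapsed_seconds=elapsed,
    )


def find_cliques_abstract(
    parts: Sequence[Sequence[Hashable]],
    compatible: Callable[[Hashable, Hashable], bool],
    *,
    trace: list | None = None,
) -> list[tuple[Hashable, ...]]:
    """Run the clique search on abstract labelled vertices.

    ``parts[k]`` lists the vertices of part ``k``; ``compatible(u, v)``
    plays the role of the 2d-distance test and must be symmetric
    (verified on all cross-part pairs before searching).  Returns the
    complete list of m-tuples, one label per part, with all pairs
    compatible — in depth-first order of the parts' given orderings.
    """
    if any(len(p) == 0 for p in parts):
        raise ValueError("every part must be non-empty")
    labels = [list(p) for p in parts]
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            for u in labels[a]:
                for v in labels[b]:
                    if compatible(u, v) != compatible(v, u):
                        raise ValueError(
                            f"compatibility predicate is not symmetric on "
                            f"({u!r}, {v!r})"
                        )

    def filter_pool(level, ref, k, pool):
        return [v for v in pool if compatible(ref, v)]

    out: list[tuple[Hashable, ...]] = []
    _search_engine(labels, filter_pool, lambda tup: out.append(tuple(tup)),
                   trace=trace)
    return out
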