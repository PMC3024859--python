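"""Quantitative instruments for the planted (l, d) problem.

Three tools:

* the *weakness probability* ``p`` — the chance two independent uniform
  random l-mers lie within Hamming distance 2d, an exact binomial tail.
  Larger p means more chance background l-mers form spurious cliques,
  i.e. a weaker, harder motif;
* the base-level recall rate of a prediction against the planted truth;
* consensus derivation from a clique, with 'x' marking columns that lack
  a dominant base.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from math import comb
from typing import Iterable, Set, Tuple

from .sequences import ALPHABET, MotifModel, hamming
from .search import Clique

BasePosition = Tuple[int, int]  # (sequence index, 0-based base coordinate)


def neighbor_probability_exact(l: int, d: int) -> Fraction:
    """Exact probability that two uniform random l-mers differ in <= 2d places.

    Each position differs independently with probability 3/4, so the
    value is the binomial tail ``sum_{i=0}^{min(2d, l)} C(l, i) (3/4)^i
    (1/4)^(l-i)``, computed in integer arithmetic.  Equals 1 whenever
    ``2d >= l``.
    """
    if l < 1:
        raise ValueError(f"motif length must be >= 1, got {l}")
    if d < 0:
        raise ValueError(f"mutation bound must be >= 0, got {d}")
    t = min(2 * d, l)
    numerator = sum(comb(l, i) * 3**i for i in range(t + 1))
    return Fraction(numerator, 4**l)


def neighbor_probability(l: int, d: int) -> float:
    """Float value of :func:`neighbor_probability_exact`."""
    return float(neighbor_probability_exact(l, d))


def rounded_probability(l: int, d: int, decimals: int = 3) -> float:
    """The weakness probability rounded half-up to ``decimals`` places,
    the convention used when reporting p alongside an (l, d) model."""
    fr = neighbor_probability_exact(l, d)
    dec = Decimal(fr.numerator) / Decimal(fr.denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RecallInput:
    """Known (planted) and predicted base-position sets for recall.

    Positions are (sequence index, base coordinate) pairs covering whole
    instance windows; for one-occurrence-per-sequence data the known set
    has exactly ``m * l`` elements.
    """

    known_positions: frozenset[BasePosition]
    predicted_positions: frozenset[BasePosition]


def recall_rate(rin: RecallInput) -> float:
    """Fraction of known planted base positions covered by predictions.

    ``|known ∩ predicted| / |known|``; equals 1 exactly when every
    planted base position was recovered.  Partial window overlap earns
    partial credit because the accounting is per base, not per window.
    """
    known = rin.known_positions
    if not known:
        raise ValueError("known position set must be non-empty")
    return len(known & rin.predicted_positions) / len(known)


def window_positions(starts: Iterable[tuple[int, int]], l: int) -> frozenset[BasePosition]:
    """Expand (sequence index, window start) pairs to the base positions
    the windows cover."""
    out: set[BasePosition] = set()
    for i, j in starts:
        out.update((i, j + off) for off in range(l))
    return frozenset(out)


@dataclass(frozen=True)
class ConsensusResult:
    """Column-wise consensus of a clique's member strings.

    ``consensus`` is over {A, C, G, T, x}: a column shows its plurality
    base when that base's frequency exceeds the dominance threshold,
    otherwise 'x'.  ``valid_within_d`` reports whether every member is
    within d of the ACGT-resolved consensus (x columns resolved to the
    plurality base, ties broken alphabetically).
    """

    consensus: str
    column_counts: tuple[dict[str, int], ...]
    valid_within_d: bool


def consensus_from_clique(
    clique: Clique,
    model: MotifModel,
    dominance_threshold: float = 0.5,
) -> ConsensusResult:
    """Derive the consensus motif from an aligned clique.

    Per column the plurality base is emitted iff its frequency is
    strictly above ``dominance_threshold`` (default 0.5, a strict
    majority); otherwise the column is shown as 'x'.  The plurality base
    at an emitted column is necessarily unique for thresholds >= 0.5.
    """
    strings = clique.strings
    m = len(strings)
    l = model.length
    if any(len(s) != l for s in strings):
        raise ValueError("clique member length does not match motif length")

    consensus_chars: list[str] = []
    resolved_chars: list[str] = []
    counts: list[dict[str, int]] = []
    for col in range(l):
        tally = Counter(s[col] for s in strings)
        counts.append({b: tally.get(b, 0) for b in ALPHABET if tally.get(b, 0)})
        top_count = max(tally.values())
        # deterministic tie-break: alphabetically first plurality base
        top_base = min(b for b, c in tally.items() if c == top_count)
        resolved_chars.append(top_base)
        if top_count / m > dominance_threshold:
            consensus_chars.append(top_base)
        else:
            consensus_chars.append("x")

    resolved = "".join(resolved_chars)
    valid = all(hamming(s, resolved) <= model.max_mutations for s in strings)
    return ConsensusResult(
        consensus="".join(consensus_chars),
        column_counts=tuple(counts),
        valid_within_d=valid,
    )
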