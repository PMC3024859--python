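"""Sequence containers, l-mer (vertex) enumeration and Hamming distance.

DNA sequences live in a :class:`SequenceSet`, an ordered, validated
collection over the alphabet {A, C, G, T}.  A *vertex* is a length-``l``
window of one sequence, named by :class:`VertexRef` = (sequence index,
0-based start offset).  The pairwise Hamming distance between vertices is
the primitive that drives the clique search: under the planted (l, d)
model every two motif instances lie within ``2d`` of each other, so the
derived threshold ``2d`` is stored on :class:`MotifModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"

#: byte value marking a base outside {A,C,G,T} when ambiguity codes are kept
AMBIGUOUS_CODE = 255

_ENCODE = np.full(256, AMBIGUOUS_CODE, dtype=np.uint8)
for _idx, _base in enumerate(ALPHABET):
    _ENCODE[ord(_base)] = _idx

# IUPAC one-letter ambiguity codes (anything valid in a DNA FASTA record
# that is not a concrete base); '-' and '.' gaps are never accepted.
IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")


class SequenceError(ValueError):
    """Base class for sequence ingestion/validation failures."""


class FastaFormatError(SequenceError):
    """The input is not usable FASTA (empty file, no records)."""


class AlphabetError(SequenceError):
    """A record contains a character outside the accepted alphabet."""


class InstanceTooShortError(ValueError):
    """A sequence is shorter than the motif length l."""


@dataclass(frozen=True)
class MotifModel:
    """The (l, d) motif model: length and maximum per-instance mutations.

    Parameters
    ----------
    length
        Motif length ``l`` in bases, at least 1.
    max_mutations
        Maximum Hamming distance ``d`` between a motif instance and the
        (unknown) true motif.  Must satisfy ``0 <= d < l``.
    """

    length: int
    max_mutations: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"motif length must be >= 1, got {self.length}")
        if self.max_mutations < 0:
            raise ValueError(
                f"mutation bound must be >= 0, got {self.max_mutations}"
            )
        if self.max_mutations >= self.length:
            raise ValueError(
                f"mutation bound d={self.max_mutations} must be smaller than "
                f"motif length l={self.length}"
            )

    @property
    def threshold(self) -> int:
        """Pairwise instance-instance distance bound ``2d``."""
        return 2 * self.max_mutations


@dataclass(frozen=True, order=True)
class VertexRef:
    """Names the l-mer starting at offset ``start`` of sequence ``seq_index``.

    Coordinates are 0-based; the window is half-open, ``[start, start+l)``.
    """

    seq_index: int
    start: int


class SequenceSet:
    """Ordered, validated set of DNA sequences (the search input ``S``).

    Record order is preserved exactly as given: sequence 0 is the first
    reference sequence of the search.  Bases are case-folded to upper
    case.  By default any character outside {A,C,G,T} is rejected; with
    ``allow_ambiguous=True`` IUPAC ambiguity codes are kept (encoded as a
    sentinel) and windows containing them are later skipped during vertex
    enumeration.
    """

    def __init__(
        self,
        records: Iterable[tuple[str, str]],
        *,
        allow_ambiguous: bool = False,
    ) -> None:
        ids: list[str] = []
        seqs: list[str] = []
        for rec_id, raw in records:
            seq = str(raw).upper()
            if not seq:
                raise SequenceError(f"record {rec_id!r} is empty")
            for pos, ch in enumerate(seq):
                if ch in ALPHABET:
                    continue
                if allow_ambiguous and ch in IUPAC_AMBIGUOUS:
                    continue
                raise AlphabetError(
                    f"record {rec_id!r} position {pos}: invalid character "
                    f"{ch!r} (alphabet is A/C/G/T"
                    + ("/IUPAC ambiguity codes)" if allow_ambiguous else ")")
                )
            ids.append(str(rec_id))
            seqs.append(seq)
        if len(seqs) < 2:
            raise SequenceError(
                f"need at least 2 sequences, got {len(seqs)}"
            )
        self._ids = ids
        self._seqs = seqs
        self._encoded = [
            _ENCODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
            for s in seqs
        ]

    # -- container protocol -------------------------------------------------
    @property
    def m(self) -> int:
        """Number of sequences."""
        return len(self._seqs)

    def __len__(self) -> int:
        return self.m

    @property
    def ids(self) -> list[str]:
        return list(self._ids)

    @property
    def lengths(self) -> list[int]:
        return [len(s) for s in self._seqs]

    def sequence(self, i: int) -> str:
        return self._seqs[i]

    def encoded(self, i: int) -> np.ndarray:
        """Sequence ``i`` as uint8 codes (A=0, C=1, G=2, T=3, ambiguous=255)."""
        return self._encoded[i]

    def windows(self, i: int, l: int) -> np.ndarray:
        """All l-mer windows of sequence ``i`` as a ``(n_i - l + 1, l)`` view."""
        n_i = len(self._seqs[i])
        if l > n_i:
            raise InstanceTooShortError(
                f"sequence {self._ids[i]!r} has length {n_i} < motif length {l}"
            )
        return sliding_window_view(self._encoded[i], l)

    def lmer(self, ref: VertexRef, l: int) -> str:
        """The l-mer string named by ``ref``."""
        return self._seqs[ref.seq_index][ref.start : ref.start + l]

    def records(self) -> list[tuple[str, str]]:
        return list(zip(self._ids, self._seqs))


def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    Records keep file order; lowercase bases are upcased.  An empty file
    (or one with no FASTA records) raises :class:`FastaFormatError`; a
    record with a character outside {A,C,G,T} raises :class:`AlphabetError`
    naming the record and position, unless ``allow_ambiguous`` is set, in
    which case IUPAC codes are kept and the affected windows are dropped
    at vertex-enumeration time.
    """
    from Bio import SeqIO

    path = Path(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return SequenceSet(records, allow_ambiguous=allow_ambiguous)


def enumerate_vertices(S: SequenceSet, i: int, l: int) -> list[VertexRef]:
    """All vertices of sequence ``i``: the initial candidate set ``P_{0,i}``.

    Returns exactly ``n_i - l + 1`` refs in ascending start order for a
    clean sequence.  Windows containing an ambiguity code (possible only
    when the set was built with ``allow_ambiguous``) are skipped with a
    logged warning.
    """
    win = S.windows(i, l)  # raises InstanceTooShortError if l > n_i
    bad = (win == AMBIGUOUS_CODE).any(axis=1)
    if bad.any():
        logger.warning(
            "sequence %s: skipping %d/%d windows containing ambiguity codes",
            S.ids[i], int(bad.sum()), len(bad),
        )
    return [VertexRef(i, j) for j in np.flatnonzero(~bad)]


def hamming(u: str, v: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(u) != len(v):
        raise ValueError(
            f"hamming distance needs equal lengths, got {len(u)} and {len(v)}"
        )
    return sum(a != b for a, b in zip(u, v))
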