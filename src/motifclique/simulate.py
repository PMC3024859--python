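"""Synthetic planted-motif benchmark generator.

Reproduces the classical motif-challenge protocol: ``m`` i.i.d. uniform
background sequences of length ``n``, a uniform random true motif of
length ``l``, and exactly one mutated instance of it overwritten into
each sequence at a uniform random start in {0, ..., n-l}.  Mutated
positions are distinct and each mutated base is replaced by a uniformly
chosen *different* base, so the realised Hamming distance to the true
motif equals the mutation count.  Two mutation modes:

* ``up_to_d`` (default) — the count is uniform on {0, ..., d}, the
  literal reading of "up to d mutations";
* ``exact_d`` — exactly d positions are mutated, the convention of the
  published challenge benchmarks.

Everything is driven by one :class:`numpy.random.Generator`, so a seed
reproduces the dataset byte-for-byte, FASTA output included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequences import ALPHABET, MotifModel, SequenceSet

MUTATION_MODES = ("up_to_d", "exact_d")

_FASTA_WIDTH = 70


@dataclass(frozen=True)
class PlantedDataset:
    """A synthetic sequence set plus its ground truth.

    ``planted_starts[i]`` and ``planted_instances[i]`` locate and spell
    the instance embedded in sequence ``i``; every instance is within
    ``d`` of ``true_motif`` (exactly ``d`` in exact mode).
    """

    sequences: SequenceSet
    true_motif: str
    planted_starts: tuple[int, ...]
    planted_instances: tuple[str, ...]
    seed: int
    mode: str

    @property
    def model_length(self) -> int:
        return len(self.true_motif)


def generate_planted(
    m: int,
    n: int,
    model: MotifModel,
    *,
    mode: str = "up_to_d",
    seed: int = 0,
) -> PlantedDataset:
    """Generate one planted (l, d) dataset.

    Parameters
    ----------
    m, n
        Number of sequences and their common length; ``n`` must exceed
        the motif length.
    model
        The (l, d) model to plant.
    mode
        ``"up_to_d"`` or ``"exact_d"`` (see module docstring).
    seed
        Seed for the single random stream; identical seeds give
        identical datasets.
    """
    l, d = model.length, model.max_mutations
    if n <= l:
        raise ValueError(f"sequence length n={n} must exceed motif length l={l}")
    if m < 2:
        raise ValueError(f"need at least 2 sequences, got m={m}")
    if mode not in MUTATION_MODES:
        raise ValueError(f"mode must be one of {MUTATION_MODES}, got {mode!r}")

    rng = np.random.default_rng(seed)
    base_arr = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

    motif_codes = rng.integers(0, 4, size=l)
    true_motif = base_arr[motif_codes].tobytes().decode()

    records: list[tuple[str, str]] = []
    starts: list[int] = []
    instances: list[str] = []
    for i in range(m):
        background = rng.integers(0, 4, size=n)
        k = d if mode == "exact_d" else int(rng.integers(0, d + 1))
        inst = motif_codes.copy()
        if k:
            positions = rng.choice(l, size=k, replace=False)
            # shift by 1..3 mod 4: uniform over the three other bases
            shifts = rng.integers(1, 4, size=k)
            inst[positions] = (inst[positions] + shifts) % 4
        start = int(rng.integers(0, n - l + 1))
        background[start : start + l] = inst
        records.append((f"seq{i}", base_arr[background].tobytes().decode()))
        starts.append(start)
        instances.append(base_arr[inst].tobytes().decode())

    return PlantedDataset(
        sequences=SequenceSet(records),
        true_motif=true_motif,
        planted_starts=tuple(starts),
        planted_instances=tuple(instances),
        seed=seed,
        mode=mode,
    )


def write_fasta(S: SequenceSet, path: str | Path, *, width: int = _FASTA_WIDTH) -> None:
    """Write the set as wrapped FASTA; fixed layout so output is
    byte-identical across runs of the same dataset."""
    with open(path, "w") as fh:
        for rec_id, seq in S.records():
            fh.write(f">{rec_id}\n")
            for off in range(0, len(seq), width):
                fh.write(seq[off : off + width] + "\n")


def write_truth(ds: PlantedDataset, tsv_path: str | Path, motif_path: str | Path) -> None:
    """Write the ground-truth sidecar: a TSV of per-sequence planted
    windows and a one-line true-motif file."""
    from .sequences import hamming

    with open(tsv_path, "w") as fh:
        fh.write("seq_id\tstart_0based\tinstance\tdistance_to_motif\n")
        for rec_id, start, inst in zip(
            ds.sequences.ids, ds.planted_starts, ds.planted_instances
        ):
            fh.write(f"{rec_id}\t{start}\t{inst}\t{hamming(inst, ds.true_motif)}\n")
    with open(motif_path, "w") as fh:
        fh.write(ds.true_motif + "\n")


def read_truth(tsv_path: str | Path) -> list[tuple[str, int, str]]:
    """Parse a ground-truth TSV back into (seq_id, start, instance) rows."""
    rows: list[tuple[str, int, str]] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["seq_id", "start_0based", "instance"]:
            raise ValueError(f"{tsv_path}: not a ground-truth TSV (header {header})")
        for line in fh:
            if not line.strip():
                continue
            seq_id, start, inst = line.rstrip("\n").split("\t")[:3]
            rows.append((seq_id, int(start), inst))
    return rows
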