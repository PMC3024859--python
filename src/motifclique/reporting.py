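"""Fixed-format reports: the clique TSV and the consensus text block.

The clique TSV layout is part of the package contract (tools downstream
parse it): a header row of ``clique`` followed by the sequence ids, one
row per clique with cells ``seq_id:start0:lmer`` (0-based starts), and a
trailing comment line with the total count (plus an ``incomplete``
marker when the search stopped early).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .search import Clique, SearchResult, VertexRef
from .sequences import MotifModel, SequenceSet
from .stats import ConsensusResult, consensus_from_clique


def format_clique_tsv(
    S: SequenceSet, result: SearchResult
) -> str:
    ids = S.ids
    lines = ["clique\t" + "\t".join(ids)]
    for idx, clique in enumerate(result.cliques):
        cells = [
            f"{ids[v.seq_index]}:{v.start}:{s}"
            for v, s in zip(clique.members, clique.strings)
        ]
        lines.append(f"{idx}\t" + "\t".join(cells))
    suffix = "" if result.complete else "\tincomplete"
    lines.append(f"# cliques\t{len(result.cliques)}{suffix}")
    return "\n".join(lines) + "\n"


def write_clique_tsv(S: SequenceSet, result: SearchResult, path: str | Path) -> None:
    Path(path).write_text(format_clique_tsv(S, result))


def read_clique_tsv(path: str | Path) -> tuple[list[str], list[list[tuple[str, int, str]]]]:
    """Parse a clique TSV back into (sequence ids, cliques), each clique
    a list of (seq_id, start, lmer)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("clique\t"):
        raise ValueError(f"{path}: not a clique TSV")
    ids = lines[0].split("\t")[1:]
    cliques: list[list[tuple[str, int, str]]] = []
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")[1:]
        members = []
        for cell in cells:
            seq_id, start, lmer = cell.rsplit(":", 2)
            members.append((seq_id, int(start), lmer))
        cliques.append(members)
    return ids, cliques


def format_consensus_report(
    S: SequenceSet,
    result: SearchResult,
    model: MotifModel,
    dominance_threshold: float = 0.5,
) -> str:
    """Plain-text block per clique: consensus string, per-column counts,
    within-d validity flag.  1-based starts are printed alongside the
    0-based ones for human reading."""
    blocks: list[str] = []
    for idx, clique in enumerate(result.cliques):
        cons: ConsensusResult = consensus_from_clique(
            clique, model, dominance_threshold
        )
        lines = [
            f"clique {idx}",
            f"  consensus: {cons.consensus}",
            f"  valid_within_d: {'yes' if cons.valid_within_d else 'no'}",
        ]
        for v, s in zip(clique.members, clique.strings):
            lines.append(
                f"  {S.ids[v.seq_index]}  start0={v.start}  start1={v.start + 1}  {s}"
            )
        for col, counts in enumerate(cons.column_counts):
            shown = " ".join(f"{b}={c}" for b, c in sorted(counts.items()))
            lines.append(f"  col {col:>2} [{cons.consensus[col]}]  {shown}")
        blocks.append("\n".join(lines))
    return ("\n\n".join(blocks) + "\n") if blocks else "no cliques\n"
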