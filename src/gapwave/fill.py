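"""Candidate gap fills and pseudo-read emission.

Each gap is decoded twice: *forward* (left to right, seeded by the tail of
the left flank) and *reverse* (the right flank is reverse-complemented so
that decoding again runs left to right, and the decoded sequence is
complemented back). Candidates are stored in reference orientation. The
top candidates are wrapped in flank margins and written as FASTA
pseudo-reads that a downstream gap filler can add to its read set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

from .corpus import reverse_complement
from .decode import DecodeConfig, NextBaseScorer, wave_beam_search
from .gapio import FlankPair, GapRecord

DEFAULT_MARGIN = 50  # flank bases wrapped around each pseudo-read


@dataclass(frozen=True)
class CandidateFill:
    """One candidate gap sequence in reference orientation."""

    gap: GapRecord
    direction: str  # "forward" | "reverse"
    sequence: str
    score: float


def generate_fills(
    model: NextBaseScorer,
    flanks: FlankPair,
    cfg: DecodeConfig,
    length_slack: int = 0,
) -> List[CandidateFill]:
    """Decode candidate fills in both directions for one gap.

    A direction whose flank is shorter than the model context is skipped
    with a warning; if both are too short this raises. ``length_slack``
    decodes extra bases beyond the N-run length for downstream trimming.
    """
    W = model.context_length
    target = flanks.gap.length + length_slack
    dcfg = DecodeConfig(
        target_length=target,
        expansion_limit=cfg.expansion_limit,
        keep=cfg.keep,
        n_best=cfg.n_best,
        accumulate=cfg.accumulate,
    )
    fills: List[CandidateFill] = []
    skipped = []
    if len(flanks.left) >= W:
        for node in wave_beam_search(model, flanks.left[-W:], dcfg):
            fills.append(CandidateFill(flanks.gap, "forward", node.bases, node.score))
    else:
        skipped.append("forward")
    if len(flanks.right) >= W:
        # Decode on the reverse-complement strand, then restore orientation.
        seed = reverse_complement(flanks.right[:W])
        for node in wave_beam_search(model, seed, dcfg):
            fills.append(
                CandidateFill(flanks.gap, "reverse", reverse_complement(node.bases), node.score)
            )
    else:
        skipped.append("reverse")
    if len(skipped) == 2:
        raise ValueError(
            f"both flanks of gap {flanks.gap} are shorter than the model context ({W})"
        )
    for direction in skipped:
        warnings.warn(
            f"gap {flanks.gap.scaffold_id}:{flanks.gap.start}-{flanks.gap.end}: "
            f"{direction} flank shorter than model context ({W}); direction skipped"
        )
    return fills


def emit_augmented_reads(
    fills: Sequence[CandidateFill],
    flanks: Mapping[GapRecord, FlankPair],
    margin: int,
    path,
) -> None:
    """Write candidate fills as flank-anchored FASTA pseudo-reads.

    Each record is (last ``margin`` bases of the left flank) + candidate +
    (first ``margin`` bases of the right flank); headers encode gap,
    direction, rank and score and are unique.
    """
    if not fills:
        raise ValueError("no candidate fills to emit")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    rank: Dict[tuple, int] = {}
    with open(path, "w") as fh:
        for fill in fills:
            key = (fill.gap, fill.direction)
            rank[key] = rank.get(key, 0) + 1
            fp = flanks[fill.gap]
            left = fp.left[-margin:] if margin else ""
            right = fp.right[:margin] if margin else ""
            header = (
                f"{fill.gap.scaffold_id}:{fill.gap.start}-{fill.gap.end}"
                f"|{fill.direction}|rank{rank[key]}|score={fill.score:.6f}"
            )
            fh.write(f">{header}\n{left}{fill.sequence}{right}\n")


def best_fill_per_gap(fills: Sequence[CandidateFill]) -> Dict[GapRecord, CandidateFill]:
    """Highest-scoring candidate per gap (ties: first in input order)."""
    best: Dict[GapRecord, CandidateFill] = {}
    for f in fills:
        if f.gap not in best or f.score > best[f.gap].score:
            best[f.gap] = f
    return best


def splice_fills(scaffold_seq: str, fills_by_gap: Mapping[GapRecord, CandidateFill]) -> str:
    """Replace each gap's N-run with its candidate sequence (same length)."""
    seq = list(scaffold_seq)
    for gap, fill in fills_by_gap.items():
        seq[gap.start : gap.end] = fill.sequence[: gap.length]
    return "".join(seq)
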