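"""End-to-end gap closing: flanks -> read recruitment -> training -> decoding.

Thin orchestration over the library modules; the CLI and the test fixtures
both run through here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .corpus import (
    DEFAULT_K,
    DEFAULT_MIN_SHARED,
    ReadSet,
    fragment_sequences,
    make_windows,
    recruit_reads,
    reverse_complement,
    subsample_windows,
)
from .decode import DecodeConfig
from .fill import CandidateFill, generate_fills
from .gapio import (
    DEFAULT_FLANK_LEN,
    FlankPair,
    GapRecord,
    GenomeSequence,
    extract_flanks,
    find_gaps,
)
from .nextbase import ModelConfig, NextBaseModel, build_model, train


@dataclass
class PipelineResult:
    model: NextBaseModel
    gaps: List[GapRecord]
    flanks: Dict[GapRecord, FlankPair]
    fills: Dict[GapRecord, List[CandidateFill]]
    n_recruited: int
    n_windows: int


def build_training_windows(
    reads: Sequence[str],
    bait: Sequence[str],
    W: int,
    k: int = DEFAULT_K,
    min_shared: int = DEFAULT_MIN_SHARED,
    stride: int = 1,
    homolog_sequences: Optional[Sequence[str]] = None,
    max_windows: Optional[int] = None,
    seed: int = 0,
):
    """Recruit reads (and homolog fragments) against the bait and window them.

    Both strands of every recruited sequence enter the corpus, since read
    strand is unknown.
    """
    recruited = recruit_reads(reads, bait, k=k, min_shared=min_shared, source="target")
    if homolog_sequences:
        frags = fragment_sequences(homolog_sequences)
        hom = recruit_reads(frags, bait, k=k, min_shared=min_shared, source="homolog")
        recruited = ReadSet(
            reads=recruited.reads + hom.reads, sources=recruited.sources + hom.sources
        )
    both_strands: List[str] = []
    for r in recruited.reads:
        both_strands.append(r)
        both_strands.append(reverse_complement(r))
    windows = make_windows(both_strands, W=W, stride=stride)
    windows = subsample_windows(windows, max_windows, seed)
    return windows, recruited


def close_gaps(
    scaffolds: Sequence[GenomeSequence],
    reads: Sequence[str],
    model_cfg: ModelConfig,
    decode_cfg: DecodeConfig,
    flank_len: int = DEFAULT_FLANK_LEN,
    k: int = DEFAULT_K,
    min_shared: int = DEFAULT_MIN_SHARED,
    stride: int = 1,
    homolog_sequences: Optional[Sequence[str]] = None,
    max_windows: Optional[int] = 20_000,
    min_gap_len: int = 1,
    verbose: bool = False,
) -> PipelineResult:
    """Run the full pipeline on a set of scaffolds.

    Finds gaps, extracts flanks, recruits a training corpus around them,
    trains the next-base model, and decodes candidate fills for every gap
    whose flanks can seed the decoder.
    """
    gaps: List[GapRecord] = []
    flanks: Dict[GapRecord, FlankPair] = {}
    by_id = {s.id: s for s in scaffolds}
    for scaf in scaffolds:
        for gap in find_gaps(scaf, min_len=min_gap_len):
            gaps.append(gap)
            flanks[gap] = extract_flanks(scaf, gap, flank_len=flank_len)
    if not gaps:
        raise ValueError("no gaps found on the input scaffolds")
    bait = [f for fp in flanks.values() for f in (fp.left, fp.right) if f]
    windows, recruited = build_training_windows(
        reads,
        bait,
        W=model_cfg.context_length,
        k=k,
        min_shared=min_shared,
        stride=stride,
        homolog_sequences=homolog_sequences,
        max_windows=max_windows,
        seed=model_cfg.seed,
    )
    if not windows:
        raise ValueError("recruited corpus produced no training windows")
    model = build_model(model_cfg)
    train(model, windows, verbose=verbose)
    fills: Dict[GapRecord, List[CandidateFill]] = {}
    W = model_cfg.context_length
    for gap in gaps:
        fp = flanks[gap]
        if len(fp.left) < W and len(fp.right) < W:
            continue  # no usable seed context on either side
        fills[gap] = generate_fills(model, fp, decode_cfg)
    return PipelineResult(
        model=model,
        gaps=gaps,
        flanks=flanks,
        fills=fills,
        n_recruited=len(recruited),
        n_windows=len(windows),
    )
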