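"""Gap-sequence decoding from a next-base model.

Three decoders share scoring and tie-breaking rules:

``wave_beam_search``
    Alternates unpruned *expand* phases with *contract* phases: every
    surviving partial path is extended by all four bases each level; only
    when the node count reaches ``expansion_limit`` are all but the ``keep``
    best (by cumulative path score) discarded. Delaying pruning until many
    levels of evidence have accumulated avoids the early loss of
    high-probability paths that fixed-width beam search suffers from.

``beam_search``
    Classic fixed-width beam (prune to ``width`` best after every level);
    ``width=1`` is greedy decoding.

``brute_force_decode``
    Exhaustive enumeration of all 4**L sequences; the test oracle.

A path's score is the cumulative log-probability, i.e. the sum over steps
of log P(base | trailing W characters of seed + prefix). An alternative
``accumulate="sum"`` mode adds raw probabilities instead (the literal
"cumulative sum" reading); both use identical pruning machinery. Ties are
broken lexicographically on the base string so output is deterministic.

Any object with a ``context_length`` attribute and a
``predict_proba(contexts) -> (n, 4)`` method can serve as the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Protocol, Sequence

import numpy as np

from .corpus import BASES

_LOG_FLOOR = 1e-300  # probabilities are clipped here before log

BRUTE_FORCE_MAX_LEN = 10


class NextBaseScorer(Protocol):
    context_length: int

    def predict_proba(self, contexts: Sequence[str]) -> np.ndarray: ...


@dataclass(frozen=True)
class PathNode:
    """A partial or complete decoded sequence with its cumulative score."""

    bases: str
    score: float


@dataclass
class DecodeConfig:
    """Wave-beam decoding parameters.

    expansion_limit: node count at which a contract phase triggers.
    keep: nodes retained by a contraction.
    n_best: complete paths returned.
    target_length: bases to decode (the gap's N-run length).
    accumulate: "log" for cumulative log-probability (default), "sum" for
        the literal running sum of raw probabilities.
    """

    target_length: int
    expansion_limit: int = 1024
    keep: int = 16
    n_best: int = 4
    accumulate: str = "log"

    def __post_init__(self) -> None:
        if self.target_length < 1:
            raise ValueError("target_length must be >= 1")
        if self.keep < 1 or self.expansion_limit < 1 or self.n_best < 1:
            raise ValueError("keep, expansion_limit and n_best must be >= 1")
        if self.keep > self.expansion_limit:
            raise ValueError("keep must not exceed expansion_limit")
        if self.n_best > self.keep:
            raise ValueError("n_best must not exceed keep")
        if self.accumulate not in ("log", "sum"):
            raise ValueError("accumulate must be 'log' or 'sum'")


def _sort_nodes(nodes: List[PathNode]) -> List[PathNode]:
    """Descending score, lexicographic tie-break on the base string."""
    return sorted(nodes, key=lambda n: (-n.score, n.bases))


def _expand_all(
    model: NextBaseScorer, seed_context: str, nodes: List[PathNode], accumulate: str
) -> List[PathNode]:
    """Extend every node by all four bases, scoring with the model on the
    trailing W characters of seed + prefix."""
    W = model.context_length
    contexts = [(seed_context + n.bases)[-W:] for n in nodes]
    probs = np.asarray(model.predict_proba(contexts))
    if accumulate == "log":
        step = np.log(np.clip(probs, _LOG_FLOOR, None))
    else:
        step = probs
    out: List[PathNode] = []
    for node, row in zip(nodes, step):
        for b_idx, base in enumerate(BASES):
            out.append(PathNode(node.bases + base, node.score + float(row[b_idx])))
    return out


def _check_seed(model: NextBaseScorer, seed_context: str) -> None:
    if len(seed_context) != model.context_length:
        raise ValueError(
            f"seed context length {len(seed_context)} != model context length "
            f"{model.context_length}"
        )


def wave_beam_search(
    model: NextBaseScorer, seed_context: str, cfg: DecodeConfig
) -> List[PathNode]:
    """Expand-contract decoding; returns the n_best complete paths, best first."""
    _check_seed(model, seed_context)
    nodes = [PathNode("", 0.0)]
    for _level in range(cfg.target_length):
        nodes = _expand_all(model, seed_context, nodes, cfg.accumulate)
        if len(nodes) >= cfg.expansion_limit:
            nodes = _sort_nodes(nodes)[: cfg.keep]
    return _sort_nodes(nodes)[: cfg.n_best]


def beam_search(
    model: NextBaseScorer,
    seed_context: str,
    target_length: int,
    width: int,
    n_best: int = 1,
    accumulate: str = "log",
) -> List[PathNode]:
    """Classic fixed-width beam search; width=1 is greedy decoding."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if width < 1:
        raise ValueError("width must be >= 1")
    _check_seed(model, seed_context)
    nodes = [PathNode("", 0.0)]
    for _level in range(target_length):
        nodes = _sort_nodes(_expand_all(model, seed_context, nodes, accumulate))[:width]
    return _sort_nodes(nodes)[:n_best]


def greedy_decode(model: NextBaseScorer, seed_context: str, target_length: int) -> PathNode:
    """Argmax chain of predict_next; identical to beam width 1."""
    return beam_search(model, seed_context, target_length, width=1, n_best=1)[0]


def brute_force_decode(
    model: NextBaseScorer,
    seed_context: str,
    target_length: int,
    n_best: int = 1,
    accumulate: str = "log",
) -> List[PathNode]:
    """Exhaustively score all 4**target_length sequences (test oracle)."""
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    if target_length > BRUTE_FORCE_MAX_LEN:
        raise ValueError(
            f"brute force enumeration limited to length {BRUTE_FORCE_MAX_LEN}"
        )
    _check_seed(model, seed_context)
    nodes = [PathNode("", 0.0)]
    for _level in range(target_length):
        nodes = _expand_all(model, seed_context, nodes, accumulate)
    return _sort_nodes(nodes)[:n_best]
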