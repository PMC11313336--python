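"""Training-corpus construction: k-mer read recruitment and window encoding.

Reads related to the gap neighbourhoods are recruited by exact canonical
k-mer membership against a bait set (the gap flanks, or fragments of a
homologous genome). Recruited sequence is then cut into fixed-length
(context, next-base) windows and one-hot encoded for the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_K = 25
DEFAULT_MIN_SHARED = 1
DEFAULT_WINDOW = 64
HOMOLOG_FRAGMENT_LEN = 150

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"cannot complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReadSet:
    """Recruited reads with their provenance (target reads vs homolog fragments)."""

    reads: List[str]
    sources: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass(frozen=True)
class TrainingWindow:
    """A context of W bases and the base that follows it."""

    context: str
    label: str


def canonical_kmers(seq: str, k: int) -> Set[str]:
    """Distinct canonical k-mers of seq (lexicographic min of k-mer and its
    reverse complement); k-mers containing N are skipped."""
    out: Set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = reverse_complement(kmer)
        out.add(min(kmer, rc))
    return out


def recruit_reads(
    reads: Sequence[str],
    bait: Sequence[str],
    k: int = DEFAULT_K,
    min_shared: int = DEFAULT_MIN_SHARED,
    source: str = "target",
) -> ReadSet:
    """Select reads sharing >= min_shared canonical k-mers with the bait set.

    The bait is typically the set of gap flanks. Strand-insensitive by
    construction (canonical k-mers).
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if not bait:
        raise ValueError("empty bait set")
    if all(len(b) < k for b in bait):
        raise ValueError(f"k={k} exceeds the length of every bait sequence")
    bait_kmers: Set[str] = set()
    for b in bait:
        bait_kmers |= canonical_kmers(b.upper(), k)
    kept: List[str] = []
    sources: List[str] = []
    for read in reads:
        read = read.upper()
        if len(read) < k:
            continue
        shared = 0
        seen: Set[str] = set()
        for i in range(len(read) - k + 1):
            kmer = read[i : i + k]
            if "N" in kmer or kmer in seen:
                continue
            seen.add(kmer)
            rc = reverse_complement(kmer)
            if min(kmer, rc) in bait_kmers:
                shared += 1
                if shared >= min_shared:
                    break
        if shared >= min_shared:
            kept.append(read)
            sources.append(source)
    return ReadSet(reads=kept, sources=sources)


def fragment_sequences(sequences: Iterable[str], fragment_len: int = HOMOLOG_FRAGMENT_LEN) -> List[str]:
    """Tile long sequences (e.g. a homologous genome) into read-sized pieces
    so they can flow through the same recruiter as real reads."""
    frags: List[str] = []
    for seq in sequences:
        seq = seq.upper()
        for i in range(0, max(1, len(seq) - fragment_len + 1), fragment_len):
            frag = seq[i : i + fragment_len]
            if frag:
                frags.append(frag)
    return frags


def make_windows(sequences: Sequence[str], W: int = DEFAULT_WINDOW, stride: int = 1) -> List[TrainingWindow]:
    """Enumerate (context, next-base) pairs at the given stride.

    Windows whose context or label contains N are skipped. Order is
    deterministic: sequence by sequence, left to right.
    """
    if W < 1 or stride < 1:
        raise ValueError("W and stride must be >= 1")
    windows: List[TrainingWindow] = []
    for seq in sequences:
        seq = seq.upper()
        for start in range(0, len(seq) - W, stride):
            chunk = seq[start : start + W + 1]
            if "N" in chunk:
                continue
            windows.append(TrainingWindow(context=chunk[:W], label=chunk[W]))
    return windows


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a sequence over {A,C,G,T} as an (L, 4) 0/1 matrix.

    Row order follows the sequence; column order is (A, C, G, T), i.e.
    A -> [1,0,0,0], C -> [0,1,0,0], G -> [0,0,1,0], T -> [0,0,0,1].
    """
    if not seq:
        raise ValueError("cannot encode an empty sequence")
    try:
        idx = [BASE_INDEX[c] for c in seq]
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None
    mat = np.zeros((len(seq), 4), dtype=np.float64)
    mat[np.arange(len(seq)), idx] = 1.0
    return mat


def windows_to_arrays(windows: Sequence[TrainingWindow]) -> Tuple[np.ndarray, np.ndarray]:
    """Pack windows into integer arrays: contexts (N, W) and labels (N,),
    values 0..3 in (A,C,G,T) order."""
    if not windows:
        raise ValueError("empty window list")
    W = len(windows[0].context)
    ctx = np.empty((len(windows), W), dtype=np.uint8)
    lab = np.empty(len(windows), dtype=np.uint8)
    for i, w in enumerate(windows):
        ctx[i] = [BASE_INDEX[c] for c in w.context]
        lab[i] = BASE_INDEX[w.label]
    return ctx, lab


def subsample_windows(
    windows: Sequence[TrainingWindow], max_windows: Optional[int], seed: int
) -> List[TrainingWindow]:
    """Seeded uniform subsample used to cap corpus size."""
    if max_windows is None or len(windows) <= max_windows:
        return list(windows)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(windows), size=max_windows, replace=False)
    idx.sort()
    return [windows[i] for i in idx]


def save_corpus(windows: Sequence[TrainingWindow], path) -> None:
    """Persist a window corpus as two-column TSV (context, label)."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.context}\t{w.label}\n")


def load_corpus(path) -> List[TrainingWindow]:
    windows: List[TrainingWindow] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            context, label = line.split("\t")
            windows.append(TrainingWindow(context=context, label=label))
    return windows
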