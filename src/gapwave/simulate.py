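"""Synthetic fixtures: reference genome, gapped scaffold, reads, homolog.

Genomes are drawn from a low-order Markov chain (order 0, 1 or 2) so that
sequence entropy is controllable: a near-deterministic order-1 chain gives
the low-complexity regime in which assembly gaps typically arise and which
a small next-base model can genuinely learn. Gaps are cut from the genome
as N-runs with the masked truth retained as recovery targets; reads are
uniform single-end substrings from both strands with optional substitution
errors. All randomness descends from one master seed, split per component
with ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .corpus import BASES, reverse_complement
from .gapio import GapRecord, GenomeSequence, write_bed, write_fasta

_STREAM_GENOME, _STREAM_GAPS, _STREAM_READS = 0, 1, 2


@dataclass
class SimConfig:
    """Fixture parameters; defaults give a desk-scale gap-closing study."""

    genome_length: int = 20_000
    gc: float = 0.5
    n_gaps: int = 10
    gap_length_range: Tuple[int, int] = (20, 50)
    read_length: int = 100
    coverage: float = 20.0
    error_rate: float = 0.0
    repeat_fraction: float = 0.0
    markov_order: int = 1
    transition: Optional[np.ndarray] = None  # (4**order, 4) row-stochastic
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.read_length < 1:
            raise ValueError("genome_length and read_length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be >= 0")
        lo, hi = self.gap_length_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid gap_length_range")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0, 1]")
        if self.markov_order not in (0, 1, 2):
            raise ValueError("markov_order must be 0, 1 or 2")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.transition is not None:
            t = np.asarray(self.transition, dtype=float)
            expected = (4**self.markov_order, 4)
            if t.shape != expected:
                raise ValueError(f"transition must have shape {expected}")
            if not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("transition rows must sum to 1")
            self.transition = t


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def near_deterministic_transition(dominant_p: float, seed: int = 0) -> np.ndarray:
    """Order-1 transition whose dominant moves form a random 4-cycle.

    Each base's dominant successor carries probability ``dominant_p``; the
    remaining mass is uniform over the other three bases. The dominant
    moves form a single 4-cycle so the noiseless skeleton visits all four
    bases (a low-complexity, tandem-repeat-like sequence).
    """
    if not 0.25 < dominant_p < 1.0:
        raise ValueError("dominant_p must be in (0.25, 1)")
    rng = np.random.default_rng(seed)
    cycle = rng.permutation(4)
    succ = np.empty(4, dtype=int)
    for i in range(4):
        succ[cycle[i]] = cycle[(i + 1) % 4]
    t = np.full((4, 4), (1.0 - dominant_p) / 3.0)
    t[np.arange(4), succ] = dominant_p
    return t


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def simulate_genome(cfg: SimConfig, seq_id: str = "ref") -> GenomeSequence:
    """Seeded Markov-chain genome with optional implanted repeats."""
    rng = _rng(cfg, _STREAM_GENOME)
    L = cfg.genome_length
    p0 = _base_probs(cfg.gc)
    order = cfg.markov_order
    if cfg.transition is not None:
        trans = cfg.transition
    else:
        # Without an explicit transition matrix, all conditionals equal the
        # base composition (the chain degenerates to iid draws).
        trans = np.tile(p0, (4**order, 1))
    cum = np.cumsum(trans, axis=1)
    u = rng.random(L)
    if order == 0:
        idx = np.minimum(
            np.searchsorted(cum[0], u, side="right"), 3
        ).astype(np.uint8)
    else:
        idx = np.empty(L, dtype=np.uint8)
        state = 0
        # warm-up: draw the first `order` bases from the base composition
        p0_cum = np.cumsum(p0)
        for i in range(min(order, L)):
            idx[i] = min(int(np.searchsorted(p0_cum, u[i], side="right")), 3)
            state = state * 4 + int(idx[i])
        mask = 4 ** max(order - 1, 0)
        for i in range(order, L):
            b = min(int(np.searchsorted(cum[state], u[i], side="right")), 3)
            idx[i] = b
            state = ((state % mask) * 4 + b) if order > 1 else b
    seq = np.array(list(BASES), dtype="U1")[idx]
    if cfg.repeat_fraction > 0.0:
        seq = _implant_repeats(seq, cfg, rng)
    return GenomeSequence(id=seq_id, seq="".join(seq))


def _implant_repeats(seq: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    L = len(seq)
    motif_len = min(100, max(10, L // 20))
    src = int(rng.integers(0, L - motif_len + 1))
    motif = seq[src : src + motif_len].copy()
    n_copies = int(np.ceil(cfg.repeat_fraction * L / motif_len))
    for _ in range(n_copies):
        pos = int(rng.integers(0, L - motif_len + 1))
        seq[pos : pos + motif_len] = motif
    return seq


def make_gapped_scaffold(
    genome: GenomeSequence, cfg: SimConfig, scaffold_id: Optional[str] = None
) -> Tuple[GenomeSequence, List[GapRecord], List[str]]:
    """Mask n_gaps disjoint intervals with N; returns (scaffold, gaps, truth).

    Gaps are kept at least ``read_length`` bases apart and away from the
    sequence ends so every gap retains clean flanks.
    """
    rng = _rng(cfg, _STREAM_GAPS)
    scaffold_id = scaffold_id or f"{genome.id}_scaffold"
    L = len(genome)
    lo, hi = cfg.gap_length_range
    n = cfg.n_gaps
    if n == 0:
        return GenomeSequence(scaffold_id, genome.seq), [], []
    lengths = rng.integers(lo, hi + 1, size=n)
    spacing = cfg.read_length
    slack = L - int(lengths.sum()) - (n + 1) * spacing
    if slack < 0:
        raise ValueError(
            f"cannot place {n} gaps of {lo}-{hi} bases with {spacing}-base spacing "
            f"in a {L}-base genome"
        )
    offsets = np.sort(rng.integers(0, slack + 1, size=n))
    seq = list(genome.seq)
    gaps: List[GapRecord] = []
    truth: List[str] = []
    pos = 0
    for i in range(n):
        start = spacing * (i + 1) + int(lengths[:i].sum()) + int(offsets[i])
        end = start + int(lengths[i])
        truth.append(genome.seq[start:end])
        seq[start:end] = "N" * (end - start)
        gaps.append(GapRecord(scaffold_id, start, end))
        pos = end
    assert pos + spacing <= L
    return GenomeSequence(scaffold_id, "".join(seq)), gaps, truth


def simulate_reads(genome: GenomeSequence, cfg: SimConfig) -> List[str]:
    """Uniform single-end reads from both strands at the requested coverage,
    with iid substitution errors at ``error_rate``."""
    if cfg.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = _rng(cfg, _STREAM_READS)
    L = len(genome)
    rl = cfg.read_length
    n_reads = int(round(L * cfg.coverage / rl))
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    base_arr = np.frombuffer(genome.seq.encode(), dtype="S1")
    base_idx = np.zeros(L, dtype=np.uint8)
    for i, b in enumerate(BASES):
        base_idx[base_arr == b.encode()] = i
    reads: List[str] = []
    letters = np.array(list(BASES), dtype="U1")
    for s, strand in zip(starts, strands):
        r = base_idx[s : s + rl].copy()
        if cfg.error_rate > 0.0:
            err = rng.random(rl) < cfg.error_rate
            if err.any():
                # substitute with one of the three other bases
                r[err] = (r[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        read = "".join(letters[r])
        if strand:
            read = reverse_complement(read)
        reads.append(read)
    return reads


def simulate_homolog(
    genome: GenomeSequence, divergence: float = 0.02, seed: int = 0, seq_id: str = "homolog"
) -> GenomeSequence:
    """A diverged copy of the genome (iid substitutions at ``divergence``),
    standing in for a related species' genome in corpus enrichment."""
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    idx = np.array([BASES.index(c) if c in BASES else 0 for c in genome.seq], dtype=np.uint8)
    mut = rng.random(len(idx)) < divergence
    idx[mut] = (idx[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
    letters = np.array(list(BASES), dtype="U1")
    seq = letters[idx]
    # keep N positions as N
    out = np.array(list(genome.seq), dtype="U1")
    not_n = out != "N"
    out[not_n] = seq[not_n]
    return GenomeSequence(id=seq_id, seq="".join(out))


def write_reads_fastq(reads: Sequence[str], path) -> None:
    """Write reads as FASTQ with flat quality."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read_{i}\n{read}\n+\n{'I' * len(read)}\n")


def write_fixture(cfg: SimConfig, outdir) -> dict:
    """Generate and write the full fixture set; returns the file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    scaffold, gaps, truth = make_gapped_scaffold(genome, cfg)
    reads = simulate_reads(genome, cfg)
    paths = {
        "reference": outdir / "reference.fa",
        "scaffold": outdir / "scaffold.fa",
        "bed": outdir / "gaps.bed",
        "reads": outdir / "reads.fq",
        "truth": outdir / "truth.tsv",
    }
    write_fasta([genome], paths["reference"])
    write_fasta([scaffold], paths["scaffold"])
    write_bed(gaps, paths["bed"])
    write_reads_fastq(reads, paths["reads"])
    with open(paths["truth"], "w") as fh:
        for gap, t in zip(gaps, truth):
            fh.write(f"{gap.scaffold_id}\t{gap.start}\t{gap.end}\t{t}\n")
    return {k: str(v) for k, v in paths.items()}
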