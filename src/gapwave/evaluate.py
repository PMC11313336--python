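"""Closure evaluation: consistency rate against the reference gap sequence.

The evaluation anchors each gap on the reference genome with long-trimmed
flanks (exact, unique substring match), then extracts the reference
sequence between short-trimmed flank ends — the true gap content plus a
few anchor bases on each side. A filled sequence is compared to that
reference by global pairwise alignment; the *consistency rate* is the
percentage of alignment columns that are identities. A gap counts as
closed at 100% when the rate is exactly 100, and in the >90% bucket under
a strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

from Bio import Align

from .gapio import FlankPair, GapRecord, GenomeSequence, extract_flanks

DEFAULT_LONG_TRIM = 300
DEFAULT_SHORT_TRIM = 20


class UnevaluableGapError(ValueError):
    """The gap's flanks cannot be located uniquely and consistently on the
    reference, so no reference gap sequence exists for it."""


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-gap alignment identity and closure classification."""

    gap: GapRecord
    consistency_rate: float  # percent in [0, 100]
    filled_length: int
    reference_length: int  # true gap content, excluding short-trim anchors

    @property
    def closed_100(self) -> bool:
        return self.consistency_rate >= 100.0

    @property
    def closed_90(self) -> bool:
        return self.consistency_rate > 90.0


@dataclass(frozen=True)
class FillMetrics:
    """Summary closure counts for one filled assembly."""

    gap_count: int
    gap_closed: int
    gap_closed_100: int
    gap_closed_90: int
    residual_n: int


def _find_unique(reference: str, query: str) -> int:
    """Start of the unique occurrence of query in reference, else raise."""
    first = reference.find(query)
    if first == -1:
        raise UnevaluableGapError("flank not found on reference")
    if reference.find(query, first + 1) != -1:
        raise UnevaluableGapError("flank matches multiple reference loci")
    return first


def reference_gap_sequence(
    reference: GenomeSequence,
    flanks: FlankPair,
    long_trim: int = DEFAULT_LONG_TRIM,
    short_trim: int = DEFAULT_SHORT_TRIM,
) -> str:
    """True gap content from the reference, plus short_trim anchor bases.

    The long-trimmed flanks (up to ``long_trim`` bases nearest the gap) are
    located on the reference by exact unique substring match; the returned
    sequence runs from ``short_trim`` bases inside the left match end to
    ``short_trim`` bases past the right match start. Ambiguous, missing or
    misordered flank matches raise :class:`UnevaluableGapError`.
    """
    if long_trim <= short_trim:
        raise ValueError("long_trim must exceed short_trim")
    left = flanks.left[-long_trim:]
    right = flanks.right[:long_trim]
    if not left or not right:
        raise UnevaluableGapError("missing flank")
    ref = reference.seq
    left_start = _find_unique(ref, left)
    right_start = _find_unique(ref, right)
    left_end = left_start + len(left)
    if left_end > right_start:
        raise UnevaluableGapError("flanks map in inconsistent order on reference")
    lo = max(left_start, left_end - short_trim)
    hi = min(right_start + len(right), right_start + short_trim)
    return ref[lo:hi]


def make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    """Biopython aligner with the same scoring; used as an independent
    cross-check of the alignment score."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_stats(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Tuple[float, int, int]:
    """Global (Needleman-Wunsch) alignment; returns (score, identities, columns).

    Among score-optimal alignments the one with the most identities and,
    within those, the fewest alignment columns is chosen. This tie rule
    makes the identity deterministic and invariant under jointly
    reverse-complementing both sequences (co-optimal alignments mirror
    one another, so the lexicographic optimum is preserved).
    """
    m, n = len(a), len(b)
    # DP over lexicographic triples (score max, identities max, columns min)
    S = [[0.0] * (n + 1) for _ in range(m + 1)]
    I = [[0] * (n + 1) for _ in range(m + 1)]
    C = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        S[i][0] = i * gap
        C[i][0] = i
    for j in range(1, n + 1):
        S[0][j] = j * gap
        C[0][j] = j
    for i in range(1, m + 1):
        ai = a[i - 1]
        Si_1, Si = S[i - 1], S[i]
        Ii_1, Ii = I[i - 1], I[i]
        Ci_1, Ci = C[i - 1], C[i]
        for j in range(1, n + 1):
            hit = ai == b[j - 1]
            best = (
                Si_1[j - 1] + (match if hit else mismatch),
                Ii_1[j - 1] + hit,
                -(Ci_1[j - 1] + 1),
            )
            up = (Si_1[j] + gap, Ii_1[j], -(Ci_1[j] + 1))
            if up > best:
                best = up
            left = (Si[j - 1] + gap, Ii[j - 1], -(Ci[j - 1] + 1))
            if left > best:
                best = left
            Si[j], Ii[j], Ci[j] = best[0], best[1], -best[2]
    return S[m][n], I[m][n], C[m][n]


def consistency_rate(
    predicted: str,
    reference: str,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> float:
    """Global-alignment identity in percent: matches / alignment columns x 100.

    Needleman-Wunsch end-to-end alignment with match +1, mismatch -1,
    gap -2 (see :func:`align_stats` for the tie rule). The ``aligner``
    argument only overrides the scoring parameters.
    """
    if not predicted or not reference:
        raise ValueError("consistency_rate requires non-empty sequences")
    if aligner is not None:
        match = float(aligner.match_score)
        mismatch = float(aligner.mismatch_score)
        gap = float(aligner.open_gap_score)
    else:
        match, mismatch, gap = 1.0, -1.0, -2.0
    _, identities, columns = align_stats(predicted, reference, match, mismatch, gap)
    return 100.0 * identities / columns


def evaluate_candidates(
    reference: GenomeSequence,
    scaffold: GenomeSequence,
    gaps: Sequence[GapRecord],
    candidates_by_gap: Mapping[GapRecord, Sequence[str]],
    long_trim: int = DEFAULT_LONG_TRIM,
    short_trim: int = DEFAULT_SHORT_TRIM,
) -> Tuple[List[ConsistencyReport], List[GapRecord]]:
    """Score each gap's best candidate against its reference gap sequence.

    For every gap, each candidate (bare gap-length sequence in reference
    orientation) is wrapped in ``short_trim`` flank anchor bases and
    aligned to the reference gap sequence; the gap's report carries the
    best rate. Returns (reports, unevaluable gaps).
    """
    aligner = make_aligner()
    reports: List[ConsistencyReport] = []
    unevaluable: List[GapRecord] = []
    for gap in gaps:
        flanks = extract_flanks(scaffold, gap, flank_len=long_trim)
        try:
            ref_seq = reference_gap_sequence(reference, flanks, long_trim, short_trim)
        except UnevaluableGapError:
            unevaluable.append(gap)
            continue
        anchor_l = flanks.left[-short_trim:]
        anchor_r = flanks.right[:short_trim]
        best_rate, best_len = 0.0, 0
        for cand in candidates_by_gap.get(gap, []):
            predicted = anchor_l + cand + anchor_r
            rate = consistency_rate(predicted, ref_seq, aligner)
            if rate > best_rate or best_len == 0:
                best_rate, best_len = rate, len(cand)
        reports.append(
            ConsistencyReport(
                gap=gap,
                consistency_rate=best_rate,
                filled_length=best_len,
                reference_length=len(ref_seq) - len(anchor_l) - len(anchor_r),
            )
        )
    return reports, unevaluable


def classify_closures(
    reports: Sequence[ConsistencyReport],
    scaffolds_before: Sequence[GenomeSequence],
    scaffolds_after: Sequence[GenomeSequence],
) -> FillMetrics:
    """Aggregate closure counts and residual N over the filled assembly.

    ``gap_closed`` counts gaps whose original interval holds no N in the
    filled scaffolds; the 100%/ >90% buckets come from the per-gap
    consistency rates; ``residual_n`` counts all N characters remaining.
    """
    after = {s.id: s.seq for s in scaffolds_after}
    gap_closed = 0
    for rep in reports:
        seq = after.get(rep.gap.scaffold_id, "")
        interval = seq[rep.gap.start : rep.gap.end]
        if interval and "N" not in interval:
            gap_closed += 1
    return FillMetrics(
        gap_count=len(reports),
        gap_closed=gap_closed,
        gap_closed_100=sum(r.closed_100 for r in reports),
        gap_closed_90=sum(r.closed_90 for r in reports),
        residual_n=sum(s.seq.count("N") for s in scaffolds_after),
    )


def improvement_pct(closed_new: int, closed_base: int, gap_count: int) -> float:
    """Absolute improvement: (closed_new - closed_base) / gap_count x 100."""
    if gap_count <= 0:
        raise ValueError("gap_count must be positive")
    return 100.0 * (closed_new - closed_base) / gap_count


def relative_improvement_pct(closed_new: int, closed_base: int) -> float:
    """Relative improvement: (closed_new - closed_base) / closed_base x 100."""
    if closed_base <= 0:
        raise ValueError("closed_base must be positive")
    return 100.0 * (closed_new - closed_base) / closed_base


def write_report_tsv(reports: Sequence[ConsistencyReport], unevaluable: Sequence[GapRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "scaffold\tstart\tend\tconsistency_rate\tclosed_100\tclosed_90\t"
            "filled_length\treference_length\tstatus\n"
        )
        for r in reports:
            fh.write(
                f"{r.gap.scaffold_id}\t{r.gap.start}\t{r.gap.end}\t"
                f"{r.consistency_rate:.2f}\t{int(r.closed_100)}\t{int(r.closed_90)}\t"
                f"{r.filled_length}\t{r.reference_length}\tok\n"
            )
        for g in unevaluable:
            fh.write(f"{g.scaffold_id}\t{g.start}\t{g.end}\t\t\t\t\t\tunevaluable\n")
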