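"""Consistency-rate evaluation and closure metrics."""

import numpy as np
import pytest

from gapwave.corpus import reverse_complement
from gapwave.evaluate import (
    ConsistencyReport,
    UnevaluableGapError,
    classify_closures,
    consistency_rate,
    evaluate_candidates,
    improvement_pct,
    reference_gap_sequence,
    relative_improvement_pct,
)
from gapwave.gapio import FlankPair, GapRecord, GenomeSequence


def make_flanks(left, right, gap=None):
    gap = gap or GapRecord("s", 10, 13)
    return FlankPair(gap=gap, left=left, right=right)


class TestReferenceGapSequence:
    def test_hand_traced_coordinates(self):
        ref = GenomeSequence("r", "AAACCGGTTT")
        out = reference_gap_sequence(
            ref, make_flanks("AAA", "TTT"), long_trim=5, short_trim=1
        )
        assert out == "ACCGGT"

    def test_flank_absent_is_unevaluable(self):
        ref = GenomeSequence("r", "AAACCGGTTT")
        with pytest.raises(UnevaluableGapError):
            reference_gap_sequence(ref, make_flanks("GGG", "TTT"), 5, 1)

    def test_ambiguous_flank_is_unevaluable(self):
        ref = GenomeSequence("r", "AAACCAAATT")
        with pytest.raises(UnevaluableGapError):
            reference_gap_sequence(ref, make_flanks("AAA", "TT"), 5, 1)

    def test_misordered_flanks_unevaluable(self):
        ref = GenomeSequence("r", "TTTCCGGAAA")
        with pytest.raises(UnevaluableGapError):
            reference_gap_sequence(ref, make_flanks("AAA", "TTT"), 5, 1)

    def test_long_trim_must_exceed_short_trim(self):
        ref = GenomeSequence("r", "AAACCGGTTT")
        with pytest.raises(ValueError):
            reference_gap_sequence(ref, make_flanks("AAA", "TTT"), 2, 2)


class TestConsistencyRate:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 100.0),
            ("ACGTACGTAC", "ACGTACGTAA", 90.0),
            ("AAAA", "TTTT", 0.0),
        ],
    )
    def test_known_rates(self, a, b, expected):
        assert consistency_rate(a, b) == pytest.approx(expected)

    def test_single_gap_column(self):
        # one deletion: 4 matches over 5 alignment columns
        assert consistency_rate("ACGTA", "ACGA") == pytest.approx(400 / 5, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consistency_rate("", "ACGT")

    def test_alignment_score_matches_independent_aligner(self):
        """The DP's optimal score agrees with Biopython's PairwiseAligner
        under identical scoring."""
        from gapwave.evaluate import align_stats, make_aligner

        aligner = make_aligner()
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 30)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 30)))
            score, identities, columns = align_stats(a, b)
            assert score == pytest.approx(aligner.score(a, b))
            assert 0 <= identities <= min(len(a), len(b))
            assert columns >= max(len(a), len(b))

    def test_self_identity_and_revcomp_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            t = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 40)))
            assert consistency_rate(s, s) == 100.0
            assert consistency_rate(s, t) == pytest.approx(
                consistency_rate(reverse_complement(s), reverse_complement(t))
            )


class TestClassifyClosures:
    def report(self, rate, gap):
        return ConsistencyReport(
            gap=gap, consistency_rate=rate, filled_length=gap.length,
            reference_length=gap.length,
        )

    def test_threshold_buckets(self):
        before = [GenomeSequence("s", "AC" + "N" * 6 + "GT" * 10)]
        after = [GenomeSequence("s", "AC" + "ACGTAC" + "GT" * 10)]
        gaps = [GapRecord("s", 2, 4), GapRecord("s", 4, 6), GapRecord("s", 6, 8)]
        reports = [self.report(r, g) for r, g in zip([100.0, 95.0, 80.0], gaps)]
        m = classify_closures(reports, before, after)
        assert (m.gap_closed_100, m.gap_closed_90) == (1, 2)
        assert m.gap_closed == 3  # no N left in any gap interval

    def test_rate_exactly_90_excluded(self):
        gap = GapRecord("s", 0, 2)
        m = classify_closures(
            [self.report(90.0, gap)],
            [GenomeSequence("s", "NNAC")],
            [GenomeSequence("s", "GGAC")],
        )
        assert m.gap_closed_90 == 0

    def test_unfilled_scaffold_residual_n(self):
        before = [GenomeSequence("s", "ACNNNNGT")]
        m = classify_closures(
            [self.report(0.0, GapRecord("s", 2, 6))], before, before
        )
        assert m.residual_n == 4
        assert m.gap_closed == 0

    def test_counts_monotone_under_added_reports(self):
        gaps = [GapRecord("s", i * 4, i * 4 + 2) for i in range(5)]
        after = [GenomeSequence("s", "ACGT" * 6)]
        before = after
        prev = None
        for n in range(1, 6):
            reports = [self.report(100.0, g) for g in gaps[:n]]
            m = classify_closures(reports, before, after)
            if prev:
                assert m.gap_closed_100 >= prev.gap_closed_100
                assert m.gap_closed >= prev.gap_closed
            prev = m


class TestImprovementFormulas:
    @pytest.mark.parametrize(
        "new,base,total,expected",
        [(109, 79, 196, 15.3), (501, 484, 1207, 1.4), (170, 148, 273, 8.1), (5, 5, 10, 0.0)],
    )
    def test_absolute_improvement(self, new, base, total, expected):
        assert round(improvement_pct(new, base, total), 1) == expected

    @pytest.mark.parametrize(
        "new,base,expected", [(73, 68, 7.35), (9, 7, 28.57), (26, 24, 8.33), (10, 7, 42.86)]
    )
    def test_relative_improvement(self, new, base, expected):
        assert round(relative_improvement_pct(new, base), 2) == expected

    def test_degenerate_denominators_rejected(self):
        with pytest.raises(ValueError):
            improvement_pct(1, 1, 0)
        with pytest.raises(ValueError):
            relative_improvement_pct(1, 0)


class TestEvaluateCandidates:
    def test_verbatim_fills_score_100(self):
        """Candidates copied from the reference give rate 100 on every
        evaluable gap."""
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        ref = GenomeSequence("r", seq)
        gaps = [GapRecord("scaf", 200, 230), GapRecord("scaf", 400, 420)]
        scaffold_seq = list(seq)
        truth = {}
        for g in gaps:
            truth[g] = seq[g.start : g.end]
            scaffold_seq[g.start : g.end] = "N" * g.length
        scaffold = GenomeSequence("scaf", "".join(scaffold_seq))
        reports, unevaluable = evaluate_candidates(
            ref, scaffold, gaps, {g: [truth[g]] for g in gaps},
            long_trim=60, short_trim=5,
        )
        assert not unevaluable
        assert all(r.consistency_rate == 100.0 for r in reports)
        assert all(r.closed_100 and r.closed_90 for r in reports)
        assert all(r.reference_length == g.length for r, g in zip(reports, gaps))
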