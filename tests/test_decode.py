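"""Decoders: wave-beam vs plain beam vs exhaustive oracle."""

import math

import numpy as np
import pytest

from gapwave.decode import (
    DecodeConfig,
    beam_search,
    brute_force_decode,
    greedy_decode,
    wave_beam_search,
)
from conftest import SeededRandomModel

SEED_CTX = "ACGT"


class TestWaveBeam:
    def test_uniform_model_lexicographic_tie(self, uniform_model):
        cfg = DecodeConfig(target_length=3, n_best=1, keep=4, expansion_limit=64)
        (top,) = wave_beam_search(uniform_model, SEED_CTX, cfg)
        assert top.bases == "AAA"
        assert top.score == pytest.approx(3 * math.log(0.25))

    def test_deterministic_model_forced_path(self, deterministic_model):
        cfg = DecodeConfig(target_length=5, n_best=1, keep=2, expansion_limit=8)
        (top,) = wave_beam_search(deterministic_model, SEED_CTX, cfg)
        # T -> A -> C -> G -> T -> A, each with probability 1
        assert top.bases == "ACGTA"
        assert top.score == 0.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DecodeConfig(target_length=0)
        with pytest.raises(ValueError):
            DecodeConfig(target_length=3, keep=8, expansion_limit=4)
        with pytest.raises(ValueError):
            DecodeConfig(target_length=3, n_best=9, keep=8)

    def test_wrong_seed_context_length(self, uniform_model):
        with pytest.raises(ValueError):
            wave_beam_search(uniform_model, "ACGTA", DecodeConfig(target_length=2))

    def test_returns_all_survivors_when_fewer_than_n_best(self, uniform_model):
        cfg = DecodeConfig(target_length=1, n_best=16, keep=16, expansion_limit=64)
        out = wave_beam_search(uniform_model, SEED_CTX, cfg)
        assert len(out) == 4  # one level only ever yields 4 paths

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_without_contraction(self, seed):
        """With an expansion limit above 4**L the search is exhaustive and
        must return the brute-force optimum (sequence and score)."""
        model = SeededRandomModel(seed)
        L = 5
        cfg = DecodeConfig(
            target_length=L, expansion_limit=4**L + 1, keep=4**L, n_best=1
        )
        (wave,) = wave_beam_search(model, SEED_CTX, cfg)
        (brute,) = brute_force_decode(model, SEED_CTX, L, n_best=1)
        assert wave.bases == brute.bases
        assert wave.score == pytest.approx(brute.score)

    def test_monotone_budget(self):
        """Raising the expansion limit never lowers the top-1 score."""
        for seed in range(20):
            model = SeededRandomModel(seed)
            scores = []
            for limit in (8, 32, 128, 1024):
                cfg = DecodeConfig(
                    target_length=6, expansion_limit=limit, keep=8, n_best=1
                )
                scores.append(wave_beam_search(model, SEED_CTX, cfg)[0].score)
            assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_scores_finite_nonpositive_and_lengths_exact(self):
        model = SeededRandomModel(99)
        cfg = DecodeConfig(target_length=7, expansion_limit=64, keep=8, n_best=4)
        for node in wave_beam_search(model, SEED_CTX, cfg):
            assert math.isfinite(node.score) and node.score <= 0
            assert len(node.bases) == 7

    def test_sum_accumulation_mode(self, uniform_model):
        cfg = DecodeConfig(target_length=3, n_best=1, accumulate="sum")
        (top,) = wave_beam_search(uniform_model, SEED_CTX, cfg)
        assert top.score == pytest.approx(0.75)


class TestBeamSearch:
    def test_width_one_equals_greedy(self):
        for seed in range(10):
            model = SeededRandomModel(seed)
            greedy = greedy_decode(model, SEED_CTX, 6)
            (beam,) = beam_search(model, SEED_CTX, 6, width=1)
            assert greedy == beam

    def test_full_width_equals_brute_force(self):
        for seed in range(10):
            model = SeededRandomModel(seed)
            L = 4
            (beam,) = beam_search(model, SEED_CTX, L, width=4**L)
            (brute,) = brute_force_decode(model, SEED_CTX, L, n_best=1)
            assert beam.bases == brute.bases
            assert beam.score == pytest.approx(brute.score)

    def test_trap_model_beats_narrow_beam(self, trap_model):
        """When the greedy prefix is globally suboptimal, wave-beam's delayed
        contraction finds the better path that width-1 beam prunes away."""
        (narrow,) = beam_search(trap_model, SEED_CTX, 2, width=1)
        cfg = DecodeConfig(target_length=2, expansion_limit=16, keep=1, n_best=1)
        (wave,) = wave_beam_search(trap_model, SEED_CTX, cfg)
        assert narrow.bases == "AA"
        assert wave.bases == "CT"
        assert wave.score > narrow.score

    def test_wave_with_matched_budget_never_below_beam(self):
        """keep = w with contraction triggered at 4w reproduces or beats the
        fixed-width beam on every seeded model."""
        w = 4
        for seed in range(60):
            model = SeededRandomModel(seed)
            (beam,) = beam_search(model, SEED_CTX, 6, width=w)
            cfg = DecodeConfig(target_length=6, expansion_limit=4 * w, keep=w, n_best=1)
            (wave,) = wave_beam_search(model, SEED_CTX, cfg)
            assert wave.score >= beam.score - 1e-12


class TestBruteForce:
    def test_uniform_ties_resolve_lexicographically(self, uniform_model):
        (top,) = brute_force_decode(uniform_model, SEED_CTX, 2, n_best=1)
        assert top.bases == "AA"

    def test_deterministic_forced_sequence(self, deterministic_model):
        (top,) = brute_force_decode(deterministic_model, SEED_CTX, 5, n_best=1)
        assert top.bases == "ACGTA"
        assert top.score == 0.0

    def test_length_guard(self, uniform_model):
        with pytest.raises(ValueError):
            brute_force_decode(uniform_model, SEED_CTX, 11)

    def test_n_best_ranking_is_sorted(self):
        model = SeededRandomModel(5)
        nodes = brute_force_decode(model, SEED_CTX, 4, n_best=10)
        scores = [n.score for n in nodes]
        assert scores == sorted(scores, reverse=True)
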