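"""Shared fixtures: lightweight next-base scorers for decoder tests.

Decoders only require ``context_length`` and ``predict_proba``; these toy
scorers exercise them without any training.
"""

from __future__ import annotations

import zlib

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


class UniformModel:
    """P = 0.25 for every base, every context."""

    def __init__(self, W: int = 4):
        self.context_length = W

    def predict_proba(self, contexts):
        return np.full((len(contexts), 4), 0.25)


class DeterministicModel:
    """P = 1 for a context-dependent forced base (cycles A->C->G->T)."""

    _next = {"A": 1, "C": 2, "G": 3, "T": 0}

    def __init__(self, W: int = 4):
        self.context_length = W

    def predict_proba(self, contexts):
        out = np.zeros((len(contexts), 4))
        for i, ctx in enumerate(contexts):
            out[i, self._next[ctx[-1]]] = 1.0
        return out


class SeededRandomModel:
    """Deterministic pseudo-random conditional distributions.

    Each context's distribution is a Dirichlet(1,1,1,1) draw keyed by a
    CRC32 of (seed, context), so the model is a pure function of its seed.
    """

    def __init__(self, seed: int, W: int = 4):
        self.seed = seed
        self.context_length = W

    def predict_proba(self, contexts):
        out = np.empty((len(contexts), 4))
        for i, ctx in enumerate(contexts):
            h = zlib.crc32(f"{self.seed}:{ctx}".encode())
            out[i] = np.random.default_rng(h).dirichlet([1.0, 1.0, 1.0, 1.0])
        return out


class TrapModel:
    """Greedy's first move is globally suboptimal.

    From a context ending in T the locally best base is A (0.40 over C's
    0.35), but continuations after A top out at 0.5 while after C the next
    step offers 0.85 — so the best 2-step path starts with the locally
    worse C (0.35 * 0.85 = 0.2975 > 0.40 * 0.50 = 0.20).
    """

    _rows = {
        "T": [0.40, 0.35, 0.15, 0.10],
        "A": [0.50, 0.30, 0.10, 0.10],
        "C": [0.05, 0.05, 0.05, 0.85],
        "G": [0.25, 0.25, 0.25, 0.25],
    }

    def __init__(self, W: int = 4):
        self.context_length = W

    def predict_proba(self, contexts):
        return np.array([self._rows[c[-1]] for c in contexts])


@pytest.fixture
def uniform_model():
    return UniformModel()


@pytest.fixture
def deterministic_model():
    return DeterministicModel()


@pytest.fixture
def trap_model():
    return TrapModel()
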