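# Methods

## Problem

Draft genome assemblies from short reads contain *gaps*: runs of `N`
characters inside scaffolds where the underlying sequence could not be
resolved, typically in repetitive or low-coverage regions. `gapwave`
treats gap closing as conditional sequence generation: a character-level
model learns the statistics of the sequence surrounding each gap from the
read data itself, and a search procedure decodes high-probability
candidate gap sequences anchored on the gap flanks. The candidates are
emitted as flank-anchored pseudo-reads so that a conventional read-based
gap filler can be re-run with an enriched read set; they are also scored
directly against a reference when one is available.

## Gap and flank model

Gaps are maximal runs of `N`/`n` on a scaffold, recorded in 0-based
half-open (BED) coordinates. A gap's *flanks* are the up-to-`flank_len`
bases immediately 5′ and 3′ of the N-run (default 500, configurable),
truncated at the sequence boundary and at the first interior `N` so that a
flank never reaches across a neighbouring gap — the encoder has no `N`
channel, so flanks must be N-free.

## Training corpus

Reads related to the gap neighbourhoods are recruited by exact canonical
k-mer membership: a read is kept when it shares at least `min_shared`
(default 1) canonical k-mers (default k = 25) with the bait set formed by
all gap flanks. Canonicalisation (lexicographic minimum of a k-mer and its
reverse complement) makes recruitment strand-insensitive. An optional
homologous genome is tiled into read-sized fragments (150 nt) and recruited
through the same path, enriching the corpus with related sequence. We use
an exact membership set rather than a Bloom filter: false positives are a
memory optimisation artefact, not part of the method, and exactness keeps
the recruiter testable.

Both strands of every recruited sequence are windowed into
(context, next base) training pairs at stride 1: context length `W`
(default 64; the desk-scale studies below use 16), label the following
base, windows containing `N` skipped. Bases are one-hot encoded in
(A, C, G, T) order. Large corpora are capped by seeded uniform subsampling
(pipeline default 20,000 windows).

## Next-base model

The model is a small hybrid network: 1-D convolution (32 filters, kernel
3, "same" padding, ReLU) extracts local motifs from the one-hot context;
max pooling (size 2, stride 2) halves the sequence axis; a bidirectional
LSTM (total output 512 units by default, i.e. 256 per direction) reads the
pooled features in both directions; the concatenated final hidden states
feed a 4-way softmax over the next base. Training minimises categorical
cross-entropy with Adam (learning rate 1e-3), batch size 64, for at most
1500 epochs with early stopping (patience 20) on a 10% seeded validation
split; the best-validation parameters are restored. The implementation is
pure NumPy with explicitly written forward and backward passes, which
keeps training bit-reproducible from the seed on any machine; the
gradients are validated against central finite differences in the test
suite.

Interpretation choices that the architecture leaves open: the recurrent
output dimension is taken as the *concatenated* size (half per direction);
pooling uses size = stride = 2; convolution uses "same" padding so the
recurrent layer sees the full (pooled) context; early stopping monitors
validation loss. Scaled-down hyperparameters (W = 16, 16 filters, 32
recurrent units, ≤ 40 epochs) are used for the in-repo studies so the full
suite trains in seconds to minutes on one CPU core; these sizes are ample
for the low-order synthetic grammars the studies use.

## Decoding: wave-beam search

Candidates are decoded base by base, scoring each extension with
P(base | trailing W characters of flank + decoded prefix). A path's score
is its cumulative log-probability (the log of the path probability); an
alternative `accumulate="sum"` mode adds raw probabilities instead, for
comparison with the literal "running sum" formulation. Ties are broken
lexicographically so all decoders are deterministic.

*Wave-beam search* alternates expansion and contraction: every surviving
path is extended by all four bases each level, and only when the node
count reaches `expansion_limit` (default 1024) are all but the `keep`
(default 16) best paths discarded. Plain beam search (prune to a fixed
width every level; width 1 = greedy) and exhaustive enumeration (lengths
≤ 10) are provided as the baseline and the oracle. With
`expansion_limit > 4^L` wave-beam is provably exhaustive, which the tests
exploit.

A subtlety found empirically: delayed contraction is *not* universally at
least as good as per-level pruning. With `expansion_limit = 4·keep` the
contraction cadence coincides with the width-matched beam and dominance is
structural; with larger limits the two searches keep diverging node sets
and, on ~1% of random Dirichlet models, the plain beam happens to win.
Wave-beam's advantage is therefore an empirical tendency (and strict on
adversarial models whose greedy prefix is globally suboptimal), not a
theorem; the dominance study is run at the matched budget.

## Candidate fills and read augmentation

Each gap is decoded forward (seeded by the last W bases of the left flank)
and in reverse (the right flank's first W bases are reverse-complemented,
decoded left-to-right, and the result complemented back), giving up to
`n_best` (default 4) candidates per direction in reference orientation.
The decoded length equals the N-run length, optionally plus
`length_slack` extra bases for downstream trimming. Candidates are written
as FASTA pseudo-reads wrapped in `margin` (default 50) bases of flank on
each side, with unique headers carrying gap, direction, rank and score;
handing these to a downstream filler is a file handoff, not a subprocess
call. Both directions' candidate sets are emitted rather than intersected.

## Evaluation: consistency rate

For each gap, the long-trimmed flanks (default 300 nt) are located on the
reference by exact, unique substring match; gaps whose flanks are missing,
ambiguous or misordered are reported *unevaluable* rather than guessed.
The reference gap sequence is the reference segment between the
short-trimmed (default 20 nt) flank ends — the true gap content plus short
anchors. The filled sequence (candidate plus the same anchors) is compared
to it by global Needleman-Wunsch alignment (match +1, mismatch −1, gap −2;
configurable), and the *consistency rate* is identities / alignment
columns × 100. Among score-optimal alignments the DP prefers more
identities, then fewer columns; this tie rule makes the rate deterministic
and invariant under jointly reverse-complementing both sequences (an
arbitrary co-optimal alignment, as returned by off-the-shelf aligners, is
not). The optimal score itself is cross-checked against Biopython's
`PairwiseAligner` in the tests.

Closure bookkeeping: a gap is *closed* when its original interval contains
no `N` after filling; *closed (100%)* when its rate is exactly 100; the
*>90%* bucket is strict (a rate of exactly 90 is excluded). Residual N is
the total `N` count on the filled scaffolds. Two improvement summaries are
provided: absolute, (closed_new − closed_base) / gap_count × 100, and
relative, (closed_new − closed_base) / closed_base × 100.

## Synthetic fixtures

The generator draws genomes from a Markov chain of order 0, 1 or 2 with a
controllable transition matrix, so sequence entropy — the property that
decides whether a small model can learn the sequence — is a dial. Gaps are
cut as N-runs (kept ≥ read_length apart and away from the ends, so flanks
stay clean) with the masked truth returned as recovery targets; reads are
uniform single-end substrings from both strands at a chosen fold coverage
with iid substitution errors; an optional "homolog" is a diverged copy of
the genome. All randomness descends from one master seed via
`SeedSequence` spawn keys.

The end-to-end study conditions: an order-1 chain whose dominant
transitions form a 4-cycle with probability 0.998 (a near-deterministic,
tandem-repeat-like regime emulating the low-complexity contexts where
gaps arise), a 20 kb genome, 10 gaps of 20–50 nt, 20× error-free 100 nt
reads. Under these conditions ~93% of 20–50 nt windows contain no
off-cycle base, so exact recovery of ≥ 80% of gaps is the expected
outcome for a correctly working pipeline, and the decoded candidates
reproduce the masked truth at consistency 100. Because such genomes are
near-periodic, their 200–300 nt flanks are intentionally *not* unique on
the reference; the recovery study therefore scores candidates against the
generator's returned truth sequences, while the flank-anchored
`reference_gap_sequence` path is exercised on non-periodic (iid) fixtures
where unique flank placement is well defined.

What the fixtures do not emulate: quality-dependent or indel errors,
paired-end inserts, diploidy, and real-genome repeat complexity. Passing
these studies shows the machinery is correct and self-consistent at desk
scale, not that the method closes gaps in arbitrary real genomes.

## Numerical and degenerate-input choices

Probabilities are clipped at 1e-300 before logs; softmax subtracts the row
maximum; LSTM gate pre-activations are clipped at ±60 inside the sigmoid.
Parameter init is Glorot-uniform with the forget-gate bias at 1, seeded.
Contexts shorter than W on both sides of a gap make that gap undecodable
(error if both, warning + skipped direction if one). `n_best` larger than
the number of surviving paths returns all survivors. Empty FASTA files,
non-ACGTN characters, k below 4, and kernel sizes exceeding the context
are rejected at parse/build time.

## Known limitations

- Training cost of the full-size default model (W = 64, 512 recurrent
  units) is high in pure NumPy; the defaults document the reference
  architecture, while realistic desk-scale runs should use the scaled
  configurations shown in the README.
- Decoded length is pinned to the N-run length, which on real scaffolds is
  only an estimate of the true gap size; `length_slack` mitigates but does
  not remove this.
- The evaluator requires exact unique flank matches; highly repetitive
  flanks make gaps unevaluable by design rather than risking a wrong
  locus.
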