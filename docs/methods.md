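# Methods

This note documents the models and numerical choices behind `embedrepeat`:
what each pipeline stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and where the design was
genuinely open.

## Similarity model

Every comparison is made in embedding space. For two residues with embedding
rows `x` and `y`, the substitution score is `cos(x, y)`. Cosine is
scale-invariant, so providers need not normalize rows, and the whole pipeline
is invariant under per-row positive rescaling (a tested property). Rows are
used raw — no centering or whitening is applied — because cosine against a
shared reference frame is exactly the quantity the planted-signal generator
controls, and centering would couple rows through the corpus mean.

## Local self-alignment

The self-similarity matrix `S` is noisy at the single-cell level: for
`D`-dimensional unit rows, unrelated cosines fluctuate with standard
deviation ≈ 1/√D (≈ 0.125 at the test dimension D = 64). Three mechanisms
make trace extraction robust:

- **Diagonal smoothing.** `S` is averaged along each diagonal with a
  centered window of `window_length` (default 15), truncated at diagonal
  ends. Genuine unit-vs-unit alignments are runs along a diagonal, so
  smoothing preserves them while shrinking noise by ≈ √15.
- **Noise gate.** θ = μ + `sigma_factor`·σ (default factor 2.0) computed
  from the smoothed off-diagonal entries (excluding the
  `diagonal_exclusion` band, default |i−j| ≤ 2, which is trivial
  self-identity signal). The dynamic program runs on `S̃ − θ`, so only
  stretches consistently above the noise floor accumulate positive score.
- **Gap charge.** Gap steps cost θ plus the configured `gap_extension`
  (default 0.0). This is load-bearing: with literally free gaps the
  recurrence `H(i,j) = max(0, H+s, H−g, H−g)` lets the score plateau of one
  strong band propagate sideways and shadow every parallel band — the
  traceback from a weaker band's end then walks into the stronger band and
  the suboptimal-trace set collapses to a single path. Charging the noise
  floor for unmatched positions keeps paths with different gap counts
  comparable. It also closes a specificity hole: on featureless inputs a
  free-gap DP can chain isolated noise cells into an increasing path whose
  mean similarity beats any fixed cutoff.

Tracebacks start at every 3×3 local maximum of `H` with positive score
(restricted to the upper triangle; mirror traces are implied), preferring
diagonal, then up, then left moves — fully deterministic. Path ends are
trimmed back to the first/last pair whose *raw* similarity clears θ, because
smoothing smears a band half a window past its true ends and a short band
must not masquerade as a span long enough to pass the `min_span` filter
(default 15).

Accepted traces must satisfy: span ≥ `min_span`; mean smoothed similarity
≥ θ; windowed trace score ≥ `score_cutoff` (default 0.3). The windowed trace
score is the mean of the centered moving average (length `window_length`,
truncated at trace ends) of the raw per-pair similarities — a smoothed mean
cosine in [−1, 1]. Exact-duplicate and strict-sub-path traces are dropped;
near-parallel traces (≥ 70% of either's pairs within Chebyshev distance 2 of
the other's) are deduplicated keeping the higher score. Note the *filtered*
trace set is monotone under tightening `score_cutoff`/`min_span`, but the
*pruned* set need not be: removing a long trace can un-shadow a shorter one.

## Transitivity

One round of composition over primary traces, treating each trace as a
partial bijection in both directions. A trace may compose with itself:
offset-l pairs chained through the shared middle copy give the offset-2l
trace, which is the canonical repeat case and the main source of mass at
length multiples. Composites are scored with the same windowed score from
the similarity matrix and pass the same filters; they never compose again
(composites are excluded from the next composition round by construction).

## Length estimation, representative, instances

The score matrix `M_s` sums trace scores into both triangles. Candidate
lengths are the diagonal distances d ∈ [1, L/2] with positive upper-triangle
sums, ranked by sum; the top `hypothesis_budget` (default 10) are evaluated.

For each candidate length l, the representative window maximizes the
triangular position-weighted column sum (leftmost tie wins), and the
representative's profile embedding is `E_repeat = M_sw^T · E_fl` with
zero-weight columns falling back to the raw embedding row (cosine is
scale-invariant, so no normalization is applied). Instance extraction runs
the same local engine with the representative as query, with a relaxed
minimum span `max(5, min(min_span, ⌈l/2⌉))`: the representative window is
phase-free relative to the true unit boundaries, so the instance tiling
rarely starts exactly at a region boundary and edge-truncated instances down
to half a unit are still informative (and needed for full unit coverage).
Overlaps are resolved greedily by descending score with pairwise overlap at
most 50% of the shorter span; accepted spans are globally aligned to the
representative (Needleman–Wunsch on cosines, linear gap penalty, diagonal-
preferring deterministic tie-break) for their final alignment and score.

**Hypothesis selection.** The default metric is mean coverage: the fraction
of representative columns matched per instance, normalized by the shorter of
the representative length and the instance span (edge-truncated instances
are not penalized for residues that do not exist). Coverage saturates near
1.0 for the true length *and* for its integer multiples — a 2l-representative
of an l-periodic region aligns its in-phase instances perfectly — so
coverage differences below a tolerance (0.05) are treated as ties, resolved
by: more instances, then larger diagonal score-sum support (the actual
periodicity evidence), then smaller length, then smaller start. A hypothesis
is discarded outright unless its instances actually recur with period ≈ l
(median spacing of instance starts within max(2, 0.1·l) of an integer
multiple of l; a multiple, not l itself, tolerates a skipped copy). Without
this check, in multi-region proteins a candidate distance arising in one
region can have its representative window placed in the other, heavier
region and tile it under the wrong length label.

**Iteration.** After a family is reported, its instance spans are masked:
rows and columns of `M_s` are zeroed and the positions are excluded from
later instance extraction (otherwise iteration 2 would simply re-extract
iteration-1 copies from the unmasked embedding). The loop ends when no
candidate produces a ≥2-instance, period-consistent family, or after
`max_iterations` (default 5).

## Synthetic data generator

Each planted protein is built from a base unit of `unit_length` random unit
vectors. Copy rows are `normalize(√(ρ−γ²)·base + γ·c + √(1−ρ)·noise)` where
ρ is `within_unit_cosine`, `c` is a fixed unit direction shared by all
repeat-region rows of all generated proteins, and γ (`context_strength`,
default 0.35) is its amplitude. Cross-copy cosines then have expectation
(ρ−γ²) + γ² = ρ, which the tests verify empirically to ±0.05. Flanks and
background proteins are independent random unit rows (mean cosine ≈ 0).
Indels delete or insert single interior positions per copy, with ground
truth spans adjusted.

The context term emulates a real property of contextual language-model
embeddings: residues inside repeat domains carry a regional signature
recognizable without alignment (this is what makes a light-attention
classifier on pooled embeddings work at all, and what attention profiles
localize). Without it, planted and background rows are identically
distributed position-by-position and only the lag-u correlation structure
distinguishes the classes — invisible to any position-local feature.

What the generator does **not** emulate: amino-acid composition biases,
length- and disorder-dependent embedding drift, structurally conserved but
sequence-divergent repeats where cosine similarity decays non-uniformly
along the unit, correlated noise between neighboring residues, and the
1024-dimensional geometry of a real language model (tests use D = 64; the
pipeline is dimension-agnostic). Passing the synthetic benchmarks therefore
demonstrates the correctness and calibration of the algorithmic machinery
under a controlled similarity model, not detection performance on real
proteins.

## Classifier

A light-attention architecture: two 1D convolutions over the sequence axis
(filter size 9, `channels` output channels) produce attention logits and
feature maps; attention is softmax-normalized over the length per channel;
the attention-weighted feature sum is concatenated with a per-channel global
max-pool into a fixed 2·`channels` vector feeding a linear head with
sigmoid. Dropout (rate 0.25) acts on the feature maps during training. The
per-residue attention profile is the channel-mean of the raw (pre-softmax)
attention logits. The model is implemented directly in numpy with
hand-derived gradients (im2col convolution, softmax and BCE backward, Adam)
— at the sizes used this is faster to load and fully deterministic under a
single seed. The head is zero-initialized, so an untrained model outputs
probability exactly 0.5; gradients reach the convolutions once the head
moves. Documented production-scale defaults are 1024 channels and learning
rate 1e−6; the test-scale configuration (32 channels, D = 64, learning rate
1e−3) is what the synthetic benchmarks use. Training splits 90/10, stops
when held-out loss has not improved for `patience` = 20 epochs, and restores
the best state.

## Benchmark definitions

A predicted repeat is *correct* when some ground-truth unit overlaps it
reciprocally (overlap ≥ 50% of each span's length) — a sequence-space
surrogate for a structural-superposition test, reusing the same coverage
threshold. A protein is *called repetitive* when strictly more than half of
its predictions align correctly with at least one other prediction; between
two predictions, alignment is judged by globally aligning their embedding
slices (score ≥ cutoff, mutual matched-length coverage ≥ 50%). Every
prediction on a background protein counts as a false-positive repeat.

## Problem sizes and determinism

The standard benchmark conditions are: units 10–40, 3–8 copies, within-unit
cosine 0.9 (0.95 for the classifier corpus), flanks 5–25, ≤1 indel per copy,
D = 64; 200 proteins for recovery and specificity, 50 two-region
constructions, 400 labeled embeddings for the classifier. All randomness
derives from a single integer seed; detection itself contains no randomness
at all, so reruns are byte-identical.

## Known limitations

- No statistical significance estimates: traces and instances carry scores,
  not P-values. Embedding shuffling destroys the contextual structure a
  null model would need.
- The MSA is a star alignment around the representative (pairwise
  alignments stitched column-wise); it is not globally optimized.
- Units shorter than `diagonal_exclusion` + 1 (≤ 3 residues) are invisible
  by construction; units shorter than ~8 residues with indels are at the
  edge of what the length-estimation step resolves.
- The selection metric degeneracy between a unit length and its multiples
  is resolved by tie rules, not by the metric itself; pathological repeat
  hierarchies (repeats of repeats) will report one level.
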