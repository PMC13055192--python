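"""Embedding-space local and global alignment.

The substitution model is the cosine similarity between per-residue embedding
rows, which acts as a context-dependent replacement for a fixed amino-acid
matrix.  Local alignment returns *all* significant suboptimal traces, not just
the single best one: tracebacks are started from every local maximum of the
Smith-Waterman matrix, which is what makes the self-comparison usable as a
repeat dot-plot.

Noise handling
--------------
Raw per-pair cosine similarities are noisy (fluctuations of order 1/sqrt(D)).
Before the dynamic program the similarity matrix is therefore smoothed along
its diagonals with a centered window (``window_length``) and a significance
gate theta = mu + sigma_factor * sigma — computed from the off-diagonal
entries of the smoothed matrix — is subtracted, so that only consistently
similar stretches can accumulate positive path score.  Gap steps are charged
theta on top of the configured gap_extension: an unmatched position is worth
at most the noise level, so paths with different gap counts stay comparable
and the score plateau of one alignment band cannot shadow a parallel band
(which would otherwise collapse the suboptimal-trace set onto a single
path).  Trace-level filters (minimum span, windowed score cutoff on the raw
similarities, mean smoothed similarity above the gate) are applied
afterwards.  Without the gate, free gaps would let the dynamic program chain
isolated noise cells into spurious high-scoring traces on unrelated
sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from numba import njit
from scipy.ndimage import maximum_filter

from .embeddings import InputError, ParameterError, ResidueEmbedding

_NEG = -1e9


@dataclass(frozen=True)
class AlignmentParams:
    """Alignment engine parameters (defaults are the tool's standard settings)."""

    window_length: int = 15
    min_span: int = 15
    sigma_factor: float = 2.0
    gap_extension: float = 0.0
    score_cutoff: float = 0.3
    diagonal_exclusion: int = 2

    def validate(self) -> None:
        if self.window_length < 1 or self.min_span < 1:
            raise ParameterError("window_length and min_span must be >= 1")
        if self.gap_extension < 0:
            raise ParameterError("gap_extension must be >= 0")
        if not 0.0 <= self.score_cutoff <= 1.0:
            raise ParameterError("score_cutoff must lie in [0, 1]")
        if self.diagonal_exclusion < 0:
            raise ParameterError("diagonal_exclusion must be >= 0")


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    query_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v > 1.0 + 1e-6) or np.any(v < -1.0 - 1e-6):
            raise InputError("cosine similarities outside [-1, 1]")
        self.values = v


class TraceOrigin(str, Enum):
    PRIMARY = "primary"
    TRANSITIVE = "transitive"


@dataclass
class Trace:
    """One suboptimal alignment path: ordered aligned index pairs + score."""

    pairs: list[tuple[int, int]]
    score: float
    origin: TraceOrigin = TraceOrigin.PRIMARY

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_set(self) -> frozenset:
        return frozenset(self.pairs)

    def target_span(self) -> tuple[int, int]:
        js = [j for _, j in self.pairs]
        return min(js), max(js) + 1

    def query_span(self) -> tuple[int, int]:
        qs = [i for i, _ in self.pairs]
        return min(qs), max(qs) + 1


@dataclass
class GlobalAlignment:
    """End-to-end alignment; ``pairs`` holds (i, j) with None marking a gap."""

    pairs: list[tuple[int | None, int | None]]
    score: float
    query_id: str = ""
    target_id: str = ""

    @property
    def matched_pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j in self.pairs if i is not None and j is not None]


# ---------------------------------------------------------------------------
# Substitution matrix
# ---------------------------------------------------------------------------

def substitution_matrix(a: ResidueEmbedding, b: ResidueEmbedding) -> SimilarityMatrix:
    """Cosine similarity between every row of ``a`` and every row of ``b``."""
    if a.dim != b.dim:
        raise InputError(f"dimension mismatch: {a.dim} vs {b.dim}")
    for name, e in (("a", a), ("b", b)):
        norms = np.linalg.norm(e.values, axis=1)
        bad = np.where(norms == 0)[0]
        if bad.size:
            raise InputError(f"zero-norm row {bad[0]} in embedding {name} "
                             f"({e.sequence_id!r})")
    an = a.values / np.linalg.norm(a.values, axis=1, keepdims=True)
    bn = b.values / np.linalg.norm(b.values, axis=1, keepdims=True)
    vals = np.clip(an @ bn.T, -1.0, 1.0)
    return SimilarityMatrix(vals, a.sequence_id, b.sequence_id)


def diagonal_smooth(s: np.ndarray, window_length: int) -> np.ndarray:
    """Centered truncated moving average along each diagonal of ``s``."""
    h = window_length // 2
    n, m = s.shape
    acc = np.zeros_like(s)
    cnt = np.zeros_like(s)
    for t in range(-h, h + 1):
        if t >= 0:
            acc[: n - t, : m - t] += s[t:, t:]
            cnt[: n - t, : m - t] += 1.0
        else:
            acc[-t:, -t:] += s[: n + t, : m + t]
            cnt[-t:, -t:] += 1.0
    return acc / cnt


def noise_gate(smoothed: np.ndarray, sigma_factor: float,
               diagonal_exclusion: int | None) -> float:
    """theta = mu + sigma_factor * sigma over the relevant entries.

    For self-comparison the |i-j| <= diagonal_exclusion band (the trivial
    self-identity signal) is excluded from the statistics; pass None for a
    query-vs-target comparison to use all entries.
    """
    if diagonal_exclusion is None:
        sel = smoothed.ravel()
    else:
        n, m = smoothed.shape
        ii, jj = np.indices((n, m))
        sel = smoothed[np.abs(ii - jj) > diagonal_exclusion]
    if sel.size == 0:
        return np.inf
    return float(sel.mean() + sigma_factor * sel.std())


# ---------------------------------------------------------------------------
# Dynamic programs (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sw_fill(sp: np.ndarray, gap: float, band: int) -> np.ndarray:
    n, m = sp.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if band >= 0 and abs(i - j) <= band:
                continue
            best = H[i - 1, j - 1] + sp[i - 1, j - 1]
            alt = H[i - 1, j] - gap
            if alt > best:
                best = alt
            alt = H[i, j - 1] - gap
            if alt > best:
                best = alt
            if best < 0.0:
                best = 0.0
            H[i, j] = best
    return H


@njit(cache=False)
def _nw_fill(s: np.ndarray, gap: float) -> np.ndarray:
    n, m = s.shape
    F = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        F[i, 0] = -gap * i
    for j in range(1, m + 1):
        F[0, j] = -gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = F[i - 1, j - 1] + s[i - 1, j - 1]
            alt = F[i - 1, j] - gap
            if alt > best:
                best = alt
            alt = F[i, j - 1] - gap
            if alt > best:
                best = alt
            F[i, j] = best
    return F


def _sw_traceback(H: np.ndarray, sp: np.ndarray, gap: float,
                  i: int, j: int) -> list[tuple[int, int]]:
    """Deterministic traceback: prefer diagonal, then up, then left."""
    pairs: list[tuple[int, int]] = []
    while i > 0 and j > 0 and H[i, j] > 0.0:
        h = H[i, j]
        if h == H[i - 1, j - 1] + sp[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif h == H[i - 1, j] - gap:
            i -= 1
        elif h == H[i, j - 1] - gap:
            j -= 1
        else:  # pragma: no cover - numerical safety net
            break
    pairs.reverse()
    return pairs


# ---------------------------------------------------------------------------
# Windowed trace score
# ---------------------------------------------------------------------------

def moving_average(vals: np.ndarray, window_length: int) -> np.ndarray:
    """Centered moving average, truncated at the ends."""
    vals = np.asarray(vals, dtype=np.float64)
    h = window_length // 2
    n = vals.size
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def windowed_trace_score(trace: Trace | list[tuple[int, int]],
                         s: SimilarityMatrix | np.ndarray,
                         window_length: int) -> float:
    """Mean over pairs of the windowed (smoothed) per-pair similarity.

    Smoothing runs *along the trace*: each pair's similarity is replaced by
    the centered moving average (length ``window_length``, truncated at the
    trace ends) and the trace score is the mean of those values.
    """
    pairs = trace.pairs if isinstance(trace, Trace) else trace
    vals = np.asarray(s.values if isinstance(s, SimilarityMatrix) else s)
    per_pair = np.array([vals[i, j] for i, j in pairs])
    return float(moving_average(per_pair, window_length).mean())


# ---------------------------------------------------------------------------
# Trace post-processing
# ---------------------------------------------------------------------------

def _prune_subpaths(traces: list[Trace]) -> list[Trace]:
    """Drop traces whose pair set is contained in an earlier/longer trace."""
    sets = [t.pair_set for t in traces]
    kept: list[Trace] = []
    for k, t in enumerate(traces):
        if not any(sets[k] < sets[o] for o in range(len(traces)) if o != k):
            kept.append(t)
    return kept


def _is_redundant(t: Trace, u: Trace, chebyshev: int = 2,
                  frac: float = 0.7) -> bool:
    """Two traces are redundant if >=70% of either's pairs lie within
    Chebyshev distance 2 of the other's pairs (near-parallel shifted paths)."""
    for a, b in ((t, u), (u, t)):
        bset = b.pair_set
        near = 0
        for i, j in a.pairs:
            hit = False
            for di in range(-chebyshev, chebyshev + 1):
                for dj in range(-chebyshev, chebyshev + 1):
                    if (i + di, j + dj) in bset:
                        hit = True
                        break
                if hit:
                    break
            near += hit
        if near >= frac * len(a.pairs):
            return True
    return False


def deduplicate_traces(traces: list[Trace]) -> list[Trace]:
    """Greedy redundancy removal, keeping higher-scoring traces."""
    order = sorted(traces, key=lambda t: (-t.score, t.pairs[0]))
    kept: list[Trace] = []
    for t in order:
        if not any(_is_redundant(t, u) for u in kept):
            kept.append(t)
    return sorted(kept, key=lambda t: t.pairs[0])


def apply_trace_filters(traces: list[Trace], s_raw: np.ndarray,
                        smoothed: np.ndarray, theta: float,
                        params: AlignmentParams,
                        min_span: int | None = None) -> list[Trace]:
    """Length filter, significance gate, windowed score cutoff; sets scores."""
    span = params.min_span if min_span is None else min_span
    out = []
    for t in traces:
        if len(t.pairs) < span:
            continue
        mean_smoothed = float(np.mean([smoothed[i, j] for i, j in t.pairs]))
        if mean_smoothed < theta:
            continue
        score = windowed_trace_score(t.pairs, s_raw, params.window_length)
        if score < params.score_cutoff:
            continue
        out.append(Trace(t.pairs, score, t.origin))
    return out


# ---------------------------------------------------------------------------
# Local alignment engine
# ---------------------------------------------------------------------------

def _trim_trace_ends(pairs: list[tuple[int, int]], s_raw: np.ndarray,
                     theta: float) -> list[tuple[int, int]]:
    """Drop leading/trailing pairs whose raw similarity is below the gate.

    Diagonal smoothing smears a band a half-window past its true ends; the
    dynamic program happily walks that smear, so the path ends are cut back
    to the first/last genuinely similar pair (otherwise a short band could
    masquerade as a span long enough to pass the length filter)."""
    lo, hi = 0, len(pairs)
    while lo < hi and s_raw[pairs[lo]] < theta:
        lo += 1
    while hi > lo and s_raw[pairs[hi - 1]] < theta:
        hi -= 1
    return pairs[lo:hi]


def align_similarity(s_raw: np.ndarray, params: AlignmentParams,
                     self_mode: bool = True,
                     excluded_targets: np.ndarray | None = None,
                     min_span: int | None = None,
                     prune: bool = True) -> list[Trace]:
    """All significant suboptimal local traces through a raw similarity matrix.

    ``self_mode`` excludes the near-diagonal band, restricts output to the
    upper triangle (mirror traces reported once) and computes the noise gate
    from off-band entries.  ``excluded_targets`` is a boolean mask of target
    columns that may not participate (used by iterative masking).
    ``prune=False`` skips sub-path and redundancy pruning, returning every
    filtered trace (the filtered set is monotone in the thresholds; the
    pruned set need not be, since removing a long trace can un-shadow a
    near-parallel shorter one).
    """
    params.validate()
    s_raw = np.asarray(s_raw, dtype=np.float64)
    n, m = s_raw.shape
    span = params.min_span if min_span is None else min_span
    if min(n, m) < span:
        return []

    smoothed = diagonal_smooth(s_raw, params.window_length)
    band = params.diagonal_exclusion if self_mode else -1
    theta = noise_gate(smoothed, params.sigma_factor,
                       params.diagonal_exclusion if self_mode else None)
    if not np.isfinite(theta):
        return []

    sp = smoothed - theta
    if self_mode:
        ii, jj = np.indices((n, m))
        sp[np.abs(ii - jj) <= band] = _NEG
    if excluded_targets is not None:
        sp[:, np.asarray(excluded_targets, dtype=bool)] = _NEG

    gap_cost = params.gap_extension + max(theta, 0.0)
    H = _sw_fill(sp, gap_cost, band)
    core = H[1:, 1:]
    local_max = core >= maximum_filter(core, size=3, mode="constant", cval=0.0)
    seeds = np.argwhere(local_max & (core > 0.0))
    if self_mode:
        seeds = seeds[seeds[:, 1] > seeds[:, 0]]
    order = np.lexsort((seeds[:, 1], seeds[:, 0], -core[seeds[:, 0], seeds[:, 1]]))
    raw_traces: list[Trace] = []
    seen: set[frozenset] = set()
    for i0, j0 in seeds[order]:
        pairs = _sw_traceback(H, sp, gap_cost, int(i0) + 1, int(j0) + 1)
        pairs = _trim_trace_ends(pairs, s_raw, theta)
        if not pairs:
            continue
        key = frozenset(pairs)
        if key in seen:
            continue
        seen.add(key)
        raw_traces.append(Trace(pairs, 0.0))

    traces = apply_trace_filters(raw_traces, s_raw, smoothed, theta, params,
                                 min_span=span)
    if not prune:
        return sorted(traces, key=lambda t: t.pairs[0])
    traces = _prune_subpaths(traces)
    return deduplicate_traces(traces)


def local_self_align(e: ResidueEmbedding, params: AlignmentParams | None = None
                     ) -> list[Trace]:
    """Self-align an embedding, returning all significant off-diagonal traces."""
    params = params or AlignmentParams()
    if e.length < params.min_span:
        return []
    s = substitution_matrix(e, e)
    return align_similarity(s.values, params, self_mode=True)


def local_align(query: ResidueEmbedding, target: ResidueEmbedding,
                params: AlignmentParams,
                excluded_targets: np.ndarray | None = None,
                min_span: int | None = None) -> list[Trace]:
    """Local query-vs-target alignment (no diagonal exclusion)."""
    s = substitution_matrix(query, target)
    return align_similarity(s.values, params, self_mode=False,
                            excluded_targets=excluded_targets,
                            min_span=min_span)


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def global_align(a: ResidueEmbedding, b: ResidueEmbedding,
                 gap_extension: float = 0.0) -> GlobalAlignment:
    """Needleman-Wunsch optimum on the cosine matrix with a linear gap penalty.

    The alignment covers both inputs end to end; the score is the mean cosine
    similarity over aligned (non-gap) pairs.  Ties prefer diagonal, then up,
    then left moves, which makes the result deterministic.
    """
    s = substitution_matrix(a, b).values
    F = _nw_fill(s, gap_extension)
    i, j = a.length, b.length
    pairs: list[tuple[int | None, int | None]] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + s[i - 1, j - 1]:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] - gap_extension:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    matched = [(i, j) for i, j in pairs if i is not None and j is not None]
    score = float(np.mean([s[i, j] for i, j in matched])) if matched else 0.0
    return GlobalAlignment(pairs, score, a.sequence_id, b.sequence_id)


__all__ = [
    "AlignmentParams", "SimilarityMatrix", "Trace", "TraceOrigin",
    "GlobalAlignment", "substitution_matrix", "diagonal_smooth", "noise_gate",
    "moving_average", "windowed_trace_score", "align_similarity",
    "local_self_align", "local_align", "global_align", "apply_trace_filters",
    "deduplicate_traces", "replace", "field",
]
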