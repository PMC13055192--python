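"""The repeat-detection algorithm proper.

Pipeline: self-align the embedding (all suboptimal traces), enrich by one
round of transitive trace composition, accumulate trace scores into a
dot-plot-like score matrix M_s, estimate candidate repeat lengths from
off-diagonal score sums, localize a representative repeat with a
position-weighted sliding window, build a profile-like weighted embedding of
the representative, extract repeat instances by searching it against the
full-length embedding, and iterate after masking detected regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (AlignmentParams, GlobalAlignment, SimilarityMatrix,
                        Trace, TraceOrigin, align_similarity,
                        apply_trace_filters, diagonal_smooth, global_align,
                        local_self_align, noise_gate, substitution_matrix)
from .embeddings import ParameterError, ResidueEmbedding


@dataclass
class ScoreMatrix:
    """M_s: per residue pair, the summed scores of all traces covering it."""

    values: np.ndarray
    traces: list[Trace] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LengthCandidate:
    """A candidate repeat length: diagonal distance d and its score sum."""

    d: int
    diagonal_sum: float


@dataclass
class RepresentativeRepeat:
    start: int              # P_r, 0-based column index
    length: int             # l
    window_score: float
    embedding: ResidueEmbedding | None = None


@dataclass
class RepeatInstance:
    span: tuple[int, int]   # 0-based half-open on the full sequence
    alignment: GlobalAlignment
    score: float

    def coverage(self, l: int) -> float:
        """Fraction of representative columns matched by this instance,
        relative to the shorter of the representative length and the
        instance span, so instances truncated at repeat-region boundaries
        are not penalized for residues that do not exist."""
        matched = {i for i, _ in self.alignment.matched_pairs}
        return len(matched) / min(l, max(self.span[1] - self.span[0], 1))


@dataclass
class RepeatFamily:
    length: int
    representative: RepresentativeRepeat
    instances: list[RepeatInstance]
    msa: list[str] = field(default_factory=list)
    selection_metric_value: float = 0.0
    iteration: int = 0
    length_support: float = 0.0  # diagonal score-sum behind this length

    def spans(self) -> list[tuple[int, int]]:
        return [inst.span for inst in self.instances]


@dataclass(frozen=True)
class DetectParams:
    """Full detector configuration (alignment engine + orchestration)."""

    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    max_iterations: int = 5
    hypothesis_budget: int = 10
    selection_metric: str = "mean_coverage"
    coverage_tie_tol: float = 0.05
    overlap_max: float = 0.5
    seed: int = 0


@dataclass
class DetectionResult:
    sequence_id: str
    families: list[RepeatFamily]
    params: DetectParams
    seed: int
    masked_spans: list[list[tuple[int, int]]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Transitivity
# ---------------------------------------------------------------------------

def _monotone_segments(pairs: list[tuple[int, int]], band: int
                       ) -> list[list[tuple[int, int]]]:
    """Split composed pairs into upper-triangle monotone segments."""
    upper = [(i, j) for i, j in pairs if j - i > band]
    lower = [(j, i) for i, j in pairs if i - j > band]
    return [sorted(seg) for seg in (upper, lower) if seg]


def apply_transitivity(traces: list[Trace], s: SimilarityMatrix | np.ndarray,
                       params: AlignmentParams) -> list[Trace]:
    """One round of transitive closure over the primary traces.

    If residues i-j are aligned in one trace and j-k in another, i-k are
    assumed aligned in the composed (transitive) trace.  Composites are scored
    from the similarity matrix with the windowed trace score and must pass the
    same span/score filters as primary traces; they never compose again.
    """
    s_raw = np.asarray(s.values if isinstance(s, SimilarityMatrix) else s,
                       dtype=np.float64)
    smoothed = diagonal_smooth(s_raw, params.window_length)
    theta = noise_gate(smoothed, params.sigma_factor, params.diagonal_exclusion)

    primaries = [t for t in traces if t.origin == TraceOrigin.PRIMARY]
    existing = {t.pair_set for t in traces}
    seen: set[frozenset] = set(existing)
    candidates: list[Trace] = []
    # each trace acts as a partial bijection in both directions
    maps = []
    for t in primaries:
        fwd = dict(t.pairs)
        inv = {j: i for i, j in t.pairs}
        maps.append((t, (fwd, inv)))
    # a trace may compose with itself: offset-l pairs chained through the
    # shared middle copy give the offset-2l trace, the canonical repeat case
    for a, (fa, ga) in maps:
        for b, (fb, gb) in maps:
            for m1 in (fa, ga):
                for m2 in (fb, gb):
                    composed = [(x, m2[y]) for x, y in m1.items() if y in m2]
                    if not composed:
                        continue
                    for seg in _monotone_segments(composed,
                                                  params.diagonal_exclusion):
                        key = frozenset(seg)
                        if key in seen:
                            continue
                        seen.add(key)
                        candidates.append(Trace(seg, 0.0, TraceOrigin.TRANSITIVE))

    accepted = apply_trace_filters(candidates, s_raw, smoothed, theta, params)
    return list(traces) + accepted


# ---------------------------------------------------------------------------
# Score matrix and repeat-length estimation
# ---------------------------------------------------------------------------

def build_score_matrix(traces: list[Trace], length: int) -> ScoreMatrix:
    """Sum trace scores into M_s; each aligned pair contributes to both
    triangles (the matrix is a symmetric dot plot)."""
    values = np.zeros((length, length))
    for t in traces:
        for i, j in t.pairs:
            values[i, j] += t.score
            values[j, i] += t.score
    return ScoreMatrix(values, list(traces))


def candidate_lengths(m: ScoreMatrix) -> list[LengthCandidate]:
    """Sum M_s over all upper-triangle cells at each diagonal distance
    d in [1, L/2]; distances with positive sums are candidate repeat lengths,
    ordered by decreasing sum."""
    out = []
    for d in range(1, m.length // 2 + 1):
        total = float(m.values.diagonal(d).sum())
        if total > 0.0:
            out.append(LengthCandidate(d, total))
    return sorted(out, key=lambda c: (-c.diagonal_sum, c.d))


def window_weights(l: int) -> np.ndarray:
    """Symmetric triangular column weights w(p) = min(p, l-p+1) - 1/2.

    Conserved positions sit in the middle of repeat units while boundaries
    accumulate substitutions and indels, so central columns weigh more.
    """
    if l < 1:
        raise ParameterError("l must be >= 1")
    p = np.arange(1, l + 1, dtype=np.float64)
    return np.minimum(p, l - p + 1) - 0.5


def locate_representative(m: ScoreMatrix, l: int) -> RepresentativeRepeat:
    """Slide an l-column window over M_s and maximize the weighted score
    Score_window(c) = sum_i sum_p w(p) * M_s[i, c+p-1]; leftmost tie wins."""
    if l > m.length:
        raise ParameterError(f"window length {l} exceeds sequence length "
                             f"{m.length}")
    w = window_weights(l)
    colsum = m.values.sum(axis=0)
    scores = np.convolve(colsum, w[::-1], mode="valid")
    start = int(np.argmax(scores))  # first occurrence = smallest c
    return RepresentativeRepeat(start, l, float(scores[start]))


def weighted_repeat_embedding(m: ScoreMatrix, e_fl: ResidueEmbedding,
                              rep: RepresentativeRepeat) -> np.ndarray:
    """Profile-like weighted embedding E_repeat = M_sw^T . E_fl.

    Row r of the result is the sum over all sequence positions i of
    M_s[i, P_r + r] * E_fl[i]: sites aligned to representative column r stack
    their embeddings, weighted by accumulated trace score, like profile
    columns built from an MSA.  Columns with no trace coverage fall back to
    the raw embedding row so no row is the zero vector.
    """
    if rep.start < 0 or rep.start + rep.length > m.length:
        raise ParameterError("representative window out of bounds")
    w = m.values[:, rep.start:rep.start + rep.length]   # (L, l)
    e_rep = w.T @ e_fl.values                           # (l, D)
    zero_rows = ~np.any(w, axis=0)
    if zero_rows.any():
        e_rep[zero_rows] = e_fl.values[rep.start + np.flatnonzero(zero_rows)]
    rep.embedding = ResidueEmbedding(e_rep, f"{e_fl.sequence_id}|rep")
    return e_rep


# ---------------------------------------------------------------------------
# Instance extraction and MSA
# ---------------------------------------------------------------------------

def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def effective_min_span(l: int, params: AlignmentParams) -> int:
    """Minimum trace span for instance extraction: half a unit, floored at 5
    and capped at the global min_span.  Units shorter than the default span
    could otherwise never be recovered, and instances truncated at the ends
    of a repeat region (the representative window is phase-free, so the
    tiling rarely starts exactly at a region boundary) are still informative
    down to half their length."""
    return max(5, min(params.min_span, (l + 1) // 2))


def extract_instances(rep_embedding: ResidueEmbedding | np.ndarray,
                      e_fl: ResidueEmbedding,
                      params: AlignmentParams,
                      excluded: np.ndarray | None = None,
                      overlap_max: float = 0.5) -> list[RepeatInstance]:
    """Search the representative profile against the full-length embedding.

    Local traces give candidate spans; overlaps are resolved greedily by
    descending score (pairwise overlap at most ``overlap_max`` of the shorter
    span); each accepted span is then globally aligned to the representative
    for its final alignment and score.
    """
    if isinstance(rep_embedding, np.ndarray):
        rep_embedding = ResidueEmbedding(rep_embedding, "representative")
    l = rep_embedding.length
    span_min = effective_min_span(l, params)
    s = substitution_matrix(rep_embedding, e_fl)
    traces = align_similarity(s.values, params, self_mode=False,
                              excluded_targets=excluded, min_span=span_min)

    accepted: list[Trace] = []
    for t in sorted(traces, key=lambda t: (-t.score, t.target_span())):
        span = t.target_span()
        ok = True
        for u in accepted:
            other = u.target_span()
            shorter = min(span[1] - span[0], other[1] - other[0])
            if _span_overlap(span, other) > overlap_max * shorter:
                ok = False
                break
        if ok:
            accepted.append(t)

    instances: list[RepeatInstance] = []
    for t in accepted:
        start, end = t.target_span()
        ga = global_align(rep_embedding, e_fl.slice_rows(start, end),
                          params.gap_extension)
        if ga.score < params.score_cutoff:
            continue
        instances.append(RepeatInstance((start, end), ga, ga.score))
    return sorted(instances, key=lambda inst: inst.span)


def assemble_msa(instances: list[RepeatInstance], rep: RepresentativeRepeat,
                 sequence: str | None = None) -> list[str]:
    """Stitch pairwise instance-vs-representative alignments into an A2M MSA.

    Representative columns are match states: residues aligned to a
    representative position are uppercase in that column, deletions are '-',
    and instance residues between representative positions become lowercase
    insert states.  Row order follows instance order along the sequence.
    """
    rows = []
    for inst in instances:
        start = inst.span[0]

        def letter(j: int) -> str:
            return sequence[start + j] if sequence else "X"

        columns = {c: "-" for c in range(rep.length)}
        inserts: dict[int, str] = {}
        col = -1  # inserts before the first match column attach to key -1
        for i, j in inst.alignment.pairs:
            if i is not None and j is not None:
                col = i
                columns[i] = letter(j).upper()
            elif i is not None:
                col = i
            else:
                inserts[col] = inserts.get(col, "") + letter(j).lower()
        row = inserts.get(-1, "")
        for c in range(rep.length):
            row += columns[c] + inserts.get(c, "")
        rows.append(row)
    return rows


def period_consistent(instances: list[RepeatInstance], l: int) -> bool:
    """A length-l hypothesis is coherent only if its instances recur with
    period ~l: the median spacing of consecutive instance starts must sit
    near an integer multiple of l (a multiple, not l itself, tolerates a
    skipped copy).  Without this check a candidate distance arising from one
    repeat region can have its representative window placed inside another,
    differently-periodic region and tile it under the wrong length label.
    """
    starts = sorted(inst.span[0] for inst in instances)
    if len(starts) < 2:
        return True
    period = float(np.median(np.diff(starts)))
    tol = max(2.0, 0.1 * l)
    k = max(1, round(period / l))
    return abs(period - k * l) <= tol


def _metric(family: RepeatFamily, name: str) -> float:
    if name == "mean_coverage":
        return float(np.mean([inst.coverage(family.length)
                              for inst in family.instances]))
    if name == "total_aligned_residues":
        return float(sum(len(inst.alignment.matched_pairs)
                         for inst in family.instances))
    raise ParameterError(f"unknown selection metric {name!r}")


def select_best_length(hypotheses: list[RepeatFamily],
                       metric_name: str = "mean_coverage",
                       tie_tol: float = 0.05) -> RepeatFamily | None:
    """Pick the repeat-length hypothesis with the best selection metric.

    Metrics within ``tie_tol`` of the maximum are treated as tied: integer
    multiples of the unit length reach nominally perfect coverage (their
    in-phase instances align to the representative without mismatch), while
    indel-induced gaps cost the true length a few per cent, so coverage
    differences below the tolerance carry no length information.  Ties go to
    more instances, then stronger diagonal score-sum support (the actual
    periodicity evidence), then smaller length, then smaller start.
    """
    if not hypotheses:
        return None
    for h in hypotheses:
        h.selection_metric_value = _metric(h, metric_name)
    best = max(h.selection_metric_value for h in hypotheses)
    tied = [h for h in hypotheses if h.selection_metric_value >= best - tie_tol]
    return min(tied, key=lambda h: (-len(h.instances), -h.length_support,
                                    h.length, h.representative.start))


def mask_score_matrix(m: ScoreMatrix, spans: list[tuple[int, int]]
                      ) -> ScoreMatrix:
    """Zero all rows and columns whose position lies in any span."""
    values = m.values.copy()
    for start, end in spans:
        if start < 0 or end > m.length:
            raise ParameterError(f"mask span ({start}, {end}) out of bounds")
        values[start:end, :] = 0.0
        values[:, start:end] = 0.0
    return ScoreMatrix(values, m.traces)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def detect_repeats(e_fl: ResidueEmbedding,
                   params: DetectParams | None = None,
                   sequence: str | None = None) -> DetectionResult:
    """Run the full detection pipeline on one embedding.

    Deterministic given the embedding and parameters.  Each masking iteration
    evaluates the top candidate lengths, keeps the best family with at least
    two instances, masks its residues out of both the score matrix and the
    extraction target, and repeats until nothing significant remains.
    """
    params = params or DetectParams()
    ap = params.alignment
    traces = local_self_align(e_fl, ap)
    s = substitution_matrix(e_fl, e_fl)
    traces = apply_transitivity(traces, s, ap)
    m = build_score_matrix(traces, e_fl.length)

    families: list[RepeatFamily] = []
    masked_per_iter: list[list[tuple[int, int]]] = []
    excluded = np.zeros(e_fl.length, dtype=bool)

    for iteration in range(params.max_iterations):
        cands = candidate_lengths(m)[:params.hypothesis_budget]
        hypotheses: list[RepeatFamily] = []
        for cand in cands:
            l = cand.d
            if l > m.length:
                continue
            rep = locate_representative(m, l)
            if rep.window_score <= 0.0:
                continue
            weighted_repeat_embedding(m, e_fl, rep)
            instances = extract_instances(rep.embedding, e_fl, ap,
                                          excluded=excluded,
                                          overlap_max=params.overlap_max)
            if len(instances) < 2 or not period_consistent(instances, l):
                continue
            fam = RepeatFamily(l, rep, instances,
                               msa=assemble_msa(instances, rep, sequence),
                               iteration=iteration,
                               length_support=cand.diagonal_sum)
            hypotheses.append(fam)
        best = select_best_length(hypotheses, params.selection_metric,
                                  params.coverage_tie_tol)
        if best is None:
            break
        families.append(best)
        spans = best.spans()
        masked_per_iter.append(spans)
        m = mask_score_matrix(m, spans)
        for start, end in spans:
            excluded[start:end] = True

    return DetectionResult(e_fl.sequence_id, families, params, params.seed,
                           masked_per_iter)


__all__ = [
    "ScoreMatrix", "LengthCandidate", "RepresentativeRepeat", "RepeatInstance",
    "RepeatFamily", "DetectParams", "DetectionResult", "apply_transitivity",
    "build_score_matrix", "candidate_lengths", "window_weights",
    "locate_representative", "weighted_repeat_embedding", "extract_instances",
    "effective_min_span", "assemble_msa", "select_best_length",
    "mask_score_matrix", "detect_repeats",
]
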