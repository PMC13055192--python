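"""Benchmark harness: protein-level and repeat-level evaluation.

A predicted repeat is *correct* if it overlaps some annotated ground-truth
unit reciprocally (overlap divided by each span's length) above a threshold —
a sequence-space surrogate for a structural-superposition test, reusing the
same 50% coverage threshold.  A protein is *called repetitive* if more than
half of its predicted repeats align correctly with at least one other
prediction; between two predictions, "aligns correctly" is judged by globally
aligning their embedding slices and requiring both a score above the
alignment cutoff and mutual length coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentParams, global_align
from .embeddings import GroundTruth, InputError, ResidueEmbedding

Span = tuple[int, int]


@dataclass(frozen=True)
class CorrectnessParams:
    min_mutual_fraction: float = 0.5
    min_coverage: float = 0.5
    score_cutoff: float = 0.3
    gap_extension: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.min_mutual_fraction <= 1.0:
            raise InputError("min_mutual_fraction must lie in (0, 1]")
        if not 0.0 < self.min_coverage <= 1.0:
            raise InputError("min_coverage must lie in (0, 1]")


@dataclass
class BenchmarkRecord:
    sequence_id: str
    predictions: list[Span]
    truth_units: list[Span]
    repeat_correct_flags: list[bool]
    protein_call: bool
    is_positive: bool


def _overlap(a: Span, b: Span) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def repeat_correct(pred: Span, truth: GroundTruth,
                   params: CorrectnessParams | None = None) -> bool:
    """True iff some truth unit overlaps the prediction reciprocally
    (overlap / len >= min_coverage on both sides)."""
    params = params or CorrectnessParams()
    params.validate()
    plen = pred[1] - pred[0]
    for unit in truth.units:
        ov = _overlap(pred, unit)
        if (ov >= params.min_coverage * plen
                and ov >= params.min_coverage * (unit[1] - unit[0])):
            return True
    return False


def protein_level_call(pairwise_correct: np.ndarray) -> bool:
    """True iff strictly more than half of the predictions align correctly
    with at least one other prediction.  Input: square symmetric boolean
    matrix with a false diagonal; zero predictions give False."""
    m = np.asarray(pairwise_correct, dtype=bool)
    if m.size == 0:
        return False
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("pairwise matrix must be square")
    if np.any(np.diag(m)) or not np.array_equal(m, m.T):
        raise InputError("pairwise matrix must be symmetric with false diagonal")
    n = m.shape[0]
    aligned = int(m.any(axis=1).sum())
    return aligned > n / 2


def pairwise_prediction_matrix(spans: list[Span], e: ResidueEmbedding,
                               params: CorrectnessParams | None = None
                               ) -> np.ndarray:
    """Pairwise 'correctly aligned' flags among predicted repeats of one
    protein, by global alignment of the two embedding slices."""
    params = params or CorrectnessParams()
    n = len(spans)
    flags = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            sa, sb = spans[a], spans[b]
            ga = global_align(e.slice_rows(*sa), e.slice_rows(*sb),
                              params.gap_extension)
            matched = len(ga.matched_pairs)
            la, lb = sa[1] - sa[0], sb[1] - sb[0]
            ok = (ga.score >= params.score_cutoff
                  and matched >= params.min_mutual_fraction * la
                  and matched >= params.min_mutual_fraction * lb)
            flags[a, b] = flags[b, a] = ok
    return flags


@dataclass
class BenchmarkSummary:
    records: list[BenchmarkRecord] = field(default_factory=list)
    correct_proteins: int = 0
    false_positive_proteins: int = 0
    correct_repeats: int = 0
    false_positive_repeats: int = 0
    n_positive: int = 0
    n_negative: int = 0

    def as_dict(self) -> dict:
        return {"correct_proteins": self.correct_proteins,
                "false_positive_proteins": self.false_positive_proteins,
                "correct_repeats": self.correct_repeats,
                "false_positive_repeats": self.false_positive_repeats,
                "n_positive": self.n_positive,
                "n_negative": self.n_negative}


def benchmark_run(predictions: dict[str, list[Span]],
                  truths: dict[str, GroundTruth],
                  embeddings: dict[str, ResidueEmbedding] | None = None,
                  params: CorrectnessParams | None = None) -> BenchmarkSummary:
    """Evaluate detector output against ground truth at both levels.

    ``truths`` must cover every predicted id; proteins whose truth has no
    units are negatives, and every prediction on a negative protein counts as
    a false-positive repeat.  Protein-level calls need ``embeddings`` for the
    pairwise alignment test; without them a protein is called repetitive from
    span-overlap-free predictions only if it has >= 2 predictions whose
    lengths agree within the mutual-fraction threshold.
    """
    params = params or CorrectnessParams()
    params.validate()
    missing = sorted(set(predictions) - set(truths))
    if missing:
        raise InputError(f"predictions without ground truth: {missing}")

    summary = BenchmarkSummary()
    for sid in sorted(truths):
        truth = truths[sid]
        preds = sorted(predictions.get(sid, []))
        positive = bool(truth.units)
        flags = [repeat_correct(p, truth, params) for p in preds]
        if embeddings is not None and sid in embeddings and preds:
            pw = pairwise_prediction_matrix(preds, embeddings[sid], params)
        else:
            pw = _length_based_pairwise(preds, params)
        call = protein_level_call(pw)
        summary.records.append(BenchmarkRecord(sid, preds, list(truth.units),
                                               flags, call, positive))
        if positive:
            summary.n_positive += 1
            summary.correct_proteins += int(call)
            summary.correct_repeats += sum(flags)
        else:
            summary.n_negative += 1
            summary.false_positive_proteins += int(call)
            summary.false_positive_repeats += len(preds)
    return summary


def _length_based_pairwise(spans: list[Span],
                           params: CorrectnessParams) -> np.ndarray:
    n = len(spans)
    flags = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            la, lb = spans[a][1] - spans[a][0], spans[b][1] - spans[b][0]
            ok = min(la, lb) >= params.min_mutual_fraction * max(la, lb)
            flags[a, b] = flags[b, a] = ok
    return flags


__all__ = [
    "CorrectnessParams", "BenchmarkRecord", "BenchmarkSummary",
    "repeat_correct", "protein_level_call", "pairwise_prediction_matrix",
    "benchmark_run", "AlignmentParams",
]
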