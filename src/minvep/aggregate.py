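"""Ensemble aggregation of aligned LLR grids.

Maximum-confidence aggregation scores each substitution by the most
pathogenic (minimum) LLR across the ensemble — the model most confident in
the wild-type residue wins. Averaging is the conventional alternative.
Supporting utilities: per-model contribution fractions to the minimum,
percentile filtering of uninformative segments, and mean-shifting of
distillation targets onto a base model's score scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .scoring import LLRMatrix

__all__ = [
    "ScoreStack",
    "AggregationResult",
    "aggregate_min",
    "aggregate_mean",
    "model_contributions",
    "segment_min_score",
    "filter_segments",
    "mean_shift_targets",
    "matrix_mean",
]


@dataclass
class ScoreStack:
    """Aligned LLR grids for one protein from M scorers."""

    protein_id: str
    model_names: list[str]
    matrices: list[LLRMatrix]

    def __post_init__(self) -> None:
        if len(self.matrices) == 0:
            raise ValueError("empty score stack")
        if len(self.model_names) != len(self.matrices):
            raise ValueError("model name / matrix count mismatch")
        L = len(self.matrices[0])
        for m in self.matrices:
            if len(m) != L or not np.array_equal(
                m.wt_indices, self.matrices[0].wt_indices
            ):
                raise ValueError("stack matrices are not aligned")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def scores(self) -> np.ndarray:  # (M, L, 20)
        return np.stack([m.scores for m in self.matrices])

    @property
    def masks(self) -> np.ndarray:  # (M, L, 20)
        return np.stack([m.mask for m in self.matrices])


@dataclass
class AggregationResult:
    """Aggregated grid plus bookkeeping (argmin indices in min mode)."""

    matrix: LLRMatrix
    aggregator: str  # "min" | "mean"
    argmin: np.ndarray | None = None  # (L, 20) model index, -1 where masked
    model_names: list[str] | None = None


def _stack_arrays(stack: ScoreStack) -> tuple[np.ndarray, np.ndarray]:
    scores = stack.scores
    masks = stack.masks
    return scores, masks


def aggregate_min(stack: ScoreStack) -> AggregationResult:
    """Elementwise minimum over unmasked models (maximum confidence).

    Argmin ties break toward the lowest model index. Entries masked in every
    model stay masked; wild-type entries remain 0.
    """
    scores, masks = _stack_arrays(stack)
    masked = np.where(masks, scores, np.inf)
    agg = masked.min(axis=0)
    argmin = np.argmin(masked, axis=0)
    any_valid = masks.any(axis=0)
    agg = np.where(any_valid, agg, 0.0)
    argmin = np.where(any_valid, argmin, -1)
    out = LLRMatrix(
        stack.protein_id, agg, stack.matrices[0].wt_indices.copy(), any_valid
    )
    return AggregationResult(out, "min", argmin=argmin, model_names=stack.model_names)


def aggregate_mean(stack: ScoreStack) -> AggregationResult:
    """Elementwise arithmetic mean over unmasked models."""
    scores, masks = _stack_arrays(stack)
    n = masks.sum(axis=0)
    any_valid = n > 0
    total = np.where(masks, scores, 0.0).sum(axis=0)
    agg = np.divide(total, n, out=np.zeros_like(total), where=any_valid)
    out = LLRMatrix(
        stack.protein_id, agg, stack.matrices[0].wt_indices.copy(), any_valid
    )
    return AggregationResult(out, "mean", model_names=stack.model_names)


def model_contributions(result: AggregationResult) -> np.ndarray:
    """Fraction of non-wild-type unmasked entries each model wins in the min.

    Fractions sum to 1. Only defined for min-mode results.
    """
    if result.aggregator != "min" or result.argmin is None:
        raise ValueError("contributions are defined for min-mode aggregation only")
    sel = result.matrix.variant_mask()
    winners = result.argmin[sel]
    winners = winners[winners >= 0]
    if winners.size == 0:
        raise ValueError("no unmasked non-wild-type entries")
    n_models = len(result.model_names) if result.model_names else int(winners.max()) + 1
    counts = np.bincount(winners, minlength=n_models).astype(float)
    return counts / counts.sum()


def segment_min_score(matrix: LLRMatrix) -> float:
    """Minimum aggregated score over variant positions, excluding position 1.

    Position 1 (the initiator methionine) is excluded from the statistic; a
    segment whose minimum sits near zero carries no damaging signal anywhere.
    """
    sel = matrix.variant_mask()
    if len(matrix) > 1:
        sel = sel.copy()
        sel[0, :] = False
    vals = matrix.scores[sel]
    if vals.size == 0:
        raise ValueError("no scoreable entries beyond position 1")
    return float(vals.min())


def filter_segments(
    segment_min_scores: Mapping[str, float], percentile: float = 95.0
) -> list[str]:
    """Keep segments whose minimum score is at or below the given percentile.

    Segments whose minimum score exceeds the 95th percentile of the
    per-segment minimum distribution are uninformative (all scores near
    zero) and are dropped. Linear-interpolation percentile convention.
    """
    if len(segment_min_scores) == 0:
        raise ValueError("no segments to filter")
    ids = list(segment_min_scores)
    vals = np.array([segment_min_scores[i] for i in ids], dtype=float)
    cut = np.percentile(vals, percentile)
    return [i for i, v in zip(ids, vals) if v <= cut]


def matrix_mean(matrix: LLRMatrix) -> float:
    """Mean score over non-wild-type unmasked entries."""
    sel = matrix.variant_mask()
    if not sel.any():
        raise ValueError("no unmasked non-wild-type entries")
    return float(matrix.scores[sel].mean())


def mean_shift_targets(targets: LLRMatrix, base_mean: float) -> tuple[LLRMatrix, float]:
    """Shift target scores by a constant so their mean matches ``base_mean``.

    The mean is computed over non-wild-type unmasked entries and the shift
    applied to those entries only (wild-type entries stay 0 and are excluded
    from any training loss). Returns the shifted grid and the shift constant,
    which is computed once and held fixed thereafter.
    """
    shift = base_mean - matrix_mean(targets)
    out = targets.copy()
    sel = out.variant_mask()
    out.scores[sel] += shift
    return out, float(shift)
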