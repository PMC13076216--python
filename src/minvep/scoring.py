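"""Log-likelihood-ratio (LLR) variant-effect scoring.

A scorer is anything exposing ``position_log_probs(sequence) -> (L, 20)``
natural-log probabilities over the canonical alphabet (wild-type-marginal
scheme: one forward pass on the unmutated sequence scores all substitutions).
The LLR of substituting residue ``wt`` by ``alt`` at position ``t`` is

    LLR(t, alt) = log p(x_t = alt | x) - log p(x_t = wt | x)

so higher scores are more benign and the wild-type entry is exactly zero.
Long proteins are segmented with an overlapping sliding window and the
per-window grids are stitched back by assigning each position to the window
in which it is most central.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20, LOGP_FLOOR, N_AA, aa_to_index, sequence_to_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinRecord",
    "PositionLogProbs",
    "LLRMatrix",
    "SegmentPlan",
    "Scorer",
    "score_position_logprobs",
    "llr_matrix",
    "score_protein",
    "plan_segments",
    "stitch_segments",
    "variant_score",
    "score_variant_table",
]


class Scorer(Protocol):
    """Anything that scores per-position amino-acid log-probabilities."""

    def position_log_probs(self, sequence: str) -> np.ndarray:  # (L, 20)
        ...


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence (uppercased on construction).

    Nonstandard letters are permitted; they are flagged via
    :attr:`nonstandard_positions` and the corresponding LLR rows are masked.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def wt_indices(self) -> np.ndarray:
        """Alphabet index of the wild-type letter per position (-1 if nonstandard)."""
        return sequence_to_indices(self.sequence)

    @property
    def nonstandard_positions(self) -> list[int]:
        """1-based positions whose letter is outside the 20-letter alphabet."""
        return [t + 1 for t, i in enumerate(self.wt_indices) if i < 0]


@dataclass(frozen=True)
class PositionLogProbs:
    """Validated per-position log-probabilities over the canonical alphabet.

    Each row log-sum-exps to 0 within tolerance before flooring; entries are
    then floored at ``LOGP_FLOOR`` to guard one-hot scorers.
    """

    protein_id: str
    logp: np.ndarray  # (L, 20), floored

    def __len__(self) -> int:
        return self.logp.shape[0]


@dataclass
class LLRMatrix:
    """L x 20 grid of substitution LLRs for one protein.

    ``scores[t, a]`` is the natural-log likelihood ratio of substituting the
    wild-type residue at (0-based) position ``t`` by alphabet letter ``a``.
    Wild-type entries are exactly 0; ``mask`` marks scoreable entries (rows at
    nonstandard wild-type letters are fully masked).
    """

    protein_id: str
    scores: np.ndarray  # (L, 20) float
    wt_indices: np.ndarray  # (L,) int, -1 for nonstandard
    mask: np.ndarray = field(default=None)  # (L, 20) bool, True = valid

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.wt_indices = np.asarray(self.wt_indices, dtype=np.int64)
        L = self.scores.shape[0]
        if self.scores.shape != (L, N_AA) or self.wt_indices.shape != (L,):
            raise ValueError("LLRMatrix shape mismatch")
        if self.mask is None:
            self.mask = np.ones((L, N_AA), dtype=bool)
            self.mask[self.wt_indices < 0, :] = False
        self.mask = np.asarray(self.mask, dtype=bool)
        # enforce the wild-type-zero invariant exactly
        rows = np.flatnonzero(self.wt_indices >= 0)
        self.scores[rows, self.wt_indices[rows]] = 0.0

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def wt_mask(self) -> np.ndarray:
        """Boolean (L, 20) grid marking wild-type entries."""
        m = np.zeros_like(self.mask)
        rows = np.flatnonzero(self.wt_indices >= 0)
        m[rows, self.wt_indices[rows]] = True
        return m

    def variant_mask(self) -> np.ndarray:
        """Scoreable non-wild-type entries: the 19 x L substitution grid."""
        return self.mask & ~self.wt_mask

    def copy(self) -> "LLRMatrix":
        return LLRMatrix(
            self.protein_id, self.scores.copy(), self.wt_indices.copy(), self.mask.copy()
        )


@dataclass(frozen=True)
class SegmentPlan:
    """Ordered sliding windows covering positions 1..L (1-based inclusive)."""

    windows: tuple[tuple[int, int], ...]
    window: int
    overlap: int

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


def score_position_logprobs(scorer: Scorer, protein: ProteinRecord) -> PositionLogProbs:
    """Run ``scorer`` on the wild-type sequence and validate its output.

    Raises ``ValueError`` on a shape mismatch and on non-finite entries other
    than -inf (which the floor absorbs); each row must be a normalized
    distribution (logsumexp 0 within 1e-6).
    """
    logp = np.asarray(scorer.position_log_probs(protein.sequence), dtype=float)
    if logp.shape != (len(protein), N_AA):
        raise ValueError(
            f"scorer returned shape {logp.shape}, expected {(len(protein), N_AA)}"
        )
    if np.any(np.isnan(logp)) or np.any(logp == np.inf):
        raise ValueError("scorer produced NaN or +inf log-probabilities")
    from scipy.special import logsumexp

    lse = logsumexp(logp, axis=1)
    if np.any(np.abs(lse) > 1e-6):
        bad = int(np.argmax(np.abs(lse)))
        raise ValueError(
            f"log-probabilities not normalized at position {bad + 1}: logsumexp={lse[bad]:.3g}"
        )
    return PositionLogProbs(protein.id, np.maximum(logp, LOGP_FLOOR))


def llr_matrix(logprobs: PositionLogProbs, protein: ProteinRecord) -> LLRMatrix:
    """Convert per-position log-probabilities into a substitution LLR grid.

    Rows whose wild-type letter falls outside the canonical alphabet are
    masked (and logged) rather than failing the whole protein.
    """
    if len(logprobs) != len(protein):
        raise ValueError("log-probability / protein length mismatch")
    wt = protein.wt_indices
    L = len(protein)
    scores = np.zeros((L, N_AA))
    mask = np.ones((L, N_AA), dtype=bool)
    rows = wt >= 0
    scores[rows] = logprobs.logp[rows] - logprobs.logp[rows, wt[rows]][:, None]
    mask[~rows, :] = False
    if np.any(~rows):
        logger.warning(
            "protein %s: masked %d position(s) with nonstandard wild-type letters",
            protein.id,
            int(np.sum(~rows)),
        )
    return LLRMatrix(protein.id, scores, wt, mask)


def plan_segments(L: int, window: int = 1022, overlap: int = 511) -> SegmentPlan:
    """Plan overlapping sliding windows over a protein of length ``L``.

    Windows of ``window`` residues advance by ``window - overlap``; the last
    window is anchored to end exactly at ``L``. A protein no longer than one
    window gets the single window ``(1, L)``.
    """
    if L < 1 or window < 1:
        raise ValueError("L and window must be positive")
    if overlap < 0 or overlap >= window:
        raise ValueError(f"overlap must satisfy 0 <= overlap < window, got {overlap}")
    if L <= window:
        return SegmentPlan(((1, L),), window, overlap)
    stride = window - overlap
    starts = [1]
    while True:
        nxt = starts[-1] + stride
        if nxt + window - 1 >= L:
            starts.append(L - window + 1)
            break
        starts.append(nxt)
    return SegmentPlan(tuple((s, s + window - 1) for s in starts), window, overlap)


def stitch_segments(
    segment_matrices: Sequence[LLRMatrix], plan: SegmentPlan
) -> LLRMatrix:
    """Assemble per-window LLR grids into one full-length grid.

    Each position takes its scores from the window in which it is most
    central (ties broken toward the earlier window) — one defensible reading
    of overlap combination for windowed scoring.
    """
    if len(segment_matrices) != len(plan):
        raise ValueError(
            f"incomplete plan: {len(segment_matrices)} matrices for {len(plan)} windows"
        )
    for m, (s, e) in zip(segment_matrices, plan):
        if len(m) != e - s + 1:
            raise ValueError(f"matrix for window ({s},{e}) has length {len(m)}")
    L = plan.windows[-1][1]
    centers = np.array([(s + e) / 2.0 for s, e in plan])
    pos = np.arange(1, L + 1)
    # distance of each position to each window center; out-of-window = inf
    dist = np.abs(pos[:, None] - centers[None, :])
    for j, (s, e) in enumerate(plan):
        dist[(pos < s) | (pos > e), j] = np.inf
    owner = np.argmin(dist, axis=1)  # ties -> earlier window

    scores = np.empty((L, N_AA))
    mask = np.empty((L, N_AA), dtype=bool)
    wt = np.empty(L, dtype=np.int64)
    for j, (s, e) in enumerate(plan):
        sel = owner == j
        local = pos[sel] - s
        scores[sel] = segment_matrices[j].scores[local]
        mask[sel] = segment_matrices[j].mask[local]
        wt[sel] = segment_matrices[j].wt_indices[local]
    return LLRMatrix(segment_matrices[0].protein_id, scores, wt, mask)


def score_protein(
    scorer: Scorer,
    protein: ProteinRecord,
    window: int = 1022,
    overlap: int = 511,
) -> LLRMatrix:
    """Score a protein end-to-end, segmenting when longer than ``window``."""
    plan = plan_segments(len(protein), window, overlap)
    if len(plan) == 1:
        return llr_matrix(score_position_logprobs(scorer, protein), protein)
    logger.info("protein %s (L=%d): scoring %d windows", protein.id, len(protein), len(plan))
    pieces = []
    for s, e in plan:
        sub = ProteinRecord(protein.id, protein.sequence[s - 1 : e])
        pieces.append(llr_matrix(score_position_logprobs(scorer, sub), sub))
    return stitch_segments(pieces, plan)


def variant_score(matrix: LLRMatrix, position: int, ref_aa: str, alt_aa: str) -> float:
    """Look up the LLR for a single substitution (1-based position).

    A mismatch between ``ref_aa`` and the stored wild-type letter signals a
    coordinate or isoform problem and raises ``ValueError``.
    """
    if position < 1 or position > len(matrix):
        raise IndexError(f"position {position} outside 1..{len(matrix)}")
    t = position - 1
    ref_idx = aa_to_index(ref_aa.upper())
    if ref_idx < 0 or matrix.wt_indices[t] != ref_idx:
        stored = AA20[matrix.wt_indices[t]] if matrix.wt_indices[t] >= 0 else "?"
        raise ValueError(
            f"reference mismatch at {matrix.protein_id} position {position}: "
            f"got {ref_aa}, matrix has {stored}"
        )
    if ref_aa.upper() == alt_aa.upper():
        return 0.0
    alt_idx = aa_to_index(alt_aa.upper())
    if alt_idx < 0:
        raise ValueError(f"nonstandard alternate amino acid {alt_aa!r}")
    if not matrix.mask[t, alt_idx]:
        return float("nan")
    return float(matrix.scores[t, alt_idx])


def score_variant_table(
    variants: pd.DataFrame, matrices: Mapping[str, LLRMatrix]
) -> pd.Series:
    """Vectorized :func:`variant_score` over a variant table.

    ``variants`` needs columns ``protein_id, position, ref, alt``; returns a
    Series of LLRs aligned to the table's index.
    """
    out = np.empty(len(variants), dtype=float)
    for i, row in enumerate(variants.itertuples(index=False)):
        out[i] = variant_score(matrices[row.protein_id], row.position, row.ref, row.alt)
    return pd.Series(out, index=variants.index, name="score")
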