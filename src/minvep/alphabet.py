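"""Canonical amino-acid alphabet shared across the toolkit.

All score grids are L x 20 with columns in the fixed order below. Nonstandard
residue letters (X, U, B, Z, ...) are tolerated in sequences but their rows
are masked rather than scored.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA20)}
N_AA: int = 20

#: Floor for log-probabilities, guarding degenerate (one-hot) scorers.
LOGP_FLOOR: float = float(np.log(1e-12))


def aa_to_index(aa: str) -> int:
    """Return the column index of a canonical amino-acid letter, or -1."""
    return AA_INDEX.get(aa, -1)


def sequence_to_indices(sequence: str) -> np.ndarray:
    """Map a protein sequence to column indices; nonstandard letters -> -1."""
    return np.fromiter(
        (AA_INDEX.get(c, -1) for c in sequence), dtype=np.int64, count=len(sequence)
    )
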