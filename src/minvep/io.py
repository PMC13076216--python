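"""Readers and writers for the toolkit's on-disk formats.

FASTA goes through Biopython. Score tables are long-format TSV
(protein_id, position, ref_aa, alt_aa, score[, model]) or wide-format CSV
(one row per position, 20 amino-acid columns). All TSV outputs carry
'#'-prefixed provenance header lines and use '.' for missing values.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .alphabet import AA20, N_AA, sequence_to_indices
from .scoring import LLRMatrix, ProteinRecord

MISSING = "."


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-FASTA file; the id is the description up to whitespace."""
    records = [
        ProteinRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def provenance_header(seed: int | None = None, **params) -> str:
    """Provenance lines recorded at the top of every TSV output."""
    cfg = json.dumps(params, sort_keys=True, default=str)
    digest = hashlib.sha256(cfg.encode()).hexdigest()[:12]
    lines = [f"# minvep {__version__}", f"# config_hash {digest}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if params:
        lines.append(f"# params {cfg}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int | None = None, **params) -> None:
    """Write a TSV with provenance header; NaN rendered as '.'."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **params))
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])


def llr_to_long(matrix: LLRMatrix, model: str | None = None) -> pd.DataFrame:
    """Long-format table of all scoreable substitutions (wild-type rows included)."""
    rows = []
    for t in range(len(matrix)):
        wt = matrix.wt_indices[t]
        if wt < 0:
            continue
        for a in range(N_AA):
            if not matrix.mask[t, a]:
                continue
            rows.append((matrix.protein_id, t + 1, AA20[wt], AA20[a], matrix.scores[t, a]))
    df = pd.DataFrame(rows, columns=["protein_id", "position", "ref_aa", "alt_aa", "score"])
    if model is not None:
        df["model"] = model
    return df


def long_to_llr(df: pd.DataFrame, protein: ProteinRecord) -> LLRMatrix:
    """Rebuild an LLRMatrix from a long-format table for one protein."""
    sub = df[df["protein_id"] == protein.id]
    L = len(protein)
    scores = np.zeros((L, N_AA))
    mask = np.zeros((L, N_AA), dtype=bool)
    wt = protein.wt_indices
    pos = sub["position"].to_numpy(dtype=int) - 1
    alt = sequence_to_indices("".join(sub["alt_aa"]))
    scores[pos, alt] = sub["score"].to_numpy(dtype=float)
    mask[pos, alt] = True
    return LLRMatrix(protein.id, scores, wt, mask)


def write_llr_long(
    matrices: Iterable[LLRMatrix], path: str | Path, model: str | None = None, **params
) -> None:
    df = pd.concat([llr_to_long(m, model=model) for m in matrices], ignore_index=True)
    write_tsv(df, path, **params)


def llr_to_wide(matrix: LLRMatrix) -> pd.DataFrame:
    """Wide-format grid: one row per position, 20 amino-acid columns."""
    df = pd.DataFrame(matrix.scores, columns=list(AA20))
    df.insert(0, "position", np.arange(1, len(matrix) + 1))
    wt = np.array([AA20[i] if i >= 0 else "X" for i in matrix.wt_indices])
    df.insert(1, "wt", wt)
    df[~np.column_stack([np.ones((len(matrix), 2), bool), matrix.mask])] = np.nan
    return df


def write_llr_wide(matrix: LLRMatrix, path: str | Path) -> None:
    llr_to_wide(matrix).to_csv(path, index=False, na_rep=MISSING)
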