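"""Continuous-phenotype association from variant scores and summary statistics.

For every gene-phenotype pair, variant-level predictions are regressed
against published single-variant effect sizes (beta coefficients); the
standardized slope (Pearson r) proxies the gene-level effect and the
two-sided product-moment p-value measures association strength. Benchmark
pairs are filtered the way a rare-variant summary-statistic benchmark is
built: enough missense variants per pair, a significant gene-level missense
test, and individually associated variants only. No multiple-testing
adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "PairResult",
    "variant_score_regression",
    "regress_pairs",
    "filter_benchmark_pairs",
    "association_strength",
    "direction_concordance",
    "log_maf_scores",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class PairResult:
    gene: str
    phenotype: str
    r: float
    p: float
    n: int


def variant_score_regression(scores, betas) -> tuple[float, float, int]:
    """Pearson r and two-sided p between variant scores and effect sizes."""
    s = np.asarray(scores, dtype=float)
    b = np.asarray(betas, dtype=float)
    if s.size != b.size:
        raise ValueError("scores and betas differ in length")
    if s.size < 3:
        raise ValueError("need at least 3 variants")
    if np.all(s == s[0]) or np.all(b == b[0]):
        raise ValueError("degenerate regression: constant input")
    res = pearsonr(s, b)
    return float(res.statistic), float(res.pvalue), int(s.size)


def regress_pairs(
    table: pd.DataFrame, score_col: str = "score", beta_col: str = "beta"
) -> pd.DataFrame:
    """Run the per-pair regression over a long table of variants.

    Requires ``gene, phenotype`` plus the score and beta columns; pair-level
    columns (``plof_beta`` etc.), when present, are carried through.
    """
    rows = []
    carry = [c for c in ("plof_beta", "plof_p", "gene_missense_p") if c in table]
    for (gene, pheno), sub in table.groupby(["gene", "phenotype"]):
        r, p, n = variant_score_regression(sub[score_col], sub[beta_col])
        row = {"gene": gene, "phenotype": pheno, "r": r, "p": p, "n": n}
        for c in carry:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def filter_benchmark_pairs(
    table: pd.DataFrame,
    min_missense: int = 25,
    gene_p_threshold: float = 1e-10,
    single_variant_p: float = 0.05,
) -> pd.DataFrame:
    """Apply the benchmark inclusion filters to a summary-statistic table.

    Pair-level: at least ``min_missense`` variants in the pair's full table
    (``variant_count`` when present, else the row count) and gene-level
    missense p below ``gene_p_threshold``. Variant-level: within kept pairs,
    only variants with single-variant p below ``single_variant_p``. Each
    filter reads pair attributes or variant rows independently, so the
    composition is order-invariant.
    """
    df = table.copy()
    if "variant_count" in df:
        counts = df["variant_count"]
    else:
        counts = df.groupby(["gene", "phenotype"])["variant_id"].transform("size")
    keep_pair = counts >= min_missense
    if "gene_missense_p" in df:
        keep_pair &= df["gene_missense_p"] < gene_p_threshold
    keep_variant = df["p"] < single_variant_p
    return df[keep_pair & keep_variant]


def association_strength(results: pd.DataFrame, floor: float = P_FLOOR) -> float:
    """Mean -log10(p) over pairs, with p floored before the log."""
    p = np.maximum(results["p"].to_numpy(dtype=float), floor)
    return float(np.mean(-np.log10(p)))


def direction_concordance(
    results: pd.DataFrame, significance: float = 0.1
) -> float:
    """Fraction of significant pairs whose r sign matches the pLoF burden sign.

    Pairs with regression p >= ``significance`` are excluded; zero pLoF betas
    cannot carry a direction and are dropped with a warning.
    """
    sub = results[results["p"] < significance]
    zero = sub["plof_beta"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} pair(s) with zero pLoF beta")
        sub = sub[~zero]
    if len(sub) == 0:
        raise ValueError("no significant pairs with a nonzero pLoF direction")
    agree = np.sign(sub["r"]) == np.sign(sub["plof_beta"])
    return float(agree.mean())


def log_maf_scores(af, pseudo: float = 1e-6) -> np.ndarray:
    """log10-transformed MAF baseline comparator (pseudo-frequency for zeros)."""
    from .evaluate import maf

    m = np.maximum(np.asarray(maf(af), dtype=float), pseudo)
    return np.log10(m)
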