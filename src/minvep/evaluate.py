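"""Clinical and deep-mutational-scan benchmark statistics.

Labeled variant sets are plain DataFrames with at least ``label`` (values
'pathogenic'/'benign'), a score column, and optionally ``gene`` and ``af``.
Scores are benign-high everywhere: AUC is P(benign-scored above pathogenic)
with half credit for ties (the Mann-Whitney statistic). Calibrated scores
are probabilities of being *benign*, so pathogenic variants map below 0.5
and 0.5 is the induced classification threshold.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "auc",
    "bootstrap_balanced_auc",
    "per_gene_auc",
    "balance_per_gene",
    "calibrate_scores",
    "accuracy_coverage_curve",
    "binary_metrics",
    "apply_wt_transform",
    "dms_spearman",
    "rank_scores",
    "win_rate_matrix",
    "maf",
    "maf_stratified_auc",
]

PATHOGENIC, BENIGN = "pathogenic", "benign"


def _benign_indicator(labels: Iterable) -> np.ndarray:
    lab = np.asarray(list(labels))
    ind = np.where(lab == BENIGN, 1, np.where(lab == PATHOGENIC, 0, -1))
    if np.any(ind < 0):
        bad = sorted(set(lab[ind < 0]))
        raise ValueError(f"labels must be pathogenic/benign, got {bad}")
    return ind


def auc(scores: Sequence[float], labels: Iterable) -> float:
    """Benign-high ROC AUC; equals the normalized Mann-Whitney U statistic."""
    y = _benign_indicator(labels)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("AUC undefined on a single-class set")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    return float(roc_auc_score(y, s))


def bootstrap_balanced_auc(
    df: pd.DataFrame,
    score_col: str,
    n_resamples: int = 50,
    resample_size: int = 6000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of AUC over label-balanced bootstrap resamples.

    Each resample draws ``resample_size/2`` variants per class with
    replacement, mirroring the balanced-resampling evaluation protocol.
    """
    rng = np.random.default_rng(seed)
    y = _benign_indicator(df["label"])
    s = df[score_col].to_numpy(dtype=float)
    idx_b, idx_p = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if idx_b.size == 0 or idx_p.size == 0:
        raise ValueError("both classes required")
    half = resample_size // 2
    aucs = np.empty(n_resamples)
    for i in range(n_resamples):
        bi = rng.choice(idx_b, size=half, replace=True)
        pi = rng.choice(idx_p, size=half, replace=True)
        sel = np.concatenate([bi, pi])
        aucs[i] = roc_auc_score(y[sel], s[sel])
    return float(aucs.mean()), float(aucs.std())


def per_gene_auc(
    df: pd.DataFrame, score_col: str, min_variants: int = 10
) -> tuple[pd.Series, float]:
    """Per-gene AUC for genes with >= ``min_variants`` labeled variants.

    Single-class genes are excluded (their AUC is undefined). Returns the
    per-gene Series and its mean.
    """
    out = {}
    for gene, sub in df.groupby("gene"):
        if len(sub) < min_variants:
            continue
        if sub["label"].nunique() < 2:
            continue
        out[gene] = auc(sub[score_col], sub["label"])
    series = pd.Series(out, dtype=float)
    if series.empty:
        raise ValueError("no gene qualifies for per-gene AUC")
    return series, float(series.mean())


def balance_per_gene(df: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Subsample the majority class per gene to the minority count.

    Genes missing a class drop out entirely; each retained gene contributes
    exactly ``2 * min(n_pathogenic, n_benign)`` variants.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _, sub in df.groupby("gene"):
        n_p = int((sub["label"] == PATHOGENIC).sum())
        n_b = int((sub["label"] == BENIGN).sum())
        k = min(n_p, n_b)
        if k == 0:
            continue
        for lab in (PATHOGENIC, BENIGN):
            pool = sub[sub["label"] == lab]
            parts.append(
                pool if len(pool) == k else pool.sample(n=k, random_state=rng.integers(2**31))
            )
    if not parts:
        raise ValueError("no gene has both classes")
    return pd.concat(parts).sort_index()


def calibrate_scores(
    df: pd.DataFrame,
    score_col: str,
    n_calibration: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Logistic calibration of raw scores to probabilities of being benign.

    Fits a one-dimensional logistic regression on a class-balanced random
    calibration subset (``n_calibration`` variants, half per class, drawn
    without replacement up to class size), then maps every score through the
    fitted monotone sigmoid. 0.5 is the induced classification threshold.
    """
    rng = np.random.default_rng(seed)
    y = _benign_indicator(df["label"])
    s = df[score_col].to_numpy(dtype=float)
    idx_b, idx_p = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if idx_b.size == 0 or idx_p.size == 0:
        raise ValueError("calibration needs both classes")
    half = n_calibration // 2
    bi = rng.choice(idx_b, size=min(half, idx_b.size), replace=False)
    pi = rng.choice(idx_p, size=min(half, idx_p.size), replace=False)
    sel = np.concatenate([bi, pi])
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(s[sel, None], y[sel])
    if lr.coef_[0, 0] < 0:
        warnings.warn("calibration slope is negative; raw scores are not benign-high")
    prob = lr.predict_proba(s[:, None])[:, 1]
    return pd.Series(prob, index=df.index, name="calibrated")


def _balanced_accuracy(y_benign: np.ndarray, pred_benign: np.ndarray) -> float:
    accs = []
    for cls in (0, 1):
        sel = y_benign == cls
        if sel.any():
            accs.append(float(np.mean(pred_benign[sel] == cls)))
    return float(np.mean(accs))


def accuracy_coverage_curve(
    df: pd.DataFrame,
    score_col: str,
    thresholds: Sequence[float] = tuple(np.linspace(0.0, 0.45, 10)),
    repeats: int = 10,
    n_calibration: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced accuracy versus coverage under symmetric threshold widening.

    Per calibration resample and exclusion half-width t, variants with
    calibrated score inside (0.5 - t, 0.5 + t) are excluded; accuracy is the
    mean of the two per-class accuracies on the rest. Returns per-threshold
    mean/sd of coverage and accuracy over ``repeats`` calibration resamples.
    """
    rng = np.random.default_rng(seed)
    y = _benign_indicator(df["label"])
    recs: dict[float, list[tuple[float, float]]] = {t: [] for t in thresholds}
    for _ in range(repeats):
        cal = calibrate_scores(
            df, score_col, n_calibration=n_calibration, seed=int(rng.integers(2**31))
        ).to_numpy()
        for t in thresholds:
            keep = (cal <= 0.5 - t) | (cal >= 0.5 + t)
            cov = float(keep.mean())
            if keep.any() and y[keep].min() != y[keep].max():
                acc = _balanced_accuracy(y[keep], (cal[keep] >= 0.5).astype(int))
            else:
                acc = np.nan
            recs[t].append((cov, acc))
    rows = []
    for t, pairs in recs.items():
        cov = np.array([c for c, _ in pairs])
        acc = np.array([a for _, a in pairs])
        rows.append(
            (t, cov.mean(), 2 * cov.std(), np.nanmean(acc), 2 * np.nanstd(acc))
        )
    return pd.DataFrame(
        rows, columns=["threshold", "coverage", "coverage_2sd", "accuracy", "accuracy_2sd"]
    )


def binary_metrics(
    labels: Iterable, calibrated: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Confusion-table metrics at a probability threshold.

    Pathogenic is the positive class; a variant is called pathogenic when its
    calibrated probability-of-benign falls below ``threshold``. The
    diagnostic odds ratio applies a +0.5 continuity correction to all cells
    only when any cell is zero.
    """
    y_benign = _benign_indicator(labels)
    c = np.asarray(calibrated, dtype=float)
    pred_path = c < threshold
    is_path = y_benign == 0
    tp = int(np.sum(pred_path & is_path))
    fp = int(np.sum(pred_path & ~is_path))
    fn = int(np.sum(~pred_path & is_path))
    tn = int(np.sum(~pred_path & ~is_path))
    n = tp + fp + fn + tn
    accuracy = (tp + tn) / n
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    denom = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn - fp * fn) / denom) if denom > 0 else 0.0
    cells = (tp, fp, fn, tn)
    if 0 in cells:
        tp_, fp_, fn_, tn_ = (x + 0.5 for x in cells)
    else:
        tp_, fp_, fn_, tn_ = cells
    dor = (tp_ * tn_) / (fp_ * fn_)
    # score-based metrics use probability-of-pathogenic orientation
    roc = roc_auc_score(is_path.astype(int), 1 - c)
    auprc = average_precision_score(is_path.astype(int), 1 - c)
    return {
        "auc": float(roc),
        "auprc": float(auprc),
        "accuracy": float(accuracy),
        "dor": float(dor),
        "mcc": float(mcc),
        "f1": float(f1),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def apply_wt_transform(measurements: Sequence[float], wt_value: float) -> np.ndarray:
    """Absolute deviation from the wild-type measurement: x -> abs(x - WT)."""
    if wt_value not in (0, 1):
        raise ValueError("wild-type convention must be 0 or 1")
    return np.abs(np.asarray(measurements, dtype=float) - wt_value)


def dms_spearman(
    assays: pd.DataFrame,
    prediction_col: str = "prediction",
    measurement_col: str = "measurement",
    transform_assays: set[str] | None = None,
    wt_values: dict[str, float] | None = None,
    group_col: str | None = None,
) -> tuple[pd.Series, float]:
    """Per-assay Spearman correlation and its aggregate.

    ``transform_assays`` names assays whose measurements first get the
    abs(x - WT) transform (applied exactly once; the transformed quantity is
    damage, so its correlation sign is flipped back to the fitness
    orientation). Ties use average ranks. Constant measurement vectors are
    skipped with a warning. The aggregate is the unweighted mean per assay,
    or a mean of per-group means when ``group_col`` is given (grouping hook,
    e.g. per protein).
    """
    transform_assays = transform_assays or set()
    wt_values = wt_values or {}
    rows = {}
    groups = {}
    for aid, sub in assays.groupby("assay_id"):
        m = sub[measurement_col].to_numpy(dtype=float)
        pred = sub[prediction_col].to_numpy(dtype=float)
        if aid in transform_assays:
            m = -apply_wt_transform(m, wt_values.get(aid, 1))
        if len(sub) < 2 or np.all(m == m[0]) or np.all(pred == pred[0]):
            warnings.warn(f"assay {aid}: constant vector, skipped")
            continue
        rho = spearmanr(pred, m).statistic
        rows[aid] = float(rho)
        if group_col is not None:
            groups[aid] = sub[group_col].iloc[0]
    series = pd.Series(rows, dtype=float)
    if series.empty:
        raise ValueError("no assay could be scored")
    if group_col is None:
        aggregate = float(series.mean())
    else:
        aggregate = float(series.groupby(pd.Series(groups)).mean().mean())
    return series, aggregate


def rank_scores(per_model_aggregate: pd.Series) -> pd.Series:
    """Ascending ranks 1..M of per-model aggregates (average ranks on ties)."""
    return pd.Series(
        rankdata(per_model_aggregate.to_numpy()),
        index=per_model_aggregate.index,
    )


def win_rate_matrix(per_assay_rho: pd.DataFrame) -> pd.DataFrame:
    """Pairwise win rates over assays (rows/cols = models).

    ``win_rate[m1, m2]`` is the fraction of assays where m1's correlation
    strictly exceeds m2's; ties credit neither model, and the diagonal is 0.
    """
    models = list(per_assay_rho.columns)
    vals = per_assay_rho.to_numpy(dtype=float)
    n = vals.shape[0]
    out = np.zeros((len(models), len(models)))
    for i in range(len(models)):
        for j in range(len(models)):
            if i != j:
                out[i, j] = np.sum(vals[:, i] > vals[:, j]) / n
    return pd.DataFrame(out, index=models, columns=models)


def maf(af) -> np.ndarray | float:
    """Minor allele frequency, min(AF, 1-AF); missing AF maps to 0."""
    a = np.asarray(af, dtype=float)
    out = np.where(np.isnan(a), 0.0, np.minimum(a, 1.0 - a))
    return float(out) if out.ndim == 0 else out


def maf_stratified_auc(
    df: pd.DataFrame,
    score_col: str,
    thresholds: Sequence[float],
    n_resamples: int = 50,
    resample_size: int = 6000,
    seed: int = 0,
) -> pd.DataFrame:
    """Balanced bootstrap AUC restricted to variants with MAF below each threshold."""
    m = maf(df["af"] if "af" in df else np.full(len(df), np.nan))
    rows = []
    rng = np.random.default_rng(seed)
    for t in thresholds:
        sub = df[m < t]
        mean, sd = bootstrap_balanced_auc(
            sub, score_col, n_resamples, resample_size, seed=int(rng.integers(2**31))
        )
        rows.append((t, len(sub), mean, sd))
    return pd.DataFrame(rows, columns=["maf_threshold", "n_variants", "auc_mean", "auc_sd"])
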