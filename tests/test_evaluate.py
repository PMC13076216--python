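"""Tests for the clinical and DMS benchmark statistics."""

import numpy as np
import pandas as pd
import pytest

from minvep import (
    accuracy_coverage_curve,
    apply_wt_transform,
    auc,
    balance_per_gene,
    binary_metrics,
    bootstrap_balanced_auc,
    calibrate_scores,
    dms_spearman,
    maf,
    maf_stratified_auc,
    per_gene_auc,
    rank_scores,
    win_rate_matrix,
)


def _pairwise_auc_oracle(scores, labels):
    """O(n^2) pairwise comparison: P(benign > pathogenic) + half ties."""
    b = [s for s, l in zip(scores, labels) if l == "benign"]
    p = [s for s, l in zip(scores, labels) if l == "pathogenic"]
    total = 0.0
    for x in b:
        for y in p:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(b) * len(p))


def _random_set(rng, n, n_genes=5, ties=False):
    labels = rng.choice(["pathogenic", "benign"], size=n)
    while len(set(labels)) < 2:
        labels = rng.choice(["pathogenic", "benign"], size=n)
    scores = rng.normal(size=n) + (labels == "benign") * rng.uniform(0, 2)
    if ties:
        scores = np.round(scores, 1)
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(n)],
            "gene": rng.choice([f"g{j}" for j in range(n_genes)], size=n),
            "label": labels,
            "score": scores,
            "af": np.where(rng.random(n) < 0.2, np.nan, rng.uniform(0, 1, n)),
        }
    )


@pytest.mark.parametrize("ties", [False, True])
def test_auc_matches_pairwise_oracle(ties):
    rng = np.random.default_rng(0)
    for _ in range(25):
        df = _random_set(rng, int(rng.integers(5, 60)), ties=ties)
        assert auc(df["score"], df["label"]) == pytest.approx(
            _pairwise_auc_oracle(df["score"].tolist(), df["label"].tolist()),
            abs=1e-12,
        )


def test_auc_edge_cases():
    assert auc([1, 2, 3, 10, 11, 12], ["pathogenic"] * 3 + ["benign"] * 3) == 1.0
    with pytest.raises(ValueError, match="single-class"):
        auc([1, 2], ["benign", "benign"])
    with pytest.raises(ValueError):
        auc([1, 2], ["benign", "weird"])


def test_bootstrap_balanced_auc():
    rng = np.random.default_rng(1)
    df = _random_set(rng, 400)
    m1, s1 = bootstrap_balanced_auc(df, "score", n_resamples=20, resample_size=100, seed=5)
    m2, s2 = bootstrap_balanced_auc(df, "score", n_resamples=20, resample_size=100, seed=5)
    assert (m1, s1) == (m2, s2)
    perfect = pd.DataFrame(
        {"label": ["pathogenic"] * 50 + ["benign"] * 50, "score": [0] * 50 + [1] * 50}
    )
    mp, sp = bootstrap_balanced_auc(perfect, "score", n_resamples=10, resample_size=40, seed=0)
    assert mp == 1.0 and sp == 0.0
    _, sd_small = bootstrap_balanced_auc(df, "score", 30, resample_size=40, seed=2)
    _, sd_big = bootstrap_balanced_auc(df, "score", 30, resample_size=400, seed=2)
    assert sd_big < sd_small


def test_per_gene_auc_matches_loop_oracle():
    rng = np.random.default_rng(2)
    df = _random_set(rng, 600, n_genes=20)
    series, mean = per_gene_auc(df, "score", min_variants=10)
    for gene, val in series.items():
        sub = df[df["gene"] == gene]
        assert len(sub) >= 10 and sub["label"].nunique() == 2
        assert val == pytest.approx(
            _pairwise_auc_oracle(sub["score"].tolist(), sub["label"].tolist())
        )
    assert mean == pytest.approx(series.mean())
    strict, _ = per_gene_auc(df, "score", min_variants=25)
    assert len(strict) <= len(series)
    one_gene = df[df["gene"] == series.index[0]]
    s1, m1 = per_gene_auc(one_gene, "score", min_variants=1)
    assert m1 == pytest.approx(s1.iloc[0])


def test_balance_per_gene_counts():
    rng = np.random.default_rng(3)
    df = _random_set(rng, 500, n_genes=12)
    bal = balance_per_gene(df, seed=0)
    expected_total = 0
    for gene, sub in df.groupby("gene"):
        n_p = (sub["label"] == "pathogenic").sum()
        n_b = (sub["label"] == "benign").sum()
        expected_total += 2 * min(n_p, n_b)
        bsub = bal[bal["gene"] == gene]
        if min(n_p, n_b) == 0:
            assert bsub.empty
        else:
            assert (bsub["label"] == "pathogenic").sum() == min(n_p, n_b)
            assert (bsub["label"] == "benign").sum() == min(n_p, n_b)
    assert len(bal) == expected_total
    already = bal.copy()
    assert len(balance_per_gene(already, seed=1)) == len(already)


def test_calibration_monotone_and_oriented():
    rng = np.random.default_rng(4)
    df = _random_set(rng, 500)
    cal = calibrate_scores(df, "score", n_calibration=200, seed=6)
    assert auc(cal, df["label"]) == pytest.approx(auc(df["score"], df["label"]))
    # well-separated set: pathogenic mean below 0.5, benign above
    sep = pd.DataFrame(
        {
            "label": ["pathogenic"] * 100 + ["benign"] * 100,
            "score": np.r_[np.random.default_rng(1).normal(-5, 1, 100),
                           np.random.default_rng(2).normal(5, 1, 100)],
        }
    )
    c = calibrate_scores(sep, "score", n_calibration=100, seed=0)
    assert c[sep["label"] == "pathogenic"].mean() < 0.5
    assert c[sep["label"] == "benign"].mean() > 0.5
    c2 = calibrate_scores(df, "score", n_calibration=200, seed=6)
    assert cal.equals(c2)
    with pytest.raises(ValueError):
        calibrate_scores(sep[sep["label"] == "benign"], "score")


def test_accuracy_coverage_curve_properties():
    sep = pd.DataFrame(
        {
            "label": ["pathogenic"] * 80 + ["benign"] * 80,
            "score": np.r_[np.full(80, -3.0), np.full(80, 3.0)]
            + np.random.default_rng(0).normal(0, 0.1, 160),
        }
    )
    curve = accuracy_coverage_curve(sep, "score", thresholds=[0.0, 0.2, 0.4],
                                    repeats=3, n_calibration=80, seed=0)
    assert curve.loc[0, "coverage"] == 1.0
    assert np.all(np.diff(curve["coverage"]) <= 1e-12)
    assert np.allclose(curve["accuracy"], 1.0)


def test_binary_metrics_hand_arithmetic():
    # confusion table TP=40 FP=10 FN=10 TN=40 built explicitly
    labels = (
        ["pathogenic"] * 40 + ["benign"] * 10 + ["pathogenic"] * 10 + ["benign"] * 40
    )
    calibrated = [0.2] * 50 + [0.8] * 50  # first 50 called pathogenic
    m = binary_metrics(labels, calibrated)
    assert m["tp"] == 40 and m["fp"] == 10 and m["fn"] == 10 and m["tn"] == 40
    assert m["accuracy"] == pytest.approx(0.8)
    assert m["f1"] == pytest.approx(0.8)
    assert m["mcc"] == pytest.approx(0.6)
    assert m["dor"] == pytest.approx(16.0)


def test_binary_metrics_perfect_and_sign_symmetry():
    labels = ["pathogenic"] * 30 + ["benign"] * 30
    cal = [0.1] * 30 + [0.9] * 30
    m = binary_metrics(labels, cal)
    assert m["accuracy"] == 1.0 and m["mcc"] == 1.0
    assert np.isfinite(m["dor"])  # continuity correction on zero cells
    flipped = binary_metrics(labels[::-1], cal)
    assert flipped["mcc"] == pytest.approx(-m["mcc"])


def test_wt_transform():
    assert apply_wt_transform([1.4], 1) == pytest.approx([0.4])
    assert apply_wt_transform([-0.3], 0) == pytest.approx([0.3])
    with pytest.raises(ValueError):
        apply_wt_transform([1.0], 0.5)


def test_dms_spearman_against_rank_oracle():
    from scipy.stats import rankdata

    rng = np.random.default_rng(5)
    frames = []
    for i in range(10):
        n = int(rng.integers(10, 40))
        m = rng.normal(size=n)
        pred = 0.6 * m + rng.normal(0, 0.5, n)
        frames.append(pd.DataFrame(
            {"assay_id": f"a{i}", "measurement": m, "prediction": pred}
        ))
    df = pd.concat(frames, ignore_index=True)
    rho, agg = dms_spearman(df)
    for aid, val in rho.items():
        sub = df[df["assay_id"] == aid]
        rm, rp = rankdata(sub["measurement"]), rankdata(sub["prediction"])
        oracle = np.corrcoef(rm, rp)[0, 1]
        assert val == pytest.approx(oracle, abs=1e-12)
    assert agg == pytest.approx(rho.mean())


def test_dms_spearman_edges():
    perfect = pd.DataFrame(
        {"assay_id": "a", "measurement": [1.0, 2, 3, 4], "prediction": [1.0, 2, 3, 4]}
    )
    rho, _ = dms_spearman(perfect)
    assert rho["a"] == 1.0
    anti = perfect.assign(prediction=[4.0, 3, 2, 1])
    rho2, _ = dms_spearman(anti)
    assert rho2["a"] == -1.0
    const = pd.DataFrame(
        {"assay_id": ["c"] * 3 + ["a"] * 3,
         "measurement": [1.0, 1, 1, 1, 2, 3],
         "prediction": [1.0, 2, 3, 1, 2, 3]}
    )
    with pytest.warns(UserWarning, match="constant"):
        rho3, _ = dms_spearman(const)
    assert list(rho3.index) == ["a"]


def test_win_rate_matrix_oracle_and_properties():
    rng = np.random.default_rng(6)
    table = pd.DataFrame(rng.normal(size=(20, 3)), columns=["m1", "m2", "m3"])
    table.iloc[0, 1] = table.iloc[0, 0]  # inject one tie
    w = win_rate_matrix(table)
    for a in table.columns:
        for b in table.columns:
            if a == b:
                assert w.loc[a, b] == 0.0
            else:
                oracle = np.mean([
                    1.0 if x > y else 0.0
                    for x, y in zip(table[a], table[b])
                ])
                assert w.loc[a, b] == pytest.approx(oracle)
                ties = np.mean(table[a] == table[b])
                assert w.loc[a, b] + w.loc[b, a] == pytest.approx(1 - ties)
    dominant = pd.DataFrame({"m1": [1.0, 2, 3], "m2": [0.0, 1, 2]})
    wd = win_rate_matrix(dominant)
    assert wd.loc["m1", "m2"] == 1.0 and wd.loc["m2", "m1"] == 0.0
    same = pd.DataFrame({"m1": [1.0, 2], "m2": [1.0, 2]})
    ws = win_rate_matrix(same)
    assert ws.loc["m1", "m2"] == 0.0 and ws.loc["m2", "m1"] == 0.0


def test_rank_scores():
    s = pd.Series({"a": 0.3, "b": 0.5, "c": 0.4, "d": 0.5})
    r = rank_scores(s)
    assert r["a"] == 1.0 and r["c"] == 2.0 and r["b"] == r["d"] == 3.5


def test_maf_formula_and_missing():
    assert maf(0.3) == pytest.approx(0.3)
    assert maf(0.9) == pytest.approx(0.1)
    assert maf(np.nan) == 0.0
    assert np.allclose(maf(np.array([0.2, 0.8, np.nan])), [0.2, 0.2, 0.0])


def test_maf_stratified_auc_monotone_counts():
    rng = np.random.default_rng(7)
    df = _random_set(rng, 300)
    res = maf_stratified_auc(df, "score", thresholds=[0.01, 0.1, 0.5],
                             n_resamples=5, resample_size=50, seed=0)
    assert np.all(np.diff(res["n_variants"]) >= 0)
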