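"""Reusable synthetic benchmarks and the end-to-end demo pipeline.

The blind-spot benchmark is the study condition the toolkit is tested under:
a two-domain family, two profile scorers with complementary blind spots
(each misses one domain), and a labeled variant set whose pathogenic
variants sit at sensitive positions. Minimum aggregation should detect both
domains where each base scorer misses one; co-distillation should transfer
that union of knowledge back into each student.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import ScoreStack, aggregate_mean, aggregate_min
from .distill import RoundSchedule, TableStudent, TrainConfig, run_schedule
from .evaluate import auc, dms_spearman
from .scoring import LLRMatrix, score_protein, score_variant_table
from .synth import (
    DomainSpec,
    generate_dms_assays,
    generate_family,
    generate_labeled_variants,
    make_blindspot_scorers,
)
from .theory import regime_map

__all__ = ["blindspot_benchmark", "codistill_benchmark", "run_demo"]

# Default study conditions of the two-domain complementarity benchmark:
# a toy family (15 sequences, length 90) with two strongly conserved domains,
# two profile scorers each blind to one domain, 40 labeled variants/protein.
DEFAULT_DOMAINS = (
    DomainSpec("domA", 11, 30, conservation=0.95),
    DomainSpec("domB", 56, 75, conservation=0.95),
)


def blindspot_benchmark(
    seed: int = 0,
    n_proteins: int = 15,
    length: int = 90,
    domains: Sequence[DomainSpec] = DEFAULT_DOMAINS,
    n_variants_per_protein: int = 40,
    label_noise: float = 0.05,
) -> dict:
    """Build the two-domain / two-scorer complementarity benchmark.

    Returns proteins, ground truth, the two blind-spot scorers, per-scorer
    LLR matrices, a labeled variant table with per-scorer plus min/mean
    aggregate scores, and the corresponding AUCs.
    """
    proteins, truth = generate_family(n_proteins, length, list(domains), seed=seed)
    names = [d.name for d in domains]
    scorers = make_blindspot_scorers(
        proteins, truth, visibility=[{names[0]}, {names[1]}], seed=seed
    )
    matrices: dict[str, dict[str, LLRMatrix]] = {
        s.name: {p.id: score_protein(s, p) for p in proteins} for s in scorers
    }
    stacks = {
        p.id: ScoreStack(
            p.id,
            [s.name for s in scorers],
            [matrices[s.name][p.id] for s in scorers],
        )
        for p in proteins
    }
    min_mats = {pid: aggregate_min(st).matrix for pid, st in stacks.items()}
    mean_mats = {pid: aggregate_mean(st).matrix for pid, st in stacks.items()}
    variants = generate_labeled_variants(
        proteins, truth, n_per_protein=n_variants_per_protein,
        label_noise=label_noise, seed=seed + 1,
    )
    for s in scorers:
        variants[s.name] = score_variant_table(variants, matrices[s.name])
    variants["min_agg"] = score_variant_table(variants, min_mats)
    variants["mean_agg"] = score_variant_table(variants, mean_mats)
    aucs = {
        col: auc(variants[col], variants["label"])
        for col in [s.name for s in scorers] + ["min_agg", "mean_agg"]
    }
    return {
        "proteins": proteins,
        "truth": truth,
        "scorers": scorers,
        "matrices": matrices,
        "min_matrices": min_mats,
        "variants": variants,
        "aucs": aucs,
    }


def codistill_benchmark(
    seed: int = 0,
    schedule: Sequence[str] = ("min",),
    epochs: int = 5,
    **bench_kwargs,
) -> dict:
    """Co-distill table students initialized from the blind-spot base scorers.

    Students start as exact copies of the base scorers' LLR grids and are
    trained through the given aggregator schedule; per-round AUCs for each
    student are recorded by the evaluation hook.
    """
    bench = blindspot_benchmark(seed=seed, **bench_kwargs)
    proteins, variants = bench["proteins"], bench["variants"]
    students = [
        TableStudent(proteins, init=bench["matrices"][s.name], name=s.name)
        for s in bench["scorers"]
    ]

    def eval_fn(studs):
        out = {}
        for st in studs:
            mats = {p.id: st.score(p) for p in proteins}
            out[st.name] = auc(score_variant_table(variants, mats), variants["label"])
        return out

    history = run_schedule(
        students,
        proteins,
        RoundSchedule(tuple(schedule)),
        TrainConfig(epochs=epochs, seed=seed),
        eval_fn=eval_fn,
    )
    return {"benchmark": bench, "students": students, "history": history}


def run_demo(seed: int = 0) -> dict:
    """End-to-end toy pipeline exercising every stage; returns the report.

    Stages: synthetic fixtures -> blind-spot scorers -> min aggregation ->
    one min + one avg co-distillation round -> clinical AUC and DMS Spearman
    evaluation -> theory regime map -> association benchmark.
    """
    from .assoc import (
        association_strength,
        direction_concordance,
        filter_benchmark_pairs,
        regress_pairs,
    )
    from .synth import generate_summary_stats, severity_from_sensitivity

    report: dict = {"seed": seed}
    cd = codistill_benchmark(seed=seed, schedule=("min", "avg"))
    bench = cd["benchmark"]
    report["base_aucs"] = {k: v for k, v in bench["aucs"].items()}
    report["round_history"] = [
        {"aggregator": h["aggregator"], "pre": h["pre"], "post": h["post"]}
        for h in cd["history"]
    ]

    # DMS evaluation of the min aggregate on one normal and one inverted assay
    proteins, truth = bench["proteins"], bench["truth"]
    p0 = proteins[0]
    assay = generate_dms_assays(p0, truth, seed=seed, assay_id="assay_plain")
    assay_inv = generate_dms_assays(
        p0, truth, seed=seed + 1, inverted=True, assay_id="assay_inverted"
    )
    dms = pd.concat([assay, assay_inv], ignore_index=True)
    dms["prediction"] = score_variant_table(
        dms.rename(columns={"protein_id": "protein_id"}), bench["min_matrices"]
    )
    rho, agg = dms_spearman(
        dms,
        transform_assays={"assay_inverted"},
        wt_values={"assay_inverted": 1},
    )
    report["dms_spearman"] = {"per_assay": rho.to_dict(), "aggregate": agg}

    grid = regime_map(
        separations=np.array([0.5, 1.0, 2.0]),
        sigma_ratios=np.array([1.0, 4.0]),
        n_models=10,
    )
    report["regime_map"] = grid.to_dict(orient="records")

    rng = np.random.default_rng(seed + 7)
    sens = truth.sensitivity
    # per-position severity with residue-level jitter so severities vary
    genes = [
        (f"G{i}", severity_from_sensitivity(sens) * rng.uniform(0.5, 1.0, sens.size))
        for i in range(6)
    ]
    stats = generate_summary_stats(
        genes, ["phenoA", "phenoB"], gamma=0.5, se=0.2, seed=seed
    )
    # regression consumes a damaging-high severity prediction (negated LLR scale)
    stats["score"] = stats["severity"]
    kept = filter_benchmark_pairs(stats, min_missense=25, gene_p_threshold=1.0)
    pairs = regress_pairs(kept)
    report["association"] = {
        "n_pairs": len(pairs),
        "mean_neglog10_p": association_strength(pairs),
        "direction_concordance": direction_concordance(pairs),
    }
    return report
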