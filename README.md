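# minvep

Maximum-confidence ensemble aggregation and co-distillation for protein
variant-effect prediction (VEP), as a desk-scale, model-agnostic toolkit.

## The problem

Protein language models score a missense variant by the log-likelihood ratio

```
LLR(t, alt) = log p(x_t = alt | x) − log p(x_t = wt | x)
```

computed from a single forward pass on the wild-type sequence (the
WT-marginal scheme). Negative LLRs mean the model considers the wild-type
residue conserved and the substitution damaging; the wild-type entry is 0.
Individual models have *blind spots*: whole conserved domains that one model
flags as mutationally sensitive and another scores as neutral. Averaging an
ensemble dilutes a signal that only a minority of models sees. The
**maximum-confidence** alternative aggregates per variant by the elementwise
**minimum** LLR — the prediction of the model most confident in the
wild-type residue:

```
agg(v) = min_s LLR(v | G_s)        (s = 1..N scorers)
```

The toolkit implements, end to end on synthetic data:

- **LLR scoring** from any scorer exposing per-position amino-acid
  log-probabilities, with sliding-window segmentation (1,022-residue
  windows, 511 overlap) and stitching for long proteins;
- **min / mean aggregation** with argmin bookkeeping, per-model contribution
  fractions, percentile filtering of uninformative segments, and mean-shift
  alignment of aggregate targets onto each model's score scale;
- **the Gaussian theory**: with class-conditional i.i.d. Gaussian scores,
  closed-form AUC for averaging, `Φ((μ_b − μ_p) / √((σ_p² + σ_b²)/N))`, and
  an order-statistic quadrature AUC for the minimum, mapping the regimes
  where each aggregator wins (minimum wins when pathogenic scores are much
  more dispersed than benign ones);
- **co-distillation**: every student regresses (MSE) onto the fixed,
  precomputed, mean-shifted aggregate of all students' predictions, over
  multi-round schedules such as min–avg; plus teacher→student **knowledge
  distillation**;
- **the evaluation suite**: Mann–Whitney AUC, balanced bootstrap AUC,
  per-gene AUC with per-gene class balancing, logistic score calibration,
  accuracy–coverage curves, confusion-table metrics (accuracy, F1, MCC,
  DOR, AUPRC), DMS Spearman with the abs(x − WT) transform, win-rate
  matrices, rank scores, and MAF-stratified AUC (MAF = min(AF, 1−AF),
  missing AF → 0);
- **summary-statistic association**: per gene–phenotype pair, Pearson
  regression of variant scores against effect sizes (β), benchmark filters
  (≥25 missense variants, gene-level p, single-variant p < 0.05), mean
  −log10(p) association strength, and pLoF direction concordance;
- **synthetic data generators** for all of the above: protein families with
  conserved domains, complementary blind-spot profile scorers, labeled
  variant sets, DMS-style assays, and rare-variant summary statistics.

## Worked example

```python
from minvep.pipeline import blindspot_benchmark
bench = blindspot_benchmark(seed=0)
print(bench["aucs"])
```

prints

```
{'scorer0': 0.607, 'scorer1': 0.554, 'min_agg': 0.927, 'mean_agg': 0.787}
```

Two profile scorers are each blind to one of two conserved domains, so each
classifies the labeled variants barely better than chance (AUC 0.55–0.61)
and plain averaging only reaches 0.79. The elementwise minimum recovers
both domains and reaches AUC 0.93. One maximum-confidence co-distillation
round then transfers that union of knowledge into each student:

```python
from minvep.pipeline import codistill_benchmark
cd = codistill_benchmark(seed=0, schedule=("min", "avg"))
# round 0 (min): mean student AUC 0.580 -> 0.927
# round 1 (avg): mean student AUC 0.927 -> 0.927
```

The `examples/` directory has one short script per capability (scoring,
aggregation, theory, co-distillation, clinical metrics, DMS + association),
each printing the numbers it computes and what they mean. A thin CLI wraps
the same functions: `minvep score|aggregate|theory|simulate|codistill|
distill|evaluate-clinical|evaluate-dms|assoc|demo` (see `minvep --help`).

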