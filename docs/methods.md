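# Methods

## Scoring model

A scorer is any object exposing `position_log_probs(sequence) -> (L, 20)`
natural-log probabilities over the fixed alphabet `ACDEFGHIKLMNPQRSTVWY`.
Scoring follows the wild-type-marginal scheme: one pass on the unmutated
sequence yields all 19×L substitution scores,
`LLR(t, α) = log p(x_t = α | x) − log p(x_t = wt_t | x)`, benign-high, with
the wild-type entry exactly 0. Natural-log base is used throughout.
Validation requires each row to log-sum-exp to 0 within 1e-6; entries are
then floored at `ln(1e-12)` so degenerate one-hot scorers produce large
finite penalties instead of −∞. Sequences may contain nonstandard letters
(X, U, B, Z, …): those rows are masked and logged rather than failing the
protein, and masked entries are excluded from every downstream mean, loss
and statistic. Positions are 1-based inclusive in all public interfaces;
storage is 0-based numpy.

Proteins longer than the window (default 1,022 residues, matching the
context limit of typical protein language models) are segmented into
overlapping windows (default overlap 511) with the last window anchored to
end at L. Stitching assigns each position the scores of the window in which
it is most central, ties to the earlier window. This centrality rule is one
of several defensible overlap-combination conventions for windowed scoring;
for proteins no longer than one window it is bit-identical to direct
scoring, which is tested.

## Aggregation

Maximum-confidence aggregation takes the elementwise minimum over unmasked
models — per variant, the prediction of the model most confident in the
wild-type residue — recording argmin indices (ties to the lowest model
index). Mean aggregation is the arithmetic mean over unmasked models.
Wild-type columns ride through aggregation at 0 but are excluded from
contribution fractions, means and filtering statistics.

Segment filtering drops uninformative segments: the per-segment statistic
is the minimum aggregated score over variant positions *excluding position
1* (the initiator methionine, whose substitutions score artifactually low),
and segments above the 95th percentile of that distribution are removed.
Percentiles use numpy's linear-interpolation convention, stated here
because conventions differ.

Mean-shift alignment adds a single constant to an aggregate target grid so
its mean over non-wild-type unmasked entries matches a base model's score
mean; the constant is computed once and held fixed. The shift is applied to
non-wild-type entries only, preserving the wild-type-zero invariant (those
entries are excluded from the training loss regardless).

## Gaussian aggregation theory

Conditional on the true class, the N scorers' LLRs are modeled i.i.d.
Gaussian: pathogenic ~ N(μ_p, σ_p²), benign ~ N(μ_b, σ_b²), μ_p ≤ μ_b.
Orientation: AUC = P(benign-scored > pathogenic-scored) with half credit
for ties. Averaging has the closed form
AUC = Φ((μ_b − μ_p)/√((σ_p² + σ_b²)/N)). The minimum aggregator's AUC,
P(min of N benign draws > min of N pathogenic draws), is evaluated by
adaptive quadrature of the order-statistic density
f_min(x) = N φ((x−μ)/σ)/σ · (1 − Φ((x−μ)/σ))^(N−1) against the benign
minimum's survival function, over a ±10-sd support window with absolute/
relative tolerance 1e-8; a Monte-Carlo simulator is the independent oracle.
Two quantities govern the regimes: the separation of the class means and
the ratio σ_p/σ_b. At equal sds averaging is never beaten beyond tie
tolerance (it gains the full √N variance reduction); when pathogenic scores
are several-fold more dispersed — the signature of complementary blind
spots, where each variant is caught by only a few models — the minimum wins
decisively. Correlated scorers and non-Gaussian class conditionals are out
of scope; the i.i.d. case is the analyzed model.

## Co-distillation

One round: all students score all proteins; the grids are aggregated (min
or mean); the aggregate is mean-shifted once per student onto that
student's own score scale and then **frozen**; each student is trained
independently with MSE against its shifted target (masked and wild-type
entries excluded). This precomputed-target simplification replaces the
online mutual-learning iteration by default; targets are bit-identical
before and after any student update within a round, which is asserted. An
``online=True`` mode re-aggregates the students' current scores before
every epoch (true mutual learning, shifts anchored at the round start); it
is provided for comparison and is not part of the default pipeline. Schedules chain
rounds with per-round aggregators (e.g. min–avg), each round continuing
from the previous student states. Knowledge distillation is the same
machinery with a single frozen teacher providing the targets.

Students are deliberately toy scorers honoring a drop-in contract
(`score`, `fit_step`):

- **TableStudent** — free per-entry parameters per known protein. Plain
  gradient descent on the per-entry squared error contracts the residual by
  (1 − 2·lr) per step; the default lr = 0.5 is the exact minimizing step for
  this quadratic, so training converges in one step and repeated rounds
  against self-consistent targets are exact fixed points. A smaller lr gives
  the gradual traces the convergence tests exercise.
- **ContextStudent** — linear in the one-hot encoding of a (2k+1)-residue
  window plus bias, mapped to 20 logits with the wild-type logit subtracted
  (wild-type-zero by construction). Fitting runs L-BFGS with an analytic
  gradient on the masked MSE plus a tiny L2 term (1e-6); the window radius
  k is the capacity knob standing in for how much of a real model is
  unfrozen. It generalizes to unseen proteins, which is what the held-out
  knowledge-distillation check needs.

Real protein-language-model fine-tuning is out of scope; the contract is
written so a heavyweight scorer can replace either student unchanged.
Default training is 5 epochs (one `fit_step` per epoch), deterministic
given the config seed.

## Synthetic data

`generate_family` draws an aligned family column-wise: background columns
from a symmetric Dirichlet (concentration 3, high entropy), domain columns
as a mixture `c·onehot(preferred) + (1−c)·Dirichlet(1)` with conservation
c, so c = 1 makes the column invariant. Ground-truth per-position
sensitivity is c inside domains and 0.05 outside. Blind-spot scorers are
profile (position-weight-matrix) scorers with pseudocount 0.5 whose
training counts are flattened inside the domains hidden from them — the
scorer then sees those columns as unconserved and scores them near zero,
reproducing the complementary-blind-spot phenomenon and, across scorers,
the pathogenic-variance asymmetry the theory module predicts the minimum
exploits.

Labeled variants: positions sampled half from sensitive, half from
background positions; pathogenic iff sensitivity > 0.5, flipped
independently with probability `label_noise` (default 0.05 in the
benchmark); allele frequencies log-uniform, rarer for pathogenic, 15%
missing. DMS assays: variant fitness = 1 − sensitivity·U(0.5, 1), wild-type
measurement equal to the 0/1 convention, Gaussian noise sd 0.05; the
*inverted* mode moves measurements away from the wild-type value in a
random direction so only abs(x − WT) recovers the damage signal. Summary
statistics: per pair, β_v = γ_g·severity_v + N(0, se²) with severity an
affine, clipped map of sensitivity (0.1 + 0.9·s); gene-level burden β is
the severity-weighted mean; the gene-level "missense test" p is a Stouffer
combined-z **synthetic surrogate** for a SKAT-O-style statistic (the real
test is consumed only as published summary statistics); the pLoF burden β
carries γ_g's sign. Defaults mirror the study conditions the recovery tests
state: γ = 0.5, se = 0.2, 50 variants per pair.

What the generators do *not* emulate: phylogenetic correlation between
family members, indels/alignment error, linkage disequilibrium, realistic
allele-frequency spectra, correlated scorer errors, and assay-specific
noise structure. Passing tests therefore show the machinery is correct
under the assumed statistical structure, not that real-data performance is
reproduced.

## Evaluation conventions

Scores are benign-high everywhere. AUC is the normalized Mann–Whitney U
(half credit for ties), via scikit-learn, cross-checked in tests against an
O(n²) pairwise oracle. Balanced bootstrap AUC draws resample_size/2 per
class with replacement. Per-gene AUC requires ≥ 10 labeled variants and
both classes; per-gene balancing subsamples the majority class to
min(n_p, n_b). Calibration fits a 1-D logistic regression (C = 1e6, i.e.
effectively unpenalized) on a class-balanced subset of default 1,000
variants and maps scores to the **probability of being benign** — monotone
in the raw score, pathogenic < 0.5 < benign, with 0.5 the classification
threshold; the accuracy–coverage curve symmetrically excludes scores in
(0.5 − t, 0.5 + t) and reports the mean of per-class accuracies over
calibration resamples. DOR applies a +0.5 continuity correction to all
cells only when a cell is zero. DMS Spearman uses average ranks; constant
vectors are skipped with a warning; the aggregate is the unweighted
per-assay mean with an optional per-group (e.g. per-protein) weighting
hook, since published weighted schemes live in external benchmark scripts.
Win rates use strict inequality (ties credit neither side). MAF =
min(AF, 1−AF), missing AF → 0. Association regression reports Pearson r
(the standardized slope) with the two-sided product-moment p, no
multiple-testing adjustment; p is floored at 1e-300 before log10. The
log-MAF baseline comparator substitutes log10(MAF) as the score with a
1e-6 pseudo-frequency for zero/missing. The `min_missense` benchmark filter
counts a pair's *total* variant table (a pair attribute), which makes the
three filters commute.

## Numerical and design notes

- Tie-breaking: argmin by lowest model index; stitching by earlier window;
  calibration threshold at exactly 0.5 counts as benign.
- Quadrature failures (non-convergence) raise with diagnostics rather than
  returning a value.
- Problem sizes in tests and in `scripts/acceptance.py` are the package's
  chosen study conditions: families of ~15 proteins × 90 residues, 5 seeds
  for benchmark properties, 1e6-draw Monte-Carlo oracles for the theory,
  2,000 null pairs for type-I calibration, 200 replicates for sign
  recovery.
- Known limitations: the table student memorizes proteins (by design); the
  context student's capacity knob is a loose analog of partial fine-tuning;
  correlated-scorer theory is not covered.
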