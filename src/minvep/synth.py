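"""Synthetic data with the statistical structure the method assumes.

Everything the toolkit consumes can be generated here at toy scale:

* aligned protein families with conserved low-entropy domains embedded in a
  high-entropy background (Dirichlet-parameterized column distributions);
* profile scorers with *complementary blind spots* — each scorer's training
  ignores some domains, so no single scorer sees every conserved region but
  the ensemble collectively does (the phenomenon that motivates
  maximum-confidence aggregation);
* clinical-style labeled variant sets whose pathogenicity tracks a known
  per-position sensitivity ground truth;
* deep-mutational-scan style assay tables, optionally "inverted" so that an
  abs(x - WT) transform is required before measurements track fitness;
* rare-variant summary statistics with a linear severity -> effect-size map
  (beta_v = gamma * severity_v + noise), gene-level burden coefficients and a
  combined-statistic stand-in for a SKAT-O-style gene p-value (synthetic
  surrogate; real SKAT-O is consumed only as published summary statistics).

All generators are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .alphabet import AA20, N_AA
from .scoring import LLRMatrix, ProteinRecord

__all__ = [
    "DomainSpec",
    "SyntheticTruth",
    "ProfileScorer",
    "generate_family",
    "make_blindspot_scorers",
    "generate_labeled_variants",
    "generate_dms_assays",
    "severity_from_sensitivity",
    "generate_summary_stats",
]

BACKGROUND_SENSITIVITY = 0.05


@dataclass(frozen=True)
class DomainSpec:
    """A conserved domain: 1-based inclusive span plus conservation strength."""

    name: str
    start: int
    end: int
    conservation: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.conservation <= 1):
            raise ValueError("conservation must be in (0, 1]")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start - 1, self.end)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated family.

    ``sensitivity[t]`` in [0, 1] is how mutationally sensitive position t+1
    is; ``column_probs`` are the per-column amino-acid distributions the
    family was drawn from.
    """

    sensitivity: np.ndarray
    column_probs: np.ndarray  # (L, 20)
    domains: tuple[DomainSpec, ...]
    seed: int
    params: dict = field(default_factory=dict)


class ProfileScorer:
    """Position-specific profile scorer built from an aligned family.

    Scores any same-length sequence with the stored per-column
    log-probabilities (a position-weight-matrix model of the family).
    """

    def __init__(self, log_probs: np.ndarray, name: str = "profile"):
        self.log_probs = np.asarray(log_probs, dtype=float)
        self.name = name

    def position_log_probs(self, sequence: str) -> np.ndarray:
        if len(sequence) != self.log_probs.shape[0]:
            raise ValueError(
                f"scorer {self.name}: expects length {self.log_probs.shape[0]}, "
                f"got {len(sequence)}"
            )
        return self.log_probs

    @classmethod
    def from_family(
        cls,
        proteins: list[ProteinRecord],
        pseudocount: float = 0.5,
        name: str = "profile",
        randomize_columns: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> "ProfileScorer":
        """Fit column frequencies with pseudocounts.

        ``randomize_columns`` marks columns whose counts are replaced by flat
        counts — the blind-spot mechanism: the scorer never learns that those
        columns are conserved.
        """
        L = len(proteins[0])
        counts = np.full((L, N_AA), pseudocount)
        for p in proteins:
            idx = p.wt_indices
            ok = idx >= 0
            np.add.at(counts, (np.flatnonzero(ok), idx[ok]), 1.0)
        if randomize_columns is not None:
            flat = len(proteins) / N_AA + pseudocount
            counts[randomize_columns] = flat
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(np.log(probs), name=name)


def _check_domains(domains: list[DomainSpec], length: int) -> None:
    occupied = np.zeros(length, dtype=bool)
    for d in domains:
        if d.end > length:
            raise ValueError(f"domain {d.name} exceeds protein length {length}")
        if occupied[d.positions].any():
            raise ValueError(f"domain {d.name} overlaps another domain")
        occupied[d.positions] = True


def generate_family(
    n_proteins: int,
    length: int,
    domain_specs: list[DomainSpec],
    background_concentration: float = 3.0,
    seed: int = 0,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Draw an aligned family with conserved domains.

    Background columns come from a symmetric Dirichlet (high entropy); each
    domain column mixes a preferred residue with weight ``conservation`` into
    a Dirichlet draw, so conservation 1.0 makes the column invariant.
    Per-position ground-truth sensitivity equals the domain's conservation
    inside domains and a small constant outside.
    """
    _check_domains(domain_specs, length)
    rng = np.random.default_rng(seed)
    col_probs = rng.dirichlet(np.full(N_AA, background_concentration), size=length)
    sensitivity = np.full(length, BACKGROUND_SENSITIVITY)
    for d in domain_specs:
        preferred = rng.integers(N_AA, size=d.end - d.start + 1)
        for j, t in enumerate(d.positions):
            base = rng.dirichlet(np.ones(N_AA))
            onehot = np.zeros(N_AA)
            onehot[preferred[j]] = 1.0
            col_probs[t] = d.conservation * onehot + (1 - d.conservation) * base
        sensitivity[d.positions] = d.conservation
    seqs = np.array(
        [rng.choice(N_AA, size=n_proteins, p=col_probs[t]) for t in range(length)]
    ).T
    proteins = [
        ProteinRecord(f"prot{i:03d}", "".join(AA20[a] for a in row))
        for i, row in enumerate(seqs)
    ]
    truth = SyntheticTruth(
        sensitivity=sensitivity,
        column_probs=col_probs,
        domains=tuple(domain_specs),
        seed=seed,
        params=dict(
            n_proteins=n_proteins,
            length=length,
            background_concentration=background_concentration,
        ),
    )
    return proteins, truth


def make_blindspot_scorers(
    family: list[ProteinRecord],
    truth: SyntheticTruth,
    visibility: list[set[str]],
    pseudocount: float = 0.5,
    seed: int = 0,
) -> list[ProfileScorer]:
    """Build one profile scorer per visibility set.

    Scorer ``s`` sees only the domains named in ``visibility[s]``; columns of
    every other domain are background-randomized in its training counts, so
    it predicts those regions as unconserved (near-zero LLRs) while visible
    domains yield strongly damaging LLRs. Collectively the scorers must cover
    all domains; a domain invisible to every scorer triggers a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    all_names = {d.name for d in truth.domains}
    covered = set().union(*visibility) if visibility else set()
    missing = all_names - covered
    if missing:
        warnings.warn(f"domains {sorted(missing)} are masked for every scorer")
    L = truth.sensitivity.shape[0]
    scorers = []
    for s, visible in enumerate(visibility):
        hide = np.zeros(L, dtype=bool)
        for d in truth.domains:
            if d.name not in visible:
                hide[d.positions] = True
        scorers.append(
            ProfileScorer.from_family(
                family,
                pseudocount=pseudocount,
                name=f"scorer{s}",
                randomize_columns=hide if hide.any() else None,
                rng=rng,
            )
        )
    return scorers


def generate_labeled_variants(
    proteins: list[ProteinRecord],
    truth: SyntheticTruth,
    n_per_protein: int = 40,
    label_noise: float = 0.0,
    seed: int = 0,
    sensitivity_threshold: float = 0.5,
) -> pd.DataFrame:
    """Clinical-style labeled variants driven by the position ground truth.

    A variant is pathogenic when its position's sensitivity exceeds the
    threshold (so at zero noise the labels are perfectly separable by ground
    truth); ``label_noise`` flips labels independently. Positions are
    sampled half from sensitive (domain) positions, half from background,
    so both classes appear whenever n permits. Allele frequencies are drawn
    log-uniform, rarer for pathogenic variants, with a fraction missing.
    """
    if n_per_protein < 2:
        raise ValueError("need at least 2 variants per protein")
    rng = np.random.default_rng(seed)
    sens = truth.sensitivity
    hot = np.flatnonzero(sens > sensitivity_threshold)
    cold = np.flatnonzero(sens <= sensitivity_threshold)
    rows = []
    for p in proteins:
        wt = p.wt_indices
        n_hot = n_per_protein // 2 if hot.size else 0
        pool = np.concatenate(
            [
                rng.choice(hot, size=n_hot) if hot.size else np.empty(0, int),
                rng.choice(cold, size=n_per_protein - n_hot)
                if cold.size
                else rng.choice(hot, size=n_per_protein - n_hot),
            ]
        )
        for t in pool:
            t = int(t)
            if wt[t] < 0:
                continue
            alt = int(rng.integers(N_AA - 1))
            if alt >= wt[t]:
                alt += 1
            pathogenic = sens[t] > sensitivity_threshold
            if label_noise > 0 and rng.random() < label_noise:
                pathogenic = not pathogenic
            if pathogenic:
                af = 10 ** rng.uniform(-6, -3)
            else:
                af = 10 ** rng.uniform(-4, -0.5)
            if rng.random() < 0.15:
                af = np.nan
            ref, alt_aa = AA20[wt[t]], AA20[alt]
            rows.append(
                (
                    f"{p.id}:{ref}{t + 1}{alt_aa}",
                    p.id,
                    p.id,
                    t + 1,
                    ref,
                    alt_aa,
                    "pathogenic" if pathogenic else "benign",
                    af,
                    float(sens[t]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "protein_id",
            "gene",
            "position",
            "ref",
            "alt",
            "label",
            "af",
            "sensitivity",
        ],
    )


def generate_dms_assays(
    protein: ProteinRecord,
    truth: SyntheticTruth,
    n_variants: int = 150,
    noise_sd: float = 0.05,
    wt_convention: int = 1,
    inverted: bool = False,
    seed: int = 0,
    assay_id: str | None = None,
) -> pd.DataFrame:
    """A deep-mutational-scan style assay table for one protein.

    True fitness of a variant is ``1 - sensitivity * aa_factor`` (aa_factor
    uniform in [0.5, 1]); the wild type has fitness 1 and measurement equal
    to ``wt_convention`` (0 or 1). Normally the measurement is fitness on the
    wild-type scale plus Gaussian noise. When ``inverted``, deviations from
    the wild-type value in *either* direction signal damage, so measurements
    only track fitness after an abs(x - WT) transform.
    """
    if wt_convention not in (0, 1):
        raise ValueError("wt_convention must be 0 or 1")
    rng = np.random.default_rng(seed)
    wt = protein.wt_indices
    ok = np.flatnonzero(wt >= 0)
    pos = rng.choice(ok, size=n_variants)
    rows = []
    aid = assay_id or f"{protein.id}_dms"
    # wild-type reference row
    t0 = int(ok[0])
    rows.append((aid, protein.id, t0 + 1, AA20[wt[t0]], AA20[wt[t0]], float(wt_convention), 1.0))
    for t in pos:
        t = int(t)
        alt = int(rng.integers(N_AA - 1))
        if alt >= wt[t]:
            alt += 1
        severity = truth.sensitivity[t] * rng.uniform(0.5, 1.0)
        fitness = 1.0 - severity
        noise = rng.normal(0.0, noise_sd)
        if inverted:
            sign = rng.choice([-1.0, 1.0])
            meas = wt_convention + sign * severity + noise
        else:
            meas = wt_convention - 1.0 + fitness + noise
        rows.append((aid, protein.id, t + 1, AA20[wt[t]], AA20[alt], float(meas), float(fitness)))
    df = pd.DataFrame(
        rows,
        columns=["assay_id", "protein_id", "position", "ref", "alt", "measurement", "fitness"],
    )
    df.attrs["wt_convention"] = wt_convention
    df.attrs["inverted"] = inverted
    return df


def severity_from_sensitivity(
    sensitivity: np.ndarray, slope: float = 0.9, intercept: float = 0.1
) -> np.ndarray:
    """Affine, clipped severity map used by the summary-statistic generator."""
    return np.clip(intercept + slope * np.asarray(sensitivity, dtype=float), 0.0, 1.0)


def generate_summary_stats(
    genes: list[tuple[str, np.ndarray]],
    phenotypes: list[str],
    gamma: float,
    se: float = 0.2,
    n_variants_per_pair: int = 50,
    seed: int = 0,
    random_sign: bool = True,
) -> pd.DataFrame:
    """Rare-variant association summary statistics under a linear effect model.

    For each gene-phenotype pair with per-pair effect gamma_g (``gamma``
    times a random sign when ``random_sign``), every variant v gets

        beta_v = gamma_g * severity_v + N(0, se^2),  p_v two-sided from beta_v/se.

    Gene-level columns: a severity-weighted burden beta, a predicted
    loss-of-function burden beta whose sign matches gamma_g, and a Stouffer
    combined-z gene p — a documented synthetic surrogate for a SKAT-O-style
    missense gene test (the real test is only ever consumed as published
    summary statistics).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, severity_arr in genes:
        severity_arr = np.asarray(severity_arr, dtype=float)
        for pheno in phenotypes:
            g = gamma * (rng.choice([-1.0, 1.0]) if random_sign else 1.0)
            idx = rng.integers(severity_arr.size, size=n_variants_per_pair)
            sev = severity_arr[idx]
            beta = g * sev + rng.normal(0.0, se, size=n_variants_per_pair)
            z = beta / se
            pvals = 2 * norm.sf(np.abs(z))
            w = sev if sev.sum() > 0 else np.ones_like(sev)
            burden = float(np.sum(w * beta) / np.sum(w))
            stouffer = float(np.sum(z) / np.sqrt(n_variants_per_pair))
            gene_p = float(2 * norm.sf(abs(stouffer)))
            plof_beta = g + rng.normal(0.0, se / np.sqrt(n_variants_per_pair))
            if random_sign and g != 0 and np.sign(plof_beta) != np.sign(g):
                plof_beta = -plof_beta  # pLoF burden direction follows the pair effect
            plof_p = float(2 * norm.sf(abs(plof_beta) / (se / np.sqrt(n_variants_per_pair) + 1e-12)))
            for v in range(n_variants_per_pair):
                rows.append(
                    (
                        gene,
                        pheno,
                        f"{gene}:{pheno}:v{v}",
                        float(sev[v]),
                        float(beta[v]),
                        float(max(pvals[v], 5e-324)),
                        gene_p,
                        float(plof_beta),
                        plof_p,
                        n_variants_per_pair,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "phenotype",
            "variant_id",
            "severity",
            "beta",
            "p",
            "gene_missense_p",
            "plof_beta",
            "plof_p",
            "variant_count",
        ],
    )
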