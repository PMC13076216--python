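"""Class-conditional Gaussian theory of min- vs mean-aggregated ensembles.

Model: conditional on the true class (pathogenic or benign), the LLR scores
emitted by N independent scorers are i.i.d. Gaussian. Pathogenic scores sit
lower (mu_p <= mu_b; benign-high orientation). Two interpretable quantities
govern everything: the separation of the class means and the ratio of the
class standard deviations.

For a variant scored by all N models, the averaging aggregator yields a
Gaussian with variance sigma^2/N per class, so

    AUC_avg = Phi( (mu_b - mu_p) / sqrt((sigma_p^2 + sigma_b^2)/N) ).

The minimum aggregator yields the first order statistic of N Gaussians per
class; its AUC = P(min_benign > min_pathogenic) has no elementary closed
form and is evaluated by one-dimensional quadrature over the order-statistic
density

    f_min(x) = N phi((x-mu)/sigma)/sigma * (1 - Phi((x-mu)/sigma))^(N-1).

Minimum aggregation beats averaging when pathogenic scores are much more
dispersed than benign ones — the regime a complementary-blind-spot ensemble
creates — and never by more than a tie tolerance when the class spreads are
equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.stats import norm

__all__ = [
    "GaussianLLRSpec",
    "AUCResult",
    "auc_single",
    "auc_average",
    "auc_min",
    "simulate_llrs",
    "mc_auc",
    "regime_map",
]


@dataclass(frozen=True)
class GaussianLLRSpec:
    """Class-conditional Gaussian score model for an ensemble of N scorers."""

    mu_p: float
    sigma_p: float
    mu_b: float
    sigma_b: float
    n_models: int = 1

    def __post_init__(self) -> None:
        if self.sigma_p <= 0 or self.sigma_b <= 0:
            raise ValueError("class standard deviations must be positive")
        if self.n_models < 1:
            raise ValueError("need at least one scorer")
        if self.mu_p > self.mu_b:
            raise ValueError("convention: mu_p <= mu_b (pathogenic scores lower)")


@dataclass(frozen=True)
class AUCResult:
    auc: float
    method: str  # closed_form | quadrature | monte_carlo
    tol: float = 0.0

    def __float__(self) -> float:
        return self.auc


def auc_single(spec: GaussianLLRSpec) -> AUCResult:
    """AUC of one scorer: Phi(separation / sqrt(sigma_p^2 + sigma_b^2))."""
    z = (spec.mu_b - spec.mu_p) / np.hypot(spec.sigma_p, spec.sigma_b)
    return AUCResult(float(norm.cdf(z)), "closed_form")


def auc_average(spec: GaussianLLRSpec) -> AUCResult:
    """AUC of the N-scorer averaging aggregator (closed form)."""
    denom = np.sqrt((spec.sigma_p**2 + spec.sigma_b**2) / spec.n_models)
    z = (spec.mu_b - spec.mu_p) / denom
    return AUCResult(float(norm.cdf(z)), "closed_form")


def _min_logpdf(x: np.ndarray, mu: float, sigma: float, n: int) -> np.ndarray:
    z = (x - mu) / sigma
    return (
        np.log(n)
        + norm.logpdf(z)
        - np.log(sigma)
        + (n - 1) * norm.logsf(z)
    )


def _min_sf(x: np.ndarray, mu: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(n * norm.logsf((x - mu) / sigma))


def auc_min(spec: GaussianLLRSpec, tol: float = 1e-8) -> AUCResult:
    """AUC of the minimum (maximum-confidence) aggregator, by quadrature.

    Integrates P(min_benign > x) against the density of min_pathogenic over a
    +/- 10-standard-deviation support window.
    """
    if spec.n_models == 1:
        return auc_single(spec)
    mu_p, s_p, mu_b, s_b, n = (
        spec.mu_p,
        spec.sigma_p,
        spec.mu_b,
        spec.sigma_b,
        spec.n_models,
    )
    lo = min(mu_p - 10 * s_p, mu_b - 10 * s_b)
    hi = max(mu_p + 10 * s_p, mu_b + 10 * s_b)

    def integrand(x):
        return np.exp(_min_logpdf(x, mu_p, s_p, n)) * _min_sf(x, mu_b, s_b, n)

    val, err = integrate.quad(integrand, lo, hi, epsabs=tol, epsrel=tol, limit=400)
    if not np.isfinite(val) or err > max(tol * 100, 1e-6):
        raise ArithmeticError(
            f"quadrature did not converge: value={val}, abs err estimate={err}"
        )
    return AUCResult(float(np.clip(val, 0.0, 1.0)), "quadrature", tol)


def simulate_llrs(
    spec: GaussianLLRSpec, n_per_class: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-scorer score blocks for both classes (reproducible by seed).

    Returns ``(pathogenic, benign)`` arrays of shape ``(n_per_class,
    n_models)``: one row per variant, one column per scorer.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    p = rng.normal(spec.mu_p, spec.sigma_p, size=(n_per_class, spec.n_models))
    b = rng.normal(spec.mu_b, spec.sigma_b, size=(n_per_class, spec.n_models))
    return p, b


def _empirical_auc(benign: np.ndarray, pathogenic: np.ndarray) -> float:
    """P(benign > pathogenic) + half-credit ties, via joint ranking."""
    from scipy.stats import rankdata

    allv = np.concatenate([benign, pathogenic])
    ranks = rankdata(allv)
    nb, npath = benign.size, pathogenic.size
    u = ranks[:nb].sum() - nb * (nb + 1) / 2.0
    return float(u / (nb * npath))


def mc_auc(
    spec: GaussianLLRSpec, aggregator: str, n_per_class: int = 1_000_000, seed: int = 0
) -> AUCResult:
    """Monte-Carlo oracle AUC for an aggregator ('min', 'mean' or 'single')."""
    p, b = simulate_llrs(spec, n_per_class, seed)
    if aggregator == "min":
        sp, sb = p.min(axis=1), b.min(axis=1)
    elif aggregator in ("mean", "avg"):
        sp, sb = p.mean(axis=1), b.mean(axis=1)
    elif aggregator == "single":
        sp, sb = p[:, 0], b[:, 0]
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    se = 1.0 / np.sqrt(n_per_class)  # conservative AUC standard-error scale
    return AUCResult(_empirical_auc(sb, sp), "monte_carlo", se)


def regime_map(
    separations: np.ndarray,
    sigma_ratios: np.ndarray,
    n_models: int,
    sigma_b: float = 1.0,
    tie_tol: float = 1e-3,
) -> pd.DataFrame:
    """Map which aggregator wins over a (separation, sigma-ratio) grid.

    ``separation`` is (mu_b - mu_p) in benign-sd units; ``sigma_ratio`` is
    sigma_p / sigma_b. Winner is 'min', 'avg' or 'tie' at ``tie_tol``.
    """
    separations = np.atleast_1d(np.asarray(separations, dtype=float))
    sigma_ratios = np.atleast_1d(np.asarray(sigma_ratios, dtype=float))
    if separations.size == 0 or sigma_ratios.size == 0:
        raise ValueError("empty grid")
    rows = []
    for sep, ratio in product(separations, sigma_ratios):
        spec = GaussianLLRSpec(
            mu_p=-sep * sigma_b,
            sigma_p=ratio * sigma_b,
            mu_b=0.0,
            sigma_b=sigma_b,
            n_models=n_models,
        )
        a_min = auc_min(spec).auc
        a_avg = auc_average(spec).auc
        if abs(a_min - a_avg) <= tie_tol:
            winner = "tie"
        else:
            winner = "min" if a_min > a_avg else "avg"
        rows.append((sep, ratio, n_models, a_min, a_avg, winner))
    return pd.DataFrame(
        rows,
        columns=["separation", "sigma_ratio", "n_models", "auc_min", "auc_avg", "winner"],
    )
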