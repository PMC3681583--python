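"""Bayesian comparison of pairwise trait correlations between two sites.

Trait vectors within a population are modelled as multivariate Gaussian with
a conjugate normal-inverse-Wishart (NIW) prior on the mean and covariance.
Conjugacy gives the posterior in closed form, so the posterior over the
covariance matrix is sampled i.i.d. from an inverse-Wishart distribution;
each draw is rescaled to a correlation matrix.  Pairing draw d from site A
with draw d from site B (the sites are independent) yields the posterior
distribution of the difference in each trait-pair correlation, and a pair is
called significantly different when zero falls outside the equal-tailed
interval between the 1st and 99th posterior percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TraitTable, ValidationError

__all__ = [
    "NIWPrior",
    "CorrPosterior",
    "default_prior",
    "posterior_sample",
    "correlation_difference",
    "summarize_north_share",
]


@dataclass(frozen=True)
class NIWPrior:
    """Normal-inverse-Wishart prior: mu | Sigma ~ N(mu0, Sigma/kappa0),
    Sigma ~ InvWishart(nu0, Lambda0)."""

    mu0: np.ndarray
    kappa0: float
    nu0: float
    Lambda0: np.ndarray

    def __post_init__(self) -> None:
        mu0 = np.asarray(self.mu0, float)
        L0 = np.asarray(self.Lambda0, float)
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "Lambda0", L0)
        n = mu0.shape[0]
        if self.kappa0 <= 0:
            raise ValidationError("kappa0 must be positive")
        if self.nu0 <= n + 1:
            raise ValidationError(
                f"nu0 must exceed N+1={n + 1} for a finite prior covariance mean"
            )
        if L0.shape != (n, n) or not np.allclose(L0, L0.T, atol=1e-10):
            raise ValidationError("Lambda0 must be symmetric N x N")
        if np.linalg.eigvalsh(L0).min() <= 0:
            raise ValidationError("Lambda0 must be positive definite")


def default_prior(
    *tables: TraitTable, kappa0: float = 1e-3
) -> NIWPrior:
    """Weakly informative, scale-aware prior built from pooled data.

    mu0 is the pooled sample mean, nu0 = N + 2 (the smallest value giving a
    finite prior covariance mean) and Lambda0 = (nu0 - N - 1) * diag(pooled
    variances), so the prior covariance mean matches the pooled per-trait
    variances while carrying minimal weight (kappa0 defaults to 1e-3).
    """
    if not tables:
        raise ValidationError("need at least one table to build a prior")
    names = tables[0].trait_names
    for t in tables[1:]:
        if t.trait_names != names:
            raise ValidationError("tables must share the trait set")
    x = np.vstack([t.values for t in tables])
    n = x.shape[1]
    nu0 = n + 2.0
    var = x.var(axis=0, ddof=1)
    return NIWPrior(
        mu0=x.mean(axis=0),
        kappa0=kappa0,
        nu0=nu0,
        Lambda0=(nu0 - n - 1.0) * np.diag(var),
    )


@dataclass(frozen=True)
class CorrPosterior:
    """Posterior correlation-matrix draws for one population."""

    draws: np.ndarray  # (D, N, N)
    trait_names: tuple[str, ...]
    site: str
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def posterior_sample(
    table: TraitTable,
    prior: NIWPrior | None = None,
    draws: int = 20_000,
    seed: int = 0,
) -> CorrPosterior:
    """Sample the NIW posterior over the correlation matrix of one population.

    Applies the conjugate update
    ``nu_n = nu0 + M``,
    ``Lambda_n = Lambda0 + S_scatter + kappa0*M/(kappa0+M) (xbar-mu0)(xbar-mu0)'``
    and draws ``Sigma ~ InvWishart(nu_n, Lambda_n)`` i.i.d., rescaling each
    draw to a correlation matrix.  Reproducible under a fixed seed.
    """
    x = table.values
    m, n = x.shape
    if m < n + 1:
        raise ValidationError("need M >= N+1 individuals")
    if draws < 1:
        raise ValidationError("need at least one draw")
    if prior is None:
        prior = default_prior(table)
    if prior.mu0.shape[0] != n:
        raise ValidationError("prior dimension does not match trait count")
    xbar = x.mean(axis=0)
    centered = x - xbar
    scatter = centered.T @ centered
    dev = xbar - prior.mu0
    lambda_n = (
        prior.Lambda0
        + scatter
        + (prior.kappa0 * m / (prior.kappa0 + m)) * np.outer(dev, dev)
    )
    lambda_n = (lambda_n + lambda_n.T) / 2.0
    if np.linalg.eigvalsh(lambda_n).min() <= 0:
        raise ValidationError("degenerate data: posterior scale matrix not PD")
    nu_n = prior.nu0 + m
    rng = np.random.default_rng(seed)
    sigma = stats.invwishart.rvs(df=nu_n, scale=lambda_n, size=draws,
                                 random_state=rng)
    sigma = np.asarray(sigma).reshape(draws, n, n)
    d = np.sqrt(np.einsum("dii->di", sigma))
    corr = sigma / (d[:, :, None] * d[:, None, :])
    ii = np.arange(n)
    corr[:, ii, ii] = 1.0
    return CorrPosterior(
        draws=corr, trait_names=table.trait_names, site=table.population, seed=seed
    )


def correlation_difference(
    a: CorrPosterior,
    b: CorrPosterior,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> pd.DataFrame:
    """Posterior difference r_a - r_b for every trait pair.

    Returns one row per unordered pair with the posterior mean difference,
    the 1st and 99th percentiles, a significance flag (interval excludes
    zero) and which site the correlation is stronger at.  Positive means
    stronger at site ``a``.
    """
    if a.trait_names != b.trait_names:
        raise ValidationError("posteriors must share the trait set")
    d = min(a.n_draws, b.n_draws)
    diff = a.draws[:d] - b.draws[:d]
    n = len(a.trait_names)
    iu, ju = np.triu_indices(n, k=1)
    pair_draws = diff[:, iu, ju]  # (D, n_pairs)
    mean = pair_draws.mean(axis=0)
    p_lo = np.percentile(pair_draws, lower_pct, axis=0)
    p_hi = np.percentile(pair_draws, upper_pct, axis=0)
    significant = (p_lo > 0) | (p_hi < 0)
    return pd.DataFrame(
        {
            "trait_i": [a.trait_names[i] for i in iu],
            "trait_j": [a.trait_names[j] for j in ju],
            "mean_diff": mean,
            "p01": p_lo,
            "p99": p_hi,
            "significant": significant,
            "stronger_site": np.where(mean > 0, a.site, np.where(mean < 0, b.site, "tie")),
        }
    )


def summarize_north_share(
    tables: dict[str, pd.DataFrame],
    north_site: str,
) -> dict:
    """Pooled share of trait pairs whose correlation is stronger in the north.

    ``tables`` maps species name to its correlation-difference table, whose
    sign convention must be "positive = stronger at the first site" with the
    first site recorded in ``stronger_site`` for positive rows.  Returns the
    overall proportion plus per-species counts.
    """
    if not tables:
        raise ValidationError("need at least one correlation-difference table")
    per_species = {}
    north_total = 0
    pairs_total = 0
    for species, df in tables.items():
        north = int((df["stronger_site"] == north_site).sum())
        pairs = int(len(df))
        per_species[species] = {"north_stronger": north, "pairs": pairs}
        north_total += north
        pairs_total += pairs
    return {
        "north_site": north_site,
        "proportion_north_stronger": north_total / pairs_total,
        "north_stronger": north_total,
        "pairs": pairs_total,
        "per_species": per_species,
    }
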