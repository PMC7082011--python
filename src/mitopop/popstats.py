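"""Diversity and neutrality statistics for haplotype samples.

Implements the per-population summary statistics of a standard mitochondrial
survey: haplotype diversity *h* (Nei's unbiased estimator), nucleotide
diversity π, Watterson's θ_S, Tajima's D, and Fu's F_S, plus coalescent
simulation-based P-values for the two neutrality tests.

Conventions
-----------
* θ estimates are carried *per locus* (mean pairwise differences over the
  whole sequence); π is per site (θ_π / L).
* Fu's F_S uses the Ewens sampling distribution of the number of distinct
  haplotypes K given θ and n:  P(K = j) = |s(n, j)| θ^j / θ^(n), with
  unsigned Stirling numbers of the first kind computed by a log-space
  recurrence.  F_S = ln(S' / (1 − S')) with S' = P(K ≥ k_obs).
* Undefined statistics (S = 0 for D, k = 1 for F_S) are returned as the
  ``UNDEFINED`` sentinel (NaN), never as numeric zero.
* P-values are lower-tail (small / negative statistic = expansion-like) and
  estimated from neutral constant-size coalescent simulations at θ = θ̂.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import InsufficientSampleError
from .seqio import Alignment, HaplotypeTable, pairwise_differences

#: Sentinel for statistics that are undefined on the given sample.
UNDEFINED = float("nan")


def is_undefined(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass(frozen=True)
class DiversityStats:
    n: int
    S: int
    k: int
    h: float
    pi: float
    theta_pi_locus: float
    theta_S: float
    L: int


@dataclass(frozen=True)
class NeutralityStats:
    tajima_D: float
    fu_Fs: float
    p_D: float
    p_Fs: float
    n_sims: int


# ---------------------------------------------------------------------------
# diversity


def _segregating_sites(matrix: np.ndarray) -> int:
    """Number of columns with ≥2 distinct called (non-missing) states."""
    miss = (matrix == ord("-")) | (matrix == ord("N"))
    S = 0
    for j in range(matrix.shape[1]):
        col = matrix[~miss[:, j], j]
        if col.size and (col != col[0]).any():
            S += 1
    return S


def haplotype_diversity(counts: np.ndarray) -> float:
    """Nei's unbiased haplotype diversity h = n(1 − Σ p_i²)/(n − 1)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise InsufficientSampleError("h requires n >= 2")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def watterson_a1(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def diversity_stats(
    haplotype_table: HaplotypeTable,
    alignment: Alignment,
    site: str | None = None,
    missing_rule: str = "ignore_missing_sites",
) -> DiversityStats:
    """Per-site (or pooled, ``site=None``) diversity summary.

    π is computed directly from the specimen alignment (mean pairwise
    differences per locus, divided by alignment length); the haplotype table
    supplies k and the frequencies behind h.
    """
    if site is None:
        sub = alignment
        counts = haplotype_table.counts.sum(axis=1)
    else:
        sub = alignment.site_subset(site)
        counts = haplotype_table.site_counts(site)
    n = sub.n
    if n < 2:
        raise InsufficientSampleError(f"site {site!r}: n = {n} < 2")
    dm = pairwise_differences(sub, missing_rule=missing_rule)
    iu = np.triu_indices(n, k=1)
    theta_pi = float(dm.values[iu].mean())
    L = sub.length
    S = _segregating_sites(sub.to_matrix())
    k = int(np.sum(counts > 0))
    return DiversityStats(
        n=n,
        S=S,
        k=k,
        h=haplotype_diversity(counts[counts > 0]),
        pi=theta_pi / L,
        theta_pi_locus=theta_pi,
        theta_S=S / watterson_a1(n) if n > 1 else UNDEFINED,
        L=L,
    )


# ---------------------------------------------------------------------------
# Tajima's D


def tajimas_d(S: int, n: int, theta_pi_locus: float) -> float:
    """Tajima's D = (θ̂_π − θ̂_S) / sqrt(e1·S + e2·S(S−1)).

    Returns the ``UNDEFINED`` sentinel when S = 0.
    """
    if n < 4:
        raise InsufficientSampleError("Tajima's D requires n >= 4")
    if S == 0:
        return UNDEFINED
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((theta_pi_locus - S / a1) / math.sqrt(var))


# ---------------------------------------------------------------------------
# Fu's F_S via the Ewens sampling distribution


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, j)| for j = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        log_m = math.log(m) if m > 0 else -np.inf
        with np.errstate(invalid="ignore"):
            new[0] = log_m + row[0]
            new[1:] = np.logaddexp(log_m + row[1:], row[:-1])
        row = new
    return tuple(row)


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = j | θ, n) for j = 1..n under the Ewens sampling distribution."""
    if n < 1:
        raise InsufficientSampleError("n >= 1 required")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    ls = np.array(_log_stirling_row(n))
    j = np.arange(n + 1)
    log_rising = gammaln(theta + n) - gammaln(theta)
    return (ls + j * math.log(theta) - log_rising)[1:]


def fus_fs(k: int, n: int, theta_pi_locus: float) -> float:
    """Fu's F_S = ln(S'/(1−S')), S' = P(K ≥ k | θ̂_π, n) under Ewens sampling.

    Computed in log space; returns the ``UNDEFINED`` sentinel when k = 1
    (a monomorphic haplotype sample carries no signal).
    """
    if n < 2:
        raise InsufficientSampleError("Fu's Fs requires n >= 2")
    if not 1 <= k <= n:
        raise ValueError(f"k = {k} outside 1..{n}")
    if k == 1 or theta_pi_locus <= 0:
        return UNDEFINED
    lp = ewens_log_pmf(n, theta_pi_locus)
    js = np.arange(1, n + 1)
    log_sp = logsumexp(lp[js >= k])
    log_1m = logsumexp(lp[js < k])
    return float(log_sp - log_1m)


# ---------------------------------------------------------------------------
# simulation-based P-values


def _simulate_neutral_stats(
    n: int,
    theta: float,
    n_sims: int,
    rng: np.random.Generator,
    condition_on: str = "theta",
    S_obs: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (D, Fs) under the constant-size neutral coalescent.

    Works on the standard exchangeable coalescent directly: inter-coalescence
    times T_k ~ Exp(k(k−1)/θ) in mutational units, infinite-sites mutations
    Poisson on branches.  Statistics need only S, mean pairwise differences
    and the haplotype count, all of which we track through the tree.
    """
    from .simulate import simulate_genealogy, sprinkle_infinite_sites

    Ds = np.empty(n_sims)
    Fss = np.empty(n_sims)
    for b in range(n_sims):
        ts = simulate_genealogy(
            n, theta, history="constant", seed=int(rng.integers(1, 2**31 - 1))
        )
        S, theta_pi, k = sprinkle_infinite_sites(
            ts, rng, condition_on=condition_on, S_fixed=S_obs
        )
        Ds[b] = tajimas_d(S, n, theta_pi) if S > 0 else 0.0
        Fss[b] = fus_fs(k, n, theta_pi) if (k > 1 and theta_pi > 0) else 0.0
    return Ds, Fss


def neutrality_pvalues(
    tajima_D: float,
    fu_Fs: float,
    n: int,
    theta_hat: float,
    n_sims: int = 1000,
    seed: int | None = None,
    condition_on: str = "theta",
    S_obs: int | None = None,
) -> tuple[float, float]:
    """Lower-tail P-values for Tajima's D and Fu's F_S.

    P = proportion of ``n_sims`` neutral constant-size coalescent replicates
    (θ = θ̂) whose statistic is ≤ the observed one.  ``condition_on="S"``
    instead places exactly ``S_obs`` mutations on each simulated genealogy.
    Undefined observed statistics yield undefined P.
    """
    if n_sims < 100:
        raise ValueError("n_sims >= 100 required for a usable P-value")
    if condition_on not in ("theta", "S"):
        raise ValueError("condition_on must be 'theta' or 'S'")
    rng = np.random.default_rng(seed)
    Ds, Fss = _simulate_neutral_stats(
        n, theta_hat, n_sims, rng, condition_on=condition_on, S_obs=S_obs
    )
    p_D = float(np.mean(Ds <= tajima_D)) if not is_undefined(tajima_D) else UNDEFINED
    p_Fs = float(np.mean(Fss <= fu_Fs)) if not is_undefined(fu_Fs) else UNDEFINED
    return p_D, p_Fs


def neutrality_stats(
    stats: DiversityStats,
    n_sims: int = 1000,
    seed: int | None = None,
) -> NeutralityStats:
    """Convenience wrapper: D, F_S and their simulated P-values from a sample."""
    D = tajimas_d(stats.S, stats.n, stats.theta_pi_locus)
    Fs = fus_fs(stats.k, stats.n, stats.theta_pi_locus)
    if stats.theta_pi_locus > 0:
        p_D, p_Fs = neutrality_pvalues(
            D, Fs, stats.n, stats.theta_pi_locus, n_sims=n_sims, seed=seed
        )
    else:
        p_D = p_Fs = UNDEFINED
    return NeutralityStats(D, Fs, p_D, p_Fs, n_sims)
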