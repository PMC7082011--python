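"""Mismatch distributions and expansion-model fitting.

The mismatch distribution is the histogram of pairwise difference counts in a
sample.  Two demographic models give closed-form expectations for it:

*Sudden (demographic) expansion* — a panmictic population at mutational
equilibrium θ0 grows instantaneously to θ1 at mutational time τ before
present.  A random pair either coalesces during the recent epoch (coalescence
hazard 1/θ1 per unit mutational time, Poisson mutations at rate 1 per unit)
or survives to τ and then draws from the ancestral geometric equilibrium
F̂_i(θ0) = θ0^i/(1+θ0)^{i+1}, carrying Poisson(τ) extra mutations.  Both
pieces have incomplete-gamma / convolution closed forms, which is what
:func:`expected_mismatch` evaluates — the familiar series expression is the
same quantity rearranged.

*Spatial (range) expansion* — at time τ a single deme of size θ seeds an
infinite array of demes of the same size exchanging migrants at scaled rate
M = 2Nm.  Within the recent epoch a co-deme pair coalesces with hazard 1/θ
or separates forever with hazard 2M/θ; separated or surviving pairs fall
back to the ancestral equilibrium at τ.  This is the three-parameter
(τ, θ, M) migrant-pool model.

Fitting minimises SSD = Σ_i (obs_i − exp_i)² over the observed support by a
coarse grid followed by Nelder–Mead refinement (the SSD surface is
multimodal).  Goodness of fit uses a parametric bootstrap: resample the
n(n−1)/2 pairwise counts from the fitted law, refit, and compare SSD (and
Harpending's raggedness) with the observed values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.special import gammainc, gammaln

from .errors import MitopopError
from .seqio import DistanceMatrix

#: printed convention for "effectively infinite" post-expansion theta
THETA_CAP = 99999.0


@dataclass(frozen=True)
class MismatchDistribution:
    """Histogram of pairwise difference counts, classes 0..d_max."""

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or (c < 0).any():
            raise MitopopError("counts must be a 1-D non-negative vector")

    @property
    def n_pairs(self) -> int:
        return int(np.sum(self.counts))

    @property
    def d_max(self) -> int:
        return len(self.counts) - 1

    @property
    def normalized(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pairs

    def trimmed(self) -> "MismatchDistribution":
        """Drop trailing empty classes."""
        nz = np.nonzero(self.counts)[0]
        last = int(nz[-1]) if nz.size else 0
        return MismatchDistribution(np.asarray(self.counts[: last + 1]))


@dataclass(frozen=True)
class ExpansionFit:
    model: str  # "sudden" | "spatial"
    tau: float
    theta0: float
    theta1: float  # capped at THETA_CAP for sudden; equals theta0 for spatial
    M: float | None  # spatial only
    SSD: float
    raggedness: float
    d_max: int
    n_pairs: int
    p_SSD: float | None = None
    p_raggedness: float | None = None

    @property
    def theta1_is_capped(self) -> bool:
        return self.theta1 >= THETA_CAP

    @property
    def params(self) -> tuple:
        if self.model == "sudden":
            return (self.tau, self.theta0, self.theta1)
        return (self.tau, self.theta0, self.M)


def mismatch_histogram(dm: DistanceMatrix) -> MismatchDistribution:
    """Tally the upper triangle of an integer pairwise-difference matrix."""
    if dm.metric != "pairwise_differences":
        raise MitopopError("mismatch histogram needs the pairwise_differences metric")
    vals = dm.values[np.triu_indices(len(dm.labels), k=1)]
    if not np.allclose(vals, np.round(vals)):
        raise MitopopError("non-integer distances; was the matrix a p-distance?")
    vals = vals.astype(int)
    counts = np.bincount(vals, minlength=int(vals.max()) + 1 if vals.size else 1)
    return MismatchDistribution(counts)


def _equilibrium(theta: float, d_max: int) -> np.ndarray:
    """Geometric equilibrium F̂_i = θ^i/(1+θ)^{i+1}, i = 0..d_max."""
    i = np.arange(d_max + 1)
    if theta <= 0:
        out = np.zeros(d_max + 1)
        out[0] = 1.0
        return out
    return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))


def expected_mismatch(model: str, params, d_max: int) -> np.ndarray:
    """Expected mismatch frequencies for classes 0..d_max.

    ``model="sudden"`` takes ``params = (tau, theta0, theta1)``;
    ``model="spatial"`` takes ``params = (tau, theta, M)``.  The returned
    vector sums to ≤ 1; the deficit is the tail mass beyond ``d_max``.
    """
    i = np.arange(d_max + 1)
    if model == "sudden":
        tau, theta0, theta1 = params
        if tau < 0 or theta0 < 0 or theta1 < 0:
            raise MitopopError("parameters must be non-negative")
        coal_rate = 1.0 / max(theta1, 1e-9)
        lam_tot = coal_rate  # only event in the recent epoch is coalescence
        surv = np.exp(-lam_tot * tau)
        ancestral = _equilibrium(theta0, d_max)
    elif model == "spatial":
        tau, theta, M = params
        if tau < 0 or theta < 0 or M < 0:
            raise MitopopError("parameters must be non-negative")
        coal_rate = 1.0 / max(theta, 1e-9)
        lam_tot = (1.0 + 2.0 * M) * coal_rate  # coalesce, or either lineage migrates
        # survive epoch: no event at all, or first event was a migration
        surv = np.exp(-lam_tot * tau) + (2 * M / (1 + 2 * M)) * (1 - np.exp(-lam_tot * tau))
        ancestral = _equilibrium(theta, d_max)
    else:
        raise MitopopError(f"unknown model {model!r}")

    # pairs coalescing inside the recent epoch at time x carry Poisson(i; x)
    # mutations: ∫_0^τ coal_rate·e^{-λx}·Pois(i; x) dx has an incomplete-gamma
    # closed form
    z = lam_tot + 1.0
    recent = coal_rate * np.exp(-(i + 1) * np.log(z)) * gammainc(i + 1, tau * z)

    # survivors: Poisson(τ) mutations in the epoch ⊕ ancestral equilibrium
    if tau > 0:
        pois = np.exp(i * np.log(tau) - tau - gammaln(i + 1.0))
    else:
        pois = np.zeros(d_max + 1)
        pois[0] = 1.0
    conv = np.convolve(pois, ancestral)[: d_max + 1]
    return recent + surv * conv


def raggedness_index(mismatch) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d+1} (x_i − x_{i−1})², x_{d+1} = 0.

    Accepts a :class:`MismatchDistribution` or a normalized frequency vector.
    Small for the smooth unimodal profiles produced by expansions.
    """
    if isinstance(mismatch, MismatchDistribution):
        x = mismatch.normalized
    else:
        x = np.asarray(mismatch, dtype=float)
    x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


def _ssd(obs: np.ndarray, model: str, params) -> float:
    exp = expected_mismatch(model, params, len(obs) - 1)
    return float(np.sum((obs - exp) ** 2))


def fit_expansion(
    mismatch: MismatchDistribution,
    model: str = "sudden",
    n_grid: int = 12,
    refine_maxiter: int = 2000,
) -> ExpansionFit:
    """Least-squares fit of an expansion model to an observed mismatch.

    A coarse log/linear grid over the parameters seeds Nelder–Mead
    refinement of the SSD.  For the sudden model θ1 estimates above the
    printed-convention cap are reported as 99999 ("effectively infinite").
    A single-class distribution degenerates to τ = 0 with a warning.
    """
    trimmed = mismatch.trimmed()
    obs = trimmed.normalized
    d_max = trimmed.d_max
    if d_max == 0:
        warnings.warn("degenerate single-class mismatch; returning tau = 0")
        return ExpansionFit(model, 0.0, 0.0, 0.0 if model == "sudden" else 0.0,
                            0.0 if model == "spatial" else None,
                            _ssd(obs, model, (0.0, 0.0, 0.0)),
                            raggedness_index(obs), 0, trimmed.n_pairs)

    mean_d = float(np.sum(np.arange(d_max + 1) * obs))
    taus = np.unique(np.concatenate([
        np.linspace(0.0, 2.0 * d_max, n_grid), [max(mean_d, 1e-3)]
    ]))
    thetas = np.geomspace(1e-3, 4.0 * max(mean_d, 1.0), n_grid)
    if model == "sudden":
        theta1s = np.geomspace(1.0, THETA_CAP, n_grid)
        grid = [(t, a, b) for t in taus for a in thetas for b in theta1s if b >= a]
    else:
        Ms = np.geomspace(1e-2, 100.0, n_grid)
        grid = [(t, a, m) for t in taus for a in thetas for m in Ms]

    best = min(grid, key=lambda p: _ssd(obs, model, p))

    LOG_HI = np.log(10.0 * THETA_CAP)  # keeps exp() finite; beyond the cap anyway

    def objective(x):
        # tau linear (clipped at 0), the two positive parameters in log space
        params = (max(x[0], 0.0), np.exp(min(x[1], LOG_HI)), np.exp(min(x[2], LOG_HI)))
        return _ssd(obs, model, params)

    x0 = np.array([best[0], np.log(max(best[1], 1e-6)), np.log(max(best[2], 1e-6))])
    res = optimize.minimize(objective, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-10,
                                     "maxiter": refine_maxiter})
    tau = max(float(res.x[0]), 0.0)
    p1 = float(np.exp(min(res.x[1], LOG_HI)))
    p2 = float(np.exp(min(res.x[2], LOG_HI)))
    ssd = _ssd(obs, model, (tau, p1, p2))

    if model == "sudden":
        theta0, theta1 = p1, min(p2, THETA_CAP)
        if p2 > THETA_CAP / 2:
            theta1 = THETA_CAP
        if theta1 < theta0:  # expansion fit convention
            theta0, theta1 = min(theta0, theta1), max(theta0, theta1)
        return ExpansionFit("sudden", tau, theta0, theta1, None, ssd,
                            raggedness_index(obs), d_max, trimmed.n_pairs)
    return ExpansionFit("spatial", tau, p1, p1, p2, ssd,
                        raggedness_index(obs), d_max, trimmed.n_pairs)


def ssd_bootstrap_p(
    fit: ExpansionFit,
    mismatch: MismatchDistribution,
    n_boot: int = 1000,
    seed: int | None = None,
    n: int | None = None,
) -> ExpansionFit:
    """Parametric-bootstrap P-values for SSD and raggedness.

    Simulates ``n_boot`` coalescent samples of the same size under the
    fitted expansion model (so the bootstrap pairwise counts carry the
    genealogical correlation of real data), refits the same model to each,
    and counts the fraction of replicates whose SSD (raggedness) is ≥ the
    observed one.  ``n`` defaults to the sample size implied by
    ``mismatch.n_pairs``.  Returns a copy of ``fit`` with
    ``p_SSD``/``p_raggedness`` filled in.
    """
    from .simulate import simulate_mismatch

    if n_boot < 100:
        raise MitopopError("n_boot >= 100 required")
    rng = np.random.default_rng(seed)
    trimmed = mismatch.trimmed()
    if n is None:
        n = int(round((1 + np.sqrt(1 + 8 * trimmed.n_pairs)) / 2))

    ge_ssd = 0
    ge_rag = 0
    for _ in range(n_boot):
        counts = simulate_mismatch(fit.model, fit.params, n, rng)
        boot = MismatchDistribution(counts).trimmed()
        bfit = fit_expansion(boot, model=fit.model, n_grid=6, refine_maxiter=300)
        if bfit.SSD >= fit.SSD - 1e-15:
            ge_ssd += 1
        if bfit.raggedness >= fit.raggedness - 1e-15:
            ge_rag += 1
    return replace(fit, p_SSD=ge_ssd / n_boot, p_raggedness=ge_rag / n_boot)
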