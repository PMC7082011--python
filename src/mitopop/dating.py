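"""Molecular-rate calibration and expansion dating.

The chain has three links:

1. **Geminate calibration** — sister clades split by the rise of the Panama
   Isthmus give a per-lineage substitution rate μ = d_net / (2·T_split) from
   the net between-clade p-distance and the closure date.
2. **θ-ratio transfer** — for two loci sequenced in the same specimens the
   effective population size cancels, so θ_target/θ_cal equals the ratio of
   mutation rates; a rate calibrated at one locus (e.g. COX1) transfers to
   an uncalibratable one (e.g. the control region) by multiplying with that
   ratio.
3. **Expansion dating** — a mismatch τ (mutational time, 2ut generations at
   per-sequence per-generation rate u = μ·L·g) converts to
   t_years = τ / (2·μ·L) with μ per site per year and L sites.  The
   generation time g cancels in years and only scales t_generations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import MitopopError


@dataclass(frozen=True)
class RatePath:
    """Full calibration chain from geminate distance to target-locus rate."""

    d_net: float
    T_split_my: float
    mu_cal_per_site_my: float
    theta_cal: float
    theta_target: float
    ratio: float
    mu_target_per_site_year: float


@dataclass(frozen=True)
class ExpansionDate:
    tau: float
    L: int
    mu_per_site_year: float
    generation_years: float
    t_generations: float
    t_years: float

    @property
    def t_kya(self) -> float:
        return self.t_years / 1000.0


def geminate_rate(d_net: float, T_split_my: float) -> float:
    """Per-lineage substitution rate (subs/site/My) from a geminate pair.

    ``d_net`` is the net between-clade p-distance; ``T_split_my`` the
    vicariance date in My.  rate = d_net / (2·T).
    """
    if d_net < 0:
        raise MitopopError("d_net must be >= 0")
    if T_split_my <= 0:
        raise MitopopError("T_split must be > 0")
    return d_net / (2.0 * T_split_my)


def theta_ratio_transfer(
    mu_cal_per_site_my: float, theta_cal: float, theta_target: float
) -> tuple[float, float]:
    """Transfer a calibrated rate between loci via the θ ratio.

    Both θ estimates must come from the same specimens so N cancels:
    μ_target/μ_cal = θ_target/θ_cal.  Returns (ratio, μ_target per site per
    *year*).
    """
    if theta_cal <= 0:
        raise MitopopError("theta_cal must be > 0")
    if theta_target < 0 or mu_cal_per_site_my < 0:
        raise MitopopError("rates and thetas must be >= 0")
    ratio = theta_target / theta_cal
    mu_target_per_year = mu_cal_per_site_my * 1e-6 * ratio
    return ratio, mu_target_per_year


def rate_path(
    d_net: float,
    T_split_my: float,
    theta_cal: float,
    theta_target: float,
    mu_cal_per_site_my: float | None = None,
) -> RatePath:
    """Assemble the full chain; ``mu_cal`` may override the geminate estimate
    (e.g. when a model-based clock rate is preferred over d/(2T))."""
    mu_cal = (
        mu_cal_per_site_my
        if mu_cal_per_site_my is not None
        else geminate_rate(d_net, T_split_my)
    )
    ratio, mu_target = theta_ratio_transfer(mu_cal, theta_cal, theta_target)
    return RatePath(
        d_net=d_net,
        T_split_my=T_split_my,
        mu_cal_per_site_my=mu_cal,
        theta_cal=theta_cal,
        theta_target=theta_target,
        ratio=ratio,
        mu_target_per_site_year=mu_target,
    )


def expansion_time(
    tau: float,
    mu_per_site_year: float,
    L: int,
    generation_years: float,
) -> ExpansionDate:
    """Convert a mismatch τ into calendar time.

    t_generations = τ / (2u) with u = μ·L·g the per-sequence per-generation
    rate; t_years = t_generations · g = τ / (2·μ·L).  Rounding is left to
    presentation (report Kya to 0.1).
    """
    if tau < 0:
        raise MitopopError("tau must be >= 0")
    if mu_per_site_year <= 0 or L <= 0 or generation_years <= 0:
        raise MitopopError("mu, L and generation time must be > 0")
    u_per_gen = mu_per_site_year * L * generation_years
    t_gen = tau / (2.0 * u_per_gen)
    t_years = t_gen * generation_years
    return ExpansionDate(
        tau=tau,
        L=L,
        mu_per_site_year=mu_per_site_year,
        generation_years=generation_years,
        t_generations=t_gen,
        t_years=t_years,
    )
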