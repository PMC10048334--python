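"""Molecular-clock conversions: per-year rates, effective population size
and divergence (domestication) time.

Coalescent analyses of the wild/domestic silkworm split report the
population mutation parameter ``theta = 4*Ne*mu`` and a divergence time
``tau`` expressed in units of 4*Ne generations. Given an independently
measured mutation rate ``mu`` these invert to

    Ne = theta / (4 * mu)        and        T = 4 * tau * Ne.

When ``mu`` is per site per *year* the time comes out directly in years;
a per-generation rate is first multiplied by the number of generations
per year (3 for reared silkworm, 365/40 for a free-running ~40-day life
cycle). Both unit pathways agree identically:
``T = 4*tau*theta / (4*mu_year) = tau*theta / mu_year``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidConfigError


def per_year_rate(mu_gen: float, generations_per_year: float) -> float:
    """Convert a per-generation rate to per site per year.

    >>> round(per_year_rate(0.41e-8, 365 / 40) * 1e8, 2)
    3.74
    """
    if mu_gen <= 0 or generations_per_year <= 0:
        raise InvalidConfigError("rate and generations per year must be positive")
    return mu_gen * generations_per_year


def effective_population_size(theta: float, mu_year: float) -> float:
    """Ne = theta / (4 * mu), with mu per site per year."""
    if theta <= 0 or mu_year <= 0:
        raise InvalidConfigError("theta and mu must be positive")
    return theta / (4.0 * mu_year)


def divergence_time_years(
    tau: float,
    ne: float,
    generations_per_year: float | None = None,
) -> float:
    """Divergence time T = 4 * tau * Ne.

    When ``ne`` was computed from a per-year mutation rate the result is
    already in years (leave ``generations_per_year`` unset). When ``ne``
    came from a per-generation rate the product is in generations and is
    divided by ``generations_per_year``.
    """
    if tau < 0 or ne <= 0:
        raise InvalidConfigError("need tau >= 0 and ne > 0")
    t = 4.0 * tau * ne
    if generations_per_year is not None:
        if generations_per_year <= 0:
            raise InvalidConfigError("generations_per_year must be positive")
        t /= generations_per_year
    return t


def round_to_hundred(years: float) -> int:
    return int(round(years / 100.0)) * 100


@dataclass(frozen=True)
class ClockParams:
    """Inputs of the domestication-time computation.

    ``theta`` and ``tau`` come from coalescent analysis of the
    wild/domestic split; ``mu_gen`` is the trio-measured per-generation
    rate; ``generations_per_year`` defaults to 3 (reared silkworm).
    """

    theta: float = 0.034
    tau: float = 0.0035
    mu_gen: float = 0.41e-8
    generations_per_year: float = 3.0

    def __post_init__(self) -> None:
        for name in ("theta", "tau", "mu_gen", "generations_per_year"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")

    @property
    def mu_year(self) -> float:
        return per_year_rate(self.mu_gen, self.generations_per_year)

    @property
    def ne(self) -> float:
        """Effective population size from the per-year rate."""
        return effective_population_size(self.theta, self.mu_year)

    @property
    def divergence_time(self) -> float:
        """Divergence time in years (per-year pathway)."""
        return divergence_time_years(self.tau, self.ne)


def clock_report(
    params: ClockParams,
    mu_ci: tuple[float, float] | None = None,
) -> dict:
    """Structured clock report: per-year rate, Ne and divergence time.

    With a (lo, hi) CI on the per-generation rate the report also carries
    the time interval obtained by recomputing at both bounds; T is
    monotone decreasing in mu, so the upper rate bound gives the earlier
    (smaller) time.
    """
    report = {
        "theta": params.theta,
        "tau": params.tau,
        "mu_gen": params.mu_gen,
        "generations_per_year": params.generations_per_year,
        "mu_year": params.mu_year,
        "ne": params.ne,
        "divergence_time_years": params.divergence_time,
        "divergence_time_rounded": round_to_hundred(params.divergence_time),
    }
    if mu_ci is not None:
        lo, hi = mu_ci
        if not 0 < lo <= hi:
            raise InvalidConfigError("mu CI must satisfy 0 < lo <= hi")
        t_at = [
            ClockParams(
                theta=params.theta,
                tau=params.tau,
                mu_gen=bound,
                generations_per_year=params.generations_per_year,
            ).divergence_time
            for bound in (lo, hi)
        ]
        report["divergence_time_ci"] = (min(t_at), max(t_at))
    return report
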