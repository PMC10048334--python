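"""Mutation-rate estimation with bootstrap confidence intervals.

The per-offspring rate is ``m_i / (2 * C_i)`` where ``m_i`` is the number
of de novo mutations called in offspring *i* and ``C_i`` its callable-site
count (the factor 2 counts both chromosome copies of a diploid site). The
family mean is the unweighted mean of per-offspring rates; its 95% CI is a
percentile bootstrap: B resamples of the n offspring with replacement, the
mean of each resample recorded, the B estimates sorted ascending, and the
values at the 2.5% and 97.5% order-statistic positions (the 25th and 975th
of 1000) taken as the interval bounds.

:class:`MutationRateModel` packages these pieces statsmodels-style: build
the model from calls plus callable masks, ``fit()`` it, and read the
estimates (whole genome, per region, per base class, per mutation type)
off the returned :class:`MutationRateResults`, whose ``summary()`` prints
rates in units of 1e-9 per site per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallableMask, DnmCall
from .exceptions import (
    InsufficientReplicatesError,
    MalformedInputError,
    UndefinedRateError,
    UndefinedTestError,
)
from .strata import split_stratum, STRATA


def per_offspring_rate(m: int, callable_sites: int) -> float:
    """Per-site per-generation rate for one offspring: m / (2 * callable)."""
    if callable_sites <= 0:
        raise UndefinedRateError("callable-site count must be positive")
    if m < 0:
        raise MalformedInputError("mutation count cannot be negative")
    return m / (2.0 * callable_sites)


def bootstrap_ci(
    values: Sequence[float],
    b: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the mean of per-offspring rates.

    Returns ``(mean, lo, hi)`` where lo/hi are the 2.5%/97.5% order
    statistics (1-based positions ``round(0.025*b)`` and ``round(0.975*b)``,
    i.e. the 25th and 975th of 1000 sorted estimates).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise MalformedInputError("bootstrap_ci needs at least one value")
    if b < 40:
        raise InsufficientReplicatesError(
            f"need at least 40 bootstrap replicates for 2.5% tails, got {b}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    n = values.size
    resamples = values[rng.integers(0, n, size=(b, n))]
    estimates = np.sort(resamples.mean(axis=1))
    lo_pos = max(int(round(0.025 * b)), 1)
    hi_pos = min(int(round(0.975 * b)), b)
    return float(values.mean()), float(estimates[lo_pos - 1]), float(estimates[hi_pos - 1])


def compare_conditions(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    method: str = "t",
    equal_var: bool = False,
) -> float:
    """Two-sided p-value comparing observed per-offspring rates.

    ``method="t"`` runs a two-sample t-test (Welch by default, matching R's
    ``t.test``; set ``equal_var=True`` for the pooled-variance flavour);
    ``method="wilcoxon"`` runs the Wilcoxon rank-sum test. Tests act on the
    observed rates, never on bootstrap estimates. Two identical constant
    groups are defined to give p = 1.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedTestError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    elif method == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise UndefinedTestError(f"unknown method {method!r}")
    return float(res.pvalue)


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    dof: int
    expected: np.ndarray
    low_expected_warning: bool


def cross_species_test(
    species_counts: Sequence[tuple[int, int]],
) -> Chi2Result:
    """Chi-square homogeneity test of mutant vs non-mutant site counts.

    Each entry is ``(mutant_count, diploid_callable_total)``; the test
    compares observed mutant counts across species against the null of a
    shared (discrete uniform) mutation probability. The statistic is the
    plain ``sum((O-E)^2 / E)`` without continuity correction. A result
    with any expected cell below 1 carries a warning flag.
    """
    if len(species_counts) < 2:
        raise UndefinedTestError("need at least two species")
    table = []
    for m, total in species_counts:
        if not 0 <= m < total:
            raise MalformedInputError(
                "each species needs 0 <= mutants < callable total"
            )
        table.append([m, total - m])
    table = np.asarray(table, dtype=float)
    statistic, pvalue, dof, expected = stats.chi2_contingency(table, correction=False)
    return Chi2Result(
        statistic=float(statistic),
        pvalue=float(pvalue),
        dof=int(dof),
        expected=expected,
        low_expected_warning=bool((expected < 1).any()),
    )


def chromosome_distribution_test(
    calls: Iterable[DnmCall] | pd.DataFrame,
    chrom_lengths: Mapping[str, int],
) -> float:
    """K-S test of DNM positions against a genome-wide uniform distribution.

    Positions are mapped onto [0, 1) through the cumulative chromosome
    offsets (so the null weights each chromosome by its length) and tested
    with a one-sample Kolmogorov-Smirnov test.
    """
    frame = calls if isinstance(calls, pd.DataFrame) else pd.DataFrame(
        [{"chrom": c.chrom, "pos": c.pos} for c in calls]
    )
    if len(frame) < 5:
        raise UndefinedTestError("need at least 5 calls for the K-S test")
    offsets = {}
    running = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = running
        running += int(length)
    try:
        mapped = np.array(
            [
                (offsets[c] + p - 0.5) / running
                for c, p in zip(frame["chrom"], frame["pos"])
            ]
        )
    except KeyError as exc:
        raise MalformedInputError(f"call on unknown chromosome {exc}") from exc
    return float(stats.kstest(mapped, "uniform").pvalue)


@dataclass
class RateEstimate:
    """Mean rate and bootstrap CI for one (condition, stratum) cell."""

    condition: str
    stratum: str
    per_offspring: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_offspring: int
    m_total: int
    diploid_callable_total: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise MalformedInputError("CI must bracket the mean")


#: Strata reported by the model, in summary order.
REPORTED_STRATA = (
    "whole_genome", "gene", "intergenic", "AT", "CG",
)


class MutationRateModel:
    """Per-offspring mutation-rate model for one family/condition.

    Parameters
    ----------
    counts
        DataFrame indexed by offspring with one column per stratum holding
        DNM counts. Strata: ``whole_genome``, ``gene``, ``intergenic``,
        ``AT``, ``CG``, plus one column per observed mutation type.
    callable_sites
        DataFrame with the same index holding callable-site counts for
        ``whole_genome``, ``gene``, ``intergenic``, ``AT`` and ``CG``
        (mutation-type rates use the origin base class's denominator).
    condition
        Label used in summaries and comparisons.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        callable_sites: pd.DataFrame,
        condition: str = "condition",
    ) -> None:
        if not counts.index.equals(callable_sites.index):
            raise MalformedInputError("counts and callable_sites must share an index")
        if len(counts) == 0:
            raise MalformedInputError("model needs at least one offspring")
        self.counts = counts
        self.callable_sites = callable_sites
        self.condition = condition

    # -- construction -------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        calls: Iterable[DnmCall] | pd.DataFrame,
        callable_masks: Mapping[str, CallableMask],
        condition: str = "condition",
    ) -> "MutationRateModel":
        """Build a model from DNM calls plus per-offspring callable masks."""
        frame = calls if isinstance(calls, pd.DataFrame) else pd.DataFrame(
            [c.__dict__ for c in calls],
            columns=["chrom", "pos", "ref", "alt", "offspring_id", "genotype",
                     "region", "base_class", "in_cpg_island", "mutation_type"],
        )
        offspring = list(callable_masks)
        types = sorted(frame["mutation_type"].dropna().unique()) if len(frame) else []
        count_cols = list(REPORTED_STRATA) + types
        counts = pd.DataFrame(0, index=offspring, columns=count_cols, dtype=int)
        for _, call in frame.iterrows():
            child = call["offspring_id"]
            if child not in counts.index:
                raise MalformedInputError(f"call for unknown offspring {child!r}")
            counts.loc[child, "whole_genome"] += 1
            if isinstance(call.get("region"), str):
                counts.loc[child, call["region"]] += 1
            if isinstance(call.get("base_class"), str):
                counts.loc[child, call["base_class"]] += 1
            if isinstance(call.get("mutation_type"), str):
                counts.loc[child, call["mutation_type"]] += 1
        callable_sites = pd.DataFrame(
            {
                "whole_genome": [callable_masks[o].total for o in offspring],
                "gene": [callable_masks[o].by_region["gene"] for o in offspring],
                "intergenic": [callable_masks[o].by_region["intergenic"] for o in offspring],
                "AT": [callable_masks[o].by_base_class["AT"] for o in offspring],
                "CG": [callable_masks[o].by_base_class["CG"] for o in offspring],
            },
            index=offspring,
        )
        return cls(counts, callable_sites, condition=condition)

    # -- estimation ----------------------------------------------------

    def _denominator_column(self, stratum: str) -> str:
        if stratum in self.callable_sites.columns:
            return stratum
        # mutation types draw their denominator from the origin base class
        if stratum.startswith("A:T"):
            return "AT"
        if stratum.startswith("G:C"):
            return "CG"
        raise MalformedInputError(f"no callable denominator for stratum {stratum!r}")

    def observed_rates(self, stratum: str = "whole_genome") -> np.ndarray:
        """Per-offspring observed rates for one stratum."""
        if stratum not in self.counts.columns:
            raise MalformedInputError(f"unknown stratum {stratum!r}")
        denom = self.callable_sites[self._denominator_column(stratum)].to_numpy()
        if (denom <= 0).any():
            raise UndefinedRateError(f"zero callable sites in stratum {stratum!r}")
        return self.counts[stratum].to_numpy() / (2.0 * denom)

    def fit(self, b: int = 1000, seed: int | None = 0) -> "MutationRateResults":
        """Estimate mean rates and percentile-bootstrap CIs for all strata."""
        rng = np.random.default_rng(seed)
        estimates: dict[str, RateEstimate] = {}
        for stratum in self.counts.columns:
            rates = self.observed_rates(stratum)
            mean, lo, hi = bootstrap_ci(rates, b=b, rng=rng)
            denom_col = self._denominator_column(stratum)
            estimates[stratum] = RateEstimate(
                condition=self.condition,
                stratum=stratum,
                per_offspring=rates,
                mean=mean,
                ci_low=lo,
                ci_high=hi,
                n_offspring=len(rates),
                m_total=int(self.counts[stratum].sum()),
                diploid_callable_total=int(2 * self.callable_sites[denom_col].sum()),
            )
        return MutationRateResults(self, estimates, b=b)


class MutationRateResults:
    """Fitted rates: point estimates, bootstrap CIs and comparisons."""

    def __init__(
        self,
        model: MutationRateModel,
        estimates: dict[str, RateEstimate],
        b: int,
    ) -> None:
        self.model = model
        self.estimates = estimates
        self.b = b

    @property
    def condition(self) -> str:
        return self.model.condition

    def __getitem__(self, stratum: str) -> RateEstimate:
        return self.estimates[stratum]

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "condition": e.condition,
                "stratum": e.stratum,
                "mean": e.mean,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "n_offspring": e.n_offspring,
                "m_total": e.m_total,
                "diploid_callable_total": e.diploid_callable_total,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def compare(
        self,
        other: "MutationRateResults",
        stratum: str = "whole_genome",
        method: str = "t",
        equal_var: bool = False,
    ) -> float:
        """p-value for a between-condition difference in observed rates."""
        return compare_conditions(
            self.estimates[stratum].per_offspring,
            other.estimates[stratum].per_offspring,
            method=method,
            equal_var=equal_var,
        )

    def plot_estimates(self, strata: Sequence[str] | None = None, ax=None, scale: float = 1e-9):
        """Error-bar plot of stratum means with bootstrap CIs.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if strata is None:
            strata = [s for s in REPORTED_STRATA if s in self.estimates]
        if ax is None:
            _, ax = plt.subplots(figsize=(1.2 * len(strata) + 2, 4))
        means = np.array([self.estimates[s].mean for s in strata]) / scale
        lows = np.array([self.estimates[s].ci_low for s in strata]) / scale
        highs = np.array([self.estimates[s].ci_high for s in strata]) / scale
        x = np.arange(len(strata))
        ax.errorbar(
            x, means, yerr=[means - lows, highs - means],
            fmt="o", capsize=4, color="k",
        )
        ax.set_xticks(x)
        ax.set_xticklabels(strata, rotation=30, ha="right")
        ax.set_ylabel(f"mutation rate (x{scale:.0e} /site/generation)")
        ax.set_title(self.condition)
        return ax

    def summary(self, scale: float = 1e-9) -> str:
        """Text table of rates in units of ``scale`` (default 1e-9)."""
        lines = [
            f"Mutation rate estimates - {self.condition}",
            f"(percentile bootstrap, B={self.b}; rates x {scale:.0e} per site per generation)",
            "",
            f"{'stratum':<16}{'mean':>8}{'2.5% CI':>10}{'97.5% CI':>10}{'m':>6}{'n':>5}",
        ]
        for stratum, e in self.estimates.items():
            lines.append(
                f"{stratum:<16}{e.mean / scale:>8.2f}{e.ci_low / scale:>10.2f}"
                f"{e.ci_high / scale:>10.2f}{e.m_total:>6d}{e.n_offspring:>5d}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        wg = self.estimates.get("whole_genome")
        if wg is None:
            return f"<MutationRateResults {self.condition}>"
        return (
            f"<MutationRateResults {self.condition}: "
            f"{wg.mean:.3g} ({wg.ci_low:.3g}-{wg.ci_high:.3g})>"
        )
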