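"""Mutation-spectrum analysis: six strand-collapsed substitution classes,
transition/transversion ratio, CpG-island association and flank context.

A single-nucleotide substitution and its reverse complement describe the
same event on the double helix, so substitutions are collapsed into six
classes written origin-pair -> result-pair (e.g. ``G:C->A:T`` covers C->T
and G->A). Transitions are C<->T and G<->A; everything else is a
transversion. Under a substitution model with no bias each class holds
1/6 of mutations and Ts/Tv = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConsistencyError,
    MalformedInputError,
    UndefinedRateError,
    UndefinedTestError,
)
from .strata import COMPLEMENT, base_class_of

#: The six strand-collapsed substitution classes, in conventional order.
SIX_TYPES = (
    "A:T->C:G",
    "A:T->G:C",
    "A:T->T:A",
    "G:C->A:T",
    "G:C->C:G",
    "G:C->T:A",
)

TRANSITION_TYPES = ("A:T->G:C", "G:C->A:T")

_PYRIMIDINE_LABEL = {
    # pyrimidine-reference canonical key -> class label
    ("T", "C"): "A:T->G:C",
    ("T", "G"): "A:T->C:G",
    ("T", "A"): "A:T->T:A",
    ("C", "T"): "G:C->A:T",
    ("C", "A"): "G:C->T:A",
    ("C", "G"): "G:C->C:G",
}


def classify_mutation(ref: str, alt: str) -> tuple[str, str]:
    """Classify a substitution into its strand-collapsed class and Ts/Tv.

    Examples
    --------
    >>> classify_mutation("C", "T")
    ('G:C->A:T', 'Ts')
    >>> classify_mutation("T", "G")
    ('A:T->C:G', 'Tv')
    """
    ref, alt = ref.upper(), alt.upper()
    for base in (ref, alt):
        if base not in "ACGT":
            raise MalformedInputError(f"unsupported base {base!r}")
    if ref == alt:
        raise MalformedInputError("ref and alt must differ")
    if ref in "AG":  # collapse to the pyrimidine-reference strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = _PYRIMIDINE_LABEL[(ref, alt)]
    return label, "Ts" if label in TRANSITION_TYPES else "Tv"


@dataclass
class SpectrumCounts:
    """Counts and conditional rates of the six substitution classes."""

    counts: dict[str, int]
    callable_at: int
    callable_cg: int

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def ts(self) -> int:
        return int(sum(self.counts[t] for t in TRANSITION_TYPES))

    @property
    def tv(self) -> int:
        return self.total - self.ts

    @property
    def ts_tv(self) -> float:
        if self.tv == 0:
            raise UndefinedRateError("no transversions observed; Ts/Tv undefined")
        return self.ts / self.tv

    def proportions(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise UndefinedRateError("no mutations observed")
        return {t: self.counts[t] / total for t in SIX_TYPES}

    def rates(self) -> dict[str, float]:
        """Per-type conditional rates: count / (2 x origin-class callable)."""
        if self.callable_at <= 0 or self.callable_cg <= 0:
            raise UndefinedRateError("need positive callable totals for both classes")
        out = {}
        for t in SIX_TYPES:
            denom = self.callable_at if t.startswith("A:T") else self.callable_cg
            out[t] = self.counts[t] / (2.0 * denom)
        return out

    def class_rates(self) -> dict[str, float]:
        rates = self.rates()
        return {
            "AT": sum(rates[t] for t in SIX_TYPES if t.startswith("A:T")),
            "CG": sum(rates[t] for t in SIX_TYPES if t.startswith("G:C")),
        }


def _calls_frame(calls) -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "mutation_type": getattr(c, "mutation_type", None),
                "in_cpg_island": getattr(c, "in_cpg_island", None),
            }
            for c in calls
        ]
    )


def spectrum_summary(calls, callable_mask) -> SpectrumCounts:
    """Tally the six classes and their conditional rates.

    ``callable_mask`` may be a :class:`~triomut.calling.CallableMask`
    (or any object with ``by_base_class``), or a mapping with ``"AT"`` and
    ``"CG"`` callable totals summed over offspring.
    """
    frame = _calls_frame(calls)
    counts = {t: 0 for t in SIX_TYPES}
    for _, row in frame.iterrows():
        label = row.get("mutation_type")
        if not isinstance(label, str):
            label, _ = classify_mutation(row["ref"], row["alt"])
        if label not in counts:
            raise MalformedInputError(f"unknown mutation type {label!r}")
        counts[label] += 1
    by_class = (
        callable_mask.by_base_class
        if hasattr(callable_mask, "by_base_class")
        else dict(callable_mask)
    )
    return SpectrumCounts(
        counts=counts,
        callable_at=int(by_class["AT"]),
        callable_cg=int(by_class["CG"]),
    )


@dataclass
class ProportionTestResult:
    observed_proportion: float
    expected_proportion: float
    statistic: float
    pvalue: float
    n_calls: int


def cpg_island_association(
    calls,
    annotation=None,
    expected_fraction: float = 0.10,
    mutation_type: str | None = "G:C->A:T",
) -> ProportionTestResult:
    """Test whether C:G->T:A-class mutations concentrate in CpG islands.

    Compares the observed fraction of qualifying calls inside CpG islands
    against the fraction expected under a length-weighted uniform null
    (the islands' genome share, ~10%), using a chi-square proportion test
    with continuity correction (the behaviour of R's ``prop.test``).

    ``annotation`` supplies island membership when the calls do not carry
    an ``in_cpg_island`` annotation already.
    """
    frame = _calls_frame(calls)
    if mutation_type is not None and "mutation_type" in frame.columns:
        frame = frame[frame["mutation_type"] == mutation_type]
    if len(frame) == 0:
        raise UndefinedTestError("no qualifying calls for the CpG-island test")
    if not 0 < expected_fraction < 1:
        raise UndefinedTestError("expected_fraction must be in (0, 1)")
    if "in_cpg_island" in frame.columns and frame["in_cpg_island"].notna().all():
        in_cpg = frame["in_cpg_island"].astype(bool).to_numpy()
    elif annotation is not None:
        in_cpg = np.zeros(len(frame), dtype=bool)
        for i, (_, row) in enumerate(frame.iterrows()):
            in_cpg[i] = bool(
                annotation.contains("cpg_islands", row["chrom"], np.array([row["pos"] - 1]))[0]
            )
    else:
        raise MalformedInputError(
            "calls lack in_cpg_island annotation and no annotation was given"
        )
    k = int(in_cpg.sum())
    n = len(frame)
    statistic, pvalue = proportion_test(k, n, expected_fraction)
    return ProportionTestResult(
        observed_proportion=k / n,
        expected_proportion=expected_fraction,
        statistic=statistic,
        pvalue=pvalue,
        n_calls=n,
    )


def proportion_test(k: int, n: int, p0: float, correction: bool = True) -> tuple[float, float]:
    """One-sample proportion test (chi-square with Yates continuity
    correction), matching R's ``prop.test(k, n, p=p0)``."""
    if n <= 0 or not 0 <= k <= n:
        raise MalformedInputError("need 0 <= k <= n with n > 0")
    expected = n * p0
    diff = abs(k - expected)
    if correction:
        diff = max(diff - 0.5, 0.0)
    statistic = diff**2 / (n * p0 * (1 - p0))
    pvalue = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), pvalue


@dataclass
class ContextMatrix:
    """Base frequencies at positions -flank..+flank around mutated sites.

    The matrix is oriented so the mutated base reads C: windows around a
    G reference are reverse-complemented before tallying. Rows index the
    bases A, C, G, T; columns index the relative positions.
    """

    matrix: np.ndarray  # (4, 2*flank + 1) frequencies
    flank: int
    n_used: int
    n_dropped: int

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def frequency(self, base: str, offset: int) -> float:
        row = "ACGT".index(base.upper())
        col = offset + self.flank
        return float(self.matrix[row, col])

    def cg_dinucleotide_fraction(self) -> float:
        """Fraction of mutated C's followed by G (the CpG-site fraction)."""
        return self.frequency("G", 1)


def context_matrix(calls, reference, flank: int = 10, mutation_type: str | None = "G:C->A:T") -> ContextMatrix:
    """Per-position base frequencies in the flanks of mutated sites.

    Calls closer than ``flank`` bases to a contig end are dropped with a
    warning. A call whose recorded reference base disagrees with the
    reference sequence raises :class:`ConsistencyError`.
    """
    frame = _calls_frame(calls)
    if mutation_type is not None and "mutation_type" in frame.columns:
        frame = frame[frame["mutation_type"] == mutation_type]
    if len(frame) == 0:
        raise MalformedInputError("no calls to build a context matrix from")
    width = 2 * flank + 1
    tallies = np.zeros((4, width), dtype=np.int64)
    used = dropped = 0
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    for _, row in frame.iterrows():
        codes = reference.codes[row["chrom"]]
        pos0 = int(row["pos"]) - 1
        ref_base = "ACGT"[codes[pos0]]
        if ref_base != row["ref"]:
            raise ConsistencyError(
                f"reference mismatch at {row['chrom']}:{row['pos']}: "
                f"call says {row['ref']}, sequence says {ref_base}"
            )
        if pos0 - flank < 0 or pos0 + flank >= len(codes):
            dropped += 1
            continue
        window = codes[pos0 - flank : pos0 + flank + 1]
        if ref_base == "G":  # orient so the mutated base is C
            window = comp[window][::-1]
        elif ref_base != "C":
            raise MalformedInputError(
                "context_matrix expects C:G-class calls; filter by mutation_type"
            )
        tallies[window, np.arange(width)] += 1
        used += 1
    if dropped:
        warnings.warn(
            f"dropped {dropped} call(s) within {flank} bp of a contig end",
            stacklevel=2,
        )
    if used == 0:
        raise MalformedInputError("all calls fell too close to contig ends")
    return ContextMatrix(
        matrix=tallies / used, flank=flank, n_used=used, n_dropped=dropped
    )
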