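"""Caller calibration: spike-in false-negative estimation and
confirmation arithmetic.

False negatives are measured by injecting synthetic heterozygous
mutations into the site table: at a spiked site with depth ``x`` the
number of reads switched to a random non-reference base is drawn
``y ~ Binomial(x, 1/2)`` — the allele-balance law of a true heterozygote
— and the full calling pipeline is re-run. The fraction of spikes the
caller fails to recover is the false-negative rate. True-positive rates
come from independent (e.g. Sanger) confirmation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallResult, DnmCall, FamilyLayout
from .exceptions import (
    InvalidConfigError,
    MalformedInputError,
    UndefinedCorrectionError,
)
from .strata import BASES

LEDGER_COLUMNS = ["chrom", "pos", "offspring_id", "x", "y", "alt"]


@dataclass
class SpikeInLedger:
    """Record of injected synthetic mutations.

    One entry per spiked site: location, targeted offspring, pre-spike
    depth ``x``, injected alternate reads ``y`` and the injected base.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        e = self.entries
        if list(e.columns) != LEDGER_COLUMNS:
            raise MalformedInputError(f"ledger needs columns {LEDGER_COLUMNS}")
        if ((e["y"] < 0) | (e["y"] > e["x"])).any():
            raise MalformedInputError("ledger requires 0 <= y <= x")
        if e.duplicated(subset=["chrom", "pos"]).any():
            raise MalformedInputError("one ledger entry per spiked site")

    @property
    def n(self) -> int:
        return len(self.entries)

    def keys(self) -> set[tuple[str, int, str]]:
        return set(
            zip(
                self.entries["chrom"],
                self.entries["pos"].astype(int),
                self.entries["offspring_id"],
            )
        )


def spike_in(
    site_table: pd.DataFrame,
    layout: FamilyLayout,
    n_sites: int = 1000,
    seed: int | None = 0,
    exclude_variant_sites: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SpikeInLedger]:
    """Inject synthetic heterozygous mutations into a site table.

    Each spike picks a random site and a random offspring, draws
    ``y ~ Binomial(x, 1/2)`` alternate reads out of the offspring's depth
    ``x`` and switches them to a uniformly chosen non-reference base,
    setting the offspring's genotype heterozygous (the site-table
    equivalent of re-genotyping realigned spiked reads). The input table
    is not modified; a spiked copy plus the ledger are returned.

    Spiked sites may by chance be non-callable (low depth / MQ); they stay
    in the denominator, since recovery is judged after the full pipeline.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if exclude_variant_sites:
        eligible = site_table.index[site_table["alt"].fillna("") == ""]
    else:
        eligible = site_table.index
    if n_sites > len(eligible):
        raise InvalidConfigError(
            f"cannot spike {n_sites} sites; only {len(eligible)} eligible"
        )
    chosen = rng.choice(np.asarray(eligible), size=n_sites, replace=False)
    children = np.asarray(layout.offspring)[rng.integers(0, len(layout.offspring), n_sites)]

    modified = site_table.copy()
    entries = []
    for row_idx, child in zip(chosen, children):
        row = site_table.loc[row_idx]
        x = int(row[f"DP_{child}"])
        y = int(rng.binomial(x, 0.5))
        ref = row["ref"]
        alt_choices = [b for b in BASES if b != ref]
        alt = alt_choices[rng.integers(0, 3)]
        modified.loc[row_idx, "alt"] = alt
        modified.loc[row_idx, f"GT_{child}"] = "0/1"
        modified.loc[row_idx, f"AD_{child}"] = y
        entries.append(
            {
                "chrom": row["chrom"],
                "pos": int(row["pos"]),
                "offspring_id": child,
                "x": x,
                "y": y,
                "alt": alt,
            }
        )
    ledger = SpikeInLedger(pd.DataFrame(entries, columns=LEDGER_COLUMNS))
    return modified, ledger


def false_negative_rate(ledger: SpikeInLedger, recalled_calls) -> float:
    """Percent of spiked mutations the pipeline failed to recover.

    ``recalled_calls`` may be a :class:`~triomut.calling.CallResult`, a
    list of calls or a calls DataFrame. Reported as a percentage rounded
    to one decimal (914/1000 recovered -> 8.6).
    """
    if ledger.n == 0:
        raise MalformedInputError("empty spike-in ledger")
    if isinstance(recalled_calls, CallResult):
        calls = recalled_calls.calls
    elif isinstance(recalled_calls, pd.DataFrame):
        calls = [
            DnmCall(chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"],
                    alt=r["alt"], offspring_id=r["offspring_id"])
            for _, r in recalled_calls.iterrows()
        ]
    else:
        calls = list(recalled_calls)
    recovered_keys = {(c.chrom, c.pos, c.offspring_id) for c in calls}
    recovered = sum(1 for key in ledger.keys() if key in recovered_keys)
    return round(100.0 * (1.0 - recovered / ledger.n), 1)


def positive_rate(n_confirmed: int, n_tested: int) -> int:
    """Confirmation (true-positive) rate as a whole percent.

    79 confirmed of 84 tested -> 94.
    """
    if n_tested < 1:
        raise MalformedInputError("need at least one tested candidate")
    if not 0 <= n_confirmed <= n_tested:
        raise MalformedInputError("need 0 <= confirmed <= tested")
    return round(100.0 * n_confirmed / n_tested)


def corrected_rate(raw_rate: float, tp_rate: float, fn_rate: float) -> float:
    """Optionally correct a raw rate for false positives and negatives.

    ``corrected = raw * tp / (1 - fn)`` with ``tp`` and ``fn`` as
    fractions. The headline estimates are reported uncorrected; this is
    an opt-in adjustment.
    """
    if not 0 < tp_rate <= 1:
        raise MalformedInputError("tp_rate must be in (0, 1]")
    if not 0 <= fn_rate < 1:
        if fn_rate == 1:
            raise UndefinedCorrectionError("fn_rate of 1 leaves no signal to correct")
        raise MalformedInputError("fn_rate must be in [0, 1)")
    return raw_rate * tp_rate / (1.0 - fn_rate)
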