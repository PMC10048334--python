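"""De novo mutation calling from a parents-progeny site table.

A *de novo* mutation (DNM) is a single-nucleotide variant carried
heterozygously by exactly one offspring of a full-sib family and absent
from both parents. Candidate sites are screened with five quality rules
before a call is accepted:

1. offspring read depth >= 10 and site mapping quality >= 20;
2. the upstream caller did not flag the site as low quality;
3. alternate-allele reads make up at least 30% of the offspring's depth;
4. no supporting read carries more than 2 non-reference sites;
5. both parents are homozygous reference with zero alternate reads and
   depth >= 10.

Every excluded candidate is recorded with the first rule it failed, so the
rejection ledger partitions all candidates into accepted and rejected.
The callable-site counter applies the depth/quality rules symmetrically to
define the rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MalformedInputError, MalformedRecordError
from .strata import REGIONS, base_class_of, split_stratum, stratum_code, STRATA

# Rejection reason codes, in evaluation order.
REASON_SHARED = "shared_across_offspring"
REASON_NON_HET = "non_heterozygous"
REASON_LOW_DEPTH = "low_depth"
REASON_LOW_MQ = "low_mq"
REASON_CALLER_LQ = "caller_low_quality"
REASON_LOW_ALT_FRACTION = "low_alt_fraction"
REASON_MULTI_NONREF = "multi_nonref_read"
REASON_PARENT = "parent_alt_or_low_depth"

REASONS = (
    REASON_SHARED,
    REASON_NON_HET,
    REASON_LOW_DEPTH,
    REASON_LOW_MQ,
    REASON_CALLER_LQ,
    REASON_LOW_ALT_FRACTION,
    REASON_MULTI_NONREF,
    REASON_PARENT,
)

_HET_GENOTYPES = frozenset({"0/1", "1/0", "0|1", "1|0"})
_REF_GENOTYPES = frozenset({"0/0", "0|0"})


def _has_alt(genotype: str) -> bool:
    return "1" in genotype


@dataclass(frozen=True)
class FamilyLayout:
    """Names of the two parents and the offspring of one family."""

    father: str
    mother: str
    offspring: tuple[str, ...]

    def __post_init__(self) -> None:
        names = [self.father, self.mother, *self.offspring]
        if len(self.offspring) < 1:
            raise MalformedInputError("a family layout needs at least one offspring")
        if len(set(names)) != len(names):
            raise MalformedInputError("sample names in a family must be unique")

    @property
    def parents(self) -> tuple[str, str]:
        return (self.father, self.mother)

    @property
    def samples(self) -> tuple[str, ...]:
        return (self.father, self.mother, *self.offspring)


@dataclass(frozen=True)
class FilterThresholds:
    """Quality thresholds of the five screening rules."""

    min_depth: int = 10
    min_mq: float = 20.0
    min_alt_fraction: float = 0.30
    max_nonref_per_read: int = 2
    min_parent_depth: int = 10

    def __post_init__(self) -> None:
        if self.min_depth <= 0 or self.min_parent_depth <= 0:
            raise MalformedInputError("depth thresholds must be positive")
        if not 0 < self.min_alt_fraction <= 1:
            raise MalformedInputError("min_alt_fraction must be in (0, 1]")


@dataclass
class TrioSiteRecord:
    """One genomic site with per-sample evidence; the atom the filters act on.

    ``mq``, ``low_quality`` and ``max_nonref_per_read`` are site-level
    (locus) properties; genotype, depth and alternate-supporting read
    counts are per sample.
    """

    chrom: str
    pos: int
    ref: str
    alt: str | None
    mq: float
    low_quality: bool
    max_nonref_per_read: int
    genotypes: dict[str, str]
    depths: dict[str, int]
    alt_reads: dict[str, int]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise MalformedRecordError(f"position must be >= 1, got {self.pos}")
        if self.alt is not None and self.alt == self.ref:
            raise MalformedRecordError("alt base equals the reference base")
        for sample, ad in self.alt_reads.items():
            dp = self.depths.get(sample, 0)
            if not 0 <= ad <= dp:
                raise MalformedRecordError(
                    f"alt reads outside [0, depth] for {sample} at {self.chrom}:{self.pos}"
                )

    @classmethod
    def from_row(cls, row: Mapping, samples: Sequence[str]) -> "TrioSiteRecord":
        """Build a record from one site-table row (wide per-sample columns)."""
        try:
            genotypes = {s: row[f"GT_{s}"] for s in samples}
            depths = {s: int(row[f"DP_{s}"]) for s in samples}
            alt_reads = {s: int(row[f"AD_{s}"]) for s in samples}
        except KeyError as exc:
            raise MalformedRecordError(f"missing sample column {exc}") from exc
        alt = row.get("alt") or None
        return cls(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=alt,
            mq=float(row["mq"]),
            low_quality=bool(row.get("low_quality", False)),
            max_nonref_per_read=int(row.get("max_nonref_per_read", 0)),
            genotypes=genotypes,
            depths=depths,
            alt_reads=alt_reads,
        )


@dataclass(frozen=True)
class DnmCall:
    """An accepted de novo mutation."""

    chrom: str
    pos: int
    ref: str
    alt: str
    offspring_id: str
    genotype: str = "0/1"
    region: str | None = None
    base_class: str | None = None
    in_cpg_island: bool | None = None
    mutation_type: str | None = None

    def __post_init__(self) -> None:
        if self.genotype not in _HET_GENOTYPES:
            raise MalformedRecordError("a DNM call must be heterozygous")


@dataclass
class CallableMask:
    """Per-offspring callable-site counts, stratified by region x base class."""

    offspring_id: str
    by_stratum: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.by_stratum.values()))

    @property
    def by_region(self) -> dict[str, int]:
        out = {r: 0 for r in REGIONS}
        for label, n in self.by_stratum.items():
            region, _ = split_stratum(label)
            out[region] += int(n)
        return out

    @property
    def by_base_class(self) -> dict[str, int]:
        out = {"AT": 0, "CG": 0}
        for label, n in self.by_stratum.items():
            _, base_class = split_stratum(label)
            out[base_class] += int(n)
        return out


@dataclass(frozen=True)
class FilterDecision:
    accepted: bool
    reason: str | None = None


def apply_filters(
    record: TrioSiteRecord,
    offspring_id: str,
    layout: FamilyLayout,
    thresholds: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Screen one candidate site for one offspring.

    Rules are evaluated in their documented order and the first failure is
    returned as the rejection reason; a site is accepted only if all pass.
    """
    for sample in (*layout.parents, offspring_id):
        if sample not in record.genotypes or sample not in record.depths:
            raise MalformedRecordError(
                f"sample {sample!r} missing from record at {record.chrom}:{record.pos}"
            )
    dp = record.depths[offspring_id]
    if dp < thresholds.min_depth:
        return FilterDecision(False, REASON_LOW_DEPTH)
    if record.mq < thresholds.min_mq:
        return FilterDecision(False, REASON_LOW_MQ)
    if record.low_quality:
        return FilterDecision(False, REASON_CALLER_LQ)
    ad = record.alt_reads[offspring_id]
    if dp == 0 or ad / dp < thresholds.min_alt_fraction:
        return FilterDecision(False, REASON_LOW_ALT_FRACTION)
    if record.max_nonref_per_read > thresholds.max_nonref_per_read:
        return FilterDecision(False, REASON_MULTI_NONREF)
    for parent in layout.parents:
        if (
            record.genotypes[parent] not in _REF_GENOTYPES
            or record.alt_reads[parent] > 0
            or record.depths[parent] < thresholds.min_parent_depth
        ):
            return FilterDecision(False, REASON_PARENT)
    return FilterDecision(True, None)


@dataclass
class CallResult:
    """Accepted DNM calls plus the rejection ledger."""

    calls: list[DnmCall]
    rejections: pd.DataFrame

    @property
    def calls_frame(self) -> pd.DataFrame:
        cols = [
            "chrom", "pos", "ref", "alt", "offspring_id", "genotype",
            "region", "base_class", "in_cpg_island", "mutation_type",
        ]
        if not self.calls:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([c.__dict__ for c in self.calls])[cols]


def _require_columns(table: pd.DataFrame, layout: FamilyLayout) -> None:
    base = {"chrom", "pos", "ref", "alt", "mq"}
    missing = base - set(table.columns)
    if missing:
        raise MalformedInputError(f"site table missing columns {sorted(missing)}")
    for s in layout.samples:
        for prefix in ("GT", "DP", "AD"):
            if f"{prefix}_{s}" not in table.columns:
                raise MalformedRecordError(f"site table missing column {prefix}_{s}")


def call_dnms(
    site_table: pd.DataFrame,
    layout: FamilyLayout,
    annotation=None,
    thresholds: FilterThresholds = FilterThresholds(),
    strict_read_sharing: bool = False,
) -> CallResult:
    """Call de novo mutations from a site table.

    A site yields a call iff exactly one offspring carries the alternate
    allele (heterozygously), that offspring passes all five filters, and
    both parents pass the parental rule. Variants seen in two or more
    offspring are rejected as ``shared_across_offspring``.

    Parameters
    ----------
    site_table
        Wide table, one row per site, with per-sample ``GT_*``, ``DP_*``
        and ``AD_*`` columns (``AD`` counts reads supporting the site's
        alternate allele).
    annotation
        Optional :class:`~triomut.simulate.Annotation` used to annotate
        calls with region and CpG-island membership; falls back to the
        table's ``region``/``in_cpg`` columns when absent.
    strict_read_sharing
        When True, any alternate-supporting read in a non-carrier
        offspring (not only an alternate genotype) rejects the site.
    """
    from .spectrum import classify_mutation  # local import; spectrum is standalone

    _require_columns(site_table, layout)
    if site_table.duplicated(subset=["chrom", "pos"]).any():
        raise MalformedInputError("duplicate (chrom, pos) rows in site table")

    n = len(site_table)
    offspring = list(layout.offspring)
    has_alt = np.column_stack(
        [site_table[f"GT_{s}"].map(_has_alt).to_numpy() for s in offspring]
    )
    carriers = has_alt.sum(axis=1)
    candidate = carriers > 0
    if not candidate.any():
        return CallResult([], pd.DataFrame(columns=["chrom", "pos", "offspring_id", "reason"]))

    calls: list[DnmCall] = []
    rej_rows: list[tuple[str, int, str, str]] = []
    idx = np.flatnonzero(candidate)
    sub = site_table.iloc[idx]
    sub_records = sub.to_dict("records")
    for k, row in zip(idx, sub_records):
        chrom, pos = row["chrom"], int(row["pos"])
        carrier_ids = [s for j, s in enumerate(offspring) if has_alt[k, j]]
        if len(carrier_ids) > 1:
            for s in carrier_ids:
                rej_rows.append((chrom, pos, s, REASON_SHARED))
            continue
        carrier = carrier_ids[0]
        if strict_read_sharing and any(
            int(row[f"AD_{s}"]) > 0 for s in offspring if s != carrier
        ):
            rej_rows.append((chrom, pos, carrier, REASON_SHARED))
            continue
        if row[f"GT_{carrier}"] not in _HET_GENOTYPES:
            rej_rows.append((chrom, pos, carrier, REASON_NON_HET))
            continue
        if not row.get("alt"):
            raise MalformedInputError(
                f"carrier genotype without an alt allele at {chrom}:{pos}"
            )
        record = TrioSiteRecord.from_row(row, layout.samples)
        decision = apply_filters(record, carrier, layout, thresholds)
        if not decision.accepted:
            rej_rows.append((chrom, pos, carrier, decision.reason))
            continue
        region, in_cpg = _annotate_site(row, annotation)
        mutation_type, _ = classify_mutation(row["ref"], row["alt"])
        calls.append(
            DnmCall(
                chrom=chrom,
                pos=pos,
                ref=row["ref"],
                alt=row["alt"],
                offspring_id=carrier,
                genotype="0/1",
                region=region,
                base_class=base_class_of(row["ref"]),
                in_cpg_island=in_cpg,
                mutation_type=mutation_type,
            )
        )
    rejections = pd.DataFrame(rej_rows, columns=["chrom", "pos", "offspring_id", "reason"])
    return CallResult(calls, rejections)


def _annotate_site(row: Mapping, annotation) -> tuple[str | None, bool | None]:
    if annotation is not None:
        pos0 = int(row["pos"]) - 1
        in_gene = bool(annotation.contains("genes", row["chrom"], np.array([pos0]))[0])
        in_cpg = bool(annotation.contains("cpg_islands", row["chrom"], np.array([pos0]))[0])
        return ("gene" if in_gene else "intergenic"), in_cpg
    region = row.get("region")
    in_cpg = row.get("in_cpg")
    return (region if isinstance(region, str) else None,
            bool(in_cpg) if in_cpg is not None and not pd.isna(in_cpg) else None)


def count_callable(
    site_table: pd.DataFrame,
    offspring_id: str,
    layout: FamilyLayout,
    annotation=None,
    thresholds: FilterThresholds = FilterThresholds(),
    require_parent_mq: bool = True,
) -> CallableMask:
    """Count sites at which a DNM could have been detected in one offspring.

    A site is callable when the offspring and both parents have depth >=
    ``min_depth``, the site mapping quality is >= ``min_mq`` (applied to
    parents too unless ``require_parent_mq`` is False; MQ is site-level
    here so the switch only matters for externally built tables), and both
    parents are genotyped homozygous reference. Counts are stratified by
    region x reference base class.

    The site table must enumerate every site of the region of interest
    (one row per site); sparse candidate-only tables do not carry enough
    information for a denominator.
    """
    _require_columns(site_table, layout)
    if offspring_id not in layout.offspring:
        raise MalformedInputError(f"{offspring_id!r} is not an offspring of the family")
    mq_ok = site_table["mq"].to_numpy() >= thresholds.min_mq
    dp_off = site_table[f"DP_{offspring_id}"].to_numpy() >= thresholds.min_depth
    ok = mq_ok & dp_off
    for parent in layout.parents:
        ok &= site_table[f"DP_{parent}"].to_numpy() >= thresholds.min_parent_depth
        ok &= site_table[f"GT_{parent}"].isin(_REF_GENOTYPES).to_numpy()
    # site-level MQ: the parent-MQ switch is a no-op unless a table carries
    # per-sample MQ columns
    if require_parent_mq:
        for parent in layout.parents:
            col = f"MQ_{parent}"
            if col in site_table.columns:
                ok &= site_table[col].to_numpy() >= thresholds.min_mq

    if annotation is not None:
        gene = np.zeros(len(site_table), dtype=bool)
        for chrom, grp in site_table.groupby("chrom", sort=False):
            pos0 = grp["pos"].to_numpy() - 1
            gene[grp.index.to_numpy()] = annotation.contains("genes", chrom, pos0)
        region = np.where(gene, "gene", "intergenic")
    elif "region" in site_table.columns:
        region = site_table["region"].to_numpy()
    else:
        raise MalformedInputError(
            "count_callable needs an annotation or a 'region' column"
        )
    base_class = site_table["ref"].map(base_class_of).to_numpy()

    by_stratum = {label: 0 for label in STRATA}
    for label in STRATA:
        reg, bc = split_stratum(label)
        by_stratum[label] = int(np.sum(ok & (region == reg) & (base_class == bc)))
    return CallableMask(offspring_id=offspring_id, by_stratum=by_stratum)
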