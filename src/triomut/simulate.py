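"""Synthetic full-sib trio experiments with known ground truth.

This module generates a complete parents-progeny sequencing experiment in
silico: a random reference genome, gene and CpG-island annotation tracks,
true de novo mutations (DNMs) placed at configurable per-stratum rates,
and per-site read evidence (depth, alternate-supporting reads, mapping
quality) for two parents and N offspring. Every downstream stage of the
pipeline can therefore be benchmarked against a known truth set.

Generative model
----------------
* Parents are homozygous reference everywhere (optional standing
  heterozygosity exercises the parental filter).
* Each offspring acquires a heterozygous DNM at a diploid site with
  probability ``2 * mu`` per generation, where ``mu`` is the per-site
  per-generation rate of the site's stratum (base class x region).
* Per-sample per-site depth is Poisson with mean ``mean_depth`` (~30x by
  default), optionally negative-binomial when overdispersion is requested.
* At a true heterozygous site the alternate-supporting read count is
  Binomial(depth, 1/2).
* Each read is miscalled with probability ``seq_error_rate``, uniformly to
  one of the three non-reference bases.
* Mapping quality is a site-level draw; a configurable fraction of loci
  (2% by default) falls below the MQ 20 threshold.

Two emission modes produce identically distributed data. The *dense* mode
materialises one row per genomic site and is meant for small genomes; the
*sparse* mode emits only variant-carrying rows and derives the callable
denominators by drawing the rare disqualifying events (low depth, low MQ)
as Binomial(L, p) site sets, which is exact in distribution and scales to
multi-megabase genomes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .calling import CallableMask, FamilyLayout
from .exceptions import InvalidConfigError
from .strata import (
    BASES,
    N_STRATA,
    STRATA,
    stratum_codes,
    stratum_label,
)

#: Default per-stratum DNM rates (per site per generation): the study's
#: normal-condition per-base-class rates, uniform across regions.
DEFAULT_MU: dict[str, float] = {
    "intergenic:AT": 3.60e-9,
    "gene:AT": 3.60e-9,
    "intergenic:CG": 4.58e-9,
    "gene:CG": 4.58e-9,
}

_GENE_BLOCK = 10_000
_CPG_BLOCK = 1_000
_DENSE_CELL_LIMIT = 20_000_000  # sites x samples guard for the dense mode


@dataclass
class SimulationConfig:
    """Parameters of one synthetic trio experiment.

    ``mu_true`` maps stratum labels (``"gene:AT"`` etc.) to per-site
    per-generation DNM rates; a bare float applies uniformly.
    """

    genome_length: int = 1_000_000
    n_chromosomes: int = 4
    gc_content: float = 0.38
    gene_fraction: float = 0.40
    cpg_island_fraction: float = 0.10
    n_offspring: int = 30
    mean_depth: float = 30.0
    depth_dispersion: float | None = None
    seq_error_rate: float = 1e-3
    mu_true: Mapping[str, float] | float = field(default_factory=lambda: dict(DEFAULT_MU))
    low_mq_fraction: float = 0.02
    low_quality_fraction: float = 0.001
    multi_nonref_fraction: float = 0.001
    parent_het_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise InvalidConfigError("genome_length must be positive")
        if self.n_chromosomes < 1 or self.genome_length < self.n_chromosomes:
            raise InvalidConfigError("need genome_length >= n_chromosomes >= 1")
        for name in ("gc_content", "gene_fraction", "cpg_island_fraction",
                     "low_mq_fraction", "low_quality_fraction",
                     "multi_nonref_fraction", "parent_het_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_offspring < 1:
            raise InvalidConfigError("n_offspring must be >= 1")
        if self.mean_depth <= 0:
            raise InvalidConfigError("mean_depth must be positive")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise InvalidConfigError("seq_error_rate must be in [0, 1)")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise InvalidConfigError("depth_dispersion must be positive when set")
        for label, mu in self.mu_by_stratum().items():
            if not 0.0 <= mu <= 1e-4:
                raise InvalidConfigError(
                    f"mu_true[{label!r}] must be in [0, 1e-4], got {mu}"
                )

    def mu_by_stratum(self) -> dict[str, float]:
        if isinstance(self.mu_true, (int, float)):
            return {label: float(self.mu_true) for label in STRATA}
        mu = {label: 0.0 for label in STRATA}
        for label, value in self.mu_true.items():
            if label not in mu:
                raise InvalidConfigError(f"unknown stratum {label!r} in mu_true")
            mu[label] = float(value)
        return mu

    def layout(self) -> FamilyLayout:
        return FamilyLayout(
            father="father",
            mother="mother",
            offspring=tuple(f"o{i + 1:02d}" for i in range(self.n_offspring)),
        )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Reference:
    """Integer-coded reference sequences (0=A, 1=C, 2=G, 3=T)."""

    codes: dict[str, np.ndarray]

    @property
    def chroms(self) -> list[str]:
        return list(self.codes)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.codes.items()}

    @property
    def total_length(self) -> int:
        return int(sum(len(a) for a in self.codes.values()))

    def sequence(self, chrom: str) -> str:
        lut = np.frombuffer(BASES.encode(), dtype="S1")
        return lut[self.codes[chrom]].tobytes().decode()

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return BASES[self.codes[chrom][pos - 1]]

    def gc_fraction(self) -> float:
        gc = sum(int(((a == 1) | (a == 2)).sum()) for a in self.codes.values())
        return gc / self.total_length

    def to_fasta(self, path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Reference":
        from pyfaidx import Fasta

        codes: dict[str, np.ndarray] = {}
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(BASES):
            lut[ord(b)] = i
            lut[ord(b.lower())] = i
        with Fasta(str(path)) as fa:
            for name in fa.keys():
                raw = np.frombuffer(str(fa[name][:]).encode(), dtype=np.uint8)
                arr = lut[raw]
                if (arr == 255).any():
                    raise InvalidConfigError(
                        f"non-ACGT base in {name}; ambiguity codes are unsupported"
                    )
                codes[name] = arr
        return cls(codes)


@dataclass
class Annotation:
    """Gene and CpG-island interval tracks (0-based, half-open)."""

    genes: dict[str, np.ndarray]
    cpg_islands: dict[str, np.ndarray]

    def _track(self, name: str) -> dict[str, np.ndarray]:
        if name == "genes":
            return self.genes
        if name == "cpg_islands":
            return self.cpg_islands
        raise KeyError(name)

    def contains(self, track: str, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Membership of 0-based positions in a track (vectorised)."""
        ivals = self._track(track).get(chrom)
        pos0 = np.asarray(pos0)
        if ivals is None or len(ivals) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        starts, ends = ivals[:, 0], ivals[:, 1]
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = idx >= 0
        out = np.zeros(pos0.shape, dtype=bool)
        out[ok] = pos0[ok] < ends[idx[ok]]
        return out

    def mask(self, track: str, chrom: str, length: int) -> np.ndarray:
        """Dense boolean membership mask for one chromosome."""
        out = np.zeros(length, dtype=bool)
        for start, end in self._track(track).get(chrom, ()):
            out[start:end] = True
        return out

    def total_length(self, track: str) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._track(track).values()))

    def to_bed(self, track: str, path) -> None:
        with open(path, "w") as fh:
            for chrom, ivals in self._track(track).items():
                for start, end in ivals:
                    fh.write(f"{chrom}\t{start}\t{end}\n")

    @classmethod
    def from_bed(cls, genes_path=None, cpg_path=None) -> "Annotation":
        def read(path) -> dict[str, np.ndarray]:
            out: dict[str, list[tuple[int, int]]] = {}
            if path is None:
                return {}
            with open(path) as fh:
                for line in fh:
                    if not line.strip() or line.startswith(("track", "#")):
                        continue
                    chrom, start, end = line.split()[:3]
                    out.setdefault(chrom, []).append((int(start), int(end)))
            return {
                c: np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
                for c, iv in out.items()
            }

        return cls(genes=read(genes_path), cpg_islands=read(cpg_path))


@dataclass
class TruthSet:
    """Ground-truth DNMs placed by the simulator."""

    records: pd.DataFrame  # chrom, pos, offspring_id, ref, alt, stratum, in_cpg

    @property
    def n(self) -> int:
        return len(self.records)

    def counts_by_stratum(self) -> dict[str, int]:
        counts = {label: 0 for label in STRATA}
        if self.n:
            counts.update(self.records["stratum"].value_counts().to_dict())
        return {k: int(v) for k, v in counts.items()}

    def keys(self) -> set[tuple[str, int, str]]:
        return set(
            zip(self.records["chrom"], self.records["pos"].astype(int),
                self.records["offspring_id"])
        )


@dataclass
class SimulatedFamily:
    """Output bundle of :func:`simulate_trio`."""

    config: SimulationConfig
    mode: str
    layout: FamilyLayout
    reference: Reference
    annotation: Annotation
    site_table: pd.DataFrame
    truth: TruthSet
    callable_masks: dict[str, CallableMask]


# ---------------------------------------------------------------------------
# reference and annotation


def _chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    base, extra = divmod(config.genome_length, config.n_chromosomes)
    return {
        f"chr{i + 1}": base + (1 if i < extra else 0)
        for i in range(config.n_chromosomes)
    }


def generate_reference(config: SimulationConfig, rng: np.random.Generator | None = None) -> Reference:
    """Draw a random reference genome with the configured GC content."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    codes = {}
    for chrom, length in _chrom_lengths(config).items():
        is_gc = rng.random(length) < config.gc_content
        second = rng.integers(0, 2, length, dtype=np.uint8)
        # GC site: C(1)/G(2); AT site: A(0)/T(3)
        arr = np.where(is_gc, 1 + second, 3 * second).astype(np.uint8)
        codes[chrom] = arr
    return Reference(codes)


def _tile_intervals(length: int, fraction: float, block: int, phase: float) -> np.ndarray:
    """Evenly spaced non-overlapping intervals covering ~fraction of [0, length)."""
    target = int(round(fraction * length))
    if target <= 0:
        return np.empty((0, 2), dtype=np.int64)
    if target >= length:
        return np.array([[0, length]], dtype=np.int64)
    block = min(block, target)
    n_blocks = max(1, round(target / block))
    sizes = np.full(n_blocks, target // n_blocks, dtype=np.int64)
    sizes[: target - sizes.sum()] += 1
    period = length / n_blocks
    intervals = []
    prev_end = 0
    for i in range(n_blocks):
        slack = max(0.0, period - sizes[i])
        start = int(i * period + phase * slack)
        start = max(start, prev_end)
        end = min(start + int(sizes[i]), length)
        if end > start:
            intervals.append((start, end))
            prev_end = end
    return np.array(intervals, dtype=np.int64)


def generate_annotation(
    config: SimulationConfig, reference: Reference
) -> Annotation:
    """Lay out gene and CpG-island tracks at the configured genome fractions.

    Blocks are tiled deterministically (genes ~10 kb, islands ~1 kb, phase
    shifted so the tracks interleave rather than coincide); per-track totals
    land within 1% of the requested fractions by construction.
    """
    genes, cpg = {}, {}
    for chrom, length in reference.lengths.items():
        genes[chrom] = _tile_intervals(length, config.gene_fraction, _GENE_BLOCK, 0.0)
        cpg[chrom] = _tile_intervals(length, config.cpg_island_fraction, _CPG_BLOCK, 0.5)
    return Annotation(genes=genes, cpg_islands=cpg)


# ---------------------------------------------------------------------------
# sampling helpers


def _low_depth_probability(config: SimulationConfig, min_depth: int = 10) -> float:
    if config.depth_dispersion is None:
        return float(stats.poisson.cdf(min_depth - 1, config.mean_depth))
    r = config.depth_dispersion
    p = r / (r + config.mean_depth)
    return float(stats.nbinom.cdf(min_depth - 1, r, p))


def _draw_depth(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    if config.depth_dispersion is None:
        return rng.poisson(config.mean_depth, n)
    r = config.depth_dispersion
    p = r / (r + config.mean_depth)
    return rng.negative_binomial(r, p, n)


def _draw_depth_conditional(
    rng: np.random.Generator, low_mask: np.ndarray, config: SimulationConfig,
    min_depth: int = 10,
) -> np.ndarray:
    """Depth draws conditioned on (depth < min_depth) indicators.

    Used by the sparse mode to keep emitted rows consistent with the
    thinned low-depth site sets.
    """
    n = len(low_mask)
    out = np.empty(n, dtype=np.int64)
    hi = ~low_mask
    # upper tail: rejection sampling, acceptance ~1 at supported depths
    pending = np.flatnonzero(hi)
    while pending.size:
        draw = _draw_depth(rng, pending.size, config)
        ok = draw >= min_depth
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
    # lower tail: inverse-CDF on the truncated distribution
    n_low = int(low_mask.sum())
    if n_low:
        support = np.arange(min_depth)
        if config.depth_dispersion is None:
            pmf = stats.poisson.pmf(support, config.mean_depth)
        else:
            r = config.depth_dispersion
            p = r / (r + config.mean_depth)
            pmf = stats.nbinom.pmf(support, r, p)
        total = pmf.sum()
        if total <= 0:
            out[low_mask] = 0
        else:
            out[low_mask] = rng.choice(support, size=n_low, p=pmf / total)
    return out


def _distinct_sites(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 0-based positions in [0, length), sorted."""
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    if n > length:
        raise InvalidConfigError("cannot sample more distinct sites than exist")
    if n * 3 >= length:
        return np.sort(rng.choice(length, size=n, replace=False))
    picks = np.unique(rng.integers(0, length, int(n * 1.2) + 16))
    while picks.size < n:
        extra = rng.integers(0, length, n)
        picks = np.unique(np.concatenate([picks, extra]))
    if picks.size > n:
        picks = np.sort(rng.choice(picks, size=n, replace=False))
    return picks.astype(np.int64)


def _draw_mq(rng: np.random.Generator, low_mask: np.ndarray) -> np.ndarray:
    """Site mapping qualities given low-MQ indicators (low: <20, else 20-60)."""
    n = len(low_mask)
    out = np.empty(n, dtype=np.int64)
    n_low = int(low_mask.sum())
    out[low_mask] = rng.integers(0, 20, n_low)
    out[~low_mask] = rng.integers(20, 61, n - n_low)
    return out


def _draw_max_nonref(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    out = rng.integers(0, 3, n)
    multi = rng.random(n) < config.multi_nonref_fraction
    out[multi] = 3 + rng.poisson(1.0, int(multi.sum()))
    return out


def _nonref_codes(ref_code: int) -> list[int]:
    return [c for c in range(4) if c != ref_code]


# ---------------------------------------------------------------------------
# truth placement


def _place_truth(
    rng: np.random.Generator,
    config: SimulationConfig,
    chrom: str,
    ref_codes: np.ndarray,
    strata: np.ndarray,
    cpg_mask_fn,
    offspring: tuple[str, ...],
    forbidden: set[int],
) -> list[dict]:
    """Place true DNMs on one chromosome.

    Per offspring and stratum the DNM count is Binomial(N_sites, 2*mu);
    positions are uniform within the stratum. Positions are kept distinct
    across offspring (collision probability is negligible at supported
    rates; duplicates are redrawn so each emitted row has one carrier).
    """
    mu = config.mu_by_stratum()
    records: list[dict] = []
    taken = set(forbidden)
    pools = {code: np.flatnonzero(strata == code) for code in range(N_STRATA)}
    for child in offspring:
        for code in range(N_STRATA):
            pool = pools[code]
            if pool.size == 0:
                continue
            rate = 2.0 * mu[stratum_label(code)]
            if rate <= 0:
                continue
            count = rng.binomial(pool.size, min(rate, 1.0))
            placed = 0
            while placed < count:
                pos0 = int(pool[rng.integers(0, pool.size)])
                if pos0 in taken:
                    continue
                taken.add(pos0)
                ref_code = int(ref_codes[pos0])
                alt_code = _nonref_codes(ref_code)[rng.integers(0, 3)]
                records.append(
                    {
                        "chrom": chrom,
                        "pos": pos0 + 1,
                        "offspring_id": child,
                        "ref": BASES[ref_code],
                        "alt": BASES[alt_code],
                        "stratum": stratum_label(code),
                        "in_cpg": bool(cpg_mask_fn(pos0)),
                    }
                )
                placed += 1
    return records


_TRUTH_COLUMNS = ["chrom", "pos", "offspring_id", "ref", "alt", "stratum", "in_cpg"]


# ---------------------------------------------------------------------------
# dense mode


def _simulate_dense(
    config: SimulationConfig,
    reference: Reference,
    annotation: Annotation,
    rng: np.random.Generator,
    layout: FamilyLayout,
) -> tuple[pd.DataFrame, TruthSet, dict[str, CallableMask]]:
    samples = layout.samples
    truth_records: list[dict] = []
    frames = []
    stratum_callable = {
        child: np.zeros(N_STRATA, dtype=np.int64) for child in layout.offspring
    }

    for chrom, length in reference.lengths.items():
        ref_codes = reference.codes[chrom]
        gene_mask = annotation.mask("genes", chrom, length)
        cpg_mask = annotation.mask("cpg_islands", chrom, length)
        strata = stratum_codes(ref_codes, gene_mask)

        low_mq = rng.random(length) < config.low_mq_fraction
        mq = _draw_mq(rng, low_mq)
        low_quality = rng.random(length) < config.low_quality_fraction
        max_nonref = _draw_max_nonref(rng, length, config)

        depth = {s: _draw_depth(rng, length, config) for s in samples}
        # per-sample sequencing-error reads, split over the 3 non-ref bases
        base_counts = {}
        for s in samples:
            err = rng.binomial(depth[s], config.seq_error_rate)
            b0 = rng.binomial(err, 1.0 / 3.0)
            b1 = rng.binomial(err - b0, 0.5)
            base_counts[s] = np.stack([b0, b1, err - b0 - b1])

        genotypes = {s: np.full(length, "0/0", dtype=object) for s in samples}

        # standing heterozygosity in parents (off by default)
        parent_het_pos = np.empty(0, dtype=np.int64)
        site_alt_code = np.full(length, -1, dtype=np.int8)
        if config.parent_het_fraction > 0:
            n_het = rng.binomial(length, config.parent_het_fraction)
            parent_het_pos = _distinct_sites(rng, n_het, length)
            which_parent = rng.integers(0, 2, parent_het_pos.size)
            for pos0, w in zip(parent_het_pos, which_parent):
                parent = layout.parents[w]
                ref_code = int(ref_codes[pos0])
                alt_code = _nonref_codes(ref_code)[rng.integers(0, 3)]
                site_alt_code[pos0] = alt_code
                genotypes[parent][pos0] = "0/1"
                for child in layout.offspring:
                    if rng.random() < 0.5:
                        genotypes[child][pos0] = "0/1"

        forbidden = set(int(p) for p in parent_het_pos)
        chrom_truth = _place_truth(
            rng, config, chrom, ref_codes, strata,
            lambda p: cpg_mask[p], layout.offspring, forbidden,
        )
        truth_records.extend(chrom_truth)

        for rec in chrom_truth:
            pos0 = rec["pos"] - 1
            site_alt_code[pos0] = BASES.index(rec["alt"])
            genotypes[rec["offspring_id"]][pos0] = "0/1"

        # choose the site alternate allele where only errors are present:
        # the non-reference base with the largest pooled support
        nonref_table = np.array(
            [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]], dtype=np.int8
        )
        codes_by_k = [nonref_table[ref_codes, k] for k in range(3)]
        support = np.zeros((4, length), dtype=np.int64)
        pos_idx = np.arange(length)
        for s in samples:
            for k in range(3):
                np.add.at(support, (codes_by_k[k], pos_idx), base_counts[s][k])
        pooled = support.sum(axis=0)
        err_sites = (pooled > 0) & (site_alt_code < 0)
        if err_sites.any():
            site_alt_code[err_sites] = np.argmax(support[:, err_sites], axis=0)

        # alternate-supporting read counts per sample for the chosen allele
        ad = {s: np.zeros(length, dtype=np.int64) for s in samples}
        has_alt = site_alt_code >= 0
        if has_alt.any():
            alt_idx = np.flatnonzero(has_alt)
            alt_codes = site_alt_code[alt_idx]
            for s in samples:
                counts = np.zeros(alt_idx.size, dtype=np.int64)
                for k in range(3):
                    counts = np.where(
                        codes_by_k[k][alt_idx] == alt_codes,
                        base_counts[s][k][alt_idx],
                        counts,
                    )
                ad[s][alt_idx] = counts
        # heterozygous carriers: Binomial(depth, 1/2) alternate reads
        for s in samples:
            het = np.flatnonzero(genotypes[s] == "0/1")
            if het.size:
                ad[s][het] = rng.binomial(depth[s][het], 0.5)

        # callable masks (same thresholds as the caller's denominator rules)
        parent_ok = np.ones(length, dtype=bool)
        for parent in layout.parents:
            parent_ok &= depth[parent] >= 10
            parent_ok &= genotypes[parent] == "0/0"
        mq_ok = mq >= 20
        for child in layout.offspring:
            ok = mq_ok & parent_ok & (depth[child] >= 10)
            stratum_callable[child] += np.bincount(strata[ok], minlength=N_STRATA)

        alt_base = np.where(
            site_alt_code >= 0,
            np.array(list(BASES))[np.clip(site_alt_code, 0, 3)],
            "",
        )
        data = {
            "chrom": chrom,
            "pos": pos_idx + 1,
            "ref": np.array(list(BASES))[ref_codes],
            "alt": alt_base,
            "mq": mq,
            "low_quality": low_quality,
            "max_nonref_per_read": max_nonref,
            "region": np.where(gene_mask, "gene", "intergenic"),
            "in_cpg": cpg_mask,
        }
        for s in samples:
            data[f"GT_{s}"] = genotypes[s]
            data[f"DP_{s}"] = depth[s]
            data[f"AD_{s}"] = np.minimum(ad[s], depth[s])
        frames.append(pd.DataFrame(data))

    table = pd.concat(frames, ignore_index=True)
    truth = TruthSet(pd.DataFrame(truth_records, columns=_TRUTH_COLUMNS))
    masks = {
        child: CallableMask(
            offspring_id=child,
            by_stratum={
                stratum_label(code): int(stratum_callable[child][code])
                for code in range(N_STRATA)
            },
        )
        for child in layout.offspring
    }
    return table, truth, masks


# ---------------------------------------------------------------------------
# sparse mode


def _simulate_sparse(
    config: SimulationConfig,
    reference: Reference,
    annotation: Annotation,
    rng: np.random.Generator,
    layout: FamilyLayout,
) -> tuple[pd.DataFrame, TruthSet, dict[str, CallableMask]]:
    samples = layout.samples
    p_low_depth = _low_depth_probability(config)
    truth_records: list[dict] = []
    rows: list[dict] = []
    stratum_callable = {
        child: np.zeros(N_STRATA, dtype=np.int64) for child in layout.offspring
    }

    for chrom, length in reference.lengths.items():
        ref_codes = reference.codes[chrom]
        gene_mask = annotation.mask("genes", chrom, length)
        cpg_mask = annotation.mask("cpg_islands", chrom, length)
        strata = stratum_codes(ref_codes, gene_mask)
        stratum_totals = np.bincount(strata, minlength=N_STRATA)

        low_mq_sites = _distinct_sites(
            rng, rng.binomial(length, config.low_mq_fraction), length
        )
        low_depth_sites = {
            s: _distinct_sites(rng, rng.binomial(length, p_low_depth), length)
            for s in samples
        }
        parent_het_pos = np.empty(0, dtype=np.int64)
        parent_het_which = np.empty(0, dtype=np.int64)
        if config.parent_het_fraction > 0:
            n_het = rng.binomial(length, config.parent_het_fraction)
            parent_het_pos = _distinct_sites(rng, n_het, length)
            parent_het_which = rng.integers(0, 2, parent_het_pos.size)

        # callable-site complement counting: subtract the union of rare
        # disqualifying site sets from the stratum totals
        parent_bad = np.concatenate(
            [low_depth_sites[p] for p in layout.parents] + [parent_het_pos]
        )
        for child in layout.offspring:
            bad = np.unique(
                np.concatenate([low_mq_sites, low_depth_sites[child], parent_bad])
            )
            bad_counts = (
                np.bincount(strata[bad], minlength=N_STRATA)
                if bad.size
                else np.zeros(N_STRATA, dtype=np.int64)
            )
            stratum_callable[child] += stratum_totals - bad_counts

        forbidden = set(int(p) for p in parent_het_pos)
        chrom_truth = _place_truth(
            rng, config, chrom, ref_codes, strata,
            lambda p: cpg_mask[p], layout.offspring, forbidden,
        )
        truth_records.extend(chrom_truth)

        emit: list[tuple[int, str, str, str | None]] = [
            (rec["pos"] - 1, rec["alt"], rec["offspring_id"], None)
            for rec in chrom_truth
        ]
        for pos0, which in zip(parent_het_pos, parent_het_which):
            ref_code = int(ref_codes[pos0])
            alt = BASES[_nonref_codes(ref_code)[rng.integers(0, 3)]]
            emit.append((int(pos0), alt, None, layout.parents[which]))
        if not emit:
            continue
        emit.sort(key=lambda t: t[0])
        pos_arr = np.array([e[0] for e in emit], dtype=np.int64)
        in_low_mq = np.isin(pos_arr, low_mq_sites)
        mq_vals = _draw_mq(rng, in_low_mq)
        depth_vals = {}
        for s in samples:
            low = np.isin(pos_arr, low_depth_sites[s])
            depth_vals[s] = _draw_depth_conditional(rng, low, config)
        low_quality = rng.random(len(emit)) < config.low_quality_fraction
        max_nonref = _draw_max_nonref(rng, len(emit), config)
        e3 = config.seq_error_rate / 3.0

        for i, (pos0, alt, carrier, het_parent) in enumerate(emit):
            row = {
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": BASES[int(ref_codes[pos0])],
                "alt": alt,
                "mq": int(mq_vals[i]),
                "low_quality": bool(low_quality[i]),
                "max_nonref_per_read": int(max_nonref[i]),
                "region": "gene" if gene_mask[pos0] else "intergenic",
                "in_cpg": bool(cpg_mask[pos0]),
            }
            het_samples = set()
            if carrier is not None:
                het_samples.add(carrier)
            if het_parent is not None:
                het_samples.add(het_parent)
                for child in layout.offspring:
                    if rng.random() < 0.5:
                        het_samples.add(child)
            for s in samples:
                dp = int(depth_vals[s][i])
                if s in het_samples:
                    gt, ad = "0/1", int(rng.binomial(dp, 0.5))
                else:
                    gt, ad = "0/0", int(rng.binomial(dp, e3))
                row[f"GT_{s}"] = gt
                row[f"DP_{s}"] = dp
                row[f"AD_{s}"] = ad
            rows.append(row)

    columns = [
        "chrom", "pos", "ref", "alt", "mq", "low_quality",
        "max_nonref_per_read", "region", "in_cpg",
    ] + [f"{p}_{s}" for s in samples for p in ("GT", "DP", "AD")]
    table = pd.DataFrame(rows, columns=columns)
    truth = TruthSet(pd.DataFrame(truth_records, columns=_TRUTH_COLUMNS))
    masks = {
        child: CallableMask(
            offspring_id=child,
            by_stratum={
                stratum_label(code): int(stratum_callable[child][code])
                for code in range(N_STRATA)
            },
        )
        for child in layout.offspring
    }
    return table, truth, masks


# ---------------------------------------------------------------------------
# public entry point


def simulate_trio(
    config: SimulationConfig,
    reference: Reference | None = None,
    annotation: Annotation | None = None,
    mode: str = "auto",
) -> SimulatedFamily:
    """Simulate one full-sib trio experiment.

    Parameters
    ----------
    config
        Simulation parameters; the RNG seed lives here, so the output is
        a pure function of ``(config, mode)``.
    reference, annotation
        Reuse pre-built inputs; generated from ``config`` when omitted.
    mode
        ``"dense"`` emits one row per genomic site (small genomes),
        ``"sparse"`` emits only variant-carrying rows and computes the
        callable denominators by exact thinning. ``"auto"`` picks dense
        when sites x samples is small enough.

    Returns
    -------
    SimulatedFamily
        Site table, truth set and per-offspring callable masks. In dense
        mode the callable masks agree with
        :func:`triomut.calling.count_callable` run on the emitted table.
    """
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = generate_reference(config, rng)
    if annotation is None:
        annotation = generate_annotation(config, reference)
    layout = config.layout()
    n_samples = len(layout.samples)
    if mode == "auto":
        mode = (
            "dense"
            if reference.total_length * n_samples <= _DENSE_CELL_LIMIT
            else "sparse"
        )
    if mode == "dense":
        if reference.total_length * n_samples > _DENSE_CELL_LIMIT:
            raise InvalidConfigError(
                "genome x samples too large for the dense mode; use mode='sparse'"
            )
        table, truth, masks = _simulate_dense(config, reference, annotation, rng, layout)
    elif mode == "sparse":
        table, truth, masks = _simulate_sparse(config, reference, annotation, rng, layout)
    else:
        raise InvalidConfigError(f"unknown mode {mode!r}")
    return SimulatedFamily(
        config=config,
        mode=mode,
        layout=layout,
        reference=reference,
        annotation=annotation,
        site_table=table,
        truth=truth,
        callable_masks=masks,
    )
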