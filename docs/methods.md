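# Methods

## The estimand and the model

The quantity of interest is the germline single-nucleotide mutation
rate µ, in mutations per site per generation, of a diploid organism
measured by sequencing two parents and N full-sib offspring. Writing
`m_i` for the number of de novo mutations (DNMs) accepted in offspring
*i* and `C_i` for its callable sites — positions at which the filters
could have detected a DNM had one occurred — the per-offspring rate is
`µ_i = m_i / (2 C_i)`: the factor 2 counts both chromosome copies, so a
heterozygous DNM is one event out of `2 C_i` opportunities. The family
estimate is the unweighted mean of the `µ_i`; weighting offspring by
callable sites would change little at uniform coverage and the
unweighted mean is what the bootstrap below resamples. Rates are
reported overall and stratified by genomic region (gene vs intergenic),
reference base class (A/T vs C/G), and the six strand-collapsed
substitution classes, each stratum using its own callable denominator.

### Uncertainty

Confidence intervals are percentile bootstrap: B = 1000 resamples of
the N per-offspring rates with replacement, the mean of each resample
recorded, the B estimates sorted ascending, and the bounds read off at
the 1-based positions `round(0.025 B)` and `round(0.975 B)` (the 25th
and 975th of 1000). B < 40 is refused because the 2.5% tail position
would collapse onto the extremes. Between-condition differences are
tested on the observed per-offspring rates, never on bootstrap
replicates. The t-test defaults to Welch's unequal-variance form —
"Student's t-test" as run in R is Welch unless requested otherwise —
with `equal_var=True` available; the rank-based alternative is the
Wilcoxon rank-sum (Mann–Whitney) test. Identical constant groups are
defined to give p = 1 rather than NaN. No multiple-testing correction
is applied; p-values are reported raw.

### Filters and the candidate definition

A site yields a DNM call iff exactly one offspring carries the
alternate allele, heterozygously, and survives, in order: depth ≥ 10;
site mapping quality ≥ 20; no upstream-caller low-quality flag;
alternate-read fraction ≥ 0.30; at most 2 non-reference sites on any
supporting read (carried as a precomputed per-site field, since a site
table has no read-level data); and both parents homozygous reference
with zero alternate-supporting reads and depth ≥ 10. The first failing
rule is recorded, so the rejection ledger partitions candidates and is
auditable. Three interpretation points were genuinely open:

- *Sharing across offspring* is judged at genotype level: a variant
  genotyped in two or more offspring is rejected as shared, but a stray
  alternate read in a non-carrier offspring does not veto the site (an
  upstream genotyper would not call one read in thirty heterozygous).
  `strict_read_sharing=True` switches to the read-level veto.
- *Parents* are held to the read-level rule (zero alternate reads), the
  conservative choice for the denominator of a de novo claim.
- *Callability* requires the same depth/MQ thresholds of the offspring
  and both parents plus parental homozygous-reference genotypes;
  because mapping quality is a locus property here, the optional
  parent-MQ switch only matters for externally supplied tables that
  carry per-sample MQ.

Sex chromosomes are not treated specially; contigs can be excluded
upstream by subsetting the site table.

## The synthetic trio generator

The generator emulates the study design the package targets: a full-sib
family at ~30× coverage with homozygous-reference parents. Defaults:
mean depth 30 (Poisson; a negative-binomial switch adds overdispersion
when `depth_dispersion` is set), per-read error 10⁻³ (uniform over the
three alternate bases), 2% of loci with mapping quality below 20, 0.1%
caller-low-quality flags and 0.1% multi-non-reference-read loci, gene
fraction 0.40, CpG-island fraction 0.10 of the genome, and true rates
of 3.60×10⁻⁹ (A/T sites) and 4.58×10⁻⁹ (C/G sites) per site per
generation, uniform across regions — the normal-rearing silkworm
values. Each offspring acquires a DNM at a site with probability 2µ of
its stratum (at most one per site; collisions are redrawn, a negligible
distortion at supported rates ≤ 10⁻⁴), and alternate reads at any
heterozygous site are Binomial(depth, ½). Mapping quality, the
low-quality flag and the read-level field are locus properties shared
by all samples. Standing parental heterozygosity is off by default and
switchable to exercise the parental filter.

Two emission modes draw from the same distribution. **Dense** mode
materialises every site (guarded to ≤ 2×10⁷ site×sample cells) so
callable counting can be re-run from the table itself; the test suite
checks that the simulator's masks equal an independent recount.
**Sparse** mode scales to tens of megabases by exact thinning: the rare
disqualifying events — depth < 10 at mean 30 (probability ~1.2×10⁻⁵
per site per sample) and MQ < 20 (2%) — are drawn as Binomial(L, p)
site-index sets, and callable counts are stratum totals minus the union
of the bad sets, which is identical in distribution to the dense
computation. Emitted rows (truth sites, optional parental variants) get
per-sample draws conditioned on membership in those sets (truncated
inverse-CDF below threshold, rejection sampling above). Error-only loci
are not emitted in sparse mode: at supported depths the probability
that sequencing errors alone reach a 30% alternate fraction at depth
≥ 10 is < 10⁻²⁰ per site, so such rows can affect neither calls nor
denominators. What the generator does **not** model: real read
alignment (no FASTQ/BAM), indels and structural variants, GC-coverage
coupling, CpG hypermutability, batch effects between families. Passing
tests therefore validate the pipeline's arithmetic and filtering logic
under the stated sampling model, not robustness to alignment artefacts.

## Spectrum analysis

Substitutions are collapsed over strands into six classes written
origin-pair → result-pair; the internal canonical form is the
pyrimidine-reference strand. Transitions are C↔T and G↔A; under a
no-bias model each class holds 1/6 of mutations and Ts/Tv = 0.5, the
null against which enrichment (e.g. of G:C→A:T) is read. Per-class
rates divide by twice the callable sites of the class's origin bases,
so the three A/T-origin rates sum exactly to the A/T-class rate. The
CpG-island association test compares the observed fraction of
G:C→A:T calls inside islands with the islands' genome share
(length-weighted uniform null, ~0.10 by default) using a chi-square
proportion test with continuity correction, verified against R's
`prop.test`. Flank-context matrices tally base frequencies at ±10 bp
with windows oriented so the mutated base reads C; calls within a
flank of a contig end are dropped with a warning.

## Calibration

False negatives are measured at site-table level: a spike sets the
chosen offspring's genotype heterozygous with `y ~ Binomial(x, ½)`
alternate reads at a site of depth x (the table-level equivalent of
rewriting reads and realigning; low-y spikes are then rejected by the
alternate-fraction filter exactly as a re-called low-balance variant
would be). Spiked sites are drawn uniformly among non-variant sites by
default (`exclude_variant_sites=False` lifts this) and remain in the
denominator even if non-callable, since recovery is judged after the
full pipeline. On clean data the measured FN rate must equal the
analytic probability that Binomial(x, ½)/x < 0.30 or x < 10, within
binomial error — a self-consistency check in the suite. The
true-positive rate is plain confirmation arithmetic, and
`corrected_rate = raw · tp / (1 − fn)` is provided but off by default:
headline estimates are reported uncorrected.

## Molecular clock

Coalescent estimates of the wild/domestic silkworm split give
θ = 4 Ne µ = 0.034 and τ = 0.0035 (in 4 Ne generations). With µ per
site per **year**, `Ne = θ/(4µ)` and `T = 4 τ Ne` is in years
directly; a per-generation rate is first scaled by generations per
year. Both pathways reduce to `T = τ θ / µ_year` and are checked to
agree to float tolerance. Defaults use 3 generations per year (reared
silkworm) for domestication dating; cross-species per-year comparisons
instead use 365/generation-days (e.g. 365/40 for the silkworm's
~40-day cycle, 1/25 for humans) — the two conventions are separate
explicit parameters, never switched silently. The headline time is
rounded to the nearest 100 years; at µ_gen = 0.41×10⁻⁸ and 3
generations/year this yields ~9700 years. θ and τ are taken as fixed
inputs; inferring them from sequence is out of scope.

## Numerical and testing choices

Determinism: every stochastic component takes a seed or Generator;
identical configuration and seed reproduce site tables, truth sets and
bootstrap intervals bit-for-bit. Tie-breaks: the alternate allele at an
error-only site is the non-reference base with the largest pooled
support, first-in-alphabet on ties; exactly 30% alternate fraction
passes the ≥ 0.30 rule. Degenerate inputs raise typed exceptions
(`UndefinedRateError` for zero callable sites, `UndefinedTestError` for
groups too small to test, and so on) rather than returning NaN.

Test problem sizes were chosen to make each property sharp but cheap:
parameter recovery runs 20 sparse replicates of a 50 Mb genome with 10
offspring at the defaults' error and depth (the whole-genome CI must
cover the true 4×10⁻⁹ in ≥ 90% of replicates); perfect-recall checks
use an error-free family at ~150× depth, where the probability of an
allele-balance failure is < 10⁻⁶; bootstrap coverage uses 500 normal
samples of n = 30; oracle-equivalence checks run brute-force
re-implementations on ≤ 1000-row tables. The null-spectrum checks use
10⁵ simulated substitutions, giving standard errors of ~0.15% on class
shares.
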