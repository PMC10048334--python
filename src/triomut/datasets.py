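"""Published study values used as inputs to desk-scale computations.

These constants are the silkworm parents-progeny study's reported
numbers (rates in units of 1e-9 per site per generation unless noted).
They are inputs for fold-comparisons and clock calculations, not outputs
of this package.
"""

from __future__ import annotations

import pandas as pd

#: Whole-genome per-generation rates of previously studied insects
#: (per site per generation).
INSECT_RATES = {
    "Bombyx mori": 0.41e-8,
    "Drosophila melanogaster": 0.28e-8,
    "Heliconius melpomene": 0.29e-8,
    "Apis mellifera": 0.34e-8,
    "Bombus terrestris": 0.36e-8,
}

#: Reported human per-generation rate and generation time (years).
HUMAN_RATE_PER_GENERATION = 1.2e-8
HUMAN_GENERATION_YEARS = 25.0

#: Silkworm generation time in days and rearing cadence.
SILKWORM_GENERATION_DAYS = 40.0
SILKWORM_GENERATIONS_PER_YEAR = 3.0

#: Coalescent parameters of the wild/domestic silkworm split.
THETA_DOMESTICATION = 0.034
TAU_DOMESTICATION = 0.0035

#: Reported stratified rates (x 1e-9 per site per generation) with
#: percentile-bootstrap 95% CIs, by genome stratum and rearing condition.
#: The low-temperature gene-region upper bound is stored as printed
#: magnitude 5.90 (x 1e-9).
STRATIFIED_RATES = pd.DataFrame(
    [
        ("whole_genome", "normal", 4.09, 3.31, 4.90),
        ("whole_genome", "high_temperature", 5.80, 4.35, 7.44),
        ("whole_genome", "low_temperature", 5.68, 4.13, 7.38),
        ("gene", "normal", 4.52, 3.23, 5.92),
        ("gene", "high_temperature", 4.95, 2.65, 7.23),
        ("gene", "low_temperature", 4.92, 3.94, 5.90),
        ("intergenic", "normal", 3.84, 2.94, 4.81),
        ("intergenic", "high_temperature", 6.05, 4.04, 8.06),
        ("intergenic", "low_temperature", 5.85, 4.01, 7.87),
        ("AT", "normal", 3.60, 2.91, 4.34),
        ("AT", "high_temperature", 3.80, 3.20, 4.44),
        ("AT", "low_temperature", 3.76, 2.88, 4.69),
        ("CG", "normal", 4.58, 3.34, 6.01),
        ("CG", "high_temperature", 8.14, 6.41, 9.87),
        ("CG", "low_temperature", 7.85, 5.81, 10.1),
    ],
    columns=["stratum", "condition", "mean", "ci_low", "ci_high"],
)

#: DNM counts and verification/spike-in tallies per family.
FAMILY_SUMMARY = pd.DataFrame(
    [
        ("normal", 30, 106, 79, 84, 914, 1000),
        ("high_temperature", 10, 48, 20, 20, 887, 1000),
        ("low_temperature", 10, 47, 20, 20, 884, 1000),
    ],
    columns=[
        "condition", "n_offspring", "n_dnms",
        "n_confirmed", "n_tested", "n_spikes_recovered", "n_spikes",
    ],
)
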