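"""End-to-end orchestration of the synthetic-benchmark workflow.

``run_full`` wires the stages together: simulate a trio experiment per
condition, call DNMs, estimate stratified rates with bootstrap CIs,
summarise the mutation spectrum, calibrate the caller by spike-in, and
convert the normal-condition rate to a domestication-time estimate. All
outputs are plain-text tables plus a JSON manifest recording the seed and
thresholds, so a rerun with the same configuration reproduces every
number.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .calibration import false_negative_rate, spike_in
from .calling import FilterThresholds, call_dnms, CallableMask
from .clock import ClockParams, clock_report
from .exceptions import InvalidConfigError
from .rates import MutationRateModel, compare_conditions
from .simulate import SimulationConfig, simulate_trio
from .spectrum import cpg_island_association, spectrum_summary


@dataclass
class RunConfig:
    """Configuration of a full synthetic-benchmark run.

    ``conditions`` maps a condition label to the per-stratum (or scalar)
    true mutation rates used for its family; every family shares the
    remaining simulation settings.
    """

    outdir: str
    seed: int = 0
    genome_length: int = 1_000_000
    n_chromosomes: int = 4
    n_offspring: int = 10
    mean_depth: float = 30.0
    seq_error_rate: float = 1e-3
    conditions: dict = field(
        default_factory=lambda: {"normal": 4.09e-9}
    )
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    bootstrap_b: int = 1000
    n_spikes: int = 0
    clock: ClockParams | None = None

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise InvalidConfigError("need at least one condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise InvalidConfigError("condition labels must be unique")
        if self.bootstrap_b < 40:
            raise InvalidConfigError("bootstrap_b must be at least 40")


def run_full(config: RunConfig) -> dict:
    """Run the full pipeline; returns the report bundle as a dict.

    Outputs per condition: site table (dense runs only), DNM calls,
    rejection ledger, callable masks, rate table; plus condition
    comparisons, spectrum summaries, optional spike-in calibration and
    clock report; and a manifest. On failure, partial outputs are
    removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_full_inner(config, outdir)
    except Exception:
        shutil.rmtree(outdir, ignore_errors=True)
        raise


def _run_full_inner(config: RunConfig, outdir: Path) -> dict:
    report: dict = {"conditions": {}}
    fits = {}
    rates_frames = []
    for i, (label, mu) in enumerate(config.conditions.items()):
        sim_config = SimulationConfig(
            genome_length=config.genome_length,
            n_chromosomes=config.n_chromosomes,
            n_offspring=config.n_offspring,
            mean_depth=config.mean_depth,
            seq_error_rate=config.seq_error_rate,
            mu_true=mu,
            seed=config.seed + i,
        )
        family = simulate_trio(sim_config)
        result = call_dnms(
            family.site_table, family.layout, family.annotation, config.thresholds
        )
        cdir = outdir / label
        cdir.mkdir(exist_ok=True)
        if family.mode == "dense":
            io.write_site_table(family.site_table, cdir / "site_table.tsv")
        io.write_truth(family.truth, cdir / "truth.tsv")
        io.write_calls(result, cdir / "dnm_calls.tsv")
        io.write_rejections(result.rejections, cdir / "rejections.tsv")
        io.write_callable_masks(family.callable_masks, cdir / "callable_masks.tsv")

        model = MutationRateModel.from_calls(
            result.calls_frame, family.callable_masks, condition=label
        )
        fit = model.fit(b=config.bootstrap_b, seed=config.seed + 1000 + i)
        fits[label] = fit
        rates_frames.append(fit.table)
        fit.table.to_csv(cdir / "rate_estimates.tsv", sep="\t", index=False)

        pooled_mask = CallableMask(
            offspring_id="pooled",
            by_stratum={
                k: sum(m.by_stratum[k] for m in family.callable_masks.values())
                for k in next(iter(family.callable_masks.values())).by_stratum
            },
        )
        spec = spectrum_summary(result.calls_frame, pooled_mask)
        spec_frame = pd.DataFrame(
            {
                "mutation_type": list(spec.counts),
                "count": list(spec.counts.values()),
            }
        )
        spec_frame.to_csv(cdir / "spectrum_counts.tsv", sep="\t", index=False)
        cond_report = {
            "n_calls": len(result.calls),
            "n_truth": family.truth.n,
            "whole_genome_rate": fit["whole_genome"].mean,
            "whole_genome_ci": [fit["whole_genome"].ci_low, fit["whole_genome"].ci_high],
            "ts": spec.ts,
            "tv": spec.tv,
        }
        if config.n_spikes > 0:
            if family.mode != "dense":
                raise InvalidConfigError(
                    "spike-in calibration needs a dense site table; shrink the genome"
                )
            spiked, ledger = spike_in(
                family.site_table, family.layout,
                n_sites=config.n_spikes, seed=config.seed + 2000 + i,
            )
            recalled = call_dnms(spiked, family.layout, family.annotation, config.thresholds)
            fn = false_negative_rate(ledger, recalled)
            ledger.entries.to_csv(cdir / "spike_ledger.tsv", sep="\t", index=False)
            cond_report["false_negative_percent"] = fn
        report["conditions"][label] = cond_report

    labels = list(config.conditions)
    comparisons = []
    for other in labels[1:]:
        for method in ("t", "wilcoxon"):
            comparisons.append(
                {
                    "a": labels[0],
                    "b": other,
                    "stratum": "whole_genome",
                    "method": method,
                    "pvalue": fits[labels[0]].compare(fits[other], method=method),
                }
            )
    if comparisons:
        pd.DataFrame(comparisons).to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        report["comparisons"] = comparisons
    pd.concat(rates_frames, ignore_index=True).to_csv(
        outdir / "rate_estimates_all.tsv", sep="\t", index=False
    )

    if config.clock is not None:
        report["clock"] = clock_report(config.clock)
        with open(outdir / "clock_report.json", "w") as fh:
            json.dump(report["clock"], fh, indent=2)

    manifest = {
        "seed": config.seed,
        "genome_length": config.genome_length,
        "n_chromosomes": config.n_chromosomes,
        "n_offspring": config.n_offspring,
        "mean_depth": config.mean_depth,
        "seq_error_rate": config.seq_error_rate,
        "conditions": {k: v if isinstance(v, (int, float)) else dict(v)
                       for k, v in config.conditions.items()},
        "thresholds": {
            "min_depth": config.thresholds.min_depth,
            "min_mq": config.thresholds.min_mq,
            "min_alt_fraction": config.thresholds.min_alt_fraction,
            "max_nonref_per_read": config.thresholds.max_nonref_per_read,
            "min_parent_depth": config.thresholds.min_parent_depth,
        },
        "bootstrap_b": config.bootstrap_b,
        "n_spikes": config.n_spikes,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    report["manifest"] = manifest
    return report
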