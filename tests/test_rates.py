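"""Rate arithmetic, percentile bootstrap, and the statistical tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomut.calling import CallableMask
from triomut.exceptions import (
    InsufficientReplicatesError,
    UndefinedRateError,
    UndefinedTestError,
)
from triomut.rates import (
    MutationRateModel,
    bootstrap_ci,
    chromosome_distribution_test,
    compare_conditions,
    cross_species_test,
    per_offspring_rate,
)


class TestPerOffspringRate:
    def test_diploid_denominator(self):
        assert per_offspring_rate(5, 100_000_000) == pytest.approx(2.5e-8)

    def test_zero_mutations_zero_rate(self):
        assert per_offspring_rate(0, 1_000) == 0.0

    def test_consistent_with_published_family_mean(self):
        # 106 DNMs over 30 offspring at a mean rate of 4.09e-9 per site per
        # generation imply ~4.32e8 callable sites per offspring; the inverse
        # computation must return the same mean.
        callable_sites = 106 / (30 * 2 * 4.09e-9)
        counts = [4] * 16 + [3] * 14  # 30 offspring, 106 DNMs
        assert sum(counts) == 106
        rates = [per_offspring_rate(m, callable_sites) for m in counts]
        assert np.mean(rates) == pytest.approx(4.09e-9, rel=1e-9)

    def test_zero_callable_raises(self):
        with pytest.raises(UndefinedRateError):
            per_offspring_rate(3, 0)


class TestBootstrapCI:
    def test_degenerate_constant_values(self):
        mean, lo, hi = bootstrap_ci([2.0] * 12, seed=0)
        assert mean == lo == hi == 2.0

    def test_matches_independent_rerun_same_stream(self):
        """The percentile rule equals a brute-force reimplementation fed
        the same RNG stream (resample means sorted, 25th/975th of 1000)."""
        values = np.arange(1.0, 11.0)
        got = bootstrap_ci(values, b=1000, seed=77)

        rng = np.random.default_rng(77)
        idx = rng.integers(0, 10, size=(1000, 10))
        means = np.sort(values[idx].mean(axis=1))
        assert got == (values.mean(), means[24], means[974])

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(5)
        values = rng.gamma(2.0, 1.0, 30)
        mean, lo, hi = bootstrap_ci(values, seed=1)
        assert lo <= mean <= hi

    def test_nominal_coverage_on_normal_samples(self):
        """~95% of percentile-bootstrap CIs cover the true mean (n=30)."""
        rng = np.random.default_rng(2024)
        covered = 0
        trials = 500
        for _ in range(trials):
            sample = rng.normal(10.0, 2.0, 30)
            _, lo, hi = bootstrap_ci(sample, b=1000, rng=rng)
            covered += lo <= 10.0 <= hi
        assert abs(covered / trials - 0.95) <= 0.03

    def test_width_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(8)
        widths = {}
        for n in (10, 40):
            w = []
            for _ in range(200):
                sample = rng.normal(0.0, 1.0, n)
                _, lo, hi = bootstrap_ci(sample, b=400, rng=rng)
                w.append(hi - lo)
            widths[n] = np.mean(w)
        ratio = widths[10] / widths[40]
        assert 1.6 <= ratio <= 2.4  # ~sqrt(40/10) = 2

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            bootstrap_ci([1.0, 2.0], b=39)


class TestCompareConditions:
    def test_identical_constant_groups_give_p_one(self):
        assert compare_conditions([3.0] * 5, [3.0] * 5, method="t") == 1.0
        assert compare_conditions([3.0] * 5, [3.0] * 5, method="wilcoxon") == 1.0

    def test_separated_groups_significant(self):
        p = compare_conditions([1, 2, 3], [101, 102, 103], method="t")
        assert p < 0.001

    def test_welch_t_matches_hand_formula(self):
        a = np.array([4.1, 3.8, 4.5, 4.0, 3.9])
        b = np.array([5.2, 5.8, 5.1, 6.0])
        p = compare_conditions(a, b, method="t")
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(UndefinedTestError):
            compare_conditions([1.0], [2.0, 3.0])


class TestCrossSpeciesTest:
    def test_identical_rates_give_p_near_one(self):
        res = cross_species_test([(100, 10_000_000), (100, 10_000_000)])
        assert res.pvalue > 0.99

    def test_statistic_matches_hand_computation(self):
        table = np.array([[30.0, 970.0], [60.0, 940.0]])
        res = cross_species_test([(30, 1000), (60, 1000)])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.dof == 1

    def test_doubling_a_count_lowers_p(self):
        base = cross_species_test([(50, 1_000_000), (60, 1_000_000)]).pvalue
        bigger = cross_species_test([(50, 1_000_000), (120, 1_000_000)]).pvalue
        assert bigger < base

    def test_low_expected_cell_flagged(self):
        res = cross_species_test([(0, 100000), (1, 100000)])
        assert res.low_expected_warning

    def test_single_species_rejected(self):
        with pytest.raises(UndefinedTestError):
            cross_species_test([(10, 1000)])


class TestChromosomeDistribution:
    LENGTHS = {"chr1": 600_000, "chr2": 400_000}

    def _frame(self, chroms, positions):
        return pd.DataFrame({"chrom": chroms, "pos": positions})

    def test_uniform_positions_usually_pass(self):
        passed = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.integers(1, 1_000_001, 200)
            chroms = np.where(raw <= 600_000, "chr1", "chr2")
            positions = np.where(raw <= 600_000, raw, raw - 600_000)
            p = chromosome_distribution_test(self._frame(chroms, positions), self.LENGTHS)
            passed += p > 0.05
        assert passed >= 18  # >= 90% of seeded trials

    def test_clustered_positions_fail(self):
        frame = self._frame(["chr1"] * 30, [1] * 1 + list(range(1, 30)))
        p = chromosome_distribution_test(frame, self.LENGTHS)
        assert p < 0.001

    def test_statistic_equals_brute_force_ecdf_gap(self):
        rng = np.random.default_rng(3)
        raw = np.sort(rng.integers(1, 1_000_001, 40))
        chroms = np.where(raw <= 600_000, "chr1", "chr2")
        positions = np.where(raw <= 600_000, raw, raw - 600_000)
        mapped = np.sort((raw - 0.5) / 1_000_000)
        n = len(mapped)
        gaps = np.maximum(
            np.arange(1, n + 1) / n - mapped, mapped - np.arange(n) / n
        )
        d_brute = gaps.max()
        d_scipy = stats.kstest(mapped, "uniform").statistic
        assert d_scipy == pytest.approx(d_brute, rel=1e-12)
        # and the module applies exactly this mapping
        p_module = chromosome_distribution_test(self._frame(chroms, positions), self.LENGTHS)
        assert p_module == pytest.approx(stats.kstest(mapped, "uniform").pvalue, rel=1e-12)

    def test_too_few_calls_rejected(self):
        with pytest.raises(UndefinedTestError):
            chromosome_distribution_test(self._frame(["chr1"] * 3, [1, 2, 3]), self.LENGTHS)


def _masks(n_offspring, per_stratum):
    return {
        f"o{i + 1:02d}": CallableMask(
            offspring_id=f"o{i + 1:02d}", by_stratum=dict(per_stratum)
        )
        for i in range(n_offspring)
    }


class TestMutationRateModel:
    def _calls(self):
        rows = []
        for i, (child, region, ref, alt) in enumerate(
            [
                ("o01", "gene", "C", "T"),
                ("o01", "intergenic", "A", "G"),
                ("o02", "intergenic", "C", "A"),
                ("o03", "gene", "T", "A"),
            ]
        ):
            rows.append(
                {
                    "chrom": "chr1",
                    "pos": 100 + i,
                    "ref": ref,
                    "alt": alt,
                    "offspring_id": child,
                    "genotype": "0/1",
                    "region": region,
                    "base_class": "CG" if ref in "CG" else "AT",
                    "in_cpg_island": False,
                    "mutation_type": None,
                }
            )
        frame = pd.DataFrame(rows)
        from triomut.spectrum import classify_mutation

        frame["mutation_type"] = [
            classify_mutation(r, a)[0] for r, a in zip(frame["ref"], frame["alt"])
        ]
        return frame

    def test_partition_additivity(self):
        masks = _masks(3, {"intergenic:AT": 400, "intergenic:CG": 200,
                           "gene:AT": 250, "gene:CG": 150})
        model = MutationRateModel.from_calls(self._calls(), masks)
        assert (
            model.counts["gene"] + model.counts["intergenic"]
        ).equals(model.counts["whole_genome"])
        rates = model.observed_rates("whole_genome")
        gene = model.observed_rates("gene")
        inter = model.observed_rates("intergenic")
        assert (np.minimum(gene, inter) <= rates + 1e-18).all()
        assert (rates <= np.maximum(gene, inter) + 1e-18).all()

    def test_mean_is_unweighted_offspring_mean(self):
        masks = _masks(3, {"intergenic:AT": 400, "intergenic:CG": 200,
                           "gene:AT": 250, "gene:CG": 150})
        model = MutationRateModel.from_calls(self._calls(), masks)
        fit = model.fit(b=200, seed=0)
        est = fit["whole_genome"]
        assert est.mean == pytest.approx(np.mean([2, 1, 1]) / (2 * 1000))
        assert est.ci_low <= est.mean <= est.ci_high

    def test_mutation_type_rates_use_base_class_denominator(self):
        masks = _masks(3, {"intergenic:AT": 400, "intergenic:CG": 200,
                           "gene:AT": 250, "gene:CG": 150})
        model = MutationRateModel.from_calls(self._calls(), masks)
        # two G:C-origin calls, denominator = CG callable = 350 per offspring
        rates = model.observed_rates("G:C->A:T")
        assert rates.sum() == pytest.approx(1 / (2 * 350))

    def test_summary_prints_scaled_rates(self):
        masks = _masks(3, {"intergenic:AT": 400, "intergenic:CG": 200,
                           "gene:AT": 250, "gene:CG": 150})
        fit = MutationRateModel.from_calls(self._calls(), masks).fit(b=100, seed=0)
        text = fit.summary()
        assert "whole_genome" in text and "2.5% CI" in text

    def test_zero_callable_stratum_raises(self):
        masks = _masks(3, {"intergenic:AT": 0, "intergenic:CG": 0,
                           "gene:AT": 250, "gene:CG": 150})
        model = MutationRateModel.from_calls(self._calls(), masks)
        with pytest.raises(UndefinedRateError):
            model.observed_rates("intergenic")
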