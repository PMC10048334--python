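"""Strand-collapsed classification, spectrum rates, CpG and flank context."""

import numpy as np
import pandas as pd
import pytest

from triomut.exceptions import (
    ConsistencyError,
    MalformedInputError,
    UndefinedTestError,
)
from triomut.simulate import Annotation, Reference
from triomut.spectrum import (
    SIX_TYPES,
    classify_mutation,
    context_matrix,
    cpg_island_association,
    proportion_test,
    spectrum_summary,
)
from triomut.strata import COMPLEMENT


class TestClassifyMutation:
    @pytest.mark.parametrize(
        "ref,alt,label,kind",
        [
            ("C", "T", "G:C->A:T", "Ts"),
            ("G", "A", "G:C->A:T", "Ts"),
            ("T", "C", "A:T->G:C", "Ts"),
            ("A", "G", "A:T->G:C", "Ts"),
            ("T", "G", "A:T->C:G", "Tv"),
            ("A", "C", "A:T->C:G", "Tv"),
            ("G", "C", "G:C->C:G", "Tv"),
            ("C", "A", "G:C->T:A", "Tv"),
            ("A", "T", "A:T->T:A", "Tv"),
        ],
    )
    def test_known_classifications(self, ref, alt, label, kind):
        assert classify_mutation(ref, alt) == (label, kind)

    def test_strand_involution_invariance(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                assert classify_mutation(ref, alt) == classify_mutation(
                    COMPLEMENT[ref], COMPLEMENT[alt]
                )

    def test_ambiguous_base_rejected(self):
        with pytest.raises(MalformedInputError):
            classify_mutation("N", "A")
        with pytest.raises(MalformedInputError):
            classify_mutation("C", "C")


def _null_calls(n, seed):
    """n substitutions with no bias: uniform ref, uniform non-ref alt."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    refs = bases[rng.integers(0, 4, n)]
    alts = np.array(
        [
            [b for b in "ACGT" if b != r][k]
            for r, k in zip(refs, rng.integers(0, 3, n))
        ]
    )
    return pd.DataFrame(
        {"chrom": "chr1", "pos": np.arange(1, n + 1), "ref": refs, "alt": alts}
    )


class TestSpectrumSummary:
    def test_unbiased_simulation_recovers_null_ts_tv_and_shares(self):
        """No-bias null: Ts/Tv -> 0.5 and each class -> 1/6 of mutations."""
        n = 100_000
        spec = spectrum_summary(_null_calls(n, seed=0), {"AT": n, "CG": n})
        ts_fraction = spec.ts / spec.total
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert abs(ts_fraction - 1 / 3) <= 3 * se  # Ts/Tv = 0.5
        assert abs(spec.ts_tv - 0.5) < 0.02
        se6 = np.sqrt((1 / 6) * (5 / 6) / n)
        for t in SIX_TYPES:
            assert abs(spec.counts[t] / n - 1 / 6) <= 3 * se6

    def test_class_rate_is_sum_of_type_rates(self):
        spec = spectrum_summary(_null_calls(600, seed=2), {"AT": 5000, "CG": 4000})
        rates = spec.rates()
        classes = spec.class_rates()
        assert classes["AT"] == pytest.approx(
            sum(rates[t] for t in SIX_TYPES if t.startswith("A:T"))
        )
        assert classes["CG"] == pytest.approx(
            sum(rates[t] for t in SIX_TYPES if t.startswith("G:C"))
        )

    def test_counts_partition_and_ts_identity(self):
        spec = spectrum_summary(_null_calls(500, seed=3), {"AT": 100, "CG": 100})
        assert sum(spec.counts.values()) == spec.total == 500
        assert spec.ts == spec.counts["A:T->G:C"] + spec.counts["G:C->A:T"]
        assert spec.ts + spec.tv == spec.total

    def test_imposed_gc_to_at_excess_recovered(self):
        rng = np.random.default_rng(9)
        n = 20_000
        # 40% G:C->A:T (as C->T), remaining mass spread over the others
        refs, alts = [], []
        for _ in range(n):
            if rng.random() < 0.4:
                refs.append("C")
                alts.append("T")
            else:
                r = "ACGT"[rng.integers(0, 4)]
                choices = [b for b in "ACGT" if b != r]
                a = choices[rng.integers(0, 3)]
                refs.append(r)
                alts.append(a)
        frame = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(1, n + 1), "ref": refs, "alt": alts}
        )
        spec = spectrum_summary(frame, {"AT": n, "CG": n})
        expected = 0.4 + 0.6 / 6
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(spec.counts["G:C->A:T"] / n - expected) <= 3 * se


class TestCpgAssociation:
    def _calls(self, n_in, n_out):
        rows = []
        for i in range(n_in + n_out):
            rows.append(
                {
                    "chrom": "chr1",
                    "pos": i + 1,
                    "ref": "C",
                    "alt": "T",
                    "mutation_type": "G:C->A:T",
                    "in_cpg_island": i < n_in,
                }
            )
        return pd.DataFrame(rows)

    def test_observed_equal_expected_gives_p_near_one(self):
        res = cpg_island_association(self._calls(10, 90), expected_fraction=0.10)
        assert res.pvalue > 0.9
        assert res.observed_proportion == pytest.approx(0.10)

    def test_extreme_enrichment_significant(self):
        res = cpg_island_association(self._calls(100, 0), expected_fraction=0.10)
        assert res.pvalue < 0.001

    def test_statistic_matches_hand_computed_continuity_corrected_chi2(self):
        from scipy import stats

        k, n, p0 = 30, 100, 0.1
        statistic, pvalue = proportion_test(k, n, p0)
        hand = (abs(k - n * p0) - 0.5) ** 2 / (n * p0 * (1 - p0))
        assert statistic == pytest.approx(hand, rel=1e-12)
        assert pvalue == pytest.approx(stats.chi2.sf(hand, 1), rel=1e-12)

    def test_no_qualifying_calls_rejected(self):
        frame = pd.DataFrame(
            [{"chrom": "chr1", "pos": 1, "ref": "A", "alt": "G",
              "mutation_type": "A:T->G:C", "in_cpg_island": False}]
        )
        with pytest.raises(UndefinedTestError):
            cpg_island_association(frame)

    def test_membership_from_annotation_track(self):
        ann = Annotation(
            genes={}, cpg_islands={"chr1": np.array([[0, 50]], dtype=np.int64)}
        )
        frame = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 10, "ref": "C", "alt": "T",
                 "mutation_type": "G:C->A:T"},
                {"chrom": "chr1", "pos": 200, "ref": "C", "alt": "T",
                 "mutation_type": "G:C->A:T"},
            ]
        )
        res = cpg_island_association(frame, annotation=ann, expected_fraction=0.5)
        assert res.observed_proportion == pytest.approx(0.5)


def _reference_from_string(seq):
    lut = {b: i for i, b in enumerate("ACGT")}
    return Reference({"chr1": np.array([lut[b] for b in seq], dtype=np.uint8)})


class TestContextMatrix:
    def test_fixed_motif_gives_unit_frequency(self):
        # every mutated C sits in an ACG motif: G at +1 with frequency 1
        seq = ("T" * 9 + "ACG" + "T" * 8) * 5
        ref = _reference_from_string(seq)
        positions = [i + 1 for i, b in enumerate(seq) if b == "C" and 10 <= i < len(seq) - 10]
        frame = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "ref": "C", "alt": "T",
             "mutation_type": "G:C->A:T"}
        )
        matrix = context_matrix(frame, ref, flank=10)
        assert matrix.frequency("C", 0) == 1.0
        assert matrix.frequency("G", 1) == 1.0
        assert matrix.frequency("A", -1) == 1.0
        assert matrix.cg_dinucleotide_fraction() == 1.0

    def test_columns_sum_to_one_and_g_calls_are_reverse_complemented(self):
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        ref = _reference_from_string(seq)
        positions = [
            i + 1 for i, b in enumerate(seq) if b in "CG" and 10 <= i < len(seq) - 10
        ][:300]
        frame = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "ref": [seq[p - 1] for p in positions],
                "alt": ["T" if seq[p - 1] == "C" else "A" for p in positions],
                "mutation_type": "G:C->A:T",
            }
        )
        matrix = context_matrix(frame, ref, flank=10)
        assert np.allclose(matrix.matrix.sum(axis=0), 1.0)
        assert matrix.frequency("C", 0) == 1.0  # all windows oriented to C

    def test_null_flank_frequencies_match_base_composition(self):
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
        ref = _reference_from_string(seq)
        positions = [
            i + 1 for i, b in enumerate(seq) if b == "C" and 10 <= i < len(seq) - 10
        ]
        frame = pd.DataFrame(
            {"chrom": "chr1", "pos": positions, "ref": "C", "alt": "T",
             "mutation_type": "G:C->A:T"}
        )
        matrix = context_matrix(frame, ref, flank=10)
        n = matrix.n_used
        se = 3 * np.sqrt(0.25 * 0.75 / n)
        # no CG-dinucleotide bias in a null genome: G at +1 ~ genome G share
        assert abs(matrix.cg_dinucleotide_fraction() - 0.25) <= se

    def test_edge_calls_dropped_with_warning(self):
        seq = "CG" + "T" * 20 + "ACG" + "T" * 20
        ref = _reference_from_string(seq)
        frame = pd.DataFrame(
            [
                {"chrom": "chr1", "pos": 1, "ref": "C", "alt": "T",
                 "mutation_type": "G:C->A:T"},  # within flank of the contig start
                {"chrom": "chr1", "pos": 24, "ref": "C", "alt": "T",
                 "mutation_type": "G:C->A:T"},
            ]
        )
        with pytest.warns(UserWarning, match="contig end"):
            matrix = context_matrix(frame, ref, flank=10)
        assert matrix.n_used == 1
        assert matrix.n_dropped == 1

    def test_reference_mismatch_raises(self):
        ref = _reference_from_string("T" * 9 + "ACG" + "T" * 9)
        frame = pd.DataFrame(
            [{"chrom": "chr1", "pos": 5, "ref": "C", "alt": "T",
              "mutation_type": "G:C->A:T"}]
        )
        with pytest.raises(ConsistencyError):
            context_matrix(frame, ref, flank=3)
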