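"""Population statistics: ANOVA, t-tests, effect sizes, Tukey, MAF."""

import itertools
import math

import numpy as np
import pytest

from codonpop import (
    GroupedValues,
    PopulationAssignment,
    bonferroni_threshold,
    cohens_d,
    count_pairwise_tests,
    minor_allele_frequency,
    one_way_anova,
    pairwise_t_tests,
    tukey_hsd,
)

from conftest import anova_f_by_hand


def grouped(**kwargs):
    return GroupedValues.from_lists(kwargs)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        result = one_way_anova(grouped(a=[1, 2, 3], b=[1, 2, 3], c=[1, 2, 3]))
        assert result.statistic == pytest.approx(0.0)

    def test_two_groups_f_is_t_squared(self):
        rng = np.random.default_rng(2)
        g = grouped(a=rng.normal(size=12), b=rng.normal(0.5, 1, size=15))
        f = one_way_anova(g).statistic
        t = pairwise_t_tests(g, threshold=0.05)[0].statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_matches_hand_sum_of_squares(self):
        data = {"a": [3.0, 5.0, 4.0], "b": [6.0, 8.0, 7.0, 9.0], "c": [2.0, 2.5]}
        result = one_way_anova(GroupedValues.from_lists(data))
        assert result.statistic == pytest.approx(anova_f_by_hand(data), rel=1e-12)

    def test_degenerate_groups_named_in_error(self):
        g = GroupedValues.from_lists({"a": [1.0], "b": [1, 2]}, gene="GENE7", codon="CTG")
        with pytest.raises(ValueError, match="GENE7.*a"):
            one_way_anova(g)
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova(GroupedValues.from_lists({"a": [1, 2]}))

    def test_significance_flag_uses_threshold(self):
        g = grouped(a=[0.0, 0.1, -0.1, 0.05], b=[5.0, 5.1, 4.9, 5.05])
        assert one_way_anova(g, threshold=1e-3).significant
        assert not one_way_anova(g, threshold=1e-30).significant


class TestPairwiseT:
    def test_combinatorial_count(self):
        rng = np.random.default_rng(3)
        g = GroupedValues.from_lists(
            {f"g{i}": rng.normal(size=5) for i in range(6)}
        )
        results = pairwise_t_tests(g, threshold=0.05)
        assert len(results) == 15  # C(6, 2)
        assert {frozenset(r.groups) for r in results} == {
            frozenset(p) for p in itertools.combinations(g.group_names, 2)
        }

    def test_identical_pair(self):
        g = grouped(a=[1.0, 2.0, 3.0], b=[1.0, 2.0, 3.0])
        r = pairwise_t_tests(g, threshold=0.05)[0]
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant
        assert r.effect_size is None  # d attached to significant tests only
        assert cohens_d(g.values["a"], g.values["b"]) == pytest.approx(0.0)

    def test_planted_shift_of_one_pooled_sd(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.0, 1.0, size=100)
        b = rng.normal(1.0, 1.0, size=100)
        r = pairwise_t_tests(grouped(a=a, b=b), threshold=1e-3)[0]
        assert r.significant
        assert abs(r.effect_size) == pytest.approx(1.0, abs=0.35)

    def test_welch_flag(self):
        rng = np.random.default_rng(9)
        g = grouped(a=rng.normal(0, 1, 10), b=rng.normal(0, 5, 40))
        student = pairwise_t_tests(g, 0.05, equal_var=True)[0]
        welch = pairwise_t_tests(g, 0.05, equal_var=False)[0]
        assert student.p_value != welch.p_value


class TestCohensD:
    def test_equal_means(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(0.0)

    def test_shift_equal_to_pooled_sd(self):
        a = [0.0, 2.0]  # sd sqrt(2), mean 1
        b = [math.sqrt(2), math.sqrt(2) + 2.0]
        assert cohens_d(b, a) == pytest.approx(1.0)

    def test_textbook_hand_calculation(self):
        # group SS are both 8 -> pooled var (8 + 8) / 6; d = 3 / sqrt(8/3)
        a = [8.0, 10.0, 12.0, 10.0]
        b = [5.0, 7.0, 9.0, 7.0]
        assert cohens_d(a, b) == pytest.approx(3.0 / math.sqrt(8.0 / 3.0))

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=10), rng.normal(1, 2, size=14)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_zero_pooled_variance_is_missing(self):
        assert math.isnan(cohens_d([2.0, 2.0], [3.0, 3.0]))


class TestMultipleTesting:
    def test_genome_wide_pairwise_test_count(self):
        assert count_pairwise_tests(17634, 61, 5) == 10_756_740

    def test_single_cell(self):
        assert count_pairwise_tests(1, 1, 2) == 1

    def test_matches_triple_loop(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            ng, nc, nk = rng.integers(1, 6, size=3)
            explicit = sum(
                1
                for _ in range(ng)
                for _ in range(nc)
                for _ in itertools.combinations(range(nk + 1), 2)
            )
            assert count_pairwise_tests(ng, nc, nk + 1) == explicit

    def test_bonferroni_values(self):
        assert bonferroni_threshold(0.05, 10_756_740) == pytest.approx(4.6483e-9, rel=1e-4)
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 15) == pytest.approx(0.003333, abs=5e-7)

    def test_bonferroni_strictly_decreasing(self):
        thresholds = [bonferroni_threshold(0.05, n) for n in range(1, 50)]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_validation(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            count_pairwise_tests(0, 61, 5)


class TestTukey:
    def test_identical_groups(self):
        results = tukey_hsd(grouped(a=[1, 2, 3], b=[1, 2, 3], c=[1, 2, 3]))
        assert all(r.p_value == pytest.approx(1.0) for r in results)

    def test_one_shifted_group_flagged_against_all_others(self):
        rng = np.random.default_rng(12)
        g = GroupedValues.from_lists(
            {
                "a": rng.normal(0, 1, 40),
                "b": rng.normal(0, 1, 40),
                "c": rng.normal(0, 1, 40),
                "shifted": rng.normal(3, 1, 40),
            }
        )
        results = tukey_hsd(g, threshold=0.05)
        for r in results:
            involves_shift = "shifted" in r.groups
            assert r.significant == involves_shift

    def test_two_group_decision_agrees_with_t_test(self):
        rng = np.random.default_rng(21)
        for shift in (0.0, 2.0):
            g = grouped(a=rng.normal(0, 1, 30), b=rng.normal(shift, 1, 30))
            tukey = tukey_hsd(g, threshold=0.05)[0]
            ttest = pairwise_t_tests(g, threshold=0.05)[0]
            assert tukey.significant == ttest.significant


class TestMinorAlleleFrequency:
    @staticmethod
    def assignment(samples_by_group):
        sub = {s: g for g, ss in samples_by_group.items() for s in ss}
        return PopulationAssignment(subpopulation=sub, superpopulation=dict(sub))

    def test_all_homozygous_reference(self):
        assign = self.assignment({"g1": ["s1", "s2"]})
        maf = minor_allele_frequency({"s1": 0, "s2": 0}, assign)
        assert maf == {"g1": 0.0}

    def test_one_het_among_two_diploids(self):
        assign = self.assignment({"g1": ["s1", "s2"]})
        maf = minor_allele_frequency({"s1": 1, "s2": 0}, assign)
        assert maf["g1"] == pytest.approx(0.25)

    def test_minor_allele_defined_on_pooled_cohort(self):
        # alt is the pooled major allele -> per-group frequency of the minor
        # (reference) allele; one group may still exceed 0.5
        assign = self.assignment({"g1": ["a1", "a2"], "g2": ["b1", "b2"]})
        genotypes = {"a1": 2, "a2": 2, "b1": 1, "b2": 0}
        maf = minor_allele_frequency(genotypes, assign)
        # pooled alt freq 5/8 -> minor allele is ref
        assert maf["g1"] == pytest.approx(0.0)
        assert maf["g2"] == pytest.approx(0.75)

    def test_missing_genotypes_shrink_denominator(self):
        assign = self.assignment({"g1": ["s1", "s2", "s3"]})
        maf = minor_allele_frequency(
            {"s1": 1, "s2": float("nan"), "s3": 0}, assign
        )
        assert maf["g1"] == pytest.approx(0.25)

    def test_matches_direct_count(self):
        rng = np.random.default_rng(4)
        samples = {f"s{i}": int(rng.integers(0, 3)) for i in range(40)}
        assign = self.assignment(
            {"g1": [s for i, s in enumerate(samples) if i % 2 == 0],
             "g2": [s for i, s in enumerate(samples) if i % 2 == 1]}
        )
        maf = minor_allele_frequency(samples, assign)
        pooled = sum(samples.values()) / (2 * len(samples))
        for group in ("g1", "g2"):
            members = [s for s in samples if assign.subpopulation[s] == group]
            alt = sum(samples[s] for s in members) / (2 * len(members))
            expected = alt if pooled <= 0.5 else 1 - alt
            assert maf[group] == pytest.approx(expected)

    def test_invalid_genotype_rejected(self):
        assign = self.assignment({"g1": ["s1", "s2"]})
        with pytest.raises(ValueError, match="s1"):
            minor_allele_frequency({"s1": 3, "s2": 0}, assign)


class TestPopulationAssignment:
    def test_subpopulation_cannot_straddle_superpopulations(self):
        with pytest.raises(ValueError, match="multiple superpopulations"):
            PopulationAssignment(
                subpopulation={"s1": "X", "s2": "X"},
                superpopulation={"s1": "A", "s2": "B"},
            )

    def test_groups_and_lookup(self):
        assign = PopulationAssignment(
            subpopulation={"s1": "X", "s2": "Y"},
            superpopulation={"s1": "A", "s2": "A"},
        )
        assert assign.groups("subpopulation") == ("X", "Y")
        assert assign.groups() == ("A",)
        assert assign.group_of("s1") == "A"
        assert assign.group_of("s1", "subpopulation") == "X"
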