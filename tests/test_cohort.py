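"""Cohort statistics: frequency classification, summary matrices,
per-sample proportions, rank-sum and chi-squared kernels checked against
exact-enumeration / closed-form oracles, validation rates."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from indelkit import cohort as cstats
from indelkit.model import (
    CohortCallSet,
    Consequence,
    FrequencyClass,
    Genotype,
    NormalizedIndel,
    Provenance,
    SampleCall,
)

C = Consequence


def make_cohort(n_samples, carriers):
    """carriers: {variant: [(sample_index, genotype), ...]}"""
    samples = {f"s{i}": ("familial" if i < 2 else "sporadic") for i in range(n_samples)}
    calls = [
        SampleCall(f"s{i}", v, gt)
        for v, lst in carriers.items()
        for i, gt in lst
    ]
    return CohortCallSet(samples=samples, calls=calls)


V1 = NormalizedIndel("chr1", 100, "A", "")
V2 = NormalizedIndel("chr1", 500, "", "TT")
V3 = NormalizedIndel("chr1", 900, "AGG", "")


class TestFrequencies:
    def test_single_het_in_173_is_private(self):
        cohort = make_cohort(173, {V1: [(0, Genotype.HET)]})
        rec = cstats.compute_frequencies(cohort)[V1]
        assert rec.freq == pytest.approx(1 / 346)
        assert rec.freq_class is FrequencyClass.PRIVATE

    def test_threshold_is_inclusive_for_common(self):
        # 9 carriers totalling 10 alleles in 100 samples -> freq exactly 0.05
        carriers = [(i, Genotype.HET) for i in range(8)] + [(8, Genotype.HOM_ALT)]
        cohort = make_cohort(100, {V1: carriers})
        rec = cstats.compute_frequencies(cohort, threshold=0.05)[V1]
        assert rec.freq == pytest.approx(0.05)
        assert rec.freq_class is FrequencyClass.COMMON

    def test_two_hets_in_173_is_rare(self):
        cohort = make_cohort(173, {V1: [(0, Genotype.HET), (1, Genotype.HET)]})
        rec = cstats.compute_frequencies(cohort)[V1]
        assert rec.freq == pytest.approx(2 / 346)
        assert rec.freq_class is FrequencyClass.RARE

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cstats.compute_frequencies(CohortCallSet(samples={}))

    def test_allele_count_conservation_and_class_partition(self):
        rng = np.random.default_rng(8)
        carriers = {}
        total_alleles = 0
        for i in range(50):
            v = NormalizedIndel("chr1", 100 + 40 * i, "A", "")
            lst = []
            for s in rng.choice(60, size=int(rng.integers(1, 12)), replace=False):
                gt = Genotype.HET if rng.random() < 0.8 else Genotype.HOM_ALT
                lst.append((int(s), gt))
                total_alleles += gt.allele_count
            carriers[v] = lst
        cohort = make_cohort(60, carriers)
        freqs = cstats.compute_frequencies(cohort)
        assert sum(r.allele_count for r in freqs.values()) == total_alleles
        for r in freqs.values():
            assert r.freq_class in FrequencyClass  # exactly one class each
            assert 0 < r.freq <= 1


class TestSummaries:
    def test_shared_variant_cell_mean_and_sd(self):
        cohort = make_cohort(2, {V1: [(0, Genotype.HET), (1, Genotype.HET)]})
        freqs = cstats.compute_frequencies(cohort)
        summary = cstats.summarize_counts(
            cohort, {V1: Provenance.KNOWN_DB}, {V1: C.INTRONIC}, freqs
        )
        assert summary.loc["INTRONIC", ("KNOWN_DB", "mean")] == pytest.approx(1.0)
        assert summary.loc["INTRONIC", ("KNOWN_DB", "sd")] == pytest.approx(0.0)
        # empty stratum keeps its zero row
        assert summary.loc["STOP", ("KNOWN_DB", "mean")] == 0.0

    def test_exclusion_moves_borderline_variant_common_to_rare(self):
        # 50 samples: 3 carriers (freq 3/100 = 0.03)... construct instead a
        # variant at freq 0.052 that drops below 0.05 once familial samples
        # (the first two) are excluded.
        # 48 sporadic + 2 familial = 50 samples; carriers: 2 familial hets +
        # 3 sporadic hets + 0 -> freq 5/100 = 0.05 (COMMON, inclusive);
        # excluding familial: 3/96 = 0.031 -> RARE
        carriers = [(0, Genotype.HET), (1, Genotype.HET)] + [
            (i, Genotype.HET) for i in (5, 6, 7)
        ]
        cohort = make_cohort(50, {V1: carriers})
        freqs = cstats.compute_frequencies(cohort)
        assert freqs[V1].freq_class is FrequencyClass.COMMON
        excl = cohort.exclude_subgroup("familial")
        f2 = cstats.compute_frequencies(excl)[V1]
        assert f2.freq == pytest.approx(3 / 96)
        assert f2.freq_class is FrequencyClass.RARE

    def test_variant_private_to_excluded_sample_disappears(self):
        cohort = make_cohort(
            10, {V1: [(0, Genotype.HET)], V2: [(5, Genotype.HET)]}
        )
        prov = {V1: Provenance.NOVEL, V2: Provenance.NOVEL}
        cons = {V1: C.INTRONIC, V2: C.INTRONIC}
        matrix = cstats.recompute_excluding(cohort, "familial", prov, cons)
        # V1 was private to familial sample s0: only V2 remains
        assert matrix.loc["INTRONIC", ("NOVEL", "mean")] == pytest.approx(1 / 8)

    def test_excluding_noncarrier_subgroup_keeps_matrix(self):
        cohort = make_cohort(10, {V1: [(5, Genotype.HET), (6, Genotype.HET)]})
        prov = {V1: Provenance.KNOWN_DB}
        cons = {V1: C.INTRONIC}
        freqs = cstats.compute_frequencies(cohort.exclude_subgroup("familial"))
        direct = cstats.summarize_counts(
            cohort.exclude_subgroup("familial"), prov, cons, freqs
        )
        via_op = cstats.recompute_excluding(cohort, "familial", prov, cons)
        pd.testing.assert_frame_equal(direct, via_op)


class TestProportions:
    def test_percentages_and_row_sums(self):
        carriers = {
            NormalizedIndel("chr1", 100 + 40 * i, "A", ""): [(0, Genotype.HET)]
            for i in range(10)
        }
        cohort = make_cohort(3, carriers)
        cons = {}
        for i, v in enumerate(carriers):
            cons[v] = C.INTRONIC if i < 4 else C.FRAMESHIFT_CODING
        props = cstats.consequence_proportions(cohort, cons)
        assert props.loc["s0", "INTRONIC"] == pytest.approx(40.0)
        assert props.loc["s0"].sum() == pytest.approx(100.0, abs=1e-9)
        # samples with zero calls are excluded
        assert list(props.index) == ["s0"]


def exact_ranksum_p(a, b):
    """Enumerate all rank assignments; two-sided Mann-Whitney p."""
    pooled = list(a) + list(b)
    n1, n2 = len(a), len(b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"

    def ustat(group):
        return sum(1 for x in group for y in pooled if y not in group and x > y)

    # enumerate U over all choices of which observations form group A
    us = [
        sum(1 for x in chosen for y in pooled if y not in set(chosen) and x > y)
        for chosen in combinations(pooled, n1)
    ]
    u_obs = sum(1 for x in a for y in b if x > y)
    u = min(u_obs, n1 * n2 - u_obs)
    p = 2 * sum(1 for x in us if x <= u) / comb(n1 + n2, n1)
    return min(1.0, p)


class TestRankSumKernel:
    def test_textbook_separation_gives_exact_point_one(self):
        a = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"X": [4.0, 5.0, 6.0]})
        res = cstats.compare_groups(a, b)
        assert res.loc["X", "p_raw"] == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        a = pd.DataFrame({"X": [1.0, 2.0, 3.0]})
        res = cstats.compare_groups(a, a.copy())
        assert res.loc["X", "p_raw"] == pytest.approx(1.0)

    def test_matches_exact_enumeration_across_group_sizes(self):
        """No-tie group sizes up to 6x6 here; the full <=8 sweep runs in the
        acceptance suite."""
        rng = np.random.default_rng(11)
        for n1 in range(2, 7):
            for n2 in range(2, 7):
                vals = rng.permutation(100)[: n1 + n2].astype(float)
                a, b = vals[:n1], vals[n1:]
                res = cstats.compare_groups(
                    pd.DataFrame({"X": a}), pd.DataFrame({"X": b})
                )
                assert res.loc["X", "p_raw"] == pytest.approx(
                    exact_ranksum_p(a, b)
                ), (n1, n2)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("wxyz"))
        b = pd.DataFrame(rng.normal(0.5, size=(6, 4)), columns=list("wxyz"))
        res = cstats.compare_groups(a, b)
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-12).all()


class TestChiSquared:
    def test_independence_gives_zero(self):
        chi2, df, p = cstats.validation_chisq([[10, 10], [10, 10]], yates=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_uncorrected_matches_closed_form(self):
        table = np.array([[20, 5], [10, 15]], dtype=float)
        chi2, _, _ = cstats.validation_chisq(table, yates=False)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum())

    def test_random_tables_match_closed_form(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            shape = (2, int(rng.integers(2, 5)))
            table = rng.integers(1, 60, size=shape).astype(float)
            chi2, df, _ = cstats.validation_chisq(table, yates=False)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            assert chi2 == pytest.approx(((table - expected) ** 2 / expected).sum())
            assert df == shape[1] - 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cstats.validation_chisq([[0, 0], [5, 5]])


class TestValidationRates:
    @pytest.mark.parametrize(
        "validated,not_validated,rate",
        [(24, 13, 64.86), (42, 3, 93.33), (66, 16, 80.49), (75, 3, 96.15)],
    )
    def test_row_rates(self, validated, not_validated, rate):
        table = pd.DataFrame(
            [[validated, not_validated]], index=["row"],
            columns=["validated", "not_validated"],
        )
        out = cstats.validation_rates(table)
        assert out.loc["row", "rate_percent"] == pytest.approx(rate)

    def test_overall_rate_half_up(self):
        # 141/160 = 88.125 -> 88.13 under half-up rounding
        table = pd.DataFrame(
            [[66, 16], [75, 3]], index=["common", "private"],
            columns=["validated", "not_validated"],
        )
        out = cstats.validation_rates(table)
        assert out.loc["Total", "rate_percent"] == pytest.approx(88.13)


class TestSizeSpectrum:
    def test_counts_and_bounds(self):
        ins = [NormalizedIndel("c", 10 * i + 10, "", "AT") for i in range(3)]
        spec = cstats.size_spectrum({"calls": ins, "known_db": []}, max_len=15)
        assert spec.loc[2, "calls"] == 3
        assert spec["calls_density"].sum() == pytest.approx(1.0)
        assert (spec.index.to_series().abs() <= 15).all()

    def test_empty_stratum_all_zero(self):
        spec = cstats.size_spectrum(
            {"calls": [NormalizedIndel("c", 5, "A", "")], "known_db": []}
        )
        assert spec["known_db"].sum() == 0
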