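"""Burden measures, permutation machinery, Fisher tests, group comparison, power."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from cnvburden import (
    GeneModel,
    GenomicInterval,
    RareCnvBurden,
    burden_measures,
    fisher_region_test,
    group_comparison,
    permutation_test,
    regional_scan,
    two_proportion_power,
)
from cnvburden.rare import AnnotatedCnv

from conftest import make_call, make_sample


def annotated(sample, start, end, cnv_type="deletion", genes=(), rare=True, chrom="chr1"):
    return AnnotatedCnv(
        call=make_call(sample, chrom, start, end, cnv_type=cnv_type),
        control_freq=0.0,
        common_overlap_frac=0.0,
        genes=genes,
        is_rare=rare,
    )


def exhaustive_perm_p(x, n_case, alternative="greater"):
    """Enumerate every case/control labelling; includes the identity labelling."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    case_idx = list(range(n_case))
    obs = x[case_idx].mean() - np.delete(x, case_idx).mean()
    count = total = 0
    for idx in combinations(range(n), n_case):
        stat = x[list(idx)].mean() - np.delete(x, list(idx)).mean()
        total += 1
        if alternative == "two-sided":
            hit = abs(stat) >= abs(obs) - 1e-12
        else:
            hit = stat >= obs - 1e-12
        count += hit
    return count / total


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exact-integer hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    obs_num = comb(row1, a) * comb(n - row1, col1 - a)
    total = 0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        num = comb(row1, k) * comb(n - row1, col1 - k)
        # integer comparison with a tiny relative slack, as scipy uses floats
        if num <= obs_num or (num - obs_num) * 10**12 <= obs_num:
            total += num
    return total / denom


class TestBurdenMeasures:
    def test_zero_cnvs_all_measures_zero(self):
        samples = [make_sample("T1"), make_sample("C1", phenotype="control")]
        per_sample, summary = burden_measures([], samples)
        assert (per_sample[["count", "total_kb", "n_genes"]].to_numpy() == 0).all()
        for group in ("case", "control", "all"):
            assert summary[group]["cnv_rate"] == 0
            assert summary[group]["sample_proportion"] == 0

    def test_two_deletion_arithmetic(self):
        """One sample with 150 kb + 250 kb deletions: rate 2, total 400 kb, average 200 kb."""
        samples = [make_sample("T1"), make_sample("C1", phenotype="control")]
        cnvs = [
            annotated("T1", 1, 150_000),
            annotated("T1", 1_000_000, 1_249_999),
        ]
        per_sample, summary = burden_measures(cnvs, samples, cnv_class="deletions")
        row = per_sample.loc["T1"]
        assert row["count"] == 2
        assert row["total_kb"] == pytest.approx(400.0)
        assert row["mean_kb"] == pytest.approx(200.0)
        assert summary["case"]["cnv_rate"] == 2.0
        assert summary["case"]["average_size"] == pytest.approx(200.0)

    def test_total_equals_rate_times_average_per_sample(self, small_cohort):
        from cnvburden import annotate_cohort

        ann = annotate_cohort(
            small_cohort.calls_by_caller, small_cohort.samples,
            small_cohort.genes, small_cohort.common_track,
        )
        per_sample, _ = burden_measures(ann, small_cohort.samples)
        np.testing.assert_allclose(
            per_sample["total_kb"], per_sample["count"] * per_sample["mean_kb"]
        )
        assert (per_sample[["count", "total_kb", "n_genes", "genes_per_kb"]] >= 0).all().all()

    def test_deletion_duplication_ratio_display(self):
        """The published T2D-side counts 189/337 give the reported 0.56 ratio."""
        assert round(189 / 337, 2) == 0.56

    def test_genic_proportion_variants(self):
        samples = [make_sample("T1"), make_sample("T2"), make_sample("C1", phenotype="control")]
        cnvs = [
            annotated("T1", 1, 150_000, genes=("G1",)),
            annotated("T1", 500_000, 700_000),
            annotated("C1", 1, 150_000),
        ]
        _, summary = burden_measures(cnvs, samples)
        assert summary["case"]["genic_proportion"] == pytest.approx(0.5)  # 1 of 2 samples
        assert summary["case"]["genic_proportion_per_cnv"] == pytest.approx(0.5)  # 1 of 2 calls
        assert summary["control"]["genic_proportion_per_cnv"] == 0.0

    def test_empty_sample_set_is_an_error(self):
        with pytest.raises(ValueError):
            burden_measures([], [])

    def test_sex_chromosome_calls_excluded_by_default(self):
        samples = [make_sample("T1"), make_sample("C1", phenotype="control")]
        cnvs = [annotated("T1", 1, 150_000, chrom="chrX")]
        _, summary = burden_measures(cnvs, samples)
        assert summary["case"]["cnv_rate"] == 0.0
        _, summary = burden_measures(cnvs, samples, autosomes_only=False)
        assert summary["case"]["cnv_rate"] == 1.0


class TestPermutationTest:
    def test_exhaustive_enumeration_on_small_instances(self, rng):
        """With C(n, k) <= n_perm the p-value equals the enumeration oracle exactly."""
        for _ in range(10):
            n = int(rng.integers(6, 11))
            k = int(rng.integers(2, n - 1))
            x = rng.normal(size=n).round(3)
            labels = np.zeros(n, dtype=int)
            labels[:k] = 1
            res = permutation_test(x, labels, n_perm=10_000, seed=0)
            assert res.p_raw == pytest.approx(exhaustive_perm_p(x, k))

    def test_sampled_p_within_monte_carlo_error_of_exhaustive(self, rng):
        x = rng.normal(size=13)
        labels = np.array([1] * 6 + [0] * 7)
        truth = exhaustive_perm_p(x, 6)
        res = permutation_test(x, labels, n_perm=1000, adaptive=False, seed=4)
        se = math.sqrt(truth * (1 - truth) / 1000)
        assert abs(res.p_raw - truth) < 4 * se + 2 / 1000

    def test_constant_statistic_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            res = permutation_test([1.0] * 10, [1] * 5 + [0] * 5)
        assert res.p_raw == 1.0

    def test_identical_seed_identical_p(self, rng):
        x = rng.normal(size=40)
        labels = np.array([1] * 25 + [0] * 15)
        cov = rng.normal(size=(40, 2))
        a = permutation_test(x, labels, covariates=cov, n_perm=500, seed=9)
        b = permutation_test(x, labels, covariates=cov, n_perm=500, seed=9)
        assert (a.p_raw, a.p_adjusted) == (b.p_raw, b.p_adjusted)

    def test_singular_covariate_design_is_an_error(self, rng):
        x = rng.normal(size=20)
        labels = np.array([1] * 10 + [0] * 10)
        cov = np.ones((20, 2))  # collinear with the intercept
        with pytest.raises(ValueError, match="singular"):
            permutation_test(x, labels, covariates=cov, n_perm=100, seed=0)

    def test_adjustment_removes_confounder_driven_signal(self, rng):
        """Statistic fully explained by a covariate: adjusted p should be null-like."""
        n = 200
        labels = np.array([1] * 100 + [0] * 100)
        confounder = labels * 2.0 + rng.normal(size=n) * 0.1
        x = confounder * 3.0  # group difference exists, but only via the confounder
        res = permutation_test(x, labels, covariates=confounder, n_perm=2000, seed=3)
        assert res.p_raw < 0.01
        assert res.p_adjusted > 0.2

    def test_string_labels_accepted(self, rng):
        x = rng.normal(size=12)
        labels = ["case"] * 6 + ["control"] * 6
        res = permutation_test(x, labels, n_perm=2000, seed=1)
        assert 0 < res.p_raw <= 1

    def test_adaptive_stops_early_for_null_statistics(self, rng):
        x = rng.normal(size=300)
        labels = np.array([1] * 150 + [0] * 150)
        res = permutation_test(x, labels, n_perm=10_000, adaptive=True, seed=2)
        if res.p_raw > 0.2:
            assert res.n_used < 10_000


class TestFisher:
    def test_znf718_table(self):
        assert round(fisher_region_test(0, 686, 2, 194), 3) == 0.048

    def test_equal_proportions_give_p_one(self):
        assert fisher_region_test(5, 50, 5, 50) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            n1, n2 = int(rng.integers(1, 31)), int(rng.integers(1, 31))
            a, b = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            p = fisher_region_test(a, n1, b, n2)
            oracle = exact_fisher_oracle(a, n1 - a, b, n2 - b)
            assert p == pytest.approx(oracle, abs=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_region_test(5, 4, 0, 10)


class TestRegionalScan:
    SAMPLES = [make_sample(f"T{i}") for i in range(686)] + [
        make_sample(f"C{i}", phenotype="control") for i in range(194)
    ]

    def test_gene_with_no_carriers_not_tested(self):
        tests = regional_scan([], self.SAMPLES)
        assert tests == []

    def test_control_only_carrier_pattern(self):
        """Two control carriers, zero cases, 686/194: the inverse-association pattern."""
        cnvs = [
            annotated("C0", 43_276, 146_490, cnv_type="deletion", genes=("ZNF718-like",), chrom="chr4"),
            annotated("C1", 43_276, 146_490, cnv_type="duplication", genes=("ZNF718-like",), chrom="chr4"),
        ]
        tests = {t.cnv_class: t for t in regional_scan(cnvs, self.SAMPLES)}
        both = tests["both"]
        assert (both.carriers_case, both.carriers_control) == (0, 2)
        assert round(both.p, 3) == 0.048
        assert tests["deletions"].carriers_control == 1

    def test_carrier_counts_invariant_to_order(self, rng):
        cnvs = [
            annotated(f"T{i}", 100_000, 300_000, genes=("G1",)) for i in range(5)
        ] + [annotated("C0", 100_000, 300_000, genes=("G1",))]
        t1 = regional_scan(cnvs, self.SAMPLES)
        t2 = regional_scan(list(reversed(cnvs)), self.SAMPLES)
        assert t1 == t2

    def test_fdr_qvalues_attached(self):
        cnvs = [annotated("T0", 100_000, 300_000, genes=("G1", "G2"))]
        tests = regional_scan(cnvs, self.SAMPLES, fdr=True)
        assert all(t.q is not None for t in tests)


class TestGroupComparison:
    def test_identical_groups_give_p_one(self):
        samples = [make_sample(f"T{i}", age=40 + i) for i in range(5)] + [
            make_sample(f"C{i}", phenotype="control", age=40 + i) for i in range(5)
        ]
        report = group_comparison(samples)
        by_char = report.set_index("characteristic")
        assert by_char.loc["male/female sex", "p"] == pytest.approx(1.0)
        assert by_char.loc["age", "p"] == pytest.approx(1.0)

    def test_u_statistic_matches_rank_enumeration(self):
        """{1,2,3} vs {4,5,6}: U = 0 pairs won; normal approximation p by hand."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u = sum(1 for a in x for b in y if a > b)  # hand enumeration: 0
        assert u == 0
        m_u, sd_u = 4.5, math.sqrt(3 * 3 * 7 / 12)
        p_hand = 2 * stats.norm.cdf((u - m_u) / sd_u)
        _, p_scipy = stats.mannwhitneyu(
            x, y, alternative="two-sided", use_continuity=False, method="asymptotic"
        )
        assert p_scipy == pytest.approx(p_hand)
        samples = [make_sample(f"T{i}", bmi=v) for i, v in enumerate(x)] + [
            make_sample(f"C{i}", phenotype="control", bmi=v) for i, v in enumerate(y)
        ]
        report = group_comparison(samples).set_index("characteristic")
        assert report.loc["bmi", "p"] == pytest.approx(p_hand)

    def test_deldup_distribution_row(self):
        samples = [make_sample("T1"), make_sample("T2"), make_sample("C1", phenotype="control"),
                   make_sample("C2", phenotype="control")]
        cnvs = (
            [annotated("T1", i * 1_000_000, i * 1_000_000 + 200_000) for i in range(1, 4)]
            + [annotated("T2", i * 1_000_000, i * 1_000_000 + 200_000, cnv_type="duplication")
               for i in range(1, 6)]
            + [annotated("C1", 1, 200_000), annotated("C2", 1_000_000, 1_200_000, cnv_type="duplication")]
        )
        report = group_comparison(samples, cnvs).set_index("characteristic")
        assert report.loc["deletions/duplications", "case"] == "3/5"
        assert report.loc["deletions/duplications", "control"] == "1/1"
        expected = stats.chi2_contingency([[3, 1], [5, 1]], correction=False)[1]
        assert report.loc["deletions/duplications", "p"] == pytest.approx(expected)

    def test_zero_variance_numeric_warns_but_runs(self):
        samples = [make_sample(f"T{i}", mds2=0.0) for i in range(3)] + [
            make_sample(f"C{i}", phenotype="control", mds2=0.0) for i in range(3)
        ]
        with pytest.warns(UserWarning, match="mds2"):
            report = group_comparison(samples)
        assert "mds2" in set(report["characteristic"])


class TestTwoProportionPower:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0.42, 0.31, 0.799),  # overall genic CNV proportion
            (0.0, 2 / 194, 0.646),  # two control carriers, none in cases
            (0.0, 1 / 194, 0.483),  # one control carrier
        ],
    )
    def test_published_posthoc_values(self, p1, p2, expected):
        assert round(two_proportion_power(p1, p2, 686, 194), 3) == expected

    def test_case_only_carrier_configuration(self):
        """A single case carrier in the larger group: power collapses to near zero.

        The unbalanced design makes a case-private CNV essentially
        undetectable (power < 0.01), far below the control-private
        configuration's 0.483.
        """
        power = two_proportion_power(1 / 686, 0.0, 686, 194)
        assert power < 0.01
        assert power < two_proportion_power(0.0, 1 / 194, 686, 194)

    def test_monotone_in_sample_size(self):
        small = two_proportion_power(0.42, 0.31, 50, 20)
        big = two_proportion_power(0.42, 0.31, 50_000, 20_000)
        assert small < big
        assert big > 0.9999

    def test_equal_proportions_return_alpha_floor(self):
        z = stats.norm.ppf(0.975)
        assert two_proportion_power(0.3, 0.3, 100, 100) == pytest.approx(stats.norm.cdf(-z))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_power(1.2, 0.3, 10, 10)
        with pytest.raises(ValueError):
            two_proportion_power(0.3, 0.2, 0, 10)


class TestBurdenModel:
    def test_fit_produces_full_grid(self, small_cohort):
        from cnvburden import annotate_cohort

        ann = annotate_cohort(
            small_cohort.calls_by_caller, small_cohort.samples,
            small_cohort.genes, small_cohort.common_track,
        )
        model = RareCnvBurden(ann, small_cohort.samples)
        res = model.fit(n_perm=300, seed=1)
        assert len(res.results) == 21  # 7 measures x 3 classes
        assert set(res.table["cnv_class"]) == {"deletions", "duplications", "both"}
        for r in res.results:
            assert 0 < r.p_raw <= 1
            assert 0 < r.p_adjusted <= 1
            assert r.n_permutations_used <= 300
        text = res.summary()
        assert "cnv_rate" in text and "p_adjusted" in text

    def test_fit_reproducible_with_seed(self, small_cohort):
        from cnvburden import annotate_cohort

        ann = annotate_cohort(
            small_cohort.calls_by_caller, small_cohort.samples,
            small_cohort.genes, small_cohort.common_track,
        )
        model = RareCnvBurden(ann, small_cohort.samples)
        a = model.fit(n_perm=200, seed=5).table
        b = model.fit(n_perm=200, seed=5).table
        assert a.equals(b)

    def test_zero_cnv_cohort_gives_p_one(self):
        samples = [make_sample(f"T{i}") for i in range(4)] + [
            make_sample(f"C{i}", phenotype="control") for i in range(4)
        ]
        model = RareCnvBurden([], samples)
        res = model.fit(n_perm=100, seed=0)
        assert (res.table["p_raw"] == 1.0).all()
        assert (res.table[["case", "control"]].fillna(0) == 0).all().all()
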