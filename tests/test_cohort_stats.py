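import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellascribe import (
    ContingencyTable,
    chi_square_test,
    extreme_group_marker_test,
    fisher_exact_2x2,
    fraction_correlation,
    fraction_distribution_tests,
    ks_two_sample,
    match_probes_by_symbol,
    paired_weight_comparison,
)
from cellascribe.cohort_stats import compartment_t_tests

from conftest import make_annotation, make_matrix


def table_2x2(a, b, c, d):
    return ContingencyTable(("r1", "r2"), ("c1", "c2"), ((a, b), (c, d)))


class TestChiSquare:
    def test_agrees_with_hand_formula_on_2x2(self, rng):
        for _ in range(20):
            counts = rng.integers(1, 60, size=(2, 2))
            table = table_2x2(*counts.ravel())
            res = chi_square_test(table)
            obs = counts.astype(float)
            expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
            stat = ((obs - expected) ** 2 / expected).sum()
            assert res.statistic == pytest.approx(stat, abs=1e-12)
            assert res.pvalue == pytest.approx(stats.chi2.sf(stat, 1), abs=1e-12)

    def test_independent_table_gives_p_one(self):
        res = chi_square_test(table_2x2(10, 20, 30, 60))  # rows proportional
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_test(table_2x2(0, 0, 5, 5))


def fisher_two_sided_oracle(a, b, c, d):
    """Enumerate all tables with the observed margins; sum point
    probabilities not exceeding the observed one (with a relative tie
    tolerance)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_gives_p_one(self):
        assert fisher_exact_2x2(table_2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_perfect_separation_hand_value(self):
        p = fisher_exact_2x2(table_2x2(10, 0, 0, 10))
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_agrees_with_enumeration_on_sample_of_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_2x2(table_2x2(a, b, c, d))
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_rejects_non_2x2(self):
        t = ContingencyTable(("r1", "r2"), ("c1", "c2", "c3"), ((1, 2, 3), (4, 5, 6)))
        with pytest.raises(ValueError):
            fisher_exact_2x2(t)


class TestKSTwoSample:
    def test_identical_samples(self):
        res = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3], [10, 11, 12]).statistic == 1.0

    def test_hand_computed_ecdf_distance(self):
        assert ks_two_sample([1, 2], [1.5, 2.5]).statistic == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(1, 2, size=15)
        assert ks_two_sample(a, b) == ks_two_sample(b, a)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestFractionDistributionTests:
    def test_balanced_groups_not_significant(self, rng):
        anns = []
        for i in range(60):
            t = rng.uniform(20, 70)
            a = rng.uniform(0, 20)
            anns.append(
                make_annotation(f"S{i}", "DM" if i % 2 else "NoDM", t, 100 - t - a, a)
            )
        res = fraction_distribution_tests(anns)
        assert set(res) == {"tumor", "stroma", "adipocyte"}
        assert all(r.pvalue > 0.01 for r in res.values())


class TestPairedWeightComparison:
    def test_identical_weights_reported_as_identical(self):
        w = {f"S{i}": 0.5 for i in range(10)}
        res = paired_weight_comparison(w, dict(w))
        assert res.identical and res.pvalue is None

    def test_pure_noise_difference_large_p(self, rng):
        w1 = {f"S{i}": v for i, v in enumerate(rng.uniform(0.2, 0.8, size=100))}
        w2 = {k: v + rng.normal(0, 0.01) for k, v in w1.items()}
        res = paired_weight_comparison(w1, w2)
        assert res.pvalue > 0.05

    def test_systematic_shift_detected(self, rng):
        w1 = {f"S{i}": v for i, v in enumerate(rng.uniform(0.2, 0.6, size=100))}
        w2 = {k: v + 0.2 + rng.normal(0, 0.01) for k, v in w1.items()}
        res = paired_weight_comparison(w1, w2)
        assert res.pvalue < 0.001

    def test_too_few_common_samples_raise(self):
        with pytest.raises(ValueError):
            paired_weight_comparison({"S1": 0.5}, {"S1": 0.6, "S2": 0.2})


class TestExtremeGroupMarkerTest:
    def test_compartment_markers_split_into_the_right_lists(self, small_cohort):
        matrix, anns, truth = small_cohort
        # add two synthetic marker probes tied to the observed fractions
        fr = {a.sample_id: a.mean_fractions for a in anns}
        tvec = np.array([fr[s][0] for s in matrix.sample_ids]) / 100
        svec = np.array([fr[s][1] for s in matrix.sample_ids]) / 100
        # small probe panel so the permutation resolution (1/(B+1)) can pass
        # the BH threshold for the genuine markers
        values = matrix.values.iloc[:40].copy()
        values.loc["TMARK"] = 8 + 4 * tvec
        values.loc["SMARK"] = 8 + 4 * svec
        values.loc["FLAT"] = 8.0
        m2 = make_matrix(values.to_numpy(), probe_ids=list(values.index), sample_ids=list(values.columns))
        list_a, list_b = extreme_group_marker_test(m2, anns, n_top=8, B=999, seed=2)
        assert "TMARK" in list_a
        assert "SMARK" in list_b
        assert "FLAT" not in list_a + list_b

    def test_requires_enough_samples(self, small_cohort):
        matrix, anns, _ = small_cohort
        with pytest.raises(ValueError):
            extreme_group_marker_test(matrix, anns, n_top=len(anns))


class TestFractionCorrelation:
    def test_affine_function_of_tumor_fraction_has_r_one(self, small_cohort):
        matrix, anns, _ = small_cohort
        fr = {a.sample_id: a.mean_fractions for a in anns}
        tvec = np.array([fr[s][0] for s in matrix.sample_ids])
        values = matrix.values.iloc[:5].copy()
        values.loc["AFFINE"] = 2 + 0.05 * tvec
        values.loc["CONST"] = 1.0
        m2 = make_matrix(values.to_numpy(), probe_ids=list(values.index), sample_ids=list(values.columns))
        res = fraction_correlation(m2, anns)
        assert res.loc["AFFINE", "r_tumor"] == pytest.approx(1.0)
        assert res.loc["AFFINE", "p_tumor"] < 1e-10
        assert res.loc["CONST", "r_tumor"] == 0.0
        assert bool(res.loc["CONST", "zero_variance"])

    def test_null_probes_show_small_correlations(self, small_cohort):
        matrix, anns, truth = small_cohort
        res = fraction_correlation(matrix, anns)
        nulls = truth.genes_of_origin("null")
        assert res.loc[nulls, "r_tumor"].abs().median() < 0.3

    def test_matches_scipy_pearson(self, small_cohort):
        matrix, anns, _ = small_cohort
        res = fraction_correlation(matrix, anns)
        fr = {a.sample_id: a.mean_fractions for a in anns}
        svec = np.array([fr[s][1] for s in matrix.sample_ids])
        probe = matrix.probe_ids[7]
        r, p = stats.pearsonr(matrix.values.loc[probe].to_numpy(), svec)
        assert res.loc[probe, "r_stroma"] == pytest.approx(r, abs=1e-12)
        assert res.loc[probe, "p_stroma"] == pytest.approx(p, rel=1e-9)


class TestMatchProbesBySymbol:
    def test_matching_rules(self, rng):
        target = make_matrix(
            np.vstack([rng.normal(0, 1.0, 8), rng.normal(0, 2.0, 8), rng.normal(size=8)]),
            probe_ids=["T1", "T2", "T3"],
        )
        # ensure T2 really has the larger variance for the shared symbol
        assert target.values.loc["T2"].var() > target.values.loc["T1"].var()
        source_symbols = {"A1": "GENE1", "A2": "GENE2", "A3": "GENE3"}
        target_symbols = {"T1": "GENE1", "T2": "GENE1", "T3": "GENE2"}
        mapping, unmatched = match_probes_by_symbol(source_symbols, target, target_symbols)
        assert mapping["GENE1"] == "T2"  # max-variance tie-break
        assert mapping["GENE2"] == "T3"  # single candidate
        assert unmatched == ["GENE3"]  # absent from target


def test_compartment_t_tests_agree_with_scipy(rng):
    X = rng.normal(size=(10, 12))
    m = make_matrix(X)
    groups = {f"S{j}": ("DM" if j < 6 else "NoDM") for j in range(12)}
    res = compartment_t_tests(m, groups)
    expected = stats.ttest_ind(X[:, :6], X[:, 6:], axis=1, equal_var=True)
    np.testing.assert_allclose(res["t"], expected.statistic, atol=1e-12)
    np.testing.assert_allclose(res["p"], expected.pvalue, atol=1e-12)
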