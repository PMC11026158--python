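"""Logistic association, inverse-variance pooling, thresholds, enrichment."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recombkit import (
    CohortSummary,
    binomial_enrichment,
    class_thresholds,
    cohort_summaries,
    ivw_meta,
    logistic_assoc,
    simulate_case_control_cohorts,
)
from recombkit.meta import filter_sumstats, harmonize_sumstats


def _two_by_two(cases_exposed, cases_unexposed, controls_exposed, controls_unexposed):
    dosage = np.concatenate(
        [
            np.ones(cases_exposed),
            np.zeros(cases_unexposed),
            np.ones(controls_exposed),
            np.zeros(controls_unexposed),
        ]
    )
    status = np.concatenate(
        [
            np.ones(cases_exposed + cases_unexposed),
            np.zeros(controls_exposed + controls_unexposed),
        ]
    )
    return dosage, status


class TestLogisticAssoc:
    def test_two_by_two_closed_form(self):
        dosage, status = _two_by_two(10, 90, 5, 95)
        beta, se, p = logistic_assoc(dosage, status)
        expected = np.log((10 * 95) / (90 * 5))
        assert beta == pytest.approx(expected, rel=1e-6)
        # Woolf SE of a 2x2 log-OR
        assert se == pytest.approx(np.sqrt(1 / 10 + 1 / 90 + 1 / 5 + 1 / 95), rel=1e-4)

    def test_doubling_halves_information(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.3, 400).astype(float)
        status = rng.binomial(1, 0.4, 400).astype(float)
        b1, s1, _ = logistic_assoc(dosage, status)
        b2, s2, _ = logistic_assoc(np.tile(dosage, 2), np.tile(status, 2))
        assert b2 == pytest.approx(b1, rel=1e-6)
        assert s2 == pytest.approx(s1 / np.sqrt(2), rel=1e-6)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(300):
            dosage = rng.binomial(2, 0.3, 150).astype(float)
            status = rng.binomial(1, 0.5, 150).astype(float)
            pvals.append(logistic_assoc(dosage, status)[2])
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings("ignore:Perfect separation")
    def test_separation_detected(self):
        dosage = np.array([0.0] * 20 + [2.0] * 20)
        status = np.array([0.0] * 20 + [1.0] * 20)
        with pytest.raises(ValueError, match="separation"):
            logistic_assoc(dosage, status)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            logistic_assoc(np.zeros(10), np.ones(10))


class TestIvwMeta:
    def test_single_study_identity(self):
        s = CohortSummary("a", beta=0.2, se=0.1, af=0.01, n_cases=10, n_controls=10)
        m = ivw_meta([s])
        assert m.beta == pytest.approx(0.2)
        assert m.se == pytest.approx(0.1)
        assert m.q == pytest.approx(0.0)
        assert m.p_het == 1.0

    def test_hand_computed_weights(self):
        ss = [
            CohortSummary("a", beta=0.2, se=0.1, af=0.01, n_cases=1, n_controls=1),
            CohortSummary("b", beta=0.1, se=0.2, af=0.01, n_cases=1, n_controls=1),
        ]
        m = ivw_meta(ss)
        assert m.beta == pytest.approx(0.18)
        assert m.se == pytest.approx(1 / np.sqrt(125), rel=1e-9)
        assert m.se == pytest.approx(0.0894, abs=5e-4)

    def test_identical_studies_replication_limit(self):
        base = CohortSummary("a", beta=0.3, se=0.15, af=0.01, n_cases=1, n_controls=1)
        k = 4
        m = ivw_meta([base] * k)
        assert m.beta == pytest.approx(0.3)
        assert m.se == pytest.approx(0.15 / np.sqrt(k))
        assert m.q == pytest.approx(0.0)

    def test_ci_definition(self):
        ss = [
            CohortSummary("a", beta=0.25, se=0.05, af=0.01, n_cases=1, n_controls=1),
            CohortSummary("b", beta=0.15, se=0.08, af=0.01, n_cases=1, n_controls=1),
        ]
        m = ivw_meta(ss)
        assert m.ci_low == pytest.approx(np.exp(m.beta - 1.96 * m.se))
        assert m.ci_high == pytest.approx(np.exp(m.beta + 1.96 * m.se))
        assert m.or_ == pytest.approx(np.exp(m.beta))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_order_invariance_and_associativity(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 8))
        ss = [
            CohortSummary(
                f"s{i}", beta=float(rng.normal(0, 0.3)), se=float(rng.uniform(0.05, 0.4)),
                af=0.01, n_cases=1, n_controls=1,
            )
            for i in range(k)
        ]
        m_all = ivw_meta(ss)
        m_perm = ivw_meta(list(rng.permutation(np.array(ss, dtype=object))))
        assert m_perm.beta == pytest.approx(m_all.beta)
        assert m_perm.q == pytest.approx(m_all.q)
        # pool two subsets, then pool the pooled results
        cut = k // 2
        m1, m2 = ivw_meta(ss[:cut]), ivw_meta(ss[cut:])
        merged = ivw_meta(
            [
                CohortSummary("g1", beta=m1.beta, se=m1.se, af=0.01, n_cases=1, n_controls=1),
                CohortSummary("g2", beta=m2.beta, se=m2.se, af=0.01, n_cases=1, n_controls=1),
            ]
        )
        assert merged.beta == pytest.approx(m_all.beta)
        assert merged.se == pytest.approx(m_all.se)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ivw_meta([])

    def test_consistency_on_simulated_cohorts(self):
        tables = simulate_case_control_cohorts(
            [(8000, 32000), (8000, 32000)], [0.01, 0.013], true_or=1.22, seed=60
        )
        m = ivw_meta(cohort_summaries(tables))
        assert m.ci_low < 1.22 < m.ci_high


class TestClassThresholds:
    def test_plain_bonferroni(self):
        scheme = class_thresholds({"all": 1000}, {"all": 1.0})
        assert scheme.thresholds[0] == pytest.approx(5e-5)

    def test_weight_proportionality(self):
        scheme = class_thresholds({"a": 100, "b": 100}, {"a": 2.0, "b": 1.0})
        ta, tb = scheme.thresholds
        assert ta / tb == pytest.approx(2.0)
        assert 100 * ta + 100 * tb == pytest.approx(0.05)

    def test_published_style_ratio_scheme_conserves_alpha(self):
        # five annotation classes with weights in the ratios used for
        # human GWAS multiple-testing control (~330:66:6:3:1)
        weights = {"high": 330.0, "moderate": 66.0, "low": 6.0, "dhs": 3.0, "other": 1.0}
        counts = {"high": 20_000, "moderate": 300_000, "low": 3_000_000,
                  "dhs": 10_000_000, "other": 36_000_000}
        scheme = class_thresholds(counts, weights)
        total = sum(
            n * t for n, t in zip(scheme.counts, scheme.thresholds)
        )
        assert total == pytest.approx(0.05, abs=1e-12)
        assert scheme.thresholds == sorted(scheme.thresholds, reverse=True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_conservation_identity_random(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 7))
        counts = {f"c{i}": int(rng.integers(1, 10**7)) for i in range(k)}
        weights = {f"c{i}": float(rng.uniform(0.1, 300)) for i in range(k)}
        scheme = class_thresholds(counts, weights, alpha=0.05)
        total = sum(n * t for n, t in zip(scheme.counts, scheme.thresholds))
        assert abs(total - 0.05) < 1e-12

    def test_empty_classes_rejected(self):
        with pytest.raises(ValueError):
            class_thresholds({}, {})
        with pytest.raises(ValueError):
            class_thresholds({"a": 0}, {"a": 1.0})


def _exact_binomial_upper_tail(k, n, p0: Fraction) -> float:
    """Big-rational binomial tail sum, independent of scipy."""
    from math import comb

    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * p0**j * (1 - p0) ** (n - j)
    return float(total)


class TestBinomialEnrichment:
    def test_zero_hits(self):
        assert binomial_enrichment(0, 46) == pytest.approx(1.0)

    def test_all_hits(self):
        assert binomial_enrichment(10, 10, p0=0.05) == pytest.approx(0.05**10, rel=1e-9)

    def test_matches_exact_sum_oracle(self):
        got = binomial_enrichment(7, 46, p0=0.05)
        expected = _exact_binomial_upper_tail(7, 46, Fraction(1, 20))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_sidedness_flag(self):
        upper = binomial_enrichment(7, 46, alternative="greater")
        two = binomial_enrichment(7, 46, alternative="two-sided")
        assert two >= upper

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_enrichment(5, 4)
        with pytest.raises(ValueError):
            binomial_enrichment(1, 10, p0=0.0)


class TestSumstatsHousekeeping:
    def _frame(self, cohort, beta, af, ref="C", alt="T"):
        return pd.DataFrame(
            {
                "chrom": ["chr19"], "pos": [12_175_438], "ref": [ref], "alt": [alt],
                "beta": [beta], "se": [0.05], "p": [0.5], "af": [af],
                "n_cases": [100], "n_controls": [400], "cohort": [cohort],
            }
        )

    def test_maf_filter(self):
        df = pd.concat(
            [self._frame("a", 0.1, 0.00005), self._frame("a", 0.1, 0.3)],
            ignore_index=True,
        )
        out = filter_sumstats(df, maf_min=1e-4)
        assert len(out) == 1 and out.iloc[0].af == 0.3

    def test_allele_flip_harmonization(self):
        a = self._frame("a", 0.2, 0.01)
        b = self._frame("b", -0.2, 0.99, ref="T", alt="C")  # swapped alleles
        out = harmonize_sumstats([a, b])
        assert len(out) == 2
        flipped = out[out.cohort == "b"].iloc[0]
        assert flipped.beta == pytest.approx(0.2)
        assert flipped.af == pytest.approx(0.01)

    def test_mismatched_alleles_dropped(self):
        a = self._frame("a", 0.2, 0.01)
        b = self._frame("b", 0.2, 0.01, ref="G", alt="A")
        out = harmonize_sumstats([a, b])
        assert list(out.cohort) == ["a"]
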