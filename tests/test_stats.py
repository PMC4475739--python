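import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from retmorph import stats
from retmorph.errors import ContractError, DegenerateDataError


def exhaustive_2means_cutoff(values):
    """Best split point by brute-force within-cluster sum of squares."""
    x = np.sort(np.asarray(values, float))
    best = None
    for i in range(1, len(x)):
        lo, hi = x[:i], x[i:]
        wss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or wss < best[0]:
            best = (wss, (lo.mean() + hi.mean()) / 2)
    return best[1]


class TestKmeansCutoff:
    def test_two_cluster_example(self):
        assert stats.kmeans_cutoff_1d([1, 2, 3, 10, 11, 12]) == pytest.approx(6.5)

    def test_symmetric_pairs(self):
        assert stats.kmeans_cutoff_1d([2.0, 2.0, 8.0, 8.0]) == pytest.approx(5.0)

    def test_degenerate_identical_values(self):
        with pytest.raises(DegenerateDataError):
            stats.kmeans_cutoff_1d([4.0, 4.0, 4.0, 4.0])

    def test_too_few_values(self):
        with pytest.raises(ContractError):
            stats.kmeans_cutoff_1d([1.0, 2.0, 3.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 1, 6), rng.normal(8, 1, 6)]
        a = stats.kmeans_cutoff_1d(x)
        b = stats.kmeans_cutoff_1d(x[::-1])
        c = stats.kmeans_cutoff_1d(rng.permutation(x))
        assert a == pytest.approx(b) == pytest.approx(c)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=4, max_size=12))
    def test_matches_exhaustive_split_oracle(self, values):
        if len(set(values)) < 2:
            return
        ours = stats.kmeans_cutoff_1d(values)
        oracle = exhaustive_2means_cutoff(values)
        assert ours == pytest.approx(oracle, abs=1e-9)


class TestConfusionTable:
    def test_reference_worked_example(self):
        t = stats.ConfusionTable(tp=11, fp=2, fn=5, tn=14)
        assert round(t.ppv, 1) == 84.6
        assert round(t.npv, 1) == 73.7
        assert round(t.sensitivity, 1) == 68.8
        assert round(t.specificity, 1) == 87.5

    def test_perfect_sensitivity(self):
        assert stats.ConfusionTable(tp=9, fp=3, fn=0, tn=5).sensitivity == 100.0

    def test_undefined_ppv_is_none(self):
        t = stats.ConfusionTable(tp=0, fp=0, fn=4, tn=6)
        assert t.ppv is None
        assert t.npv is not None

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(*(st.integers(0, 30) for _ in range(4)))
    def test_metric_identities(self, tp, fp, fn, tn):
        t = stats.ConfusionTable(tp, fp, fn, tn)
        if tp + fn:
            assert t.sensitivity == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert t.specificity == pytest.approx(100 * tn / (tn + fp))
        if tp + fp:
            assert t.ppv == pytest.approx(100 * tp / (tp + fp))
        if tn + fn:
            assert t.npv == pytest.approx(100 * tn / (tn + fn))


class TestClassify:
    @staticmethod
    def cohort(n_abnormal_disease, n_disease, n_abnormal_control, n_control):
        """Records placed on either side of the AVR cutoff 0.70."""
        rows = []
        for i in range(n_disease):
            rows.append({"subject_id": f"d{i}", "group": "disease",
                         "avr": 0.60 if i < n_abnormal_disease else 0.80,
                         "ti": 60.0, "mean_d": 1.45})
        for i in range(n_control):
            rows.append({"subject_id": f"c{i}", "group": "control",
                         "avr": 0.60 if i < n_abnormal_control else 0.80,
                         "ti": 60.0, "mean_d": 1.45})
        return pd.DataFrame(rows)

    def test_avr_direction(self):
        df = self.cohort(11, 16, 2, 16)
        t = stats.classify(df, stats.REFERENCE_CUTOFFS, index="avr")
        assert (t.tp, t.fp, t.fn, t.tn) == (11, 2, 5, 14)

    def test_combined_rule_equals_avr_by_default(self):
        df = self.cohort(11, 16, 2, 16)
        a = stats.classify(df, stats.REFERENCE_CUTOFFS, index="avr")
        c = stats.classify(df, stats.REFERENCE_CUTOFFS, index="combined")
        assert a == c

    def test_or_rule_can_differ(self):
        df = self.cohort(0, 6, 0, 6)
        df.loc[df.group == "disease", "ti"] = 80.0  # abnormal TI only
        a = stats.classify(df, stats.REFERENCE_CUTOFFS, index="combined",
                           combined_rule="avr")
        o = stats.classify(df, stats.REFERENCE_CUTOFFS, index="combined",
                           combined_rule="or")
        assert a.tp == 0 and o.tp == 6

    def test_missing_value_reported_with_subject(self):
        df = self.cohort(2, 4, 1, 4)
        df.loc[1, "avr"] = np.nan
        with pytest.raises(ContractError, match="d1"):
            stats.classify(df, stats.REFERENCE_CUTOFFS, index="avr")


class TestMetricCis:
    def test_matches_reference_interval_11_of_16(self):
        t = stats.ConfusionTable(tp=11, fp=2, fn=5, tn=14)
        lo, hi = stats.metric_cis(t)["sensitivity"]
        assert lo == pytest.approx(41.4, abs=0.15)
        assert hi == pytest.approx(88.9, abs=0.15)

    def test_zero_successes_lower_bound(self):
        t = stats.ConfusionTable(tp=0, fp=5, fn=8, tn=5)
        lo, hi = stats.metric_cis(t)["sensitivity"]
        assert lo == pytest.approx(0.0, abs=1e-9)

    def test_all_successes_upper_bound(self):
        t = stats.ConfusionTable(tp=8, fp=0, fn=0, tn=5)
        lo, hi = stats.metric_cis(t)["sensitivity"]
        assert hi == pytest.approx(100.0, abs=1e-9)


def wilcoxon_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all sign patterns."""
    d = np.asarray([x for x in diffs if x != 0], float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    n = len(d)
    center = n * (n + 1) / 4
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if abs(w - center) >= abs(w_obs - center) - 1e-12:
            count += 1
    return count / 2 ** n


class TestPairedWilcoxon:
    def test_five_positive_differences_exact_p(self):
        stat, p = stats.paired_wilcoxon([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert p == pytest.approx(2 / 32)

    def test_antisymmetric_differences_near_null_center(self):
        _, p = stats.paired_wilcoxon([1, 2, 11, 12, 20], [3, 3, 10, 10, 20.5])
        assert p > 0.5

    def test_too_few_pairs(self):
        with pytest.raises(ContractError):
            stats.paired_wilcoxon([1, 2, 3], [0, 0, 0])

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateDataError):
            stats.paired_wilcoxon([1.0] * 6, [1.0] * 6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = rng.normal(0.4, 1.0, 8)
            d = np.where(d == 0, 0.1, d)
            _, p = stats.paired_wilcoxon(d, np.zeros_like(d))
            assert p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-9)


class TestIcc:
    def test_identical_raters_give_100(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        assert stats.icc_two_rater(x, x) == pytest.approx(100.0)

    def test_constant_offset_penalized(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        val = stats.icc_two_rater(x, x + 2.0)
        assert val is not None and val < 100.0

    def test_matches_variance_ratio_closed_form(self):
        rng = np.random.default_rng(42)
        subj = rng.normal(0.0, 1.0, 200)
        noise_sd = 0.2
        a = subj + rng.normal(0, noise_sd, 200)
        b = subj + rng.normal(0, noise_sd, 200)
        icc = stats.icc_two_rater(a, b)
        expected = 100.0 / (1 + noise_sd**2)  # sigma_s^2/(sigma_s^2+sigma_e^2)
        assert icc == pytest.approx(expected, abs=5.0)

    def test_zero_between_subject_variance_undefined(self):
        assert stats.icc_two_rater([3.0] * 6, [3.0] * 6) is None


def test_chi_squared_2x2_smoke():
    stat, p = stats.chi_squared_2x2([[16, 0], [0, 16]])
    assert p < 0.001
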