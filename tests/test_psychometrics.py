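"""Psychometrics: ICC(2,1) against a brute-force ANOVA oracle and pingouin,
SEM/MDC contracts, t-test closed forms, Hedges' g, change classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gaitvae.psychometrics import (MDC_FACTOR, classify_change, compare_groups,
                                   hedges_g, icc_2_1, icc_category,
                                   independent_t, reliability,
                                   reliability_table, responsiveness, sem_mdc)


def brute_force_icc21(x):
    """Independent oracle: ICC(2,1) from explicitly enumerated sums of squares."""
    n, k = x.shape
    grand = x.mean()
    ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_sess = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_subj / (n - 1)
    msc = ss_sess / (k - 1)
    mse = (ss_tot - ss_subj - ss_sess) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        icc, lo, hi = icc_2_1(x, x)
        assert icc == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        x = np.array([1.0, 1.1, 0.9, 1.05, 0.95])
        icc, *_ = icc_2_1(x, x + 10.0)  # offset >> between-subject SD
        assert icc < 0.1

    def test_oracle_equivalence_100_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            x = rng.normal(size=(20, 2)) + rng.normal(size=(20, 1))
            icc, *_ = icc_2_1(x[:, 0], x[:, 1])
            assert abs(icc - brute_force_icc21(x)) < 1e-10

    def test_matches_pingouin_including_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=(15, 2)) + 2.0 * rng.normal(size=(15, 1))
        icc, lo, hi = icc_2_1(x[:, 0], x[:, 1])
        df = pd.DataFrame({"s": np.repeat(np.arange(15), 2),
                           "r": np.tile([0, 1], 15), "y": x.ravel()})
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="y")
        row = ref.set_index("Type").loc["ICC(A,1)"]
        assert icc == pytest.approx(row["ICC"], abs=1e-12)
        assert lo == pytest.approx(row["CI95"][0], abs=0.01)  # pingouin rounds
        assert hi == pytest.approx(row["CI95"][1], abs=0.01)
        assert lo <= icc <= hi

    def test_constant_matrix_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            icc_2_1([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_category_cut_points(self):
        assert icc_category(0.49) == "poor"
        assert icc_category(0.5) == "moderate"
        assert icc_category(0.75) == "good"
        assert icc_category(0.9) == "excellent"
        assert icc_category(0.963) == "excellent"


class TestSemMdc:
    def test_icc_one_gives_zero(self):
        x = [1.0, 2.0, 3.0]
        sem, mdc = sem_mdc(x, x, icc=1.0)
        assert sem == 0.0 and mdc == 0.0

    def test_mdc_sem_ratio_constant(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        sem, mdc = sem_mdc(a, b, icc=0.8)
        assert mdc / sem == pytest.approx(MDC_FACTOR)
        assert MDC_FACTOR == pytest.approx(2.77186, abs=1e-5)

    def test_sem_0478_gives_mdc_1325(self):
        # the MDC that corresponds to an SEM of 0.478 under the 1.96*sqrt(2) rule
        assert 0.478 * MDC_FACTOR == pytest.approx(1.325, abs=1e-3)

    def test_ms_error_variant_close_for_high_icc(self):
        rng = np.random.default_rng(5)
        subj = rng.normal(0, 1, 30)
        a = subj + rng.normal(0, 0.2, 30)
        b = subj + rng.normal(0, 0.2, 30)
        icc, *_ = icc_2_1(a, b)
        s1, _ = sem_mdc(a, b, icc, estimator="pooled_sd")
        s2, _ = sem_mdc(a, b, icc, estimator="ms_error")
        assert s1 == pytest.approx(s2, rel=0.25)


class TestTTest:
    def test_identical_groups(self):
        t, p = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_closed_form(self):
        t, p = independent_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)  # df = 4, pooled variance
        assert p == pytest.approx(2 * stats.t.sf(3.674, df=4), abs=1e-4)

    def test_symmetry_in_group_order(self):
        a, b = [1.0, 2.0, 2.5], [3.0, 4.0, 3.5]
        t1, p1 = independent_t(a, b)
        t2, p2 = independent_t(b, a)
        assert t1 == -t2 and p1 == p2


class TestHedges:
    def test_equal_means_zero(self):
        assert hedges_g(1.0, 0.5, 10, 1.0, 0.7, 12) == 0.0

    def test_printed_summary_effect_sizes(self):
        # recomputed from the group summary statistics of the clinical tables
        g_speed = hedges_g(0.4, 0.3, 68, 1.1, 0.2, 42)
        assert round(abs(g_speed), 1) == 2.6
        g_l2 = hedges_g(0.0, 0.6, 68, -0.1, 0.8, 42)
        assert round(abs(g_l2), 2) == 0.15

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(0.01, 100.0), shift=st.floats(-50.0, 50.0))
    def test_affine_invariance(self, scale, shift):
        base = hedges_g(0.3, 0.2, 20, 0.8, 0.4, 25)
        scaled = hedges_g(0.3 * scale + shift, 0.2 * scale, 20,
                          0.8 * scale + shift, 0.4 * scale, 25)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_compare_groups_signs_consistent(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(1.0, 1.0, 30)
        res = compare_groups(a, b)
        assert math.copysign(1, res.t_stat) == math.copysign(1, res.mean_a - res.mean_b)
        assert 0.0 <= res.p_value <= 1.0


class TestResponsiveness:
    def _reliability(self, mdc=0.5):
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 1, 20)
        a = subj + rng.normal(0, 0.1, 20)
        b = subj + rng.normal(0, 0.1, 20)
        r = reliability(a, b, feature="f")
        r.mdc = mdc
        r.category = "good"
        return r

    def test_boundary_rule_strict(self):
        assert classify_change(0.5, 0.5) == "none"  # delta == mdc -> no change
        assert classify_change(0.5001, 0.5) == "increased"
        assert classify_change(-0.6, 0.5) == "decreased"

    def test_no_change_when_identical(self):
        rel = [self._reliability()]
        df = pd.DataFrame({"subject_id": ["a", "b"], "f": [1.0, 2.0]})
        out = responsiveness(df, df.copy(), rel, features=["f"],
                             speed_feature="missing")
        assert (out["table"]["changed"] == "none").all()
        assert out["n_changed_any"] == 0

    def test_injected_gain_half_subjects(self):
        rel = [self._reliability(mdc=0.5)]
        t0 = pd.DataFrame({"subject_id": [f"s{i}" for i in range(10)],
                           "f": np.zeros(10)})
        tend = t0.copy()
        tend.loc[:4, "f"] = 1.0  # 2 x MDC gain in half the subjects
        out = responsiveness(t0, tend, rel, features=["f"], speed_feature="missing")
        counts = out["per_feature_counts"].loc["f"]
        assert counts["increased"] == 5
        assert counts["none"] == 5

    def test_missing_pair_excluded(self):
        rel = [self._reliability()]
        t0 = pd.DataFrame({"subject_id": ["a", "b", "c"], "f": [0.0, 0.0, 0.0]})
        tend = pd.DataFrame({"subject_id": ["a", "b"], "f": [2.0, 0.0]})
        out = responsiveness(t0, tend, rel, features=["f"], speed_feature="missing")
        assert out["excluded_subjects"] == ["c"]
        assert out["n_subjects"] == 2

    def test_unreliable_features_excluded(self):
        good = self._reliability(mdc=0.5)
        poor = self._reliability(mdc=0.5)
        poor.feature = "g"
        poor.category = "poor"
        t0 = pd.DataFrame({"subject_id": ["a"], "f": [0.0], "g": [0.0]})
        tend = pd.DataFrame({"subject_id": ["a"], "f": [0.0], "g": [5.0]})
        out = responsiveness(t0, tend, [good, poor], speed_feature="missing")
        assert set(out["table"]["feature"]) == {"f"}


def test_reliability_table_pairs_by_subject():
    rng = np.random.default_rng(1)
    subj = rng.normal(0, 1, 15)
    test_df = pd.DataFrame({"subject_id": [f"s{i}" for i in range(15)],
                            "f": subj + rng.normal(0, 0.2, 15)})
    retest_df = test_df.copy()
    retest_df["f"] = subj + rng.normal(0, 0.2, 15)
    df, results = reliability_table(test_df, retest_df.sample(frac=1.0, random_state=2),
                                    ["f"])
    assert df.loc[0, "icc"] > 0.8  # pairing survived the row shuffle
    assert df.loc[0, "ci_low"] <= df.loc[0, "icc"] <= df.loc[0, "ci_high"]
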