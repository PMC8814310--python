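"""ICC/SEM/MDC, subject aggregation, paired Wilcoxon comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

import armsmooth as am
from armsmooth.errors import (
    DegenerateTestError,
    InvalidArgumentError,
    MissingDataError,
    UndefinedICCError,
)
from armsmooth.stats import icc_classify, reliability_report


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        m = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert am.icc(m, "ICC31") == pytest.approx(1.0)
        assert am.icc(m, "ICC21") == pytest.approx(1.0)

    def test_no_subject_variance_reported_negative_without_clamping(self):
        # equal row means, pure within-subject disagreement: ICC(3,1) = -1
        m = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert am.icc(m, "ICC31") == pytest.approx(-1.0)

    def test_zero_total_variance_undefined(self):
        with pytest.raises(UndefinedICCError):
            am.icc(np.full((5, 3), 2.0))

    def test_matches_pingouin_on_random_matrices(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            m = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1))
            long = pd.DataFrame(
                [
                    {"subject": i, "rater": j, "score": m[i, j]}
                    for i, j in itertools.product(range(12), range(4))
                ]
            )
            ref = pingouin.intraclass_corr(
                long, targets="subject", raters="rater", ratings="score"
            ).set_index("Type")["ICC"]
            # ICC(C,1) is consistency (3,1); ICC(A,1) is absolute agreement (2,1)
            assert am.icc(m, "ICC31") == pytest.approx(ref["ICC(C,1)"], abs=1e-6)
            assert am.icc(m, "ICC21") == pytest.approx(ref["ICC(A,1)"], abs=1e-6)

    @given(
        shift=stn.floats(min_value=-50, max_value=50),
        scale=stn.floats(min_value=0.1, max_value=20),
    )
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_affine_invariance(self, shift, scale):
        m = np.random.default_rng(3).normal(size=(15, 3)) + np.random.default_rng(
            4
        ).normal(size=(15, 1))
        base = am.icc(m, "ICC21")
        assert am.icc(scale * m + shift, "ICC21") == pytest.approx(base, abs=1e-8)

    def test_classification_thresholds(self):
        assert icc_classify(0.39) == "poor"
        assert icc_classify(0.40) == "fair"
        assert icc_classify(0.60) == "good"
        assert icc_classify(0.74) == "good"
        assert icc_classify(0.75) == "excellent"


class TestSemMdc:
    def test_perfect_reliability_gives_zero_sem(self):
        assert am.sem_mdc(2.0, 1.0) == (0.0, 0.0)

    def test_hand_computed_values(self):
        sem, mdc = am.sem_mdc(1.0, 0.0)
        assert sem == 1.0 and mdc == pytest.approx(1.96 * np.sqrt(2))
        sem, mdc = am.sem_mdc(2.0, 0.75)
        assert sem == pytest.approx(1.0) and mdc == pytest.approx(2.7718, abs=1e-3)

    def test_mdc_sem_identity(self, rng):
        for _ in range(20):
            sem, mdc = am.sem_mdc(rng.uniform(0, 5), rng.uniform(-1, 1))
            assert mdc == pytest.approx(1.96 * np.sqrt(2) * sem, abs=1e-12)

    def test_icc_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            am.sem_mdc(1.0, 1.1)

    def test_sem_scales_linearly_with_sd(self):
        s1, m1 = am.sem_mdc(1.0, 0.5)
        s3, m3 = am.sem_mdc(3.0, 0.5)
        assert s3 == pytest.approx(3 * s1) and m3 == pytest.approx(3 * m1)


class TestSubjectMedians:
    @staticmethod
    def table(values_by_subject):
        rows = [
            {"subject": s, "jerk": v}
            for s, vals in values_by_subject.items()
            for v in vals
        ]
        return pd.DataFrame(rows)

    def test_constant_values(self):
        med = am.subject_medians(self.table({"a": [2.0] * 9}))
        assert med["a"] == 2.0

    def test_odd_count_median(self):
        med = am.subject_medians(self.table({"a": list(range(1, 10))}))
        assert med["a"] == 5.0

    def test_even_count_median_after_dropout(self):
        med = am.subject_medians(self.table({"a": [1, 2, 3, 4, 5, 6, 7, 8]}))
        assert med["a"] == 4.5  # mean of 4th/5th order statistics

    def test_empty_table_rejected(self):
        with pytest.raises(MissingDataError):
            am.subject_medians(pd.DataFrame(columns=["subject", "jerk"]))


def wilcoxon_sign_flip_oracle(diffs):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    total = ranks.sum()
    obs = min(ranks[d > 0].sum(), total - ranks[d > 0].sum())
    count = 0
    n = len(d)
    for signs in itertools.product([0, 1], repeat=n):
        wp = ranks[np.array(signs, dtype=bool)].sum()
        if min(wp, total - wp) <= obs:
            count += 1
    return count / 2**n


class TestPairedComparison:
    def test_all_zero_differences_degenerate(self):
        x = np.arange(1.0, 11.0)
        with pytest.raises(DegenerateTestError):
            am.paired_comparison(x, x.copy())

    def test_matches_sign_flip_permutation_oracle(self, rng):
        for _ in range(5):
            x = rng.lognormal(size=9)
            y = x * rng.lognormal(sigma=0.3, size=9)
            res = am.paired_comparison(x, y)
            assert res.p_raw == pytest.approx(wilcoxon_sign_flip_oracle(x - y), abs=1e-12)

    def test_bonferroni_adjustment(self, rng):
        x = rng.lognormal(size=12)
        y = x * rng.lognormal(sigma=0.4, size=12)
        r1 = am.paired_comparison(x, y, family_size=1)
        r7 = am.paired_comparison(x, y, family_size=7)
        assert r1.p_adj == r1.p_raw
        assert r7.p_adj == pytest.approx(min(1.0, 7 * r7.p_raw))
        assert r7.p_adj >= r7.p_raw

    def test_mean_ratio_reported_on_jerk_scale(self):
        x = np.full(8, 1.0)
        y = np.full(8, 9.0)
        y[0] = 8.9  # avoid fully degenerate-looking but keep ratio near 0.1
        res = am.paired_comparison(x, y)
        assert res.mean_ratio == pytest.approx(0.1, abs=0.01)

    def test_acceptance_level_binning(self, rng):
        strong = am.paired_comparison(
            np.arange(1, 30.0), np.arange(1, 30.0) * 2, family_size=1
        )
        assert strong.acceptance_level == "<0.01"


class TestReliabilitySuite:
    @staticmethod
    def cohort_table(n_subjects=12, session_sd=0.0, trial_sd=0.05, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subjects):
            base = rng.lognormal(0.7, 0.4)
            for sess, obs in [(1, "A"), (2, "A"), (3, "B")]:
                sess_fac = rng.lognormal(0.0, session_sd)
                for trial in (1, 2, 3):
                    rows.append(
                        {
                            "subject": f"s{s:02d}",
                            "session": sess,
                            "observer": obs,
                            "movement": "sagittal_bilateral",
                            "trial": trial,
                            "arm": "total",
                            "phase": "full",
                            "jerk": base * sess_fac * rng.lognormal(0.0, trial_sd),
                        }
                    )
        return pd.DataFrame(rows)

    def test_report_shape_and_columns(self):
        rep = am.reliability_suite(self.cohort_table())
        assert len(rep) == 1
        for col in (
            "icc_intra",
            "sem_intra",
            "mdc_intra",
            "icc_inter_intraobs",
            "icc_inter_interobs",
        ):
            assert col in rep.columns

    def test_zero_session_variance_gives_high_intersession_icc(self):
        rep = am.reliability_suite(
            self.cohort_table(n_subjects=40, session_sd=0.0, trial_sd=0.02)
        )
        assert rep.loc[0, "icc_inter_intraobs"] > 0.95
        assert rep.loc[0, "icc_inter_interobs"] > 0.95

    def test_session_noise_equal_to_subject_sd_halves_icc(self):
        # additive two-way model oracle: ICC(2,1) ~ var_s / (var_s + var_e)
        m = am.simulate_rating_study(200, 2, 1.0, 0.0, 1.0, rng_seed=5)
        assert am.icc(m, "ICC21") == pytest.approx(0.5, abs=0.1)

    def test_missing_columns_rejected(self):
        with pytest.raises(InvalidArgumentError):
            am.reliability_suite(pd.DataFrame({"subject": [], "jerk": []}))


class TestReliabilityReport:
    def test_report_consistency(self, rng):
        m = rng.normal(size=(20, 3)) + 2 * rng.normal(size=(20, 1))
        rep = reliability_report(m, "ICC31")
        assert rep.icc_class == icc_classify(rep.icc)
        assert rep.mdc95 == pytest.approx(1.96 * np.sqrt(2) * rep.sem)
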