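import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betainc

from parpiomics.stats import (
    adaptive_sd_threshold,
    bh_adjust,
    impute_column_min,
    log2_transform,
    two_sample_t,
    two_sample_t_matrix,
)


class TestImpute:
    def test_column_example(self):
        out = impute_column_min(np.array([[4.0], [np.nan], [8.0]]))
        assert out[:, 0].tolist() == [4.0, 4.0, 8.0]

    def test_identity_without_missing(self):
        mat = np.arange(9, dtype=float).reshape(3, 3) + 1
        assert np.array_equal(impute_column_min(mat), mat)

    def test_each_column_uses_its_own_minimum(self):
        rng = np.random.default_rng(7)
        mat = rng.uniform(1, 100, (3, 3))
        holes = mat.copy()
        for j in range(3):
            holes[j, j] = np.nan
        out = impute_column_min(holes)
        for j in range(3):
            expected = min(v for i, v in enumerate(mat[:, j]) if i != j)  # brute-force column scan
            assert out[j, j] == expected
        present = ~np.isnan(holes)
        assert np.array_equal(out[present], holes[present])

    def test_fully_missing_column_raises(self):
        with pytest.raises(ValueError, match="1"):
            impute_column_min(np.array([[1.0, np.nan], [2.0, np.nan]]))


class TestLog2:
    def test_exact_values(self):
        out = log2_transform(np.array([[8.0, 1.0, 10.0]]))
        assert out[0, 0] == 3.0
        assert out[0, 1] == 0.0
        assert out[0, 2] == pytest.approx(3.321928094887362, abs=1e-12)

    def test_nonpositive_reports_coordinates(self):
        frame = pd.DataFrame({"S1": [1.0, 0.0]}, index=["F1", "F2"])
        with pytest.raises(ValueError, match=r"F2.*S1"):
            log2_transform(frame)


class TestTwoSampleT:
    def test_equal_groups_give_null_result(self):
        t, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_student_matches_textbook_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = two_sample_t(a, b, variant="student")
        # pooled-variance formula evaluated from first principles
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_exp = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        df = 4
        p_exp = betainc(df / 2, 0.5, df / (df + t_exp**2))  # regularized incomplete beta tail
        assert t == pytest.approx(t_exp, rel=1e-12)
        assert p == pytest.approx(p_exp, rel=1e-10)

    def test_antisymmetric_in_group_order(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        t1, p1 = two_sample_t(a, b)
        t2, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_constant_equal_convention(self):
        assert two_sample_t([2, 2, 2], [2, 2]) == (0.0, 1.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])

    def test_close_to_exact_permutation_reference(self):
        """Student p tracks the exact permutation p under normal data."""
        rng = np.random.default_rng(11)
        splits = list(itertools.combinations(range(10), 5))  # all 252 relabelings
        diffs, rej_t, rej_perm = [], 0, 0
        for _ in range(150):
            x = rng.normal(0, 1, 10)
            _, p_t = two_sample_t(x[:5], x[5:])
            obs = abs(x[:5].mean() - x[5:].mean())
            count = 0
            for idx in splits:
                mask = np.zeros(10, bool)
                mask[list(idx)] = True
                if abs(x[mask].mean() - x[~mask].mean()) >= obs - 1e-12:
                    count += 1
            p_perm = count / len(splits)
            diffs.append(abs(p_t - p_perm))
            rej_t += p_t < 0.1
            rej_perm += p_perm < 0.1
        assert np.mean(diffs) < 0.05
        assert abs(rej_t - rej_perm) / 150 < 0.05

    def test_matrix_version_matches_scalar(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, (20, 3)), rng.normal(0.5, 1, (20, 3))
        t, p = two_sample_t_matrix(a, b)
        for i in (0, 7, 19):
            ts, ps = two_sample_t(a[i], b[i])
            assert t[i] == pytest.approx(ts) and p[i] == pytest.approx(ps)


class TestBhAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]).tolist() == [0.03]

    def test_hand_stepup_enumeration(self):
        # q_i = min_{j>=i} p_(j) * n / j: (0.03, 0.03, 0.03)
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_dominates_p_and_preserves_order(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))


class TestAdaptiveThreshold:
    def test_arithmetic_mean_of_replicate_sds(self):
        rng = np.random.default_rng(0)
        mat = np.column_stack([rng.normal(0, 0.2, 4000), rng.normal(0, 0.4, 4000)])
        thr = adaptive_sd_threshold(mat, estimator="sample")
        sds = mat.std(axis=0, ddof=1)
        assert thr.average_sd == pytest.approx(sds.mean())
        assert thr.threshold == pytest.approx(2 * sds.mean())

    @pytest.mark.parametrize("estimator", ["sample", "mad"])
    def test_converges_to_two_sigma_on_null(self, estimator):
        rng = np.random.default_rng(1)
        mat = rng.normal(0, 0.3, (20000, 3))
        thr = adaptive_sd_threshold(mat, estimator=estimator)
        assert thr.threshold == pytest.approx(0.6, rel=0.05)

    def test_mad_ignores_regulated_minority(self):
        """2% of features at +-1.5 inflate the sample SD but not the MAD."""
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 0.25, (5000, 3))
        mat[:50] += 1.5
        mat[50:100] -= 1.5
        robust = adaptive_sd_threshold(mat, estimator="mad").threshold
        plain = adaptive_sd_threshold(mat, estimator="sample").threshold
        assert robust == pytest.approx(0.5, rel=0.05)
        assert plain > robust

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            adaptive_sd_threshold(np.zeros((10, 1)))

    def test_per_feature_mode(self):
        mat = np.array([[0.0, 0.2], [0.0, 0.4]])
        thr = adaptive_sd_threshold(mat, mode="per_feature", estimator="sample")
        per_feature = mat.std(axis=1, ddof=1)
        assert thr.average_sd == pytest.approx(per_feature.mean())
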