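"""ROUT outlier removal, Student's t, fold changes, ΔΔCT and LOD censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from plaquant.exceptions import InsufficientDataError, ParameterError, ValidationError
from plaquant.stats import (
    MeasurementSample,
    QpcrSample,
    censor_below_lod,
    delta_delta_ct,
    fold_change_vs_calibrator,
    rout_outliers,
    t_test_two_tailed,
)


class TestRout:
    def test_homogeneous_data_untouched(self):
        r = rout_outliers([10, 11, 9, 10, 10], q=0.001)
        assert r.n_outliers == 0
        assert r.kept.size == 5

    def test_single_gross_outlier_flagged(self):
        r = rout_outliers([10, 11, 9, 10, 10, 1000], q=0.001)
        assert r.outlier_indices.tolist() == [5]
        assert r.robust_center == pytest.approx(10.0, abs=0.5)

    def test_constant_data_untouched(self):
        r = rout_outliers([5.0] * 8)
        assert r.n_outliers == 0 and r.rsdr == 0.0

    def test_never_removes_more_than_half(self, rng):
        x = np.concatenate([np.zeros(5), 100 + rng.standard_normal(5)])
        r = rout_outliers(x, q=0.5)
        assert r.n_outliers <= 5

    def test_requires_three_points(self):
        with pytest.raises(InsufficientDataError):
            rout_outliers([1.0, 2.0])

    def test_kept_and_outliers_partition_input(self, rng):
        x = rng.standard_normal(30)
        x[3] += 12
        r = rout_outliers(x)
        assert r.kept.size + r.n_outliers == 30
        removed = x[r.outlier_indices]
        assert np.max(np.abs(r.kept - r.robust_center)) <= np.min(
            np.abs(removed - r.robust_center))


class TestTTest:
    def test_identical_samples_give_p_one(self):
        c = t_test_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t_statistic == 0.0 and c.p_value == 1.0

    def test_closed_form_example(self):
        c = t_test_two_tailed([1, 2, 3], [4, 5, 6])
        assert c.t_statistic == pytest.approx(-3.6742346, abs=1e-6)
        assert c.df == 4
        assert c.p_value == pytest.approx(0.021312, abs=1e-5)

    def test_agrees_with_scipy_to_1e10(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.3, 9)
        c = t_test_two_tailed(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert c.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert c.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_symmetric_under_group_swap(self, rng):
        a, b = rng.normal(size=8), rng.normal(1, 1, size=8)
        assert (t_test_two_tailed(a, b).p_value
                == pytest.approx(t_test_two_tailed(b, a).p_value, abs=1e-12))

    def test_zero_variance_conventions(self):
        same = t_test_two_tailed([2.0, 2.0], [2.0, 2.0])
        assert same.p_value == 1.0
        diff = t_test_two_tailed([2.0, 2.0], [3.0, 3.0])
        assert diff.p_value == 0.0 and diff.degenerate

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, scale):
        a, b = np.array([1.0, 2.0, 4.0]), np.array([3.0, 5.0, 6.0])
        c0 = t_test_two_tailed(a, b)
        c1 = t_test_two_tailed(a * scale, b * scale)
        assert c1.t_statistic == pytest.approx(c0.t_statistic, rel=1e-9)
        assert c1.p_value == pytest.approx(c0.p_value, rel=1e-9)


class TestFoldChange:
    def test_direct_example(self):
        r = fold_change_vs_calibrator([4.0, 4.0], [8.0, 8.0])
        assert r.mean_fold_other_vs_calibrator == 2.0

    def test_calibrator_maps_to_mean_one(self, rng):
        a = rng.uniform(1, 5, size=10)
        r = fold_change_vs_calibrator(a, a)
        assert r.per_value_calibrator.mean() == pytest.approx(1.0)

    def test_zero_calibrator_mean_rejected(self):
        with pytest.raises(ParameterError):
            fold_change_vs_calibrator([0.0, 0.0], [1.0, 2.0])


class TestDeltaDeltaCt:
    def test_identical_to_calibrator_gives_rq_one(self):
        samples = [QpcrSample(25.0, [20.0, 22.0], "cal", calibrator=True),
                   QpcrSample(25.0, [20.0, 22.0], "s1")]
        table = delta_delta_ct(samples)
        assert table["rq"].tolist() == [1.0, 1.0]

    def test_direct_formula_example(self):
        # delta-CT -2 vs calibrator +2 -> RQ = 2^4 = 16
        samples = [QpcrSample(22.0, [20.0], "cal", calibrator=True),
                   QpcrSample(18.0, [20.0], "s1")]
        table = delta_delta_ct(samples)
        assert table.loc[1, "rq"] == 16.0

    def test_duplicates_averaged_first(self):
        samples = [QpcrSample([24.0, 26.0], [[19.0, 21.0]], "cal", calibrator=True),
                   QpcrSample(25.0, [20.0], "s1")]
        table = delta_delta_ct(samples)
        assert table.loc[1, "rq"] == 1.0

    def test_matches_spreadsheet_recomputation(self, rng):
        cts = rng.uniform(18, 30, size=(5, 3))
        samples = [QpcrSample(row[0], [row[1], row[2]], f"s{i}", calibrator=(i == 0))
                   for i, row in enumerate(cts)]
        table = delta_delta_ct(samples)
        dct = cts[:, 0] - cts[:, 1:].mean(axis=1)
        expected = 2.0 ** (-(dct - dct[0]))
        assert np.allclose(table["rq"], expected)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(shift=st.floats(-5, 5))
    def test_global_ct_shift_invariance(self, shift):
        base = [QpcrSample(24.0, [20.0, 21.0], "cal", calibrator=True),
                QpcrSample(27.0, [19.0, 22.0], "s1")]
        shifted = [QpcrSample(24.0 + shift, [20.0 + shift, 21.0 + shift],
                              "cal", calibrator=True),
                   QpcrSample(27.0 + shift, [19.0 + shift, 22.0 + shift], "s1")]
        assert np.allclose(delta_delta_ct(base)["rq"],
                           delta_delta_ct(shifted)["rq"])

    def test_missing_references_rejected(self):
        with pytest.raises(ValidationError):
            delta_delta_ct([QpcrSample(24.0, [], "cal", calibrator=True)])


class TestLodCensoring:
    def test_direct_rule(self):
        out, n = censor_below_lod([4.0, 12.0, 9.0], lod=10.0)
        assert out.tolist() == [5.0, 12.0, 5.0] and n == 2

    def test_all_above_identity(self):
        out, n = censor_below_lod([11.0, 12.0], lod=10.0)
        assert out.tolist() == [11.0, 12.0] and n == 0

    def test_value_exactly_at_lod_unchanged(self):
        out, n = censor_below_lod([10.0], lod=10.0)
        assert out.tolist() == [10.0] and n == 0

    def test_negative_lod_rejected(self):
        with pytest.raises(ParameterError):
            censor_below_lod([1.0], lod=-1.0)


def test_measurement_sample_rejects_nonfinite():
    with pytest.raises(ValidationError):
        MeasurementSample([1.0, np.inf])
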