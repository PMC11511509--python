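"""Agreement statistics against hand-computed and independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinekin.errors import InvalidInputError
from spinekin.stats import (
    adjusted_rmse,
    agreement,
    bland_altman,
    flag_outliers,
    icc,
    icc_band,
    rmse,
)

# six-subject, two-rater table used for the closed-form ANOVA oracle
TABLE6 = np.array([
    [41.0, 43.5],
    [35.2, 36.0],
    [50.1, 47.9],
    [28.7, 30.2],
    [44.4, 44.0],
    [38.9, 41.1],
])


def _icc21_oracle(x):
    """Closed-form ICC(2,1) from explicitly summed ANOVA mean squares."""
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_matches_hand_anova_oracle(self):
        val, lo, hi = icc(TABLE6)
        assert val == pytest.approx(_icc21_oracle(TABLE6), abs=1e-10)
        assert lo < val < hi

    def test_perfect_agreement(self):
        x = np.column_stack([TABLE6[:, 0], TABLE6[:, 0]])
        val, _, _ = icc(x)
        assert val == pytest.approx(1.0, abs=1e-12)

    def test_matches_pingouin(self):
        """Independent cross-check against pingouin's ICC implementation."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(0, 2, size=(10, 2)) + rng.normal(40, 8, size=(10, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(10), 2),
            "raters": np.tile([0, 1], 10),
            "ratings": x.ravel(),
        })
        ref = pingouin.intraclass_corr(df, "targets", "raters", "ratings")
        ref = ref.set_index("Type")
        val, lo, hi = icc(x, model="ICC2_1")
        assert val == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-8)
        ref_ci = ref.loc["ICC(A,1)", "CI95"]
        assert (lo, hi) == pytest.approx(tuple(ref_ci), abs=5e-3)
        val3, _, _ = icc(x, model="ICC3_1")
        assert val3 == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-8)
        valk, _, _ = icc(x, model="ICC2_k")
        assert valk == pytest.approx(ref.loc["ICC(A,k)", "ICC"], abs=1e-8)

    def test_banding(self):
        assert icc_band(0.77) == "good"
        assert icc_band(0.96) == "excellent"
        assert icc_band(0.49) == "poor"
        # boundary convention: 0.50 and 0.75 belong to moderate, 0.90 to good
        assert icc_band(0.50) == "moderate"
        assert icc_band(0.75) == "moderate"
        assert icc_band(0.90) == "good"

    def test_negative_icc_reported_as_computed(self):
        # anti-correlated columns -> negative ICC, not truncated to 0
        x = np.column_stack([[1, 2, 3, 4, 5.0], [5, 4, 3, 2, 1.0]])
        val, lo, _ = icc(x)
        assert val < 0
        assert lo <= val

    def test_zero_between_subject_variance_warns(self):
        x = np.full((5, 2), 7.0)
        with pytest.warns(RuntimeWarning):
            val, _, _ = icc(x)
        assert np.isnan(val) or val == 0.0

    def test_too_few_rows(self):
        with pytest.raises(InvalidInputError):
            icc(TABLE6[:2])

    def test_incomplete_rows_dropped_pairwise(self):
        x = TABLE6.copy()
        x[1, 1] = np.nan
        val, _, _ = icc(x)
        ref, _, _ = icc(np.delete(TABLE6, 1, axis=0))
        assert val == pytest.approx(ref, abs=1e-12)

    def test_shift_one_column_decreases_absolute_agreement_icc(self):
        base, _, _ = icc(TABLE6, model="ICC2_1")
        shifted = TABLE6 + np.array([0.0, 6.0])
        val, _, _ = icc(shifted, model="ICC2_1")
        assert val < base

    def test_consistency_model_invariant_to_one_column_shift(self):
        base, _, _ = icc(TABLE6, model="ICC3_1")
        val, _, _ = icc(TABLE6 + np.array([0.0, 6.0]), model="ICC3_1")
        assert val == pytest.approx(base, abs=1e-10)

    def test_both_column_shift_and_rescale_invariance(self):
        base, _, _ = icc(TABLE6, model="ICC2_1")
        val, _, _ = icc(TABLE6 * 1.7 + 12.0, model="ICC2_1")
        assert val == pytest.approx(base, abs=1e-10)


class TestRmse:
    def test_identical_columns(self):
        assert rmse(np.column_stack([TABLE6[:, 0]] * 2)) == 0.0

    def test_hand_arithmetic(self):
        # differences [3, -4] -> sqrt((9 + 16) / 2)
        x = np.array([[3.0, 0.0], [0.0, 4.0]])
        assert rmse(x) == pytest.approx(np.sqrt(25 / 2), abs=1e-4)
        assert rmse(x) == pytest.approx(3.5355, abs=1e-4)

    def test_single_pair(self):
        assert rmse(np.array([[10.0, 5.0]])) == pytest.approx(5.0)


class TestBlandAltman:
    def test_identical_columns(self):
        ba = bland_altman(np.column_stack([TABLE6[:, 0]] * 2))
        assert ba.bias_mean == 0.0 and ba.bias_sd == 0.0

    def test_constant_offset(self):
        x = np.column_stack([TABLE6[:, 0] + 2.0, TABLE6[:, 0]])
        ba = bland_altman(x)
        assert ba.bias_mean == pytest.approx(2.0)
        assert ba.bias_sd == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_five_pairs(self):
        a = np.array([40.0, 35.0, 50.0, 28.0, 44.0])
        b = np.array([38.0, 36.0, 47.0, 30.0, 43.0])
        ba = bland_altman(np.column_stack([a, b]))
        d = a - b
        assert ba.bias_mean == pytest.approx(d.mean())
        assert ba.bias_sd == pytest.approx(d.std(ddof=1))


class TestOutliers:
    def test_no_outliers_when_all_equal(self):
        assert flag_outliers(np.full(6, 2.0)) == []

    def test_injected_5sd_outlier_flagged(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0, 1, 20)
        d[7] = d.mean() + 5 * d.std(ddof=1)
        assert flag_outliers(d) == [7]

    def test_exactly_two_sd_boundary_is_strict(self):
        # drive the extreme difference onto the 2-SD boundary by fixed-point
        # iteration, then check the strict-inequality convention
        s = np.sqrt(0.05)
        d = np.array([2.0, -0.4 + s, -0.4 - s, -0.4 + s, -0.4 - s, -0.4])
        for _ in range(100):
            d[0] = d.mean() + 2.0 * np.std(d, ddof=1)
        mu, sd = d.mean(), np.std(d, ddof=1)
        assert abs(d[0] - mu - 2.0 * sd) < 1e-9  # on the boundary
        expected = [0] if (np.abs(d[0] - mu) > 2.0 * sd) else []
        assert flag_outliers(d) == expected
        assert expected == []  # at exactly 2 SD the point is not an outlier

    def test_adjusted_rmse_hand_arithmetic(self):
        # differences [1, 1, 1, 20]: removing the extreme point leaves rmse 1
        # (a lone extreme among only 4 points can never exceed 2 sample SDs,
        # so the outlier id is supplied explicitly here; rule tested above)
        x = np.column_stack([[1.0, 1.0, 1.0, 20.0], np.zeros(4)])
        assert adjusted_rmse(x, [3]) == pytest.approx(1.0)
        assert adjusted_rmse(x, [3]) < rmse(x)

    def test_large_outlier_reduces_adjusted_rmse(self):
        rng = np.random.default_rng(2)
        d = rng.normal(1, 0.5, 12)
        d[4] = 25.0
        x = np.column_stack([d, np.zeros(12)])
        out = flag_outliers(d)
        assert out == [4]
        assert adjusted_rmse(x, out) < rmse(x)

    def test_all_rows_flagged_is_error(self):
        with pytest.raises(InvalidInputError):
            adjusted_rmse(TABLE6, list(range(6)))


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-50, 50), min_size=4, max_size=24))
def test_adjusted_rmse_consistency(diffs):
    """Adjusted RMSE equals the RMSE of the retained subset, and removing
    flagged outliers lowers it whenever their mean square exceeds the
    overall mean square (the typical case the adjustment exists for)."""
    d = np.asarray(diffs)
    x = np.column_stack([d, np.zeros(len(d))])
    out = flag_outliers(d) if np.std(d) > 0 else []
    keep = np.delete(d, out)
    adj = adjusted_rmse(x, out)
    assert adj == pytest.approx(np.sqrt(np.mean(keep**2)), abs=1e-9)
    if out and np.mean(d[np.asarray(out)] ** 2) >= np.mean(d**2):
        assert adj <= rmse(x) + 1e-12


def test_agreement_panel_consistency():
    rng = np.random.default_rng(5)
    base = rng.normal(40, 8, 12)
    x = pd.DataFrame({"IMU": base + rng.normal(1, 2, 12), "OMC": base},
                     index=[f"S{i:02d}" for i in range(12)])
    res = agreement(x)
    assert res.adjusted_rmse <= res.rmse
    assert res.icc_band == icc_band(res.icc)
    assert res.n == 12
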