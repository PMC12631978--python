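"""Dose-response fitting, EC extraction and bioanalytical equivalents."""

import numpy as np
import pytest

from hteda import (
    CalibrationError,
    DoseResponseModel,
    FitFailureError,
    HtedaError,
    beq_from_ec,
    ec_at,
    fit_sigmoid,
    linear_range_ec10,
    normalize_to_reference,
)


def _curve(dose, bottom, top, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


class TestNormalization:
    def test_anchors(self):
        # saturating response -> 100%, background -> 0%, midpoint -> 50%
        out = normalize_to_reference([50000.0, 2000.0, 26000.0], 50000.0, 2000.0)
        assert out == pytest.approx([100.0, 0.0, 50.0])

    def test_replicates_averaged_before_normalization(self):
        out = normalize_to_reference([[40000.0, 60000.0]], 50000.0, 2000.0)
        assert out == pytest.approx([100.0])

    def test_reference_below_background_rejected(self):
        with pytest.raises(CalibrationError):
            normalize_to_reference([10.0], 100.0, 200.0)


class TestSigmoidFit:
    @pytest.mark.parametrize("ec50,hill", [(1.0, 1.0), (0.3, 2.4), (40.0, 0.8)])
    def test_noiseless_recovery(self, ec50, hill):
        dose = np.geomspace(ec50 / 30, ec50 * 30, 10)
        fit = fit_sigmoid(dose, _curve(dose, 0, 100, ec50, hill))
        assert fit.ec50 == pytest.approx(ec50, rel=1e-6)
        assert fit.hill == pytest.approx(hill, rel=1e-6)
        assert fit.top == pytest.approx(100.0, rel=1e-6)

    def test_noisy_ec50_recovery_seeded(self):
        # 5% multiplicative noise on 8 doses: typical run recovers the
        # EC50 within 15% (median over seeded repeats)
        dose = np.geomspace(0.05, 20.0, 8)
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = _curve(dose, 0, 100, 1.0, 1.0) * rng.normal(1.0, 0.05, dose.size)
            errors.append(abs(fit_sigmoid(dose, y).ec50 - 1.0))
        assert np.median(errors) < 0.15

    def test_uninformative_low_responses_fail(self):
        dose = np.geomspace(0.01, 1.0, 6)
        with pytest.raises(FitFailureError):
            fit_sigmoid(dose, np.full(6, 3.0))  # never exceeds 5%

    def test_too_few_points(self):
        with pytest.raises(FitFailureError):
            fit_sigmoid([1.0, 2.0, 3.0], [10.0, 50.0, 90.0])

    def test_high_dose_suppression_excluded(self):
        # cytotoxic collapse at the top dose: flagged and excluded
        dose = np.array([0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
        y = _curve(dose, 0, 100, 1.0, 1.0)
        y[-1] = 20.0  # 77 percentage points below the running max
        fit = fit_sigmoid(dose, y)
        assert fit.excluded_points.shape[0] == 1
        assert fit.excluded_points[0, 0] == pytest.approx(30.0)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-4)

    def test_scale_equivariance(self):
        dose = np.geomspace(0.02, 50.0, 9)
        y = _curve(dose, 0, 100, 1.3, 1.6)
        k = 7.5
        f1 = fit_sigmoid(dose, y)
        f2 = fit_sigmoid(k * dose, y)
        for level in (10.0, 30.0, 50.0):
            assert f2.ec(level) == pytest.approx(k * f1.ec(level), rel=1e-6)


class TestEcInversion:
    @pytest.mark.parametrize(
        "ec50,hill,level,expected",
        [
            (1.0, 1.0, 50.0, 1.0),  # EC50 by definition
            (1.0, 1.0, 10.0, 1.0 / 9.0),
            (2.0, 2.0, 10.0, 2.0 * (1.0 / 9.0) ** 0.5),
        ],
    )
    def test_closed_form(self, ec50, hill, level, expected):
        dose = np.geomspace(ec50 / 50, ec50 * 50, 10)
        fit = fit_sigmoid(dose, _curve(dose, 0, 100, ec50, hill))
        assert ec_at(fit, level) == pytest.approx(expected, rel=1e-6)
        # inversion consistency: predicting at the EC returns the level
        assert fit.predict([fit.ec(level)])[0] == pytest.approx(level, rel=1e-9)

    def test_level_outside_range_rejected(self):
        dose = np.geomspace(0.1, 10, 8)
        fit = fit_sigmoid(dose, _curve(dose, 0, 100, 1.0, 1.0))
        for bad in (0.0, -5.0, 100.0, 130.0):
            with pytest.raises(HtedaError):
                fit.ec(bad)

    def test_right_censoring_when_level_unreached(self):
        # weak sample: response tops out ~6.6% in the tested range
        dose = np.geomspace(0.25, 16.0, 8)
        y = _curve(dose, 0, 100, 60.0, 2.0)
        fit = fit_sigmoid(dose, y, min_signal=1.0)
        est = fit.ec_estimate(10.0)
        assert est.censored
        assert est.value == pytest.approx(16.0)
        assert str(est).startswith(">")


class TestLinearRangeEc10:
    def test_exact_lines(self):
        fit = linear_range_ec10(
            [0.01, 0.02, 0.04, 0.08], [2.0, 4.0, 8.0, 16.0]
        )  # response = 200*dose
        assert fit.ec(10.0) == pytest.approx(0.05)
        fit2 = linear_range_ec10([0.1, 0.2, 0.3], [5.0, 10.0, 15.0])
        assert fit2.ec(10.0) == pytest.approx(0.2)
        assert fit2.method == "linear_range"

    def test_zero_slope_rejected(self):
        with pytest.raises(FitFailureError):
            linear_range_ec10([0.1, 0.2, 0.3], [5.0, 5.0, 5.0])

    def test_ceiling_excludes_high_responses(self):
        fit = linear_range_ec10(
            [0.01, 0.02, 0.04, 1.0], [2.0, 4.0, 8.0, 95.0], ceiling=30.0
        )
        assert int(fit.used_mask.sum()) == 3
        assert fit.ec(10.0) == pytest.approx(0.05, rel=1e-9)


class TestBeq:
    def test_ratio_definition(self):
        assert beq_from_ec(10.0, 0.1).beq == pytest.approx(100.0)
        # reference EC10 14.5 ng/L over sample EC10 at REF 0.052
        assert beq_from_ec(14.5, 0.052).beq == pytest.approx(278.8, abs=0.1)

    def test_degenerate_inputs(self):
        for ref, sample in [(10.0, 0.0), (0.0, 0.1), (-1.0, 0.1)]:
            with pytest.raises(HtedaError):
                beq_from_ec(ref, sample)

    def test_monotone_in_ref_antitone_in_sample(self):
        base = beq_from_ec(10.0, 0.1).beq
        assert beq_from_ec(20.0, 0.1).beq > base
        assert beq_from_ec(10.0, 0.2).beq < base
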