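"""Cosinor fitting: exact recovery, rhythm detection, eligibility and the
model's equivariance properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circamark.cosinor import (
    check_eligibility,
    circular_mean_hours,
    circular_median_hours,
    detect_rhythm,
    fit_multicomponent_cosinor,
    summarize_cohort,
)
from circamark.exceptions import (
    DegenerateDataError,
    EligibilityError,
    ParameterError,
)
from circamark.synthetic import UrineSimParams, generate_urine_series


def _wrap_angle(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


class TestFit:
    def test_noiseless_parameters_recovered_exactly(self, study_times):
        truth = UrineSimParams(
            mesor_log=np.log(7.0), amp12_log=0.22, amp24_log=0.45,
            phase12=0.9, phase24=-2.1, noise_sd_log=0.0,
        )
        df = generate_urine_series(truth, seed=0)
        fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        assert abs(fit.mesor_log - truth.mesor_log) < 1e-6
        assert abs(fit.A12 - truth.amp12_log) < 1e-6
        assert abs(fit.A24 - truth.amp24_log) < 1e-6
        assert abs(_wrap_angle(fit.theta12 - truth.phase12)) < 1e-6
        assert abs(_wrap_angle(fit.theta24 - truth.phase24)) < 1e-6

    def test_constant_series_has_zero_amplitude_and_p_one(self, study_times):
        fit = fit_multicomponent_cosinor(study_times, np.full(10, 4.2))
        assert fit.A12 < 1e-9 and fit.A24 < 1e-9
        assert fit.amp_p[12.0] == pytest.approx(1.0)
        assert fit.amp_p[24.0] == pytest.approx(1.0)
        assert fit.mesor == pytest.approx(4.2)
        assert not fit.rhythmic_any

    def test_acrophase_recovery_under_noise(self, study_times):
        """Median absolute 24-h acrophase error stays below 1.5 h at sd 0.1."""
        truth = UrineSimParams(amp12_log=0.15, amp24_log=0.3, noise_sd_log=0.1)
        true_peak = (-truth.phase24 * 24 / (2 * np.pi)) % 24
        errors = []
        for seed in np.random.SeedSequence(17).spawn(100):
            df = generate_urine_series(truth, seed=seed)
            fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
            e = abs(fit.component_peak_hours(24.0) - true_peak)
            errors.append(min(e, 24 - e))
        assert np.median(errors) < 1.5

    def test_too_few_samples_rejected(self, study_times):
        with pytest.raises(EligibilityError):
            fit_multicomponent_cosinor(study_times[:6], np.full(6, 3.0))

    def test_nonpositive_concentration_rejected(self, study_times):
        values = np.full(10, 3.0)
        values[4] = 0.0
        with pytest.raises(ParameterError, match="non-positive"):
            fit_multicomponent_cosinor(study_times, values)

    def test_single_clock_time_design_rejected(self):
        t = np.array([7.0, 31.0] * 4)  # same clock time both days
        with pytest.raises(DegenerateDataError):
            fit_multicomponent_cosinor(t, np.linspace(2, 3, 8))

    def test_short_span_rejected(self):
        t = np.linspace(7, 23, 8)
        with pytest.raises(EligibilityError):
            fit_multicomponent_cosinor(t, np.linspace(2, 3, 8))


class TestDetectRhythm:
    def test_strong_component_flagged(self, study_times):
        truth = UrineSimParams(amp12_log=0.0, amp24_log=0.8, noise_sd_log=0.05)
        df = generate_urine_series(truth, seed=3)
        fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        assert fit.A24 > 5 * fit.amp_se[24.0]
        assert fit.rhythmic_24h and fit.rhythmic_any

    def test_alpha_zero_never_flags(self, noisy_urine):
        _, df = noisy_urine
        fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        fit0 = detect_rhythm(fit, alpha=0.0)
        assert not fit0.rhythmic_12h and not fit0.rhythmic_24h

    def test_rhythmic_any_is_or_of_components(self, noisy_urine):
        _, df = noisy_urine
        fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        for alpha in (0.01, 0.1, 0.5, 1.0):
            f = detect_rhythm(fit, alpha)
            assert f.rhythmic_any == (f.rhythmic_12h or f.rhythmic_24h)


class TestEligibility:
    def test_ten_samples_eligible(self):
        assert check_eligibility(np.full(10, 1.0))

    def test_six_samples_excluded(self):
        assert not check_eligibility(np.full(6, 1.0))

    def test_nonpositive_sample_does_not_count(self):
        values = [1.0] * 7
        values[0] = 0.0
        assert not check_eligibility(values)


class TestEquivariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        shift=st.floats(min_value=-24, max_value=24),
        scale=st.floats(min_value=0.1, max_value=50),
    )
    def test_time_shift_and_scale_equivariance(self, shift, scale):
        truth = UrineSimParams(amp12_log=0.1, amp24_log=0.3, noise_sd_log=0.1)
        df = generate_urine_series(truth, seed=99)
        base = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        shifted = fit_multicomponent_cosinor(df["time_h"] + shift, df["concentration"])
        assert shifted.overall_acrophase_h == pytest.approx(
            (base.overall_acrophase_h + shift) % 24, abs=2 / 60
        )
        assert shifted.A24 == pytest.approx(base.A24, abs=1e-9)
        assert shifted.amp_p[24.0] == pytest.approx(base.amp_p[24.0], abs=1e-9)
        scaled = fit_multicomponent_cosinor(df["time_h"], df["concentration"] * scale)
        assert scaled.mesor == pytest.approx(base.mesor * scale, rel=1e-9)
        assert scaled.overall_amplitude == pytest.approx(
            base.overall_amplitude * scale, rel=1e-9
        )
        assert scaled.relative_amplitude == pytest.approx(
            base.relative_amplitude, rel=1e-9
        )
        assert scaled.amp_p[24.0] == pytest.approx(base.amp_p[24.0], abs=1e-9)

    def test_overall_amplitude_bounds_component_difference(self):
        """Log-scale half-range of the fitted curve >= |A24 - A12|, checked
        against a dense-grid evaluation."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            truth = UrineSimParams(
                amp12_log=rng.uniform(0, 0.5),
                amp24_log=rng.uniform(0, 0.5),
                phase12=rng.uniform(-np.pi, np.pi),
                phase24=rng.uniform(-np.pi, np.pi),
                noise_sd_log=0.0,
            )
            df = generate_urine_series(truth, seed=seed)
            fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
            grid = np.arange(0, 24, 1 / 60)
            log_curve = np.log(fit.curve(grid))
            half_range = (log_curve.max() - log_curve.min()) / 2
            assert half_range >= abs(fit.A24 - fit.A12) - 1e-9


class TestCircularStats:
    def test_median_of_times_straddling_midnight(self):
        assert circular_median_hours([23.0, 1.0]) == pytest.approx(0.0, abs=1 / 60)

    def test_mean_respects_wraparound(self):
        assert circular_mean_hours([23.0, 1.0]) == pytest.approx(0.0, abs=1e-9)


class TestCohortSummary:
    def test_single_patient_degenerate_summary(self, study_times):
        truth = UrineSimParams(noise_sd_log=0.1)
        df = generate_urine_series(truth, seed=12)
        fit = fit_multicomponent_cosinor(df["time_h"], df["concentration"])
        table = summarize_cohort({"pseudouridine": [fit]})
        row = table.loc["pseudouridine"]
        assert row["n_patients"] == 1
        assert row["mesor_mean"] == pytest.approx(row["mesor_median"])
        assert row["mesor_min"] == pytest.approx(row["mesor_max"])

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            summarize_cohort({})
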