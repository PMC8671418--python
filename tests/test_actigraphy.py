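"""HMM segmentation and rest-activity indices on constructed and simulated
series with known structure."""

import numpy as np
import pandas as pd
import pytest

from circamark.actigraphy import (
    ActigraphySeries,
    StateFingerprint,
    activity_cosinor,
    autocorr24,
    dichotomy_index,
    dominant_period,
    fingerprint,
    fit_hmm,
    hmm_indices,
)
from circamark.exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)

def _toy_series(counts, diary=None, start="2021-03-01 00:00"):
    return ActigraphySeries(start=start, counts=np.asarray(counts, float), diary=diary)


class TestFitHmm:
    def test_viterbi_recovers_latent_states(self, fitted_regular):
        series, states, model = fitted_regular
        accuracy = (model.decode(series) == states).mean()
        assert accuracy >= 0.95

    def test_emission_means_relabelled_increasing(self, fitted_regular):
        _, _, model = fitted_regular
        assert model.means[0] < model.means[1] < model.means[2]
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)

    def test_refit_is_deterministic(self, regular_recording):
        _, series, _ = regular_recording
        m1 = fit_hmm(series, n_restarts=2, seed=4)
        m2 = fit_hmm(series, n_restarts=2, seed=4)
        assert m1.log_likelihood == m2.log_likelihood
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_constant_zero_series_rejected(self):
        series = _toy_series(np.zeros(2 * 1440))
        with pytest.raises(DegenerateDataError):
            fit_hmm(series, n_restarts=1, seed=0)

    def test_short_series_rejected(self):
        series = _toy_series(np.random.default_rng(0).poisson(5, 600))
        with pytest.raises(InsufficientDataError):
            fit_hmm(series, n_restarts=1, seed=0)


class TestFingerprint:
    def test_probabilities_sum_to_one(self, fitted_regular):
        series, _, model = fitted_regular
        fp = fingerprint(series, model)
        np.testing.assert_allclose(fp.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_regular_rest_window_is_sharp(self, fitted_regular):
        """IA probability ~1 inside the fixed 00:00-08:00 window, ~0 outside."""
        series, _, model = fitted_regular
        fp = fingerprint(series, model)
        inside = (fp.clock_hours > 0.5) & (fp.clock_hours < 7.5)
        outside = (fp.clock_hours > 9.0) & (fp.clock_hours < 23.0)
        assert fp.p_ia[inside].min() > 0.95
        assert fp.p_ia[outside].max() < 0.05

    def test_shuffled_epochs_flatten_the_fingerprint(self, fitted_regular):
        """Permuting epochs destroys the time-of-day structure; judged on
        hourly bins so per-bin sampling noise averages down."""
        series, _, model = fitted_regular
        rng = np.random.default_rng(1)
        shuffled = ActigraphySeries(
            start=series.start,
            counts=rng.permutation(series.counts),
            epoch_minutes=series.epoch_minutes,
        )
        fp = fingerprint(shuffled, model, bin_minutes=60)
        assert fp.p_ia.max() - fp.p_ia.min() < 0.2
        sharp = fingerprint(series, model, bin_minutes=60)
        assert sharp.p_ia.max() - sharp.p_ia.min() > 0.9


class TestHmmIndices:
    @staticmethod
    def _square_fingerprint(rest_hours, bin_minutes=10):
        n = 1440 // bin_minutes
        centres = (np.arange(n) + 0.5) * bin_minutes / 60
        p_ia = ((centres > 0) & (centres < rest_hours)).astype(float)
        probs = np.column_stack([p_ia, 1 - p_ia, np.zeros(n)])
        return StateFingerprint(clock_hours=centres, probs=probs, bin_minutes=bin_minutes)

    def test_square_wave_rest_gives_full_rhythm_index(self):
        fp = self._square_fingerprint(8.0)
        idx = hmm_indices(fp)
        assert idx.rest_duration_a == pytest.approx(8.0, abs=1e-9)
        assert idx.rhythm_index == pytest.approx(100.0, abs=1e-6)
        assert idx.center_of_rest_c == pytest.approx(4.0, abs=1e-6)

    def test_flat_profile_gives_zero_rhythm_index(self):
        n = 144
        centres = (np.arange(n) + 0.5) / 6
        probs = np.column_stack(
            [np.full(n, 1 / 3), np.full(n, 1 / 3), np.full(n, 1 / 3)]
        )
        fp = StateFingerprint(clock_hours=centres, probs=probs, bin_minutes=10)
        idx = hmm_indices(fp)
        assert idx.rhythm_index == pytest.approx(0.0, abs=1e-6)

    def test_all_rest_profile_has_undefined_rhythm_index(self):
        n = 144
        centres = (np.arange(n) + 0.5) / 6
        probs = np.column_stack([np.ones(n), np.zeros(n), np.zeros(n)])
        fp = StateFingerprint(clock_hours=centres, probs=probs, bin_minutes=10)
        assert hmm_indices(fp).rhythm_index is None

    def test_simulated_regular_sleeper_scores_high(self, fitted_regular):
        series, _, model = fitted_regular
        fp = fingerprint(series, model)
        idx = hmm_indices(fp, model, series)
        assert idx.rhythm_index > 85.0
        assert idx.p11 > 0.95
        assert 7.0 < idx.rest_duration_a < 9.0
        assert idx.median_ha > 0


class TestDichotomyIndex:
    def test_silent_nights_give_hundred_percent(self):
        counts = np.tile(np.r_[np.zeros(480), np.full(960, 50.0)], 2)
        diary = [
            (pd.Timestamp("2021-03-01 00:00"), pd.Timestamp("2021-03-01 08:00")),
            (pd.Timestamp("2021-03-02 00:00"), pd.Timestamp("2021-03-02 08:00")),
        ]
        assert dichotomy_index(_toy_series(counts, diary)) == 100.0

    def test_in_bed_at_median_gives_zero_percent(self):
        counts = np.tile(np.r_[np.full(480, 50.0), np.full(960, 50.0)], 2)
        diary = [
            (pd.Timestamp("2021-03-01 00:00"), pd.Timestamp("2021-03-01 08:00")),
            (pd.Timestamp("2021-03-02 00:00"), pd.Timestamp("2021-03-02 08:00")),
        ]
        assert dichotomy_index(_toy_series(counts, diary)) == 0.0

    def test_invariance_under_monotone_transform(self, default_recording):
        _, series, _ = default_recording
        base = dichotomy_index(series)
        transformed = ActigraphySeries(
            start=series.start,
            counts=np.sqrt(series.counts) * 3 + 1,
            epoch_minutes=series.epoch_minutes,
            diary=series.diary,
        )
        assert dichotomy_index(transformed) == pytest.approx(base, abs=1e-12)

    def test_missing_diary_rejected(self, default_recording):
        _, series, _ = default_recording
        bare = ActigraphySeries(start=series.start, counts=series.counts)
        with pytest.raises(ParameterError):
            dichotomy_index(bare)


class TestAutocorr24:
    def test_exactly_periodic_series_gives_one(self):
        t = np.arange(3 * 1440)
        counts = 50 + 30 * np.cos(2 * np.pi * t / 1440)
        assert autocorr24(_toy_series(counts)) == pytest.approx(1.0, abs=1e-9)

    def test_twelve_hour_period_also_gives_one(self):
        t = np.arange(3 * 1440)
        counts = 50 + 30 * np.cos(2 * np.pi * t / 720)
        assert autocorr24(_toy_series(counts)) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_is_near_zero(self):
        counts = np.random.default_rng(2).poisson(40, 5 * 1440).astype(float)
        assert abs(autocorr24(_toy_series(counts))) < 0.05

    def test_constant_series_undefined(self):
        assert np.isnan(autocorr24(_toy_series(np.full(2 * 1440, 7.0))))

    def test_under_two_days_rejected(self):
        with pytest.raises(InsufficientDataError):
            autocorr24(_toy_series(np.random.default_rng(0).poisson(5, 1500)))


class TestDominantPeriod:
    @pytest.mark.parametrize("true_period", [24.0, 25.0])
    def test_sinusoid_period_recovered(self, true_period):
        t = np.arange(5 * 1440)
        rng = np.random.default_rng(int(true_period))
        counts = 50 + 30 * np.cos(2 * np.pi * t / (true_period * 60)) + rng.normal(0, 5, t.size)
        counts = np.maximum(counts, 0)
        dp = dominant_period(_toy_series(counts), n_resamples=20, seed=0)
        assert abs(dp.period_hours - true_period) < 0.5

    def test_white_noise_has_wide_interval(self):
        counts = np.random.default_rng(5).poisson(40, 5 * 1440).astype(float)
        dp = dominant_period(_toy_series(counts), n_resamples=60, seed=1)
        assert dp.ci_width > 2.0


class TestActivityCosinor:
    def test_pure_cosine_recovered_to_the_minute(self):
        t = np.arange(3 * 1440) / 60.0
        counts = 50 + 20 * np.cos(2 * np.pi * (t - 15.0) / 24)
        ac = activity_cosinor(_toy_series(counts))
        assert ac.amplitude == pytest.approx(20.0, abs=1e-9)
        assert ac.acrophase_hours == pytest.approx(15.0, abs=1 / 60)

    def test_constant_counts_have_zero_amplitude(self):
        ac = activity_cosinor(_toy_series(np.full(2 * 1440, 33.0)))
        assert ac.amplitude == pytest.approx(0.0, abs=1e-9)

    def test_acrophase_referenced_to_clock_time(self):
        # same physical signal, recording starting at 15:00 instead of 00:00
        t = np.arange(3 * 1440) / 60.0 + 15.0
        counts = 50 + 20 * np.cos(2 * np.pi * (t - 15.0) / 24)
        ac = activity_cosinor(_toy_series(counts, start="2021-03-01 15:00"))
        assert ac.acrophase_hours == pytest.approx(15.0, abs=1 / 60)
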