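"""Spearman machinery, residual-bootstrap uncertainty check, stepwise AIC
selection and the two-sample group comparison."""

import numpy as np
import pandas as pd
import pytest

from circamark.association import (
    bootstrap_correlation_check,
    group_comparison,
    significance_tier,
    spearman,
    spearman_matrix,
    stepwise_covariate_model,
)
from circamark.cosinor import fit_multicomponent_cosinor
from circamark.exceptions import DegenerateDataError, InsufficientDataError
from circamark.synthetic import generate_cohort


class TestSpearman:
    def test_monotone_pairs_hit_the_bounds(self):
        x = np.arange(12.0)
        rho, p, n = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho2, _, _ = spearman(x, -(x**3))
        assert rho2 == pytest.approx(-1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho1, p1, _ = spearman(x, y)
        rho2, p2, _ = spearman(np.exp(x), y**3 + 5 * y)
        # y**3 + 5y is strictly increasing, exp strictly increasing
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_constant_variable_flagged_missing(self):
        rho, p, n = spearman(np.ones(10), np.arange(10.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_exact_permutation_p_small_sample(self):
        # perfectly monotone n=6: exact two-sided p = 2/6!
        x = np.arange(6.0)
        _, p, _ = spearman(x, x * 2 + 1)
        assert p == pytest.approx(2 / 720)

    def test_null_rho_is_small_at_cohort_size(self):
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(200):
            rho, _, _ = spearman(rng.uniform(size=29), rng.uniform(size=29))
            rhos.append(abs(rho))
        assert np.median(rhos) < 0.25

    def test_matrix_layout_and_tiers(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"a": np.arange(20.0), "b": np.arange(20.0) ** 2, "c": rng.normal(size=20)}
        )
        grid = spearman_matrix(df)
        assert set(grid.columns) >= {"var_x", "var_y", "rho", "p_value", "tier", "grid_class"}
        ab = grid[(grid.var_x == "a") & (grid.var_y == "b")].iloc[0]
        assert ab.rho == pytest.approx(1.0)
        assert ab.grid_class == "significant"
        assert significance_tier(0.0005) == "***"
        assert significance_tier(0.07) == "^"


class TestBootstrapCheck:
    @staticmethod
    def _fits_for(cohort, nucleoside="pseudouridine"):
        fits = {}
        sub = cohort.urine[cohort.urine.nucleoside == nucleoside]
        for pid, g in sub.groupby("patient_id"):
            fits[pid] = fit_multicomponent_cosinor(g.time_h, g.concentration)
        return fits

    def test_fixed_seed_reproduces_flags(self):
        cohort = generate_cohort(12, "mixed", seed=4, rest_amplitude_coupling=0.25)
        fits = self._fits_for(cohort)
        kwargs = dict(
            covariates=cohort.truth,
            pairs=[("relative_amplitude", "rest_hours")],
            B=300,
            seed=42,
        )
        r1 = bootstrap_correlation_check(fits, **kwargs)[0]
        r2 = bootstrap_correlation_check(fits, **kwargs)[0]
        assert r1.bootstrap_p_q90 == r2.bootstrap_p_q90
        assert r1.bootstrap_significant == r2.bootstrap_significant

    def test_coupled_cohort_flagged_significant(self):
        cohort = generate_cohort(29, "mixed", seed=7, rest_amplitude_coupling=0.25)
        r = bootstrap_correlation_check(
            self._fits_for(cohort),
            cohort.truth,
            [("relative_amplitude", "rest_hours")],
            B=500,
            seed=0,
        )[0]
        assert r.bootstrap_significant

    def test_flag_never_exceeds_plain_significance(self):
        """The 90th-percentile rule is conservative: no pair is flagged when
        the plain Spearman p exceeds the alpha threshold."""
        for seed in range(10):
            cohort = generate_cohort(15, "mixed", seed=seed)
            results = bootstrap_correlation_check(
                self._fits_for(cohort),
                cohort.truth,
                [("relative_amplitude", "rest_hours"), ("mesor", "rest_hours")],
                B=200,
                seed=seed,
            )
            for r in results:
                if r.bootstrap_significant:
                    assert r.p_value <= 0.1

    def test_small_b_warns(self):
        cohort = generate_cohort(6, "mixed", seed=2)
        with pytest.warns(UserWarning, match="bootstrap trials"):
            bootstrap_correlation_check(
                self._fits_for(cohort),
                cohort.truth,
                [("mesor", "rest_hours")],
                B=50,
                seed=1,
            )


class TestStepwise:
    @staticmethod
    def _frame(seed, n=100, signal=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "sex": rng.choice(["m", "f"], n),
                "age": rng.normal(65, 10, n),
                "ps": rng.choice([0.0, 1.0], n),
            }
        )
        noise = rng.normal(0, 1, n)
        df["y"] = (2.0 * (df.sex == "f") if signal else 0.0) + noise
        return df

    def test_strong_sex_effect_always_selected(self):
        for seed in range(10):
            res = stepwise_covariate_model(self._frame(seed), "y", ["sex", "age", "ps"])
            assert "sex" in res.selected_terms
            assert res.aic <= res.aic_full + 1e-9

    def test_pure_noise_usually_selects_null_model(self):
        """Intercept-only is the single most common selection under noise."""
        from collections import Counter

        counts = Counter(
            stepwise_covariate_model(
                self._frame(seed, signal=False), "y", ["sex", "age", "ps"]
            ).selected_terms
            for seed in range(30)
        )
        assert counts.most_common(1)[0][0] == ()

    def test_order_invariance(self):
        df = self._frame(5)
        a = stepwise_covariate_model(df, "y", ["sex", "age", "ps"]).selected_terms
        b = stepwise_covariate_model(df, "y", ["ps", "age", "sex"]).selected_terms
        assert a == b

    def test_aliased_covariates_named(self):
        df = self._frame(1)
        df["age_copy"] = df["age"]
        with pytest.raises(DegenerateDataError, match="age"):
            stepwise_covariate_model(df, "y", ["sex", "age", "age_copy"])


class TestGroupComparison:
    def test_identical_groups_null_result(self):
        v = np.r_[np.arange(5.0), np.arange(5.0)]
        g = np.r_[["a"] * 5, ["b"] * 5]
        res = group_comparison(v, g)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_negates_t(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=20)
        g = np.r_[["a"] * 10, ["b"] * 10]
        res = group_comparison(v, g)
        swapped = group_comparison(v, np.where(g == "a", "b", "a"))
        assert swapped.t_statistic == pytest.approx(-res.t_statistic)
        assert swapped.p_value == pytest.approx(res.p_value)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(200):
            v = np.r_[rng.normal(0, 1, 15), rng.normal(3, 1, 15)]
            g = np.r_[["a"] * 15, ["b"] * 15]
            hits += group_comparison(v, g).p_value < 0.001
        assert hits / 200 >= 0.99

    def test_tiny_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            group_comparison([1.0, 2.0, 3.0], ["a", "b", "b"])
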