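"""Multiple-component cosinor rhythmometry for sparsely timed biomarker series.

The model is

    y(t) = M + sum_k A_k * cos(2*pi*t / T_k + theta_k) + e(t)

with fixed periods, by default T = {12, 24} hours.  M is the mesor
(rhythm-adjusted mean), A_k >= 0 the component amplitudes and theta_k the
component acrophases in radians.  Concentrations are log-transformed before
fitting so that multiplicative noise becomes additive and near-Gaussian;
mesor and amplitude are transformed back to the measurement scale
(micrograms per gram creatinine) for reporting.

Because the periods are fixed, the nonlinear model is exactly equivalent to a
linear regression on cos/sin pairs; the fit is therefore a single ordinary
least-squares solve with no starting-value or convergence issues.  Amplitude
standard errors come from the delta method applied to the OLS covariance.
Each component is tested against zero amplitude with the classical cosinor
zero-amplitude test: because A_k = 0 exactly when the component's cos and
sin coefficients both vanish, this is an F test with (2, n - 5) degrees of
freedom, exactly calibrated under Gaussian errors (a statistic built on the
non-negative |A_k| alone is inflated in small samples because the acrophase
is unidentified at zero amplitude).  A series is called rhythmic when either
component's amplitude differs from zero at the chosen level (default
alpha = 0.1, deliberately liberal for designs with ~10 samples).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, EligibilityError, ParameterError

__all__ = [
    "CosinorFit",
    "fit_multicomponent_cosinor",
    "detect_rhythm",
    "check_eligibility",
    "summarize_cohort",
    "harmonic_design",
    "fit_harmonic",
    "circular_mean_hours",
    "circular_median_hours",
    "circular_quantile_hours",
]

DEFAULT_PERIODS: tuple[float, float] = (12.0, 24.0)
MIN_SAMPLES = 7
#: clock-grid step (minutes) used to evaluate the fitted curve for the
#: overall amplitude/acrophase; ties at the maximum break to the earliest time
ACROPHASE_GRID_MINUTES = 1


def harmonic_design(t_hours: np.ndarray, periods: Sequence[float]) -> np.ndarray:
    """Design matrix [1, cos(2pi t/T1), sin(2pi t/T1), ...] for fixed periods."""
    t = np.asarray(t_hours, dtype=float)
    cols = [np.ones_like(t)]
    for T in periods:
        w = 2.0 * np.pi * t / T
        cols.append(np.cos(w))
        cols.append(np.sin(w))
    return np.column_stack(cols)


def fit_harmonic(
    t_hours: np.ndarray, y: np.ndarray, periods: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float, int, np.ndarray]:
    """OLS fit of the harmonic regression; returns (beta, cov, sigma2, dof, resid).

    ``cov`` is the parameter covariance sigma2 * (X'X)^-1.  Raises
    :class:`DegenerateDataError` if the design is singular (e.g. all samples
    at the same clock time).
    """
    X = harmonic_design(t_hours, periods)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateDataError(
            "singular cosinor design: sample times do not identify all "
            f"{p} parameters (e.g. all samples at the same clock time)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv
    return beta, cov, sigma2, dof, resid


def _amp_phase_from_beta(beta_c: float, beta_s: float) -> tuple[float, float]:
    # y = bc*cos(wt) + bs*sin(wt) == A*cos(wt + theta) with
    # bc = A cos(theta), bs = -A sin(theta)
    A = float(np.hypot(beta_c, beta_s))
    theta = float(np.arctan2(-beta_s, beta_c))
    return A, theta


def _amp_se(beta_c: float, beta_s: float, cov2: np.ndarray) -> float:
    """Delta-method SE of A = hypot(bc, bs) given the 2x2 (bc, bs) covariance."""
    A = np.hypot(beta_c, beta_s)
    if A == 0.0:
        # gradient undefined at the origin; use the larger marginal SD as a
        # conservative scale
        return float(np.sqrt(max(cov2[0, 0], cov2[1, 1])))
    g = np.array([beta_c, beta_s]) / A
    return float(np.sqrt(g @ cov2 @ g))


@dataclass(frozen=True)
class CosinorFit:
    """Result of a fixed-period multi-component cosinor fit.

    Amplitudes, acrophases and the mesor ``mesor_log`` live on the fitting
    scale (log concentrations unless ``log_scale`` is False).  ``mesor``,
    ``overall_amplitude`` and ``overall_acrophase_h`` are the reported,
    back-transformed quantities: exp(M), half-range of the exponentiated
    fitted curve over 24 h, and the clock time (hours) of its maximum.
    """

    periods: tuple[float, ...]
    mesor_log: float
    amplitudes: dict[float, float]
    acrophases_rad: dict[float, float]
    amp_se: dict[float, float]
    amp_p: dict[float, float]
    dof: int
    n_samples: int
    sigma2: float
    times: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    log_scale: bool
    mesor: float
    overall_amplitude: float
    relative_amplitude: float
    overall_acrophase_h: float
    rhythmic: dict[float, bool]
    alpha: float

    # -- convenience accessors matching the two-component naming -----------
    @property
    def A12(self) -> float:
        return self.amplitudes[12.0]

    @property
    def A24(self) -> float:
        return self.amplitudes[24.0]

    @property
    def theta12(self) -> float:
        return self.acrophases_rad[12.0]

    @property
    def theta24(self) -> float:
        return self.acrophases_rad[24.0]

    @property
    def rhythmic_12h(self) -> bool:
        return self.rhythmic[12.0]

    @property
    def rhythmic_24h(self) -> bool:
        return self.rhythmic[24.0]

    @property
    def rhythmic_any(self) -> bool:
        return any(self.rhythmic.values())

    def component_peak_hours(self, period: float) -> float:
        """Clock time (mod period) at which this component alone peaks."""
        theta = self.acrophases_rad[period]
        return float((-theta * period / (2.0 * np.pi)) % period)

    def curve(self, t_hours: np.ndarray) -> np.ndarray:
        """Fitted curve on the reporting (back-transformed) scale."""
        t = np.asarray(t_hours, dtype=float)
        y = np.full_like(t, self.mesor_log)
        for T in self.periods:
            y = y + self.amplitudes[T] * np.cos(
                2.0 * np.pi * t / T + self.acrophases_rad[T]
            )
        return np.exp(y) if self.log_scale else y


def _overall_curve_summary(
    mesor_log: float,
    periods: Sequence[float],
    amplitudes: Mapping[float, float],
    phases: Mapping[float, float],
    log_scale: bool,
    grid_minutes: int = ACROPHASE_GRID_MINUTES,
) -> tuple[float, float, float]:
    """(mesor_reported, overall_amplitude, overall_acrophase_h) from a dense grid."""
    t = np.arange(0.0, 24.0, grid_minutes / 60.0)
    y = np.full_like(t, mesor_log)
    for T in periods:
        y = y + amplitudes[T] * np.cos(2.0 * np.pi * t / T + phases[T])
    curve = np.exp(y) if log_scale else y
    mesor = float(np.exp(mesor_log)) if log_scale else float(mesor_log)
    overall_amp = float((curve.max() - curve.min()) / 2.0)
    acro = float(t[int(np.argmax(curve))])  # argmax returns earliest tie
    return mesor, overall_amp, acro


def _amplitude_pvalue(A: float, se: float, dof: int) -> float:
    """Fallback amplitude p-value from the delta-method t statistic."""
    if not np.isfinite(se) or se == 0.0:
        # exact fit: zero amplitude is certain, nonzero amplitude exact
        return 1.0 if A < 1e-12 else 0.0
    t = A / se
    return float(2.0 * stats.t.sf(abs(t), dof))


def _zero_amplitude_pvalue(
    beta2: np.ndarray, cov2: np.ndarray, dof: int
) -> float:
    """Exact zero-amplitude test for one component.

    The amplitude is zero iff both the cos and sin coefficients vanish, so
    the test of A = 0 is the 2-df Wald/F test on that coefficient pair with
    (2, dof) degrees of freedom.  Unlike a t statistic built on |A| (whose
    phase is unidentified at A = 0), this test is exactly calibrated under
    Gaussian errors.
    """
    A2 = float(beta2 @ beta2)
    if A2 < 1e-24:
        return 1.0
    try:
        F = float(beta2 @ np.linalg.solve(cov2, beta2)) / 2.0
    except np.linalg.LinAlgError:
        return 1.0 if A2 < 1e-12 else 0.0
    if not np.isfinite(F):
        return 0.0
    return float(stats.f.sf(F, 2, dof))


def check_eligibility(
    concentrations: Iterable[float], min_samples: int = MIN_SAMPLES
) -> bool:
    """A patient/nucleoside series is eligible iff it has >= 7 valid samples.

    Valid means finite and strictly positive (a non-positive concentration
    cannot be log-transformed and does not count toward the minimum).
    """
    c = np.asarray(list(concentrations), dtype=float)
    n_valid = int(np.sum(np.isfinite(c) & (c > 0)))
    return n_valid >= min_samples


def fit_multicomponent_cosinor(
    times_hours: np.ndarray,
    concentrations: np.ndarray,
    periods: Sequence[float] = DEFAULT_PERIODS,
    alpha: float = 0.1,
    log_scale: bool = True,
    min_samples: int = MIN_SAMPLES,
    require_span_hours: float = 24.0,
) -> CosinorFit:
    """Fit the fixed-period cosinor model to timed concentrations.

    Parameters
    ----------
    times_hours:
        Sample times in hours; day-2 samples are simply offset by 24 h (the
        model is 24-h periodic so replicate clock times on consecutive days
        act as replicates).
    concentrations:
        Strictly positive values (micrograms per gram creatinine for urinary
        nucleosides).
    periods:
        Fixed component periods in hours, default (12, 24).
    alpha:
        Per-component significance level for rhythm detection.
    log_scale:
        Fit on natural-log concentrations (default) and back-transform for
        reporting.  Set False for series already on an additive scale
        (e.g. activity counts).
    """
    t = np.asarray(times_hours, dtype=float)
    y_raw = np.asarray(concentrations, dtype=float)
    if t.shape != y_raw.shape or t.ndim != 1:
        raise ParameterError("times and concentrations must be equal-length 1-D arrays")
    ok = np.isfinite(t) & np.isfinite(y_raw)
    if log_scale:
        bad = ok & (y_raw <= 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParameterError(
                f"non-positive concentration {y_raw[i]!r} at sample index {i}; "
                "log-scale cosinor requires strictly positive values"
            )
    t, y_raw = t[ok], y_raw[ok]
    if t.size < min_samples:
        raise EligibilityError(
            f"{t.size} valid timed samples; at least {min_samples} required"
        )
    if np.ptp(t) < require_span_hours - 1e-9:
        raise InsufficientSpan(
            f"sample times span {np.ptp(t):.1f} h; >= {require_span_hours:g} h required"
        )

    y = np.log(y_raw) if log_scale else y_raw
    beta, cov, sigma2, dof, resid = fit_harmonic(t, y, periods)

    amplitudes: dict[float, float] = {}
    phases: dict[float, float] = {}
    amp_se: dict[float, float] = {}
    amp_p: dict[float, float] = {}
    # residual variance at roundoff level means the model fits exactly;
    # any amplitude is then certain rather than tested
    scale = max(1.0, float(y @ y) / y.size)
    exact_fit = sigma2 <= 1e-20 * scale
    amp_tol = 1e-9 * max(1.0, abs(float(beta[0])))
    for k, T in enumerate(periods):
        i = 1 + 2 * k
        A, theta = _amp_phase_from_beta(beta[i], beta[i + 1])
        se = _amp_se(beta[i], beta[i + 1], cov[i : i + 2, i : i + 2])
        amplitudes[T] = A
        phases[T] = theta
        amp_se[T] = se
        if exact_fit:
            amp_p[T] = 1.0 if A <= amp_tol else 0.0
        else:
            amp_p[T] = _zero_amplitude_pvalue(
                beta[i : i + 2], cov[i : i + 2, i : i + 2], dof
            )

    mesor, overall_amp, acro = _overall_curve_summary(
        beta[0], periods, amplitudes, phases, log_scale
    )
    rel = overall_amp / mesor if mesor != 0 else np.nan
    rhythmic = {T: bool(amp_p[T] <= alpha) for T in periods}

    return CosinorFit(
        periods=tuple(float(T) for T in periods),
        mesor_log=float(beta[0]),
        amplitudes=amplitudes,
        acrophases_rad=phases,
        amp_se=amp_se,
        amp_p=amp_p,
        dof=dof,
        n_samples=int(t.size),
        sigma2=sigma2,
        times=t,
        residuals=resid,
        fitted=y - resid,
        log_scale=log_scale,
        mesor=mesor,
        overall_amplitude=overall_amp,
        relative_amplitude=float(rel),
        overall_acrophase_h=acro,
        rhythmic=rhythmic,
        alpha=alpha,
    )


class InsufficientSpan(EligibilityError):
    """Sample times do not span a full circadian cycle."""


def detect_rhythm(fit: CosinorFit, alpha: float = 0.1) -> CosinorFit:
    """Re-evaluate the per-component rhythm flags at a new significance level.

    A component is rhythmic when its amplitude t-test p-value (df = n - 5)
    is <= alpha; the series is rhythmic when any component is.
    """
    if not all(np.isfinite(se) for se in fit.amp_se.values()):
        raise ParameterError("fit has no finite amplitude standard errors")
    if not (0.0 <= alpha <= 1.0):
        raise ParameterError(f"alpha must lie in [0, 1], got {alpha}")
    rhythmic = {T: bool(fit.amp_p[T] <= alpha) for T in fit.periods}
    return dataclasses.replace(fit, rhythmic=rhythmic, alpha=alpha)


def bootstrap_refit(
    fit: CosinorFit,
    n_trials: int,
    rng: np.random.Generator,
    grid_minutes: int = 5,
) -> pd.DataFrame:
    """Residual-bootstrap refits of a cosinor fit, vectorised over trials.

    Each trial resamples the fit's own residuals with replacement, rebuilds
    the response around the fitted values, re-solves the (linear) cosinor
    model and recomputes the derived reporting parameters on a ``grid_minutes``
    clock grid.  Returns one row per trial with columns ``mesor``,
    ``overall_amplitude``, ``relative_amplitude``, ``overall_acrophase_h``.
    """
    X = harmonic_design(fit.times, fit.periods)
    pinv = np.linalg.pinv(X)
    idx = rng.integers(0, fit.n_samples, size=(n_trials, fit.n_samples))
    y_star = fit.fitted[None, :] + fit.residuals[idx]
    betas = y_star @ pinv.T  # (n_trials, p)

    t_grid = np.arange(0.0, 24.0, grid_minutes / 60.0)
    G = harmonic_design(t_grid, fit.periods)  # (n_grid, p)
    curves = betas @ G.T
    if fit.log_scale:
        curves = np.exp(curves)
        mesor = np.exp(betas[:, 0])
    else:
        mesor = betas[:, 0]
    amp = (curves.max(axis=1) - curves.min(axis=1)) / 2.0
    acro = t_grid[np.argmax(curves, axis=1)]
    return pd.DataFrame(
        {
            "mesor": mesor,
            "overall_amplitude": amp,
            "relative_amplitude": amp / mesor,
            "overall_acrophase_h": acro,
        }
    )


# ---------------------------------------------------------------------------
# circular statistics on clock times (hours on [0, 24))
# ---------------------------------------------------------------------------

def _to_angles(hours: np.ndarray) -> np.ndarray:
    return np.asarray(hours, dtype=float) * (2.0 * np.pi / 24.0)


def circular_mean_hours(hours: Iterable[float], weights=None) -> float:
    """(Weighted) circular mean of clock times, in hours on [0, 24)."""
    h = np.asarray(list(hours), dtype=float)
    a = _to_angles(h)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    if np.hypot(s, c) < 1e-12 * max(1.0, np.abs(w).sum()):
        return float("nan")
    out = float((np.arctan2(s, c) * 24.0 / (2.0 * np.pi)) % 24.0)
    return 0.0 if out >= 24.0 else out


def _circ_dist_hours(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % 24.0
    return np.minimum(d, 24.0 - d)


def circular_median_hours(hours: Iterable[float], grid_minutes: int = 1) -> float:
    """Circular median clock time: minimiser of summed circular distances.

    Evaluated on a fine clock grid; when the minimiser is a whole arc (as for
    two antipode-free points, e.g. {23:00, 01:00}), the midpoint of that arc
    is returned (00:00 in the example), which matches the intuitive notion of
    a central time.
    """
    h = np.asarray(list(hours), dtype=float) % 24.0
    if h.size == 0:
        return float("nan")
    if h.size == 1:
        return float(h[0])
    grid = np.arange(0.0, 24.0, grid_minutes / 60.0)
    cost = _circ_dist_hours(grid[:, None], h[None, :]).sum(axis=1)
    tol = 1e-9 * max(1.0, float(cost.min()))
    argmin = cost <= cost.min() + tol
    if argmin.all():
        return circular_mean_hours(h)
    # midpoint of the (possibly wrapped) arc of minimisers
    idx = np.flatnonzero(argmin)
    if argmin[0] and argmin[-1]:
        # arc wraps midnight: rotate so it is contiguous
        breaks = np.flatnonzero(~argmin)
        start = breaks[-1] + 1
        end = breaks[0] - 1
        lo, hi = grid[start], grid[end] + 24.0
    else:
        lo, hi = grid[idx[0]], grid[idx[-1]]
    return float(((lo + hi) / 2.0) % 24.0)


def circular_quantile_hours(hours: Iterable[float], q: float | np.ndarray):
    """Quantiles of clock times computed after centring at the circular median."""
    h = np.asarray(list(hours), dtype=float) % 24.0
    center = circular_median_hours(h)
    dev = (h - center + 12.0) % 24.0 - 12.0
    return (np.quantile(dev, q) + center) % 24.0


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def _summary_row(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
        "median": float(np.median(values)),
        "q1": float(np.quantile(values, 0.25)),
        "q3": float(np.quantile(values, 0.75)),
    }


def summarize_cohort(fits: Mapping[str, Sequence[CosinorFit]]) -> pd.DataFrame:
    """Cohort rhythm summary per nucleoside.

    For each nucleoside: number of eligible patients, number with a
    significant (12-h or 24-h) rhythm, then mean/range/median/quartiles of
    mesor, overall amplitude and relative amplitude, plus the coefficient of
    variation of the mesor.  Acrophase summaries use circular statistics.
    """
    if not fits:
        raise ParameterError("no cosinor fits supplied")
    rows = []
    for nucleoside, patient_fits in fits.items():
        patient_fits = list(patient_fits)
        if not patient_fits:
            raise ParameterError(f"no fits for nucleoside {nucleoside!r}")
        mesor = np.array([f.mesor for f in patient_fits])
        amp = np.array([f.overall_amplitude for f in patient_fits])
        rel = np.array([f.relative_amplitude for f in patient_fits])
        acro = np.array([f.overall_acrophase_h for f in patient_fits])
        row: dict[str, object] = {
            "nucleoside": nucleoside,
            "n_patients": len(patient_fits),
            "n_rhythmic": int(sum(f.rhythmic_any for f in patient_fits)),
        }
        for name, vals in (("mesor", mesor), ("amplitude", amp), ("relative_amplitude", rel)):
            for stat, v in _summary_row(vals).items():
                row[f"{name}_{stat}"] = v
        row["mesor_cv"] = float(np.std(mesor, ddof=1) / np.mean(mesor)) if len(mesor) > 1 else 0.0
        row["acrophase_circmean_h"] = circular_mean_hours(acro)
        row["acrophase_circmedian_h"] = circular_median_hours(acro)
        row["acrophase_q1_h"] = float(circular_quantile_hours(acro, 0.25))
        row["acrophase_q3_h"] = float(circular_quantile_hours(acro, 0.75))
        rows.append(row)
    return pd.DataFrame(rows).set_index("nucleoside")
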