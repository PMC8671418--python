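"""Rest-activity quantification from 1-min wrist-actigraphy series.

A 3-state Gaussian hidden Markov model on log1p-transformed activity counts
segments each recording into inactive/rest (IA), moderately active (MA) and
highly active (HA) states; states are relabelled after fitting so emission
means are increasing (IA lowest).  From the fitted model and its posterior
state probabilities we derive a daily "fingerprint" (state probabilities by
clock time, averaged over days) and the circadian summary indices:

* p1-1 - IA self-transition probability (rest continuity);
* median HA activity;
* rest duration ``a`` - integral of the IA probability profile over 24 h;
* centre of rest ``c`` - circular gravity centre of the IA profile;
* Rhythm Index - (W - a^2/24) / (a - a^2/24) in percent, where W is the IA
  probability mass inside the a-hour window centred at c.  It is 100% for a
  square-wave rest profile with regular bedtimes and 0% for a flat profile
  (no circadian regulation of rest);
* dichotomy index I<O - percentage of in-bed epochs (from the sleep diary)
  with activity below the median out-of-bed activity, pooled over days;
* r24 - autocorrelation of the count series at a 24-h lag;
* dominant period - peak of a smoothed periodogram in a 16-32 h band with a
  day-block resampling confidence interval;
* 24-h cosinor amplitude and acrophase of the raw counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import get_window

from . import cosinor as _cosinor
from .exceptions import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)

__all__ = [
    "ActigraphySeries",
    "HmmModel",
    "StateFingerprint",
    "RestActivityIndices",
    "fit_hmm",
    "fingerprint",
    "hmm_indices",
    "dichotomy_index",
    "autocorr24",
    "dominant_period",
    "activity_cosinor",
    "rest_activity_indices",
]

IA, MA, HA = 0, 1, 2
STATE_NAMES = ("IA", "MA", "HA")
MINUTES_PER_DAY = 1440


@dataclass
class ActigraphySeries:
    """Uniformly spaced activity counts with optional diary bed intervals.

    ``counts[i]`` covers the half-open epoch [start + i*epoch, start + (i+1)*epoch).
    ``diary`` holds absolute (in-bed, out-of-bed) timestamp pairs, one per
    recorded night; intervals may wrap midnight.
    """

    start: pd.Timestamp
    counts: np.ndarray
    epoch_minutes: int = 1
    diary: list[tuple[pd.Timestamp, pd.Timestamp]] | None = None

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ParameterError("counts must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.counts)):
            raise ParameterError("counts must be finite")
        if (self.counts < 0).any():
            i = int(np.flatnonzero(self.counts < 0)[0])
            raise ParameterError(f"negative activity count at epoch {i}")
        if self.epoch_minutes < 1:
            raise ParameterError("epoch_minutes must be a positive integer")

    @property
    def n_epochs(self) -> int:
        return self.counts.size

    @property
    def duration_hours(self) -> float:
        return self.n_epochs * self.epoch_minutes / 60.0

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start, periods=self.n_epochs, freq=f"{self.epoch_minutes}min"
        )

    @property
    def minute_of_day(self) -> np.ndarray:
        start_min = self.start.hour * 60 + self.start.minute
        return (start_min + np.arange(self.n_epochs) * self.epoch_minutes) % MINUTES_PER_DAY

    def in_bed_mask(self) -> np.ndarray:
        """Boolean mask of epochs whose start falls inside a diary bed interval."""
        if not self.diary:
            raise ParameterError("series has no diary bed intervals")
        ts = self.timestamps
        mask = np.zeros(self.n_epochs, dtype=bool)
        for bed_start, bed_end in self.diary:
            mask |= (ts >= pd.Timestamp(bed_start)) & (ts < pd.Timestamp(bed_end))
        return mask


@dataclass
class HmmModel:
    """Fitted 3-state Gaussian HMM on log1p counts, states ordered IA < MA < HA."""

    means: np.ndarray  # (3,) emission means on log1p scale
    sds: np.ndarray  # (3,) emission SDs
    transmat: np.ndarray  # (3, 3) row-stochastic
    startprob: np.ndarray
    log_likelihood: float
    converged: bool
    n_restarts: int
    _backend: object = field(repr=False, default=None)

    @property
    def p11(self) -> float:
        """IA self-transition probability (the rest-continuity scalar p1-1)."""
        return float(self.transmat[IA, IA])

    def decode(self, series: ActigraphySeries) -> np.ndarray:
        """Viterbi most-likely state sequence (0=IA, 1=MA, 2=HA)."""
        x = np.log1p(series.counts).reshape(-1, 1)
        return self._backend.predict(x)

    def posteriors(self, series: ActigraphySeries) -> np.ndarray:
        """Forward-backward posterior state probabilities, shape (n, 3)."""
        x = np.log1p(series.counts).reshape(-1, 1)
        return self._backend.predict_proba(x)


def fit_hmm(
    series: ActigraphySeries,
    n_restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-4,
    min_variance: float = 0.01,
) -> HmmModel:
    """Baum-Welch maximum-likelihood fit of the 3-state HMM.

    Counts are log1p-transformed; ``n_restarts`` independent EM runs (each
    with its own deterministic initialisation stream derived from ``seed``)
    are fitted and the best log-likelihood kept.  States are relabelled so
    emission means are increasing.  Non-convergence of the winning run is
    reported through ``HmmModel.converged`` (with a warning), never silently.

    ``min_variance`` floors the per-state emission variance on the log1p
    scale: integer counts place a point mass at exactly zero during rest,
    and without a floor EM can collapse one state onto that spike instead of
    separating the moderate and high activity levels.
    """
    from hmmlearn.hmm import GaussianHMM

    if series.duration_hours < 24.0:
        raise InsufficientDataError(
            f"recording spans {series.duration_hours:.1f} h; >= 24 h required"
        )
    x = np.log1p(series.counts).reshape(-1, 1)
    if np.ptp(x) < 1e-12 or np.unique(x).size < 3:
        raise DegenerateDataError(
            "activity series has fewer than 3 distinct levels; "
            "a 3-state model is not identifiable"
        )
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")

    best = None
    best_ll = -np.inf
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    base_means = np.quantile(x, [0.1, 0.5, 0.9])
    spread = max(np.ptp(base_means), 1.0)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        rs = np.random.RandomState(child.generate_state(1)[0] % (2**32 - 1))
        model = GaussianHMM(
            n_components=3,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            random_state=rs,
            min_covar=min_variance,
            init_params="stc",  # means initialised at count quantiles below
        )
        jitter = 0.0 if r == 0 else rng.normal(0.0, 0.08 * spread, size=3)
        model.means_ = (base_means + jitter).reshape(3, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(x)
            except Exception:
                continue
            ll = float(model.score(x))
        if ll > best_ll:
            best, best_ll = model, ll
    if best is None:
        raise DegenerateDataError("EM failed on every restart")

    order = np.argsort(best.means_.ravel())
    variances = np.maximum(best.covars_.reshape(3), min_variance)[order]
    relabelled = GaussianHMM(n_components=3, covariance_type="diag", min_covar=min_variance)
    relabelled.n_features = 1
    relabelled.startprob_ = best.startprob_[order]
    relabelled.transmat_ = best.transmat_[np.ix_(order, order)]
    relabelled.means_ = best.means_[order]
    relabelled.covars_ = variances.reshape(3, 1)
    converged = bool(best.monitor_.converged)
    if not converged:
        warnings.warn(
            "EM did not converge within the iteration limit; "
            "result flagged via HmmModel.converged=False",
            stacklevel=2,
        )
    return HmmModel(
        means=relabelled.means_.ravel().copy(),
        sds=np.sqrt(variances),
        transmat=relabelled.transmat_.copy(),
        startprob=relabelled.startprob_.copy(),
        log_likelihood=best_ll,
        converged=converged,
        n_restarts=n_restarts,
        _backend=relabelled,
    )


@dataclass
class StateFingerprint:
    """Posterior state probabilities by clock-time bin, averaged over days."""

    clock_hours: np.ndarray  # bin centres, hours on [0, 24)
    probs: np.ndarray  # (n_bins, 3), rows sum to 1
    bin_minutes: int

    @property
    def p_ia(self) -> np.ndarray:
        return self.probs[:, IA]


def fingerprint(
    series: ActigraphySeries, model: HmmModel, bin_minutes: int = 10
) -> StateFingerprint:
    """Average forward-backward posteriors into clock-time bins over all days."""
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ParameterError("bin_minutes must divide 1440")
    post = model.posteriors(series)
    bins = series.minute_of_day // bin_minutes
    n_bins = MINUTES_PER_DAY // bin_minutes
    probs = np.zeros((n_bins, 3))
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    for s in range(3):
        probs[:, s] = np.bincount(bins, weights=post[:, s], minlength=n_bins)
    present = counts > 0
    probs[present] /= counts[present, None]
    probs[~present] = np.nan
    centres = (np.arange(n_bins) + 0.5) * bin_minutes / 60.0
    return StateFingerprint(clock_hours=centres, probs=probs, bin_minutes=bin_minutes)


def _window_overlap_hours(
    bin_start: float, bin_end: float, win_start: float, win_len: float
) -> float:
    """Overlap (hours) of clock bin [bin_start, bin_end) with the wrapped
    window [win_start, win_start + win_len) on the 24-h circle."""
    if win_len <= 0:
        return 0.0
    if win_len >= 24.0:
        return bin_end - bin_start
    # shift so the window starts at 0
    b0 = (bin_start - win_start) % 24.0
    b1 = b0 + (bin_end - bin_start)
    total = 0.0
    # the shifted bin may extend past 24; fold the excess back
    for lo, hi in ((b0, min(b1, 24.0)), (0.0, max(b1 - 24.0, 0.0))):
        total += max(0.0, min(hi, win_len) - max(lo, 0.0))
    return total


@dataclass
class RestActivityIndices:
    """Container for all per-patient rest-activity summary indices."""

    i_lt_o: float | None = None  # % in [0, 100]
    r24: float | None = None
    p11: float | None = None
    median_ha: float | None = None
    rest_duration_a: float | None = None  # hours
    center_of_rest_c: float | None = None  # clock hours
    rhythm_index: float | None = None  # % in [0, 100]
    dominant_period: float | None = None  # hours
    dominant_period_ci: tuple[float, float] | None = None
    activity_amplitude: float | None = None  # counts
    activity_acrophase: float | None = None  # clock hours

    def as_dict(self) -> dict[str, float | None]:
        d = {
            k: getattr(self, k)
            for k in (
                "i_lt_o",
                "r24",
                "p11",
                "median_ha",
                "rest_duration_a",
                "center_of_rest_c",
                "rhythm_index",
                "dominant_period",
                "activity_amplitude",
                "activity_acrophase",
            )
        }
        if self.dominant_period_ci is not None:
            d["dominant_period_ci_low"] = self.dominant_period_ci[0]
            d["dominant_period_ci_high"] = self.dominant_period_ci[1]
        return d


def hmm_indices(
    fp: StateFingerprint,
    model: HmmModel | None = None,
    series: ActigraphySeries | None = None,
) -> RestActivityIndices:
    """HMM-derived indices from a state fingerprint.

    rest_duration_a integrates the IA probability profile over 24 h;
    center_of_rest_c is the circular mean clock time weighted by IA
    probability; the Rhythm Index is (W - a^2/24)/(a - a^2/24) in percent,
    clipped to [0, 100], with W the IA mass in the a-hour window centred at
    c.  It is undefined (None) when a is 0 or 24.  p11 and the median HA
    activity require ``model`` (and ``series`` for the Viterbi decode).
    """
    p_ia = fp.p_ia
    if np.isnan(p_ia).any():
        valid = ~np.isnan(p_ia)
        mean_ia = float(np.mean(p_ia[valid]))
    else:
        valid = np.ones_like(p_ia, dtype=bool)
        mean_ia = float(np.mean(p_ia))
    a = mean_ia * 24.0
    dt = fp.bin_minutes / 60.0

    if np.sum(p_ia[valid]) > 1e-12:
        c = _cosinor.circular_mean_hours(fp.clock_hours[valid], weights=p_ia[valid])
    else:
        c = float("nan")

    if a <= 1e-9 or a >= 24.0 - 1e-9:
        ri = None
    elif not np.isfinite(c):
        # IA profile has no preferred clock direction (flat): by the limit
        # law this is the absence of circadian rest regulation
        ri = 0.0
    else:
        win_start = (c - a / 2.0) % 24.0
        W = 0.0
        for i in np.flatnonzero(valid):
            b0 = fp.clock_hours[i] - dt / 2.0
            W += p_ia[i] * _window_overlap_hours(b0, b0 + dt, win_start, a) / dt
        # W is in probability-hours
        uniform = a * a / 24.0
        ri = float(np.clip((W - uniform) / (a - uniform), 0.0, 1.0) * 100.0)

    p11 = model.p11 if model is not None else None
    median_ha = None
    if model is not None and series is not None:
        states = model.decode(series)
        ha_counts = series.counts[states == HA]
        median_ha = float(np.median(ha_counts)) if ha_counts.size else float("nan")

    return RestActivityIndices(
        p11=p11,
        median_ha=median_ha,
        rest_duration_a=float(a),
        center_of_rest_c=float(c) if np.isfinite(c) else None,
        rhythm_index=ri,
    )


def dichotomy_index(series: ActigraphySeries) -> float:
    """Dichotomy index I<O in percent, pooled over the whole recording.

    100 * #{in-bed epochs with count < median(out-of-bed counts)} /
    #{in-bed epochs}.  The comparison is strict, and the out-of-bed median is
    computed once over all recorded days.  Because only the ordering of
    counts matters, I<O is invariant to any strictly monotone transform of
    the counts.
    """
    mask = series.in_bed_mask()
    n_in = int(mask.sum())
    n_out = int((~mask).sum())
    if n_in == 0:
        raise InsufficientDataError("no in-bed epochs in the diary intervals")
    if n_out == 0:
        raise InsufficientDataError("no out-of-bed epochs")
    median_out = float(np.median(series.counts[~mask]))
    return float(100.0 * np.mean(series.counts[mask] < median_out))


def autocorr24(series: ActigraphySeries) -> float:
    """Pearson autocorrelation of the counts at a 24-h lag (overlapping pairs).

    Returns NaN for a constant series (undefined).  Requires >= 48 h of data.
    """
    if series.duration_hours < 48.0:
        raise InsufficientDataError(
            f"recording spans {series.duration_hours:.1f} h; >= 48 h required for r24"
        )
    lag = MINUTES_PER_DAY // series.epoch_minutes
    x0 = series.counts[:-lag]
    x1 = series.counts[lag:]
    if np.std(x0) < 1e-12 or np.std(x1) < 1e-12:
        return float("nan")
    x0c = x0 - x0.mean()
    x1c = x1 - x1.mean()
    return float(x0c @ x1c / np.sqrt((x0c @ x0c) * (x1c @ x1c)))


@dataclass(frozen=True)
class DominantPeriod:
    period_hours: float
    ci_low: float
    ci_high: float
    n_resamples: int

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low


def _peak_period_hours(
    counts: np.ndarray,
    epoch_minutes: int,
    band: tuple[float, float],
    pad_factor: int = 32,
    smooth_bins: int = 3,
) -> float:
    x = counts - counts.mean()
    n = x.size
    w = get_window("hann", n)
    nfft = int(2 ** np.ceil(np.log2(n * pad_factor)))
    power = np.abs(np.fft.rfft(x * w, nfft)) ** 2
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        power = np.convolve(power, kernel, mode="same")
    freqs = np.fft.rfftfreq(nfft, d=epoch_minutes)  # cycles per minute
    with np.errstate(divide="ignore"):
        periods_h = np.where(freqs > 0, 1.0 / (freqs * 60.0), np.inf)
    in_band = (periods_h >= band[0]) & (periods_h <= band[1])
    if not in_band.any():
        raise ParameterError(
            f"no periodogram frequencies inside the {band[0]}-{band[1]} h band"
        )
    idx = np.flatnonzero(in_band)
    i = idx[int(np.argmax(power[idx]))]
    # parabolic interpolation on the frequency grid for sub-bin precision
    if 0 < i < power.size - 1:
        y0, y1, y2 = power[i - 1], power[i], power[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            f = freqs[i] + delta * (freqs[1] - freqs[0])
            if f > 0:
                return float(np.clip(1.0 / (f * 60.0), band[0], band[1]))
    return float(periods_h[i])


def dominant_period(
    series: ActigraphySeries,
    n_resamples: int = 100,
    seed: int | None = None,
    band: tuple[float, float] = (16.0, 32.0),
) -> DominantPeriod:
    """Dominant rest-activity period via a smoothed periodogram peak.

    The point estimate is the peak of a Hann-windowed, lightly smoothed,
    zero-padded periodogram in the 16-32 h search band (parabolic
    interpolation for sub-grid precision).  The confidence interval comes
    from resampling whole recording days with replacement ``n_resamples``
    times and taking the 2.5th/97.5th percentiles of the resampled peaks.
    """
    if band[0] >= band[1] or band[0] <= 0:
        raise ParameterError(f"invalid search band {band}")
    epd = MINUTES_PER_DAY // series.epoch_minutes
    n_days = series.n_epochs // epd
    if n_days < 3:
        raise InsufficientDataError(
            f"{n_days} complete days recorded; >= 3 required for period estimation"
        )
    point = _peak_period_hours(series.counts, series.epoch_minutes, band)
    rng = np.random.default_rng(seed)
    blocks = series.counts[: n_days * epd].reshape(n_days, epd)
    estimates = np.empty(n_resamples)
    for b in range(n_resamples):
        pick = rng.integers(0, n_days, size=n_days)
        resampled = blocks[pick].ravel()
        estimates[b] = _peak_period_hours(resampled, series.epoch_minutes, band)
    lo, hi = np.quantile(estimates, [0.025, 0.975])
    return DominantPeriod(
        period_hours=point, ci_low=float(lo), ci_high=float(hi), n_resamples=n_resamples
    )


@dataclass(frozen=True)
class ActivityCosinor:
    amplitude: float  # counts
    acrophase_hours: float  # clock time of the fitted 24-h peak
    mesor: float
    p_value: float


def activity_cosinor(series: ActigraphySeries) -> ActivityCosinor:
    """Single-component 24-h cosinor of the raw counts (linear scale)."""
    # hours since the midnight preceding the recording start, so the phase is
    # referenced to clock time
    start_min = series.start.hour * 60 + series.start.minute
    t_hours = (start_min + np.arange(series.n_epochs) * series.epoch_minutes) / 60.0
    beta, cov, _, dof, _ = _cosinor.fit_harmonic(t_hours, series.counts, periods=(24.0,))
    A = float(np.hypot(beta[1], beta[2]))
    theta = float(np.arctan2(-beta[2], beta[1]))
    se = _cosinor._amp_se(beta[1], beta[2], cov[1:3, 1:3])
    p = _cosinor._amplitude_pvalue(A, se, dof)
    acro = float((-theta * 24.0 / (2.0 * np.pi)) % 24.0)
    if A < 1e-12:
        acro = 0.0
    return ActivityCosinor(amplitude=A, acrophase_hours=acro, mesor=float(beta[0]), p_value=p)


def rest_activity_indices(
    series: ActigraphySeries,
    n_restarts: int = 10,
    seed: int | None = None,
    n_resamples: int = 100,
    bin_minutes: int = 10,
) -> RestActivityIndices:
    """Compute the full per-patient index set (HMM + diary + spectral)."""
    model = fit_hmm(series, n_restarts=n_restarts, seed=seed)
    fp = fingerprint(series, model, bin_minutes=bin_minutes)
    out = hmm_indices(fp, model, series)
    out.i_lt_o = dichotomy_index(series) if series.diary else None
    out.r24 = autocorr24(series) if series.duration_hours >= 48 else None
    if series.n_epochs // (MINUTES_PER_DAY // series.epoch_minutes) >= 3:
        dp = dominant_period(series, n_resamples=n_resamples, seed=seed)
        out.dominant_period = dp.period_hours
        out.dominant_period_ci = (dp.ci_low, dp.ci_high)
    ac = activity_cosinor(series)
    out.activity_amplitude = ac.amplitude
    out.activity_acrophase = ac.acrophase_hours
    return out
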