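"""Correlation and regression machinery linking rhythm parameters to
rest-activity indices and patient covariates.

Three tools:

* Spearman rank correlations between any pair of per-patient parameters,
  with pairwise deletion of missing values and the significance tiers used
  in correlation-grid displays (p <= 0.05 significant, 0.05 < p <= 0.1
  trend, p > 0.1 not significant).
* A residual-bootstrap uncertainty check: each patient's cosinor residuals
  are resampled with replacement (within patient), the cosinor model is
  refitted, the derived parameter recomputed, and the Spearman p-value
  re-evaluated across patients; a correlation survives the check only if the
  90th percentile of the bootstrap p-values is <= 0.1.  This is deliberately
  more conservative than the plain test.
* Bidirectional stepwise OLS model selection by AIC over patient covariates,
  and a two-sample (Welch) t-test helper for group contrasts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import CosinorFit, bootstrap_refit
from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError

__all__ = [
    "CorrelationResult",
    "spearman",
    "spearman_matrix",
    "bootstrap_correlation_check",
    "stepwise_covariate_model",
    "group_comparison",
    "significance_tier",
    "grid_class",
]

_EXACT_PERM_MAX_N = 9  # exact permutation p-value below this sample size


def significance_tier(p: float) -> str:
    """Star codes matching the usual correlation-diagram legend."""
    if not np.isfinite(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    if p <= 0.1:
        return "^"
    return ""


def grid_class(p: float) -> str:
    """Three-level shading used in the correlation grid output."""
    if not np.isfinite(p):
        return "missing"
    if p <= 0.05:
        return "significant"
    if p <= 0.1:
        return "trend"
    return "ns"


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x)


def _pearson_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom == 0:
        return np.nan
    return float(rxc @ ryc / denom)


def _spearman_p_t(rho: float, n: int) -> float:
    if not np.isfinite(rho) or n < 3:
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _spearman_p_exact(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation two-sided p-value (all n! permutations of one margin)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    count = 0
    total = perms.shape[0]
    chunk = 200_000
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    thresh = abs(rho_obs) - 1e-12
    for start in range(0, total, chunk):
        block = perms[start : start + chunk]
        rhos = (ryc[block] @ rxc) / denom
        count += int(np.sum(np.abs(rhos) >= thresh))
    return count / total


def spearman(x, y, min_pairs: int = 4) -> tuple[float, float, int]:
    """Spearman rho and two-sided p with pairwise deletion.

    Uses the t-approximation for n >= 10 and an exact permutation test for
    smaller samples (where the approximation is poor).  Returns
    (rho, p, n_pairs); rho is NaN when either variable is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < min_pairs:
        raise InsufficientDataError(f"{n} complete pairs; >= {min_pairs} required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan, n
    rx, ry = _rank(x), _rank(y)
    rho = _pearson_of_ranks(rx, ry)
    if n <= _EXACT_PERM_MAX_N:
        p = _spearman_p_exact(rx, ry, rho)
    else:
        p = _spearman_p_t(rho, n)
    return rho, p, n


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    rho: float
    p_value: float
    n: int
    bootstrap_significant: bool | None = None
    bootstrap_p_q90: float | None = None
    n_failed_trials: int = 0

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)

    @property
    def grid_class(self) -> str:
        return grid_class(self.p_value)


def spearman_matrix(table: pd.DataFrame, min_pairs: int = 4) -> pd.DataFrame:
    """All pairwise Spearman correlations of the numeric columns of ``table``.

    Returns a tidy DataFrame (var_x, var_y, rho, p_value, n, tier,
    grid_class), one row per unordered pair.  Pairs with a constant variable
    get NaN rho and the 'missing' grid class; pairs with fewer than
    ``min_pairs`` complete observations raise.
    """
    cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for cx, cy in itertools.combinations(cols, 2):
        rho, p, n = spearman(table[cx], table[cy], min_pairs=min_pairs)
        rows.append(
            {
                "var_x": cx,
                "var_y": cy,
                "rho": rho,
                "p_value": p,
                "n": n,
                "tier": significance_tier(p),
                "grid_class": grid_class(p),
            }
        )
    return pd.DataFrame(rows)


def _vectorised_spearman_p(param_trials: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Spearman p-values of each row of ``param_trials`` against ``x``.

    Uses the t-approximation (the bootstrap check is used at cohort sizes
    around 29 patients, well above the exact-permutation cutoff).
    """
    B, n = param_trials.shape
    rx = _rank(x)
    rxc = rx - rx.mean()
    ry = stats.rankdata(param_trials, axis=1)
    ryc = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * np.sum(ryc * ryc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ryc @ rxc) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[~np.isfinite(rho)] = np.nan
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def bootstrap_correlation_check(
    fits: Mapping[str, CosinorFit],
    covariates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.1,
    quantile: float = 0.9,
) -> list[CorrelationResult]:
    """Residual-bootstrap uncertainty check of Spearman correlations.

    Parameters
    ----------
    fits:
        Per-patient cosinor fits for one nucleoside, keyed by patient id.
    covariates:
        Per-patient table (indexed by patient id) holding the non-bootstrap
        member of each pair (e.g. rest-activity indices).
    pairs:
        (derived_parameter, covariate_column) pairs, where the derived
        parameter is one of mesor / overall_amplitude / relative_amplitude /
        overall_acrophase_h, recomputed from each bootstrap refit.
    B:
        Number of bootstrap trials (default 1000).  For each trial every
        patient's residuals are resampled with replacement, the cosinor model
        refitted, the derived parameter recomputed, and the cross-patient
        Spearman p-value re-evaluated.
    quantile / alpha:
        The correlation is flagged bootstrap-significant iff the ``quantile``
        (default 90th percentile) of the B bootstrap p-values is <= ``alpha``.
    """
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap trials is below the intended minimum of 100; "
            "the quantile criterion will be noisy",
            stacklevel=2,
        )
    pids = [pid for pid in covariates.index if pid in fits]
    if len(pids) < 4:
        raise InsufficientDataError(
            f"{len(pids)} patients with both a fit and covariates; >= 4 required"
        )
    rng = np.random.default_rng(seed)
    # one resampled-parameter table per patient, shared across all pairs
    trials: dict[str, pd.DataFrame] = {}
    for pid in pids:
        trials[pid] = bootstrap_refit(fits[pid], B, rng)

    results = []
    for param, covar in pairs:
        if covar not in covariates.columns:
            raise ParameterError(f"covariate {covar!r} not in the patient table")
        x = covariates.loc[pids, covar].to_numpy(dtype=float)
        observed = np.array([getattr(fits[pid], _PARAM_ATTR[param]) for pid in pids])
        rho, p, n = spearman(x, observed)
        param_trials = np.column_stack([trials[pid][param].to_numpy() for pid in pids])
        p_boot = _vectorised_spearman_p(param_trials, x)
        failed = int(np.sum(~np.isfinite(p_boot)))
        p_ok = p_boot[np.isfinite(p_boot)]
        if p_ok.size == 0:
            q90 = np.nan
            significant = False
        else:
            q90 = float(np.quantile(p_ok, quantile))
            significant = bool(q90 <= alpha)
        results.append(
            CorrelationResult(
                var_x=param,
                var_y=covar,
                rho=rho,
                p_value=p,
                n=n,
                bootstrap_significant=significant,
                bootstrap_p_q90=q90,
                n_failed_trials=failed,
            )
        )
    return results


_PARAM_ATTR = {
    "mesor": "mesor",
    "overall_amplitude": "overall_amplitude",
    "relative_amplitude": "relative_amplitude",
    "overall_acrophase_h": "overall_acrophase_h",
}


# ---------------------------------------------------------------------------
# stepwise AIC covariate selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    response: str
    selected_terms: tuple[str, ...]
    aic: float
    aic_full: float
    params: pd.Series
    pvalues: pd.Series
    model_result: object  # statsmodels RegressionResults


def _design_for_terms(data: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["Intercept"] = 1.0
    for term in terms:
        col = data[term]
        if pd.api.types.is_numeric_dtype(col) and not isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            X[term] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=term, drop_first=True, dtype=float)
            for c in dummies.columns:
                X[c] = dummies[c]
    return X


def _check_full_rank(data: pd.DataFrame, covariates: Sequence[str], response: str) -> None:
    X = _design_for_terms(data, covariates)
    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(M, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(M.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[piv[i]] for i in range(len(diag), M.shape[1])]
        raise DegenerateDataError(
            "rank-deficient covariate design; aliased columns: " + ", ".join(sorted(aliased))
        )


def stepwise_covariate_model(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
) -> StepwiseResult:
    """Bidirectional stepwise OLS selection by AIC, starting from the full model.

    At each step every single-term deletion and addition is scored; the move
    with the lowest AIC is taken if it improves on the current model, until
    no move improves.  Because the search starts at the full main-effects
    model and only accepts improvements, the selected AIC never exceeds the
    full model's.  Categorical covariates enter/leave as whole terms.
    """
    import statsmodels.api as sm

    if response not in data.columns:
        raise ParameterError(f"response {response!r} not in data")
    missing = [c for c in covariates if c not in data.columns]
    if missing:
        raise ParameterError(f"covariates not in data: {missing}")
    data = data.dropna(subset=[response, *covariates])
    n = len(data)
    if n <= len(covariates) + 2:
        raise InsufficientDataError(
            f"n={n} rows with complete data; need > {len(covariates) + 2}"
        )
    _check_full_rank(data, covariates, response)

    y = data[response].astype(float)
    cache: dict[frozenset, tuple[float, object]] = {}

    def fit_terms(terms: frozenset):
        if terms not in cache:
            X = _design_for_terms(data, sorted(terms))
            res = sm.OLS(y, X).fit()
            cache[terms] = (float(res.aic), res)
        return cache[terms]

    current = frozenset(covariates)
    aic_full, _ = fit_terms(current)
    current_aic, current_res = fit_terms(current)
    while True:
        moves = []
        for term in sorted(current):
            cand = current - {term}
            moves.append((fit_terms(cand)[0], 0, term, cand))  # prefer drops on ties
        for term in sorted(set(covariates) - current):
            cand = current | {term}
            moves.append((fit_terms(cand)[0], 1, term, cand))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, _, _, best_set = moves[0]
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_set, best_aic
            current_res = fit_terms(current)[1]
        else:
            break

    return StepwiseResult(
        response=response,
        selected_terms=tuple(sorted(current)),
        aic=current_aic,
        aic_full=aic_full,
        params=current_res.params,
        pvalues=current_res.pvalues,
        model_result=current_res,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float


def group_comparison(
    values,
    grouping,
    equal_var: bool = False,
    log_transform: bool = False,
) -> GroupComparison:
    """Two-sample t-test (Welch by default) of ``values`` between two groups.

    Group labels are ordered alphabetically as (a, b) and the statistic is
    computed for a - b, so swapping the labels negates t and leaves p
    unchanged.  Identical groups give t = 0, p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(grouping)
    ok = np.isfinite(v)
    v, g = v[ok], g[ok]
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ParameterError(f"grouping must have exactly 2 levels, got {labels}")
    a, b = (v[g == labels[0]], v[g == labels[1]])
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"both groups need n >= 2 (got {len(a)} and {len(b)})"
        )
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ParameterError("log transform requires strictly positive values")
        a, b = np.log(a), np.log(b)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p) and np.array_equal(np.sort(a), np.sort(b)):
        t, p = 0.0, 1.0
    return GroupComparison(
        group_a=str(labels[0]),
        group_b=str(labels[1]),
        n_a=len(a),
        n_b=len(b),
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        t_statistic=float(t),
        p_value=float(p),
    )
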