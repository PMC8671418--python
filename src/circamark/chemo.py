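"""Chemotherapy-response classification for daily urinary nucleoside series.

A treatment course contributes: (i) daily overnight excretions around the
course (a few days before, ~two weeks after), classified as an increasing,
decreasing or unchanged trend by OLS regression of log excretion on day;
(ii) plasma CEA (carcinoembryonic antigen) values, categorised by whether the
1-2-month follow-up changed by more than 50% relative to baseline; and
(iii) survival in months.  Trend and CEA categories are cross-tabulated in a
2x3 contingency table and tested for independence with the Freeman-Halton
generalisation of Fisher's exact test; survival is compared between trend and
no-trend patients with a two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, InsufficientDataError, ParameterError

__all__ = [
    "TreatmentCourse",
    "TrendResult",
    "classify_trend",
    "classify_cea_change",
    "fisher_exact_rxc",
    "trend_cea_association",
    "survival_by_trend",
    "TREND_NUCLEOSIDES",
    "CEA_CATEGORIES",
]

#: nucleosides whose post-course dynamics define a patient's trend status
TREND_NUCLEOSIDES: tuple[str, ...] = (
    "1-methylguanosine",
    "4-acetylcytidine",
    "adenosine",
    "cytidine",
)

CEA_CATEGORIES: tuple[str, ...] = ("decrease", "no_change", "increase")
TREND_CATEGORIES: tuple[str, ...] = ("decrease", "no_change", "increase")


@dataclass
class TreatmentCourse:
    """Per-patient data around one chemotherapy course.

    ``excretions`` has columns day (integer offset from course start; pre-course
    days are negative), nucleoside, concentration (ug/g creatinine).
    ``cea_days``/``cea_values`` hold plasma CEA (mg/L) at day offsets from the
    course start; the baseline is the last value at day <= 0.
    """

    patient_id: str
    excretions: pd.DataFrame
    cea_days: np.ndarray = field(default_factory=lambda: np.array([]))
    cea_values: np.ndarray = field(default_factory=lambda: np.array([]))
    survival_months: float | None = None
    toxicity_grade: int | None = None


@dataclass(frozen=True)
class TrendResult:
    slope: float  # per day, log scale
    p_value: float
    category: str  # increase / decrease / no_change

    @property
    def has_trend(self) -> bool:
        return self.category != "no_change"


def classify_trend(
    days: Sequence[float],
    excretions: Sequence[float],
    alpha: float = 0.05,
    min_points: int = 5,
) -> TrendResult:
    """OLS regression of log excretion on day; trend iff slope p <= alpha.

    The log scale makes the category invariant to rescaling the assay
    (multiplying all excretions by a constant).
    """
    d = np.asarray(days, dtype=float)
    y = np.asarray(excretions, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y) & (y > 0)
    d, y = d[ok], y[ok]
    if d.size < min_points:
        raise InsufficientDataError(
            f"{d.size} usable daily excretion points; >= {min_points} required"
        )
    if np.ptp(d) == 0:
        raise DegenerateDataError("all excretion points share the same day")
    ly = np.log(y)
    n = d.size
    dc = d - d.mean()
    slope = float(dc @ ly / (dc @ dc))
    resid = ly - ly.mean() - slope * dc
    rss = float(resid @ resid)
    if rss <= 1e-24 * max(1.0, float(ly @ ly)):
        # exact line: any nonzero slope is certain
        p = 1.0 if abs(slope) < 1e-12 else 0.0
    else:
        se = np.sqrt(rss / (n - 2) / (dc @ dc))
        from scipy import stats

        p = float(2.0 * stats.t.sf(abs(slope) / se, n - 2))
    if p <= alpha:
        category = "increase" if slope > 0 else "decrease"
    else:
        category = "no_change"
    return TrendResult(slope=slope, p_value=p, category=category)


def classify_cea_change(
    days: Sequence[float],
    values: Sequence[float],
    window_days: tuple[float, float] = (30.0, 61.0),
    mode: Literal["multiplicative", "additive"] = "multiplicative",
) -> str | None:
    """Categorise the CEA change 1-2 months after the course start.

    Baseline is the last value at day <= 0; the follow-up is the last value
    inside ``window_days``.  Under the default symmetric multiplicative
    reading of "changed by more than 50%", the category is increase when
    follow-up/baseline > 1.5, decrease when < 2/3, and no_change otherwise.
    ``mode="additive"`` instead uses (follow-up - baseline)/baseline beyond
    +/-0.5.  Returns None when baseline or follow-up is missing.
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(d) & np.isfinite(v) & (v > 0)
    d, v = d[ok], v[ok]
    pre = d <= 0
    post = (d >= window_days[0]) & (d <= window_days[1])
    if not pre.any() or not post.any():
        return None
    baseline = v[pre][np.argmax(d[pre])]
    follow = v[post][np.argmax(d[post])]
    ratio = follow / baseline
    if mode == "multiplicative":
        if ratio > 1.5:
            return "increase"
        if ratio < 2.0 / 3.0:
            return "decrease"
        return "no_change"
    if mode == "additive":
        change = ratio - 1.0
        if change > 0.5:
            return "increase"
        if change < -0.5:
            return "decrease"
        return "no_change"
    raise ParameterError(f"unknown CEA change mode {mode!r}")


# ---------------------------------------------------------------------------
# Freeman-Halton exact test for r x c tables
# ---------------------------------------------------------------------------

def _logfact(n: int) -> float:
    return lgamma(n + 1)


def _row_compositions(total: int, caps: Sequence[int]):
    """All length-len(caps) tuples of non-negative ints with given sum, x_i <= caps_i."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    head_cap = caps[0]
    tail_cap = sum(caps[1:])
    lo = max(0, total - tail_cap)
    hi = min(head_cap, total)
    for x in range(lo, hi + 1):
        for rest in _row_compositions(total - x, caps[1:]):
            yield (x,) + rest


def _enumerate_logprobs(row_margins, col_margins):
    """Yield (cells_logfact_sum) over all tables with the given margins.

    Tables are enumerated row by row; the last row is determined by the
    column margins.  Only sum(log n_ij!) varies between tables, so that is
    what is yielded.
    """
    rows = list(row_margins)

    def rec(i: int, remaining_cols, acc: float):
        if i == len(rows) - 1:
            yield acc + sum(_logfact(c) for c in remaining_cols)
            return
        for comp in _row_compositions(rows[i], remaining_cols):
            new_cols = tuple(rc - x for rc, x in zip(remaining_cols, comp))
            yield from rec(i + 1, new_cols, acc + sum(_logfact(x) for x in comp))

    yield from rec(0, tuple(col_margins), 0.0)


def fisher_exact_rxc(table, tie_tol: float = 1e-12) -> float:
    """Freeman-Halton exact test of independence for an r x c count table.

    Enumerates every table sharing the observed margins; the p-value is the
    total conditional (multivariate hypergeometric) probability of tables no
    more probable than the observed one, with a relative tolerance
    ``tie_tol`` for probability ties.  Rows or columns with a zero margin are
    dropped before enumeration; a table reduced to a single row or column has
    p = 1 by convention (independence cannot be rejected).
    """
    t = np.asarray(table)
    if t.ndim != 2:
        raise ParameterError("contingency table must be 2-dimensional")
    if not np.issubdtype(t.dtype, np.integer):
        t_int = np.rint(t).astype(np.int64)
        if not np.allclose(t, t_int):
            raise ParameterError("contingency table must hold integer counts")
        t = t_int
    if (t < 0).any():
        raise ParameterError("contingency table counts must be non-negative")
    if t.sum() == 0:
        raise ParameterError("contingency table is empty")

    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0

    R = t.sum(axis=1)
    C = t.sum(axis=0)
    N = int(t.sum())
    const = sum(_logfact(int(r)) for r in R) + sum(_logfact(int(c)) for c in C) - _logfact(N)
    # log P(table) = const - sum log n_ij!; larger cell term => less probable
    obs_cells = float(sum(_logfact(int(x)) for x in t.flat))
    log_tie = np.log1p(tie_tol)
    p = 0.0
    for cells in _enumerate_logprobs(R.tolist(), C.tolist()):
        if cells >= obs_cells - log_tie:  # P <= P_obs * (1 + tol)
            p += np.exp(const - cells)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# patient-level association and survival
# ---------------------------------------------------------------------------

def patient_trend_status(
    course: TreatmentCourse,
    nucleosides: Sequence[str] = TREND_NUCLEOSIDES,
    alpha: float = 0.05,
) -> bool | None:
    """True if any monitored nucleoside shows a significant post-course trend.

    Returns None when no monitored nucleoside has enough daily points.
    """
    any_evaluated = False
    for nuc in nucleosides:
        sub = course.excretions[course.excretions["nucleoside"] == nuc]
        if len(sub) < 5:
            continue
        any_evaluated = True
        res = classify_trend(sub["day"].to_numpy(), sub["concentration"].to_numpy(), alpha=alpha)
        if res.has_trend:
            return True
    return False if any_evaluated else None


def trend_cea_association(
    courses: Iterable[TreatmentCourse],
    nucleosides: Sequence[str] = TREND_NUCLEOSIDES,
    alpha: float = 0.05,
    cea_mode: Literal["multiplicative", "additive"] = "multiplicative",
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate nucleoside trend status against CEA change; exact p.

    Rows: no_trend / trend (any monitored nucleoside with a significant
    slope).  Columns: CEA decrease / no_change / increase.  Patients missing
    either classification are dropped.  Returns the table (as a DataFrame)
    and the Freeman-Halton p-value.
    """
    counts = {(r, c): 0 for r in ("no_trend", "trend") for c in CEA_CATEGORIES}
    n_used = 0
    any_cea = False
    for course in courses:
        cea_cat = classify_cea_change(course.cea_days, course.cea_values, mode=cea_mode)
        if cea_cat is not None:
            any_cea = True
        status = patient_trend_status(course, nucleosides, alpha=alpha)
        if cea_cat is None or status is None:
            continue
        counts[("trend" if status else "no_trend", cea_cat)] += 1
        n_used += 1
    if not any_cea:
        raise InsufficientDataError("no patient has a classifiable CEA change")
    if n_used < 2:
        raise InsufficientDataError(
            f"only {n_used} patients with both trend and CEA classifications"
        )
    table = pd.DataFrame(
        [[counts[(r, c)] for c in CEA_CATEGORIES] for r in ("no_trend", "trend")],
        index=["no_trend", "trend"],
        columns=list(CEA_CATEGORIES),
    )
    p = fisher_exact_rxc(table.to_numpy())
    return table, p


def survival_by_trend(
    courses: Iterable[TreatmentCourse],
    nucleosides: Sequence[str] = TREND_NUCLEOSIDES,
    alpha: float = 0.05,
    log_transform: bool = False,
):
    """Two-sample t-test of survival months between trend and no-trend patients."""
    from .association import group_comparison

    values, groups = [], []
    for course in courses:
        status = patient_trend_status(course, nucleosides, alpha=alpha)
        if status is None or course.survival_months is None:
            continue
        values.append(course.survival_months)
        groups.append("trend" if status else "no_trend")
    return group_comparison(np.asarray(values), np.asarray(groups), log_transform=log_transform)
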