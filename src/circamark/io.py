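"""CSV interchange formats, pipeline configuration and the end-to-end runner.

Schemas (all plain CSV, timezone-naive local clock times):

* actigraphy counts: ``timestamp`` (ISO-8601), ``counts`` (non-negative);
  strictly uniform epoch spacing is enforced on read.
* diary: ``date``, ``bed_start``, ``bed_end`` (HH:MM clock times; an end at
  or before the start wraps past midnight).
* urine: ``patient_id``, ``nucleoside``, ``datetime``,
  ``concentration_ug_per_g_creatinine`` (> 0, duplicates rejected).
* course excretions: ``patient_id``, ``day``, ``nucleoside``,
  ``concentration``; CEA: ``patient_id``, ``day``, ``cea_mg_per_l``;
  outcomes: ``patient_id``, ``survival_months``, ``toxicity_grade``.

``run_pipeline`` binds the stages (simulate/read -> actigraphy indices ->
cosinor fits -> correlation grid with bootstrap check -> chemo-response
tests) and writes every table plus a JSON run manifest that suffices to
reproduce the report bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .actigraphy import ActigraphySeries, rest_activity_indices
from .association import bootstrap_correlation_check, spearman_matrix
from .chemo import TreatmentCourse, survival_by_trend, trend_cea_association
from .cosinor import (
    check_eligibility,
    detect_rhythm,
    fit_multicomponent_cosinor,
    summarize_cohort,
)
from .exceptions import CircamarkError, EligibilityError, SchemaError
from .synthetic import Cohort, generate_cohort

log = logging.getLogger("circamark")

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "read_actigraphy",
    "write_actigraphy",
    "read_urine",
    "write_urine",
    "read_courses",
    "write_courses",
]


# ---------------------------------------------------------------------------
# actigraphy
# ---------------------------------------------------------------------------

def write_actigraphy(series: ActigraphySeries, counts_path, diary_path=None) -> None:
    pd.DataFrame({"timestamp": series.timestamps, "counts": series.counts}).to_csv(
        counts_path, index=False
    )
    if diary_path is not None and series.diary:
        rows = [
            {
                "date": s.date().isoformat(),
                "bed_start": s.strftime("%H:%M"),
                "bed_end": e.strftime("%H:%M"),
            }
            for s, e in series.diary
        ]
        pd.DataFrame(rows).to_csv(diary_path, index=False)


def read_actigraphy(counts_path, diary_path=None) -> ActigraphySeries:
    df = pd.read_csv(counts_path)
    for col in ("timestamp", "counts"):
        if col not in df.columns:
            raise SchemaError(f"{counts_path}: missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"])
    counts = df["counts"].to_numpy(dtype=float)
    neg = np.flatnonzero(~np.isfinite(counts) | (counts < 0))
    if neg.size:
        raise SchemaError(
            f"{counts_path}: row {neg[0] + 2}, column 'counts': "
            f"invalid value {df['counts'].iloc[neg[0]]!r}"
        )
    diffs = ts.diff().dropna().dt.total_seconds().to_numpy() / 60.0
    if len(ts) < 2:
        raise SchemaError(f"{counts_path}: need at least 2 epochs")
    epoch = diffs[0]
    bad = np.flatnonzero(np.abs(diffs - epoch) > 1e-9)
    if bad.size:
        raise SchemaError(
            f"{counts_path}: row {bad[0] + 3}, column 'timestamp': "
            f"non-uniform spacing ({diffs[bad[0]]:g} min vs {epoch:g} min)"
        )
    if abs(epoch - round(epoch)) > 1e-9 or epoch < 1:
        raise SchemaError(f"{counts_path}: epoch spacing must be a whole number of minutes")
    diary = None
    if diary_path is not None:
        ddf = pd.read_csv(diary_path)
        for col in ("date", "bed_start", "bed_end"):
            if col not in ddf.columns:
                raise SchemaError(f"{diary_path}: missing column {col!r}")
        diary = []
        for _, row in ddf.iterrows():
            start = pd.Timestamp(f"{row['date']} {row['bed_start']}")
            end = pd.Timestamp(f"{row['date']} {row['bed_end']}")
            if end <= start:
                end += pd.Timedelta(days=1)
            diary.append((start, end))
    return ActigraphySeries(
        start=ts.iloc[0], counts=counts, epoch_minutes=int(round(epoch)), diary=diary
    )


# ---------------------------------------------------------------------------
# urine
# ---------------------------------------------------------------------------

URINE_COLUMNS = ("patient_id", "nucleoside", "datetime", "concentration_ug_per_g_creatinine")


def write_urine(urine: pd.DataFrame, path, start_date: str = "2021-03-01") -> None:
    """Write the internal (patient_id, nucleoside, time_h, concentration) table.

    ``time_h`` is hours since midnight of the first collection day and is
    rendered as an absolute datetime.
    """
    base = pd.Timestamp(start_date)
    out = pd.DataFrame(
        {
            "patient_id": urine["patient_id"],
            "nucleoside": urine["nucleoside"],
            "datetime": base + pd.to_timedelta(urine["time_h"], unit="h"),
            "concentration_ug_per_g_creatinine": urine["concentration"],
        }
    )
    out.to_csv(path, index=False)


def read_urine(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in URINE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    conc = df["concentration_ug_per_g_creatinine"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(conc) | (conc <= 0))
    if bad.size:
        raise SchemaError(
            f"{path}: row {bad[0] + 2}, column 'concentration_ug_per_g_creatinine': "
            f"non-positive value {conc[bad[0]]!r}"
        )
    dup = df.duplicated(subset=["patient_id", "nucleoside", "datetime"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise SchemaError(
            f"{path}: row {i + 2}: duplicate (patient_id, nucleoside, datetime) sample"
        )
    dt = pd.to_datetime(df["datetime"])
    base = dt.min().normalize()
    time_h = (dt - base).dt.total_seconds() / 3600.0
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "nucleoside": df["nucleoside"],
            "time_h": time_h,
            "concentration": conc,
        }
    )


# ---------------------------------------------------------------------------
# treatment courses
# ---------------------------------------------------------------------------

def write_courses(courses: list[TreatmentCourse], excretion_path, cea_path, outcomes_path) -> None:
    exc = []
    cea = []
    outcomes = []
    for c in courses:
        e = c.excretions.copy()
        e.insert(0, "patient_id", c.patient_id)
        exc.append(e)
        for d, v in zip(c.cea_days, c.cea_values):
            cea.append({"patient_id": c.patient_id, "day": d, "cea_mg_per_l": v})
        outcomes.append(
            {
                "patient_id": c.patient_id,
                "survival_months": c.survival_months,
                "toxicity_grade": c.toxicity_grade,
            }
        )
    pd.concat(exc, ignore_index=True).to_csv(excretion_path, index=False)
    pd.DataFrame(cea).to_csv(cea_path, index=False)
    pd.DataFrame(outcomes).to_csv(outcomes_path, index=False)


def read_courses(excretion_path, cea_path=None, outcomes_path=None) -> list[TreatmentCourse]:
    exc = pd.read_csv(excretion_path)
    for col in ("patient_id", "day", "nucleoside", "concentration"):
        if col not in exc.columns:
            raise SchemaError(f"{excretion_path}: missing column {col!r}")
    conc = exc["concentration"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(conc) | (conc <= 0))
    if bad.size:
        raise SchemaError(
            f"{excretion_path}: row {bad[0] + 2}, column 'concentration': "
            f"non-positive value {conc[bad[0]]!r}"
        )
    cea = pd.read_csv(cea_path) if cea_path is not None else None
    outcomes = pd.read_csv(outcomes_path) if outcomes_path is not None else None
    courses = []
    for pid, sub in exc.groupby("patient_id", sort=True):
        kwargs: dict = {}
        if cea is not None:
            csub = cea[cea["patient_id"] == pid]
            kwargs["cea_days"] = csub["day"].to_numpy(dtype=float)
            kwargs["cea_values"] = csub["cea_mg_per_l"].to_numpy(dtype=float)
        if outcomes is not None:
            osub = outcomes[outcomes["patient_id"] == pid]
            if len(osub):
                sm = osub["survival_months"].iloc[0]
                kwargs["survival_months"] = None if pd.isna(sm) else float(sm)
                tg = osub.get("toxicity_grade")
                if tg is not None and not pd.isna(tg.iloc[0]):
                    kwargs["toxicity_grade"] = int(tg.iloc[0])
        courses.append(
            TreatmentCourse(
                patient_id=str(pid),
                excretions=sub[["day", "nucleoside", "concentration"]].reset_index(drop=True),
                **kwargs,
            )
        )
    return courses


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration for an end-to-end run (simulated or file-based inputs)."""

    seed: int = 0
    scenario: str | None = "mixed"  # None => read from the paths below
    n_patients: int = 29
    n_days: int = 5
    alpha_rhythm: float = 0.1
    alpha_trend: float = 0.05
    bootstrap_trials: int = 1000
    bootstrap_quantile: float = 0.9
    bootstrap_alpha: float = 0.1
    hmm_restarts: int = 5
    period_resamples: int = 50
    bootstrap_nucleoside: str = "pseudouridine"
    urine_path: str | None = None
    excretion_path: str | None = None
    cea_path: str | None = None
    outcomes_path: str | None = None
    outdir: str = "circamark_report"

    def __post_init__(self):
        for name in ("alpha_rhythm", "alpha_trend", "bootstrap_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise CircamarkError(f"{name} must lie in [0, 1), got {v}")
        if not (0.0 < self.bootstrap_quantile < 1.0):
            raise CircamarkError("bootstrap_quantile must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class RunReport:
    manifest: dict
    indices: pd.DataFrame
    cosinor_params: pd.DataFrame
    cohort_summary: pd.DataFrame
    correlation_grid: pd.DataFrame
    bootstrap_results: pd.DataFrame
    contingency: pd.DataFrame | None
    fisher_p: float | None
    survival_p: float | None


def _cosinor_stage(urine: pd.DataFrame, alpha: float):
    fits: dict[str, dict[str, object]] = {}
    params_rows = []
    n_excluded = 0
    for (pid, nuc), sub in urine.groupby(["patient_id", "nucleoside"], sort=True):
        if not check_eligibility(sub["concentration"]):
            n_excluded += 1
            continue
        try:
            fit = fit_multicomponent_cosinor(
                sub["time_h"].to_numpy(),
                sub["concentration"].to_numpy(),
                alpha=alpha,
            )
        except EligibilityError:
            n_excluded += 1
            continue
        fit = detect_rhythm(fit, alpha)
        fits.setdefault(nuc, {})[pid] = fit
        params_rows.append(
            {
                "patient_id": pid,
                "nucleoside": nuc,
                "n_samples": fit.n_samples,
                "mesor": fit.mesor,
                "overall_amplitude": fit.overall_amplitude,
                "relative_amplitude": fit.relative_amplitude,
                "overall_acrophase_h": fit.overall_acrophase_h,
                "A12_log": fit.A12,
                "A24_log": fit.A24,
                "p_12h": fit.amp_p[12.0],
                "p_24h": fit.amp_p[24.0],
                "rhythmic_12h": fit.rhythmic_12h,
                "rhythmic_24h": fit.rhythmic_24h,
                "rhythmic_any": fit.rhythmic_any,
            }
        )
    params = pd.DataFrame(params_rows)
    return fits, params, n_excluded


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full study pipeline and write all report tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "circamark",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": asdict(config),
        "stages": {},
    }

    # --- stage 1: data ----------------------------------------------------
    log.info("[data] acquiring inputs")
    cohort: Cohort | None = None
    if config.scenario is not None:
        cohort = generate_cohort(
            config.n_patients, config.scenario, seed=config.seed, n_days=config.n_days
        )
        urine = cohort.urine
        courses = cohort.courses
        actigraphy = cohort.actigraphy
    else:
        if config.urine_path is None:
            raise CircamarkError("[data] scenario=None requires urine_path")
        urine = read_urine(config.urine_path)
        courses = (
            read_courses(config.excretion_path, config.cea_path, config.outcomes_path)
            if config.excretion_path
            else []
        )
        actigraphy = {}
    n_patients = urine["patient_id"].nunique()
    manifest["stages"]["data"] = {"patients": int(n_patients)}
    log.info("[data] %d patients", n_patients)

    # --- stage 2: actigraphy ---------------------------------------------
    log.info("[actigraphy] fitting HMMs for %d recordings", len(actigraphy))
    idx_rows = []
    for j, (pid, series) in enumerate(sorted(actigraphy.items())):
        idx = rest_activity_indices(
            series,
            n_restarts=config.hmm_restarts,
            seed=config.seed + 1000 + j,
            n_resamples=config.period_resamples,
        )
        idx_rows.append({"patient_id": pid, **idx.as_dict()})
    indices = pd.DataFrame(idx_rows)
    manifest["stages"]["actigraphy"] = {"patients": len(idx_rows)}

    # --- stage 3: cosinor -------------------------------------------------
    log.info("[cosinor] fitting per-patient models")
    fits, params, n_excluded = _cosinor_stage(urine, config.alpha_rhythm)
    summary = (
        summarize_cohort({n: list(d.values()) for n, d in fits.items()})
        if fits
        else pd.DataFrame()
    )
    manifest["stages"]["cosinor"] = {
        "fits": int(len(params)),
        "excluded_series": int(n_excluded),
        "rhythmic": int(params["rhythmic_any"].sum()) if len(params) else 0,
    }
    log.info("[cosinor] %d fits, %d series excluded", len(params), n_excluded)

    # --- stage 4: association --------------------------------------------
    log.info("[association] correlation grid and bootstrap check")
    merged = indices.copy()
    if len(params):
        rel = params.pivot_table(
            index="patient_id", columns="nucleoside", values="relative_amplitude"
        )
        rel.columns = [f"relamp_{c}" for c in rel.columns]
        if len(merged):
            merged = merged.merge(rel, left_on="patient_id", right_index=True, how="left")
        else:
            merged = rel.reset_index()
    numeric = merged.drop(columns=["patient_id"], errors="ignore")
    grid = spearman_matrix(numeric) if len(numeric.columns) > 1 and len(numeric) >= 4 else pd.DataFrame()

    boot_rows = []
    boot_nuc = config.bootstrap_nucleoside
    if boot_nuc in fits and len(indices):
        covars = indices.set_index("patient_id")
        pair_cols = [
            c for c in ("rest_duration_a", "i_lt_o", "rhythm_index", "r24") if c in covars
        ]
        results = bootstrap_correlation_check(
            fits[boot_nuc],
            covars,
            [("relative_amplitude", c) for c in pair_cols],
            B=config.bootstrap_trials,
            seed=config.seed + 77,
            alpha=config.bootstrap_alpha,
            quantile=config.bootstrap_quantile,
        )
        boot_rows = [
            {
                "nucleoside": boot_nuc,
                "parameter": r.var_x,
                "index": r.var_y,
                "rho": r.rho,
                "p_value": r.p_value,
                "bootstrap_p_q90": r.bootstrap_p_q90,
                "bootstrap_significant": r.bootstrap_significant,
            }
            for r in results
        ]
    bootstrap_results = pd.DataFrame(boot_rows)
    manifest["stages"]["association"] = {
        "grid_pairs": int(len(grid)),
        "bootstrap_pairs": int(len(bootstrap_results)),
    }

    # --- stage 5: chemo response -----------------------------------------
    contingency = None
    fisher_p = None
    survival_p = None
    if courses:
        log.info("[chemo] trend classification and CEA association")
        try:
            contingency, fisher_p = trend_cea_association(courses, alpha=config.alpha_trend)
        except CircamarkError as err:
            log.warning("[chemo] association unavailable: %s", err)
        try:
            survival_p = survival_by_trend(courses, alpha=config.alpha_trend).p_value
        except CircamarkError as err:
            log.warning("[chemo] survival comparison unavailable: %s", err)
    manifest["stages"]["chemo"] = {
        "courses": len(courses),
        "fisher_p": fisher_p,
        "survival_p": survival_p,
    }

    # --- write report -----------------------------------------------------
    indices.to_csv(outdir / "rest_activity_indices.csv", index=False)
    params.to_csv(outdir / "cosinor_params.csv", index=False)
    if len(summary):
        summary.to_csv(outdir / "cohort_summary.csv")
    if len(grid):
        grid.to_csv(outdir / "correlation_grid.csv", index=False)
    if len(bootstrap_results):
        bootstrap_results.to_csv(outdir / "bootstrap_check.csv", index=False)
    if contingency is not None:
        contingency.to_csv(outdir / "contingency.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("[report] written to %s", outdir)

    return RunReport(
        manifest=manifest,
        indices=indices,
        cosinor_params=params,
        cohort_summary=summary,
        correlation_grid=grid,
        bootstrap_results=bootstrap_results,
        contingency=contingency,
        fisher_p=fisher_p,
        survival_p=survival_p,
    )
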