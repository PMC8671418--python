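"""Synthetic cohorts with known circadian ground truth.

Generates the four data streams the analysis pipeline consumes, with
controllable circadian structure so every downstream stage can be tested
without any clinical data:

* 1-min wrist-actigraphy counts over several days, produced by a latent
  3-state process (rest IA / moderate MA / high HA activity) with a nightly
  bed window, optional bedtime jitter and Poisson-count night interruptions;
  emissions are lognormal on the log1p scale, rounded to integer counts.
* Timed urinary nucleoside concentrations following the two-component
  (12 h + 24 h) cosinor model on the log scale with Gaussian noise, sampled
  at the study's ten collection times over two days (07:00, 11:00, 15:00,
  19:00, 23:00 on both days).
* Daily overnight excretion series around a chemotherapy course (3 days
  before, 14 days after by default) following a log-linear trend, plus a
  baseline/follow-up plasma CEA pair consistent with a chosen change
  category and a survival time.
* A patient covariate table (sex, age, WHO performance status, primary
  site, comorbidities, prior surgery, chemotherapy lines) drawn from
  realistic categorical frequencies for a metastatic colorectal cancer
  cohort.

All generators are fully deterministic given (params, seed); under zero
noise every output is an exact closed-form function of its parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .actigraphy import ActigraphySeries, IA, MA, HA, MINUTES_PER_DAY
from .chemo import TreatmentCourse
from .exceptions import ParameterError

__all__ = [
    "ActigraphyParams",
    "UrineSimParams",
    "CourseSimParams",
    "ScenarioConfig",
    "Cohort",
    "generate_actigraphy",
    "generate_urine_series",
    "generate_treatment_course",
    "generate_cohort",
    "NUCLEOSIDES",
    "NUCLEOSIDE_MEDIAN_MESOR",
    "STUDY_SAMPLE_TIMES_H",
    "SCENARIOS",
]

#: the eight nucleosides with detectable urinary excretion, and typical
#: cohort-median mesors (ug/g creatinine) used as simulation baselines
NUCLEOSIDE_MEDIAN_MESOR: dict[str, float] = {
    "pseudouridine": 64.3,
    "1-methylguanosine": 7.22,
    "1-methyladenosine": 6.84,
    "N2-N2-dimethylguanosine": 6.35,
    "4-acetylcytidine": 3.11,
    "1-methylinosine": 2.32,
    "adenosine": 0.69,
    "cytidine": 0.58,
}
NUCLEOSIDES: tuple[str, ...] = tuple(NUCLEOSIDE_MEDIAN_MESOR)

#: study urine collection times (hours): 07/11/15/19/23 on two consecutive days
STUDY_SAMPLE_TIMES_H: tuple[float, ...] = (7, 11, 15, 19, 23, 31, 35, 39, 43, 47)

_DEFAULT_START = pd.Timestamp("2021-03-01 15:00")


@dataclass(frozen=True)
class ActigraphyParams:
    """Design of a simulated actigraphy recording.

    Clock times are minutes since midnight.  ``emission_means``/``emission_sds``
    parameterise the per-state Gaussian on the log1p-count scale (IA < MA < HA
    strictly).  ``stay_probs`` are per-state self-transition probabilities:
    the MA and HA entries drive the out-of-bed activity chain and the
    persistence of night-time excursions; rest continuity in bed is governed
    by ``night_interruption_rate`` (expected Poisson count of brief MA
    excursions per night), so the IA entry is carried as the nominal rest
    self-transition but the realised one follows from the interruption
    process.
    """

    bed_start: int = 23 * 60
    bed_end: int = 7 * 60
    bedtime_jitter_sd: float = 10.0
    emission_means: tuple[float, float, float] = (1.3, 3.2, 4.8)
    emission_sds: tuple[float, float, float] = (0.5, 0.5, 0.4)
    stay_probs: tuple[float, float, float] = (0.99, 0.9, 0.9)
    night_interruption_rate: float = 1.0
    n_days: int = 5
    epoch_minutes: int = 1
    start_clock: int = 15 * 60  # recording starts mid-afternoon
    start_date: str = "2021-03-01"

    def __post_init__(self):
        m = self.emission_means
        if not (m[0] < m[1] < m[2]):
            raise ParameterError(
                f"emission means must be strictly increasing IA < MA < HA, got {m}"
            )
        if any(s <= 0 for s in self.emission_sds):
            raise ParameterError("emission SDs must be positive")
        if any(not (0.0 < p < 1.0) for p in self.stay_probs):
            raise ParameterError("stay probabilities must lie in (0, 1)")
        if self.night_interruption_rate < 0:
            raise ParameterError("night_interruption_rate must be >= 0")
        if self.bedtime_jitter_sd < 0:
            raise ParameterError("bedtime_jitter_sd must be >= 0")
        if self.n_days < 1 or self.epoch_minutes < 1:
            raise ParameterError("n_days and epoch_minutes must be positive")
        if (self.bed_end - self.bed_start) % MINUTES_PER_DAY == 0:
            raise ParameterError("bed interval must be non-degenerate")

    @property
    def bed_duration_min(self) -> int:
        return (self.bed_end - self.bed_start) % MINUTES_PER_DAY


def generate_actigraphy(
    params: ActigraphyParams, seed: int | None = None
) -> tuple[ActigraphySeries, np.ndarray]:
    """Simulate one actigraphy recording; returns (series, latent states).

    The recording covers ``n_days`` x 24 h starting at ``start_clock``.  Each
    night's bed window is jittered independently at both ends; inside it the
    latent state is IA except during Poisson-count MA excursions whose
    lengths are geometric with continuation probability ``stay_probs[MA]``.
    Outside bed the latent state alternates between MA and HA as a Markov
    chain with the given self-transition probabilities.  The diary records
    the jittered bed windows.
    """
    rng = np.random.default_rng(seed)
    epm = params.epoch_minutes
    n = params.n_days * MINUTES_PER_DAY // epm
    states = np.empty(n, dtype=np.int8)

    # --- latent day-time chain over MA/HA --------------------------------
    state = MA
    stay_ma, stay_ha = params.stay_probs[MA], params.stay_probs[HA]
    u = rng.random(n)
    for i in range(n):
        states[i] = state
        if state == MA:
            state = MA if u[i] < stay_ma else HA
        else:
            state = HA if u[i] < stay_ha else MA

    # --- nightly bed windows (absolute epoch indices) ---------------------
    offset = (params.bed_start - params.start_clock) % MINUTES_PER_DAY
    diary: list[tuple[pd.Timestamp, pd.Timestamp]] = []
    start_ts = pd.Timestamp(f"{params.start_date} "
                            f"{params.start_clock // 60:02d}:{params.start_clock % 60:02d}")
    for night in range(params.n_days):
        s = offset + night * MINUTES_PER_DAY
        e = s + params.bed_duration_min
        if params.bedtime_jitter_sd > 0:
            s = s + rng.normal(0.0, params.bedtime_jitter_sd)
            e = e + rng.normal(0.0, params.bedtime_jitter_sd)
        s_i = int(np.clip(round(s / epm), 0, n))
        e_i = int(np.clip(round(e / epm), 0, n))
        if e_i <= s_i:
            continue
        day_chain = states[s_i:e_i].copy()  # pre-bed activity chain, reused in excursions
        states[s_i:e_i] = IA
        # Poisson-count brief wake excursions (night interruptions): each
        # excursion resumes the day-time MA/HA chain for a geometric duration
        k = rng.poisson(params.night_interruption_rate)
        for _ in range(k):
            ex_start = int(rng.integers(s_i, e_i))
            ex_len = 1 + int(rng.geometric(1.0 - stay_ma))
            ex_end = min(ex_start + ex_len, e_i)
            states[ex_start:ex_end] = day_chain[ex_start - s_i : ex_end - s_i]
        diary.append(
            (
                start_ts + pd.Timedelta(minutes=s_i * epm),
                start_ts + pd.Timedelta(minutes=e_i * epm),
            )
        )

    # --- emissions: lognormal on log1p scale, integer counts --------------
    means = np.asarray(params.emission_means)
    sds = np.asarray(params.emission_sds)
    z = rng.normal(means[states], sds[states])
    counts = np.maximum(np.rint(np.expm1(z)), 0.0)

    series = ActigraphySeries(
        start=start_ts, counts=counts, epoch_minutes=epm, diary=diary
    )
    return series, states


@dataclass(frozen=True)
class UrineSimParams:
    """Two-component cosinor generator for one nucleoside's timed samples.

    concentration(t) = exp(mesor_log + amp12*cos(2*pi*t/12 + phase12)
                           + amp24*cos(2*pi*t/24 + phase24) + eps),
    eps ~ Normal(0, noise_sd_log).
    """

    mesor_log: float = float(np.log(6.0))
    amp12_log: float = 0.15
    amp24_log: float = 0.30
    phase12: float = 0.0
    phase24: float = float(-2.0 * np.pi * 13.0 / 24.0)  # peak ~13:00
    noise_sd_log: float = 0.25
    sample_times: tuple[float, ...] = STUDY_SAMPLE_TIMES_H

    def __post_init__(self):
        if self.noise_sd_log < 0:
            raise ParameterError("noise_sd_log must be >= 0")
        if self.amp12_log < 0 or self.amp24_log < 0:
            raise ParameterError("component amplitudes must be >= 0")

    def curve_log(self, t_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        return (
            self.mesor_log
            + self.amp12_log * np.cos(2.0 * np.pi * t / 12.0 + self.phase12)
            + self.amp24_log * np.cos(2.0 * np.pi * t / 24.0 + self.phase24)
        )


def generate_urine_series(
    params: UrineSimParams, seed: int | None = None
) -> pd.DataFrame:
    """Timed concentrations for one nucleoside; columns time_h, concentration."""
    rng = np.random.default_rng(seed)
    t = np.asarray(params.sample_times, dtype=float)
    log_c = params.curve_log(t)
    if params.noise_sd_log > 0:
        log_c = log_c + rng.normal(0.0, params.noise_sd_log, size=t.size)
    return pd.DataFrame({"time_h": t, "concentration": np.exp(log_c)})


@dataclass(frozen=True)
class CourseSimParams:
    """Daily overnight-excretion generator around one chemotherapy course."""

    baseline_log: float = float(np.log(6.0))
    daily_slope_log: float = 0.0  # per day on the log scale
    noise_sd_log: float = 0.1
    n_pre_days: int = 3
    n_post_days: int = 14
    cea_category: str = "no_change"  # decrease / no_change / increase
    cea_baseline: float = 20.0  # mg/L
    survival_months: float = 12.0
    nucleoside: str = "cytidine"

    def __post_init__(self):
        if self.noise_sd_log < 0:
            raise ParameterError("noise_sd_log must be >= 0")
        if self.n_pre_days + self.n_post_days < 5:
            raise ParameterError("need at least 5 daily excretion points")
        if self.cea_category not in ("decrease", "no_change", "increase"):
            raise ParameterError(f"unknown cea_category {self.cea_category!r}")
        if self.survival_months <= 0:
            raise ParameterError("survival_months must be > 0")


#: follow-up/baseline CEA ratio ranges realising each change category
_CEA_RATIO_RANGES = {
    "increase": (1.6, 3.0),
    "no_change": (0.8, 1.25),
    "decrease": (0.35, 0.6),
}


def generate_treatment_course(
    params: CourseSimParams, seed: int | None = None, patient_id: str = "P1"
) -> TreatmentCourse:
    """Simulate one treatment course (single nucleoside unless used via cohort)."""
    rng = np.random.default_rng(seed)
    days = np.concatenate(
        [np.arange(-params.n_pre_days, 0), np.arange(1, params.n_post_days + 1)]
    ).astype(float)
    log_exc = params.baseline_log + params.daily_slope_log * days
    if params.noise_sd_log > 0:
        log_exc = log_exc + rng.normal(0.0, params.noise_sd_log, size=days.size)
    excretions = pd.DataFrame(
        {
            "day": days,
            "nucleoside": params.nucleoside,
            "concentration": np.exp(log_exc),
        }
    )
    lo, hi = _CEA_RATIO_RANGES[params.cea_category]
    ratio = rng.uniform(lo, hi)
    follow_day = float(rng.uniform(35.0, 55.0))
    return TreatmentCourse(
        patient_id=patient_id,
        excretions=excretions,
        cea_days=np.array([-7.0, follow_day]),
        cea_values=np.array([params.cea_baseline, params.cea_baseline * ratio]),
        survival_months=params.survival_months,
        toxicity_grade=int(rng.integers(0, 3)),
    )


# ---------------------------------------------------------------------------
# cohort scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Cohort-level simulation scenario.

    ``disruption_range`` draws a per-patient disruption score u ~ U(range);
    u interpolates bedtime jitter, night interruptions and rhythm amplitude
    between the robust (u=0) and disrupted (u=1) extremes.
    ``rest_amplitude_coupling`` adds coupling*(rest_hours - 8) to each
    nucleoside's 24-h log-amplitude, linking rest duration to excretion
    rhythm strength (0 = independent).
    """

    name: str
    disruption_range: tuple[float, float]
    rest_hours_range: tuple[float, float]
    amp24_log_base: float
    amp24_log_spread: float
    urine_noise_sd: float
    rest_amplitude_coupling: float = 0.0
    trend_fraction: float = 0.4
    trend_slope_log: float = 0.08
    course_noise_sd: float = 0.12


SCENARIOS: dict[str, ScenarioConfig] = {
    "robust-rhythm": ScenarioConfig(
        name="robust-rhythm",
        disruption_range=(0.0, 0.1),
        rest_hours_range=(7.5, 8.5),
        amp24_log_base=0.35,
        amp24_log_spread=0.10,
        urine_noise_sd=0.15,
    ),
    "disrupted": ScenarioConfig(
        name="disrupted",
        disruption_range=(0.7, 1.0),
        rest_hours_range=(5.0, 9.0),
        amp24_log_base=0.08,
        amp24_log_spread=0.05,
        urine_noise_sd=0.35,
    ),
    "mixed": ScenarioConfig(
        name="mixed",
        disruption_range=(0.0, 1.0),
        rest_hours_range=(6.0, 10.0),
        amp24_log_base=0.30,
        amp24_log_spread=0.12,
        urine_noise_sd=0.20,
    ),
}

# covariate frequencies typical of a metastatic colorectal cancer cohort
_COVARIATE_DISTS: dict[str, tuple[tuple[object, float], ...]] = {
    "sex": (("male", 0.6), ("female", 0.4)),
    "who_ps": ((0, 0.77), (1, 0.23)),
    "primary_site": (("colon", 0.67), ("rectum", 0.33)),
    "comorbidities": (("yes", 0.47), ("no", 0.53)),
    "prior_metastasis_surgery": (("yes", 0.53), ("no", 0.47)),
    "chemo_lines": ((1, 0.07), (2, 0.50), (3, 0.23), (4, 0.20)),
}


@dataclass
class Cohort:
    """A fully simulated study cohort with ground truth retained for testing."""

    scenario: str
    seed: int | None
    covariates: pd.DataFrame  # indexed by patient_id
    actigraphy: dict[str, ActigraphySeries]
    latent_states: dict[str, np.ndarray]
    urine: pd.DataFrame  # patient_id, nucleoside, time_h, concentration
    courses: list[TreatmentCourse]
    truth: pd.DataFrame  # per-patient generating parameters

    @property
    def patient_ids(self) -> list[str]:
        return list(self.covariates.index)


def _draw_categorical(rng: np.random.Generator, dist) -> object:
    values, probs = zip(*dist)
    return values[rng.choice(len(values), p=np.asarray(probs))]


def generate_cohort(
    n_patients: int,
    scenario: str | ScenarioConfig = "mixed",
    seed: int | None = 0,
    n_days: int = 5,
    rest_amplitude_coupling: float | None = None,
    with_courses: bool = True,
) -> Cohort:
    """Simulate a full cohort for the given scenario preset.

    Every patient gets covariates, an actigraphy recording (with latent
    states), ten timed urine samples per nucleoside, and (optionally) a
    treatment course.  ``rest_amplitude_coupling`` overrides the scenario's
    coupling between planned rest duration and the 24-h log-amplitude of
    every nucleoside.
    """
    if n_patients < 1:
        raise ParameterError(f"n_patients must be >= 1, got {n_patients}")
    if isinstance(scenario, str):
        if scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {scenario!r}; available: {sorted(SCENARIOS)}"
            )
        cfg = SCENARIOS[scenario]
    else:
        cfg = scenario
    if rest_amplitude_coupling is not None:
        cfg = replace(cfg, rest_amplitude_coupling=rest_amplitude_coupling)

    root = np.random.SeedSequence(seed)
    pid_seeds = root.spawn(n_patients)
    cov_rows = []
    actigraphy: dict[str, ActigraphySeries] = {}
    latent: dict[str, np.ndarray] = {}
    urine_rows = []
    courses: list[TreatmentCourse] = []
    truth_rows = []

    for i, pid_seed in enumerate(pid_seeds):
        pid = f"P{i + 1:03d}"
        streams = pid_seed.spawn(5)
        rng = np.random.default_rng(streams[0])

        covs = {name: _draw_categorical(rng, dist) for name, dist in _COVARIATE_DISTS.items()}
        covs["age"] = float(np.clip(rng.normal(64.0, 10.0), 23, 81))
        cov_rows.append({"patient_id": pid, **covs})

        u = rng.uniform(*cfg.disruption_range)
        rest_hours = rng.uniform(*cfg.rest_hours_range)
        bed_end = 7 * 60
        bed_start = int(round(bed_end - rest_hours * 60)) % MINUTES_PER_DAY
        act_params = ActigraphyParams(
            bed_start=bed_start,
            bed_end=bed_end,
            bedtime_jitter_sd=2.0 + 80.0 * u,
            night_interruption_rate=0.2 + 8.0 * u,
            n_days=n_days,
        )
        series, states = generate_actigraphy(
            act_params, seed=int(streams[1].generate_state(1)[0] % 2**31)
        )
        actigraphy[pid] = series
        latent[pid] = states

        urng = np.random.default_rng(streams[2])
        amp_shift = cfg.rest_amplitude_coupling * (rest_hours - 8.0)
        phase24 = float(-2.0 * np.pi * 13.0 / 24.0 + urng.normal(0.0, 0.5))
        patient_amp = max(
            0.02,
            cfg.amp24_log_base * (1.0 - 0.7 * u)
            + urng.normal(0.0, cfg.amp24_log_spread)
            + amp_shift,
        )
        for j, nuc in enumerate(NUCLEOSIDES):
            nuc_rng = np.random.default_rng(
                [int(streams[2].generate_state(1)[0] % 2**31), j]
            )
            params = UrineSimParams(
                mesor_log=float(
                    np.log(NUCLEOSIDE_MEDIAN_MESOR[nuc]) + nuc_rng.normal(0.0, 0.3)
                ),
                amp12_log=0.5 * patient_amp,
                amp24_log=patient_amp,
                phase12=float(nuc_rng.uniform(-np.pi, np.pi)),
                phase24=phase24,
                noise_sd_log=cfg.urine_noise_sd,
            )
            df = generate_urine_series(
                params, seed=int(nuc_rng.integers(0, 2**31))
            )
            df.insert(0, "nucleoside", nuc)
            df.insert(0, "patient_id", pid)
            urine_rows.append(df)

        truth_rows.append(
            {
                "patient_id": pid,
                "disruption": u,
                "rest_hours": rest_hours,
                "amp24_log": patient_amp,
                "phase24": phase24,
            }
        )

        if with_courses:
            crng = np.random.default_rng(streams[3])
            has_trend = bool(crng.random() < cfg.trend_fraction)
            slope = (
                cfg.trend_slope_log * (1 if crng.random() < 0.5 else -1)
                if has_trend
                else 0.0
            )
            cea_cat = (
                ("increase" if crng.random() < 0.7 else "no_change")
                if has_trend
                else ("no_change" if crng.random() < 0.85 else "decrease")
            )
            survival = float(
                np.exp(crng.normal(np.log(6.0 if has_trend else 16.0), 0.4))
            )
            day_rng = np.random.default_rng(streams[4])
            days = np.concatenate([np.arange(-3, 0), np.arange(1, 15)]).astype(float)
            exc_frames = []
            for nuc in ("1-methylguanosine", "4-acetylcytidine", "adenosine", "cytidine"):
                log_exc = (
                    np.log(NUCLEOSIDE_MEDIAN_MESOR[nuc])
                    + slope * days
                    + day_rng.normal(0.0, cfg.course_noise_sd, size=days.size)
                )
                exc_frames.append(
                    pd.DataFrame(
                        {"day": days, "nucleoside": nuc, "concentration": np.exp(log_exc)}
                    )
                )
            lo, hi = _CEA_RATIO_RANGES[cea_cat]
            ratio = day_rng.uniform(lo, hi)
            cea_base = float(np.exp(day_rng.normal(np.log(20.0), 0.5)))
            courses.append(
                TreatmentCourse(
                    patient_id=pid,
                    excretions=pd.concat(exc_frames, ignore_index=True),
                    cea_days=np.array([-7.0, float(day_rng.uniform(35.0, 55.0))]),
                    cea_values=np.array([cea_base, cea_base * ratio]),
                    survival_months=survival,
                    toxicity_grade=int(day_rng.integers(0, 2 if not has_trend else 4)),
                )
            )

    covariates = pd.DataFrame(cov_rows).set_index("patient_id")
    urine = pd.concat(urine_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows).set_index("patient_id")
    return Cohort(
        scenario=cfg.name,
        seed=seed,
        covariates=covariates,
        actigraphy=actigraphy,
        latent_states=latent,
        urine=urine,
        courses=courses,
        truth=truth,
    )
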