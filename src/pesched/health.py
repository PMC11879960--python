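"""Health-outcome model for weekly physical-education schedules.

A candidate schedule (sessions per week, session length, activity mix,
intensity mix) is mapped to four predicted health outcomes per student:

* ``delta_bmi`` — BMI reduction (kg/m²) from the energy balance of the
  extra weekly expenditure, using the 7700 kcal/kg-fat convention, capped;
* ``delta_f``   — fitness-score gain (points), a saturating exponential in
  weekly moderate-to-vigorous (MVPA) hours;
* ``calories``  — per-session caloric expenditure (kcal), the MET formula
  ``MET · W · t · (1 + BMR/1000)`` with the Mifflin-style linear BMR;
* ``delta_hr``  — resting-heart-rate reduction (bpm), a saturating
  exponential in weekly aerobic hours.

The four outcomes are min–max normalised against decision-space bounds and
combined into one scalar score with weights (default 0.4/0.3/0.2/0.1 for
BMI, fitness, calories, heart rate). The cohort-level objective is the mean
of per-student scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIVITIES = ("aerobic", "strength", "team", "flexibility", "recreational")
INTENSITIES = ("low", "moderate", "vigorous")
SEXES = ("male", "female")

#: Session-effective intensity multipliers by (activity, intensity).
#: These are *net* per-session multipliers, not instantaneous compendium
#: METs: the caloric formula already carries the (1 + BMR/1000) metabolic
#: factor (≈2.2–2.5 for school-age students), so entries are calibrated so
#: that a vigorous aerobic session for a median adolescent expends roughly
#: 300–400 kcal/hour. Orderings follow field convention (aerobic > team >
#: strength > recreational > flexibility; vigorous > moderate > low).
DEFAULT_MET_TABLE: dict[tuple[str, str], float] = {
    ("aerobic", "low"): 1.8, ("aerobic", "moderate"): 2.1, ("aerobic", "vigorous"): 2.5,
    ("strength", "low"): 1.3, ("strength", "moderate"): 1.6, ("strength", "vigorous"): 1.9,
    ("team", "low"): 1.5, ("team", "moderate"): 1.8, ("team", "vigorous"): 2.2,
    ("flexibility", "low"): 1.1, ("flexibility", "moderate"): 1.2, ("flexibility", "vigorous"): 1.4,
    ("recreational", "low"): 1.3, ("recreational", "moderate"): 1.5, ("recreational", "vigorous"): 1.8,
}

SIMPLEX_TOL = 1e-9


class HealthModelError(ValueError):
    """Invalid input to the health model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitnessWeights:
    """Relative importance of the four health metrics (must sum to 1)."""

    w1: float = 0.4   # BMI reduction
    w2: float = 0.3   # fitness improvement
    w3: float = 0.2   # calories burned
    w4: float = 0.1   # heart-rate reduction

    def __post_init__(self) -> None:
        ws = self.as_array()
        if np.any(ws < 0):
            raise HealthModelError("FitnessWeights: weights must be non-negative")
        if abs(float(ws.sum()) - 1.0) > SIMPLEX_TOL:
            raise HealthModelError(
                f"FitnessWeights: weights must sum to 1 (got {ws.sum():.6g})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4], dtype=float)


@dataclass
class Schedule:
    """One candidate weekly PE schedule (the decision vector)."""

    n_sessions: int
    t_session: float
    activity_mix: np.ndarray    # 5 proportions, order ACTIVITIES
    intensity_mix: np.ndarray   # 3 proportions, order INTENSITIES

    def __post_init__(self) -> None:
        self.activity_mix = np.asarray(self.activity_mix, dtype=float)
        self.intensity_mix = np.asarray(self.intensity_mix, dtype=float)
        if self.activity_mix.shape != (5,) or self.intensity_mix.shape != (3,):
            raise HealthModelError("Schedule: activity_mix must have 5 entries, intensity_mix 3")
        for name, mix in (("activity_mix", self.activity_mix),
                          ("intensity_mix", self.intensity_mix)):
            if np.any(mix < -SIMPLEX_TOL):
                raise HealthModelError(f"Schedule: {name} has negative entries")
            if abs(float(mix.sum()) - 1.0) > SIMPLEX_TOL:
                raise HealthModelError(f"Schedule: {name} must sum to 1 (got {mix.sum():.6g})")
        if self.n_sessions != int(self.n_sessions) or self.n_sessions < 0:
            raise HealthModelError("Schedule: n_sessions must be a non-negative integer")
        self.n_sessions = int(self.n_sessions)
        if self.t_session < 0:
            raise HealthModelError("Schedule: t_session must be non-negative")

    @property
    def weekly_hours(self) -> float:
        return self.n_sessions * self.t_session

    def to_dict(self) -> dict:
        return {
            "n_sessions": self.n_sessions,
            "t_session": self.t_session,
            "activity_mix": dict(zip(ACTIVITIES, map(float, self.activity_mix))),
            "intensity_mix": dict(zip(INTENSITIES, map(float, self.intensity_mix))),
            "weekly_hours": self.weekly_hours,
        }


@dataclass
class ResponseParams:
    """Dose–response coefficients mapping a schedule to predicted outcomes.

    horizon_weeks
        Programme horizon over which the energy balance accumulates into a
        BMI change (default 12, one school term).
    met_table
        (activity, intensity) → session-effective intensity multiplier.
    kcal_per_kg_fat
        Energy content of body fat (7700 kcal/kg convention).
    bmi_cap / f_gain_max / hr_drop_max
        Saturation ceilings for the three delta outcomes.
    k_f / k_h
        Saturation rates per weekly MVPA hour / weekly aerobic hour.
    """

    horizon_weeks: float = 12.0
    met_table: dict = field(default_factory=lambda: dict(DEFAULT_MET_TABLE))
    kcal_per_kg_fat: float = 7700.0
    bmi_cap: float = 2.5
    f_gain_max: float = 25.0
    k_f: float = 0.15
    hr_drop_max: float = 10.0
    k_h: float = 0.2

    def __post_init__(self) -> None:
        for name in ("horizon_weeks", "kcal_per_kg_fat", "bmi_cap",
                     "f_gain_max", "k_f", "hr_drop_max", "k_h"):
            if getattr(self, name) <= 0:
                raise HealthModelError(f"ResponseParams: {name} must be > 0")
        for a in ACTIVITIES:
            for i in INTENSITIES:
                if (a, i) not in self.met_table:
                    raise HealthModelError(f"ResponseParams: met_table missing entry ({a}, {i})")
                v = self.met_table[(a, i)]
                if not 1.0 <= v <= 15.0:
                    raise HealthModelError(
                        f"ResponseParams: MET value for ({a}, {i}) must lie in [1, 15], got {v}"
                    )

    def met_matrix(self) -> np.ndarray:
        """The MET table as a (5 activities × 3 intensities) array."""
        return np.array([[self.met_table[(a, i)] for i in INTENSITIES] for a in ACTIVITIES])


@dataclass(frozen=True)
class OutcomeVector:
    """Predicted health outcomes for one (student, schedule) pair."""

    delta_bmi: float   # kg/m²
    delta_f: float     # points
    calories: float    # kcal per session
    delta_hr: float    # bpm

    def as_array(self) -> np.ndarray:
        return np.array([self.delta_bmi, self.delta_f, self.calories, self.delta_hr])


@dataclass(frozen=True)
class MetricNorms:
    """Per-metric (lo, hi) decision-space bounds used to normalise outcomes.

    Raw calories (~10²) would otherwise swamp heart-rate change (~10⁰) in
    the weighted sum, making the 40/30/20/10 priorities meaningless.
    """

    delta_bmi: tuple[float, float] = (0.0, 2.5)
    delta_f: tuple[float, float] = (0.0, 25.0)
    calories: tuple[float, float] = (0.0, 500.0)
    delta_hr: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        for name in ("delta_bmi", "delta_f", "calories", "delta_hr"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise HealthModelError(f"MetricNorms: degenerate bounds for {name}: ({lo}, {hi})")

    @classmethod
    def from_params(cls, params: ResponseParams, calories_hi: float = 500.0) -> "MetricNorms":
        return cls(
            delta_bmi=(0.0, params.bmi_cap),
            delta_f=(0.0, params.f_gain_max),
            calories=(0.0, calories_hi),
            delta_hr=(0.0, params.hr_drop_max),
        )


# ---------------------------------------------------------------------------
# Closed-form metrics
# ---------------------------------------------------------------------------

def bmr(weight, height, age, sex):
    """Basal metabolic rate, kcal/day: ``10·W + 6.25·H − 5·A + S``.

    ``S`` is +5 for males and −161 for females. Accepts scalars or arrays;
    ``sex`` is "male"/"female" (or an array thereof).
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0) or np.any(age <= 0):
        raise HealthModelError("bmr: weight, height and age must be positive")
    sex_arr = np.asarray(sex)
    if not np.all(np.isin(sex_arr, SEXES)):
        bad = sex_arr[~np.isin(sex_arr, SEXES)]
        raise HealthModelError(f"bmr: sex must be one of {SEXES}, got {np.unique(bad)}")
    s_const = np.where(sex_arr == "male", 5.0, -161.0)
    out = 10.0 * weight + 6.25 * height - 5.0 * age + s_const
    return float(out) if out.ndim == 0 else out


def calories_burned(met, weight, t, bmr_value):
    """Per-session energy expenditure, kcal: ``MET · W · t · (1 + BMR/1000)``."""
    met = np.asarray(met, dtype=float)
    weight = np.asarray(weight, dtype=float)
    t = np.asarray(t, dtype=float)
    bmr_value = np.asarray(bmr_value, dtype=float)
    if np.any(met < 0) or np.any(t < 0) or np.any(weight < 0) or np.any(bmr_value < 0):
        raise HealthModelError("calories_burned: inputs must be non-negative")
    out = met * weight * t * (1.0 + bmr_value / 1000.0)
    return float(out) if out.ndim == 0 else out


def effective_met(schedule: Schedule, params: ResponseParams) -> float:
    """Mix-weighted session MET: activity_mix · M · intensity_mix."""
    m = params.met_matrix()
    return float(schedule.activity_mix @ m @ schedule.intensity_mix)


def optimal_pe_time(n_sessions, t_session, days_per_week: int = 7):
    """Weekly and daily PE hours for n sessions of t_session hours.

    Returns ``(weekly_hours, daily_hours)`` where daily hours spread the
    weekly total over ``days_per_week`` (5–7). Weekly hours are what the
    rest of the pipeline reports.
    """
    if n_sessions < 0:
        raise HealthModelError("optimal_pe_time: n_sessions must be >= 0")
    if not 5 <= days_per_week <= 7:
        raise HealthModelError("optimal_pe_time: days_per_week must lie in [5, 7]")
    weekly = n_sessions * t_session
    return weekly, weekly / days_per_week


# ---------------------------------------------------------------------------
# Dose–response prediction
# ---------------------------------------------------------------------------

def predict_outcomes(student, schedule: Schedule, params: ResponseParams) -> OutcomeVector:
    """Predicted outcomes for one student (mapping with weight_kg, height_cm, age, sex)."""
    w = float(student["weight_kg"])
    h_cm = float(student["height_cm"])
    bmr_v = bmr(w, h_cm, float(student["age"]), student["sex"])
    if schedule.n_sessions == 0 or schedule.t_session == 0:
        return OutcomeVector(0.0, 0.0, 0.0, 0.0)
    met = effective_met(schedule, params)
    cal = calories_burned(met, w, schedule.t_session, bmr_v)
    weekly_kcal = cal * schedule.n_sessions
    h_m2 = (h_cm / 100.0) ** 2
    d_bmi = min(params.bmi_cap,
                params.horizon_weeks * weekly_kcal / params.kcal_per_kg_fat / h_m2)
    weekly = schedule.weekly_hours
    mvpa_hours = weekly * float(schedule.intensity_mix[1] + schedule.intensity_mix[2])
    d_f = params.f_gain_max * (1.0 - math.exp(-params.k_f * mvpa_hours))
    aerobic_hours = weekly * float(schedule.activity_mix[0])
    d_hr = params.hr_drop_max * (1.0 - math.exp(-params.k_h * aerobic_hours))
    return OutcomeVector(d_bmi, d_f, cal, d_hr)


def predict_outcomes_frame(cohort: pd.DataFrame, schedule: Schedule,
                           params: ResponseParams) -> pd.DataFrame:
    """Vectorised :func:`predict_outcomes` over a cohort DataFrame."""
    if len(cohort) == 0:
        raise HealthModelError("predict_outcomes_frame: empty cohort")
    w = cohort["weight_kg"].to_numpy(dtype=float)
    h_cm = cohort["height_cm"].to_numpy(dtype=float)
    bmr_v = bmr(w, h_cm, cohort["age"].to_numpy(dtype=float),
                cohort["sex"].to_numpy())
    if schedule.n_sessions == 0 or schedule.t_session == 0:
        zero = np.zeros(len(cohort))
        return pd.DataFrame(
            {"delta_bmi": zero, "delta_f": zero, "calories": zero, "delta_hr": zero},
            index=cohort.index)
    met = effective_met(schedule, params)
    cal = calories_burned(met, w, schedule.t_session, bmr_v)
    weekly_kcal = cal * schedule.n_sessions
    h_m2 = (h_cm / 100.0) ** 2
    d_bmi = np.minimum(params.bmi_cap,
                       params.horizon_weeks * weekly_kcal / params.kcal_per_kg_fat / h_m2)
    weekly = schedule.weekly_hours
    mvpa = weekly * float(schedule.intensity_mix[1] + schedule.intensity_mix[2])
    d_f = params.f_gain_max * (1.0 - math.exp(-params.k_f * mvpa))
    aer = weekly * float(schedule.activity_mix[0])
    d_hr = params.hr_drop_max * (1.0 - math.exp(-params.k_h * aer))
    return pd.DataFrame(
        {"delta_bmi": d_bmi, "delta_f": np.full(len(cohort), d_f),
         "calories": cal, "delta_hr": np.full(len(cohort), d_hr)},
        index=cohort.index)


# ---------------------------------------------------------------------------
# Scalarisation
# ---------------------------------------------------------------------------

def _norm(x, lo: float, hi: float):
    # min-max against decision-space bounds, clipped so the score stays in
    # [0, 1] even when an outcome exceeds its nominal bound
    return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)


def weighted_fitness(outcomes: OutcomeVector, weights: FitnessWeights,
                     norms: MetricNorms) -> float:
    """Scalar health-fitness score in [0, 1] for one outcome vector."""
    parts = [
        _norm(outcomes.delta_bmi, *norms.delta_bmi),
        _norm(outcomes.delta_f, *norms.delta_f),
        _norm(outcomes.calories, *norms.calories),
        _norm(outcomes.delta_hr, *norms.delta_hr),
    ]
    return float(np.dot(weights.as_array(), parts))


def cohort_fitness(cohort: pd.DataFrame, schedule: Schedule, weights: FitnessWeights,
                   params: ResponseParams, norms: MetricNorms) -> float:
    """Mean per-student weighted fitness of a schedule over a cohort."""
    if len(cohort) == 0:
        raise HealthModelError("cohort_fitness: empty cohort")
    out = predict_outcomes_frame(cohort, schedule, params)
    score = (weights.w1 * _norm(out["delta_bmi"].to_numpy(), *norms.delta_bmi)
             + weights.w2 * _norm(out["delta_f"].to_numpy(), *norms.delta_f)
             + weights.w3 * _norm(out["calories"].to_numpy(), *norms.calories)
             + weights.w4 * _norm(out["delta_hr"].to_numpy(), *norms.delta_hr))
    return float(score.mean())
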