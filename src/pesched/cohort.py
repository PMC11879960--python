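"""Seeded synthetic student cohorts.

No real student dataset is distributed with this package, so cohorts are
synthesised: ages uniform over the requested range, heights from sex- and
age-conditional piecewise-linear growth means with additive noise, BMI from
an age-shifted right-skewed (lognormal) distribution, and weight derived as
``bmi · (height/100)²`` so the anthropometrics are mutually consistent.
Missing cells and extreme values can be injected on top so the downstream
imputation / outlier-removal stages are testable against a known ground
truth.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .health import DEFAULT_MET_TABLE, ACTIVITIES, INTENSITIES, bmr

#: Fixed cohort CSV column order. Missing cells are written as empty strings.
COLUMNS = (
    "id", "age", "sex", "height_cm", "weight_kg", "bmi", "fitness_score",
    "rhr_bpm", "pe_time_hr_wk", "session_frequency",
    "act_aerobic", "act_strength", "act_team", "act_flexibility", "act_recreational",
    "intensity_level", "caloric_expenditure_kcal", "instructor_ratio",
    "facility_utilization",
)

CATEGORICAL_COLUMNS = ("sex", "intensity_level")
NUMERIC_COLUMNS = tuple(c for c in COLUMNS if c not in ("id",) + CATEGORICAL_COLUMNS)

ACT_COLUMNS = tuple(f"act_{a}" for a in ACTIVITIES)

#: Columns eligible for missingness injection: everything except the id and
#: BMI (kept per record so every row retains an anthropometric anchor).
MISSING_ELIGIBLE = tuple(c for c in COLUMNS if c not in ("id", "bmi"))

#: Numeric columns eligible for outlier injection. Activity proportions and
#: session counts are excluded (bounded/categorical-like by construction).
OUTLIER_ELIGIBLE = (
    "height_cm", "weight_kg", "fitness_score", "rhr_bpm", "pe_time_hr_wk",
    "caloric_expenditure_kcal", "instructor_ratio", "facility_utilization",
)

# Piecewise-linear growth reference: mean height (cm) at the knot ages.
_KNOT_AGES = np.array([6.0, 10.0, 14.0, 18.0])
_KNOT_HEIGHT = {
    "male": np.array([116.0, 138.0, 163.0, 176.0]),
    "female": np.array([115.0, 138.0, 160.0, 163.0]),
}
_HEIGHT_SD = 5.5        # cm, around the age/sex mean
_BMI_MEDIAN_6 = 15.5    # kg/m² at age 6; median rises ~0.5 per year
_BMI_SLOPE = 0.5
_BMI_LOG_SD = 0.12      # lognormal shape → right skew


class CohortError(ValueError):
    """Invalid cohort specification or malformed cohort file."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort draw."""

    n_students: int = 1360
    seed: int = 0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    age_range: tuple[int, int] = (6, 18)
    sex_ratio: float = 0.5   # fraction male

    def __post_init__(self) -> None:
        if self.n_students < 1:
            raise CohortError("CohortSpec: n_students must be >= 1")
        for name in ("missing_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise CohortError(f"CohortSpec: {name} must lie in [0, 0.5], got {v}")
        lo, hi = self.age_range
        if not (6 <= lo <= hi <= 18):
            raise CohortError(f"CohortSpec: age_range must satisfy 6 <= lo <= hi <= 18, got {self.age_range}")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise CohortError(f"CohortSpec: sex_ratio must lie in [0, 1], got {self.sex_ratio}")


def _mean_height(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    out = np.empty(len(age))
    for s in ("male", "female"):
        m = sex == s
        out[m] = np.interp(age[m], _KNOT_AGES, _KNOT_HEIGHT[s])
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort of ``spec.n_students`` records (bit-reproducible per seed).

    Missingness/outlier injection requested via the spec is applied after
    the clean draw; the injection log is discarded here — call
    :func:`inject_missingness` / :func:`inject_outliers` directly when the
    log is needed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_students
    lo, hi = spec.age_range

    age = rng.integers(lo, hi + 1, size=n).astype(float)
    sex = np.where(rng.random(n) < spec.sex_ratio, "male", "female")
    height = _mean_height(age, sex) + rng.normal(0.0, _HEIGHT_SD, size=n)
    bmi_median = _BMI_MEDIAN_6 + _BMI_SLOPE * (age - 6.0)
    bmi = np.clip(bmi_median * np.exp(rng.normal(0.0, _BMI_LOG_SD, size=n)), 13.0, 40.0)
    weight = bmi * (height / 100.0) ** 2

    fitness = np.clip(rng.normal(60.0, 15.0, size=n), 5.0, 100.0)
    rhr = np.clip(85.0 - 1.2 * (age - 6.0) + rng.normal(0.0, 7.0, size=n), 50.0, 120.0)
    pe_time = np.clip(rng.normal(3.5, 1.0, size=n), 1.0, 8.0)
    freq = rng.integers(2, 6, size=n).astype(float)
    act = rng.dirichlet((2.5, 2.0, 2.0, 1.5, 2.0), size=n)
    intensity = rng.choice(INTENSITIES, size=n, p=(0.25, 0.5, 0.25))

    # Baseline per-session expenditure, self-consistent with the caloric model:
    # the student's own activity mix at their intensity level.
    met_col = {i: np.array([DEFAULT_MET_TABLE[(a, i)] for a in ACTIVITIES])
               for i in INTENSITIES}
    met = np.array([act[j] @ met_col[intensity[j]] for j in range(n)])
    bmr_v = bmr(weight, height, age, sex)
    kcal = met * weight * (pe_time / freq) * (1.0 + bmr_v / 1000.0)

    df = pd.DataFrame({
        "id": [f"S{j:05d}" for j in range(n)],
        "age": age,
        "sex": sex,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "fitness_score": fitness,
        "rhr_bpm": rhr,
        "pe_time_hr_wk": pe_time,
        "session_frequency": freq,
        **{col: act[:, k] for k, col in enumerate(ACT_COLUMNS)},
        "intensity_level": intensity,
        "caloric_expenditure_kcal": kcal,
        "instructor_ratio": rng.uniform(15.0, 40.0, size=n),
        "facility_utilization": rng.beta(5.0, 2.0, size=n),
    }, columns=list(COLUMNS))

    if spec.missing_rate > 0:
        df = inject_missingness(df, spec.missing_rate, seed=spec.seed + 1)
    if spec.outlier_rate > 0:
        df, _ = inject_outliers(df, spec.outlier_rate, seed=spec.seed + 2)
    return df


def inject_missingness(cohort: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank exactly ``round(rate·n)`` cells per eligible feature (MCAR).

    ``id`` and ``bmi`` are never blanked. Returns a copy.
    """
    if not 0.0 <= rate <= 0.5:
        raise CohortError(f"inject_missingness: rate must lie in [0, 0.5], got {rate}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    k = int(round(rate * n))
    for col in MISSING_ELIGIBLE:
        rows = rng.permutation(n)[:k]
        if col in CATEGORICAL_COLUMNS:
            out[col] = out[col].astype(object)
            out.iloc[rows, out.columns.get_loc(col)] = None
        else:
            out.iloc[rows, out.columns.get_loc(col)] = np.nan
    return out


def inject_outliers(cohort: pd.DataFrame, rate: float, seed: int,
                    columns: tuple[str, ...] | None = None):
    """Displace exactly ``round(rate·n)`` cells per eligible numeric feature.

    Injected values are moved at least 3.5 interquartile ranges away from
    the feature median (computed on the incoming values), which puts them
    outside any Tukey fence with k ≤ 2 on large cohorts. Categorical
    features are untouched by contract; ``columns`` restricts injection to
    a subset of the eligible numeric features.

    Returns ``(cohort_copy, log)`` where ``log`` is a list of
    ``(student_id, column)`` pairs naming every injected cell.
    """
    if not 0.0 <= rate <= 0.5:
        raise CohortError(f"inject_outliers: rate must lie in [0, 0.5], got {rate}")
    targets = OUTLIER_ELIGIBLE if columns is None else tuple(columns)
    bad_cols = [c for c in targets if c not in OUTLIER_ELIGIBLE]
    if bad_cols:
        raise CohortError(f"inject_outliers: column(s) {bad_cols} not eligible "
                          f"(numeric features only: {OUTLIER_ELIGIBLE})")
    out = cohort.copy()
    log: list[tuple[str, str]] = []
    if rate == 0.0:
        return out, log
    rng = np.random.default_rng(seed)
    n = len(out)
    k = int(round(rate * n))
    for col in targets:
        vals = out[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        q1, med, q3 = np.quantile(finite, [0.25, 0.5, 0.75])
        iqr = max(q3 - q1, 1e-6 * max(1.0, abs(med)))
        rows = rng.permutation(n)[:k]
        sign = rng.choice([-1.0, 1.0], size=k)
        mag = 3.5 + rng.exponential(1.0, size=k)
        out.iloc[rows, out.columns.get_loc(col)] = med + sign * mag * iqr
        log.extend((out["id"].iloc[r], col) for r in rows)
    return out, log


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort with the fixed header; missing cells become empty strings."""
    cohort.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the header and every numeric cell.

    Raises :class:`CohortError` naming the offending column (unknown or
    missing header fields) or row/column (non-numeric cell).
    """
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"read_cohort_csv: {path} is empty") from exc
    unknown = [c for c in raw.columns if c not in COLUMNS]
    if unknown:
        raise CohortError(f"read_cohort_csv: unknown column(s) {unknown}")
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise CohortError(f"read_cohort_csv: missing column(s) {missing_cols}")
    out = pd.DataFrame()
    out["id"] = raw["id"]
    for col in COLUMNS[1:]:
        s = raw[col].replace("", None)
        if col in CATEGORICAL_COLUMNS:
            out[col] = s.astype(object)
            continue
        num = pd.to_numeric(s, errors="coerce")
        bad = num.isna() & s.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortError(
                f"read_cohort_csv: non-numeric value {raw[col].iloc[row]!r} "
                f"in column {col!r}, row {row}")
        out[col] = num.astype(float)
    return out[list(COLUMNS)]
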