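"""Data-refinement chain: imputation, IQR outlier removal, scaling, encoding.

The pipeline order is fixed: mean/mode imputation first (so fences are
computed on complete data), then record-wise removal of IQR outliers, with
min–max scaling parameters and one-hot category orders estimated on the
surviving records. :func:`preprocess_cohort` returns the cleaned cohort in
original units together with a :class:`PreprocessReport`;
:func:`transform_features` applies the stored scaling/encoding to produce a
numeric model matrix. Re-running the pipeline on its own output with the
stored report is the identity.

Quartiles use linear interpolation of order statistics (numpy's default
quantile rule).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_COLUMNS, NUMERIC_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_ORDERS = {
    "sex": ("male", "female"),
    "intensity_level": ("low", "moderate", "vigorous"),
}

#: Numeric features screened for outliers by default. Activity proportions
#: and session counts are bounded by construction and are not screened.
DEFAULT_IQR_FEATURES = (
    "height_cm", "weight_kg", "fitness_score", "rhr_bpm", "pe_time_hr_wk",
    "caloric_expenditure_kcal", "instructor_ratio", "facility_utilization",
)


class PreprocessError(ValueError):
    """Invalid input to a preprocessing stage."""


@dataclass(frozen=True)
class PreprocessConfig:
    iqr_k: float = 1.5
    iqr_features: tuple[str, ...] = DEFAULT_IQR_FEATURES
    category_orders: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_ORDERS))


@dataclass
class PreprocessReport:
    """Bookkeeping of one preprocessing pass (JSON-serialisable)."""

    n_in: int
    n_out: int
    imputed_cells_by_feature: dict
    imputation_values: dict
    removed_records: list          # [{"id": ..., "features": [...]}]
    fences: dict                   # feature -> (lo, hi)
    scaling_params: dict           # feature -> (xmin, xmax)
    encoded_features: dict         # feature -> category order

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)

    @classmethod
    def from_json(cls, path) -> "PreprocessReport":
        with open(path) as fh:
            d = json.load(fh)
        d["fences"] = {k: tuple(v) for k, v in d["fences"].items()}
        d["scaling_params"] = {k: tuple(v) for k, v in d["scaling_params"].items()}
        d["encoded_features"] = {k: tuple(v) for k, v in d["encoded_features"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def impute_mean(values: pd.Series, fill_value: float | None = None) -> pd.Series:
    """Replace missing entries with the mean of the non-missing ones."""
    s = pd.to_numeric(values, errors="raise")
    if fill_value is None:
        if s.notna().sum() == 0:
            raise PreprocessError(f"impute_mean: all values missing in {values.name!r}")
        fill_value = float(s.mean())
    return s.fillna(fill_value)


def impute_mode(values: pd.Series, fill_value=None) -> pd.Series:
    """Replace missing entries with the most frequent category.

    Ties are broken by first occurrence order in the series.
    """
    s = values
    present = s.dropna()
    if fill_value is None:
        if len(present) == 0:
            raise PreprocessError(f"impute_mode: all values missing in {values.name!r}")
        counts: dict = {}
        for v in present:            # insertion order = first occurrence
            counts[v] = counts.get(v, 0) + 1
        fill_value = max(counts, key=counts.get)   # ties -> earliest key
    return s.fillna(fill_value)


def iqr_filter(values, k: float = 1.5, fences: tuple[float, float] | None = None):
    """Tukey-fence partition of a numeric series.

    Returns ``(kept_idx, flagged_idx, (lo, hi))`` with positional indices.
    Flagged iff value < Q1 − k·IQR or value > Q3 + k·IQR; quartiles use
    linear interpolation of order statistics.
    """
    x = np.asarray(values, dtype=float)
    if fences is None:
        if len(x) < 4:
            raise PreprocessError(f"iqr_filter: need at least 4 values, got {len(x)}")
        q1, q3 = np.quantile(x, [0.25, 0.75])
        iqr = q3 - q1
        fences = (q1 - k * iqr, q3 + k * iqr)
    lo, hi = fences
    flagged = np.flatnonzero((x < lo) | (x > hi))
    kept = np.flatnonzero((x >= lo) & (x <= hi))
    return kept, flagged, (float(lo), float(hi))


def min_max_scale(x, xmin: float, xmax: float):
    """Eq.-style min–max scaling ``(x − xmin)/(xmax − xmin)``.

    Degenerate features (xmax == xmin) scale to 0.0 with a logged warning.
    """
    if xmax < xmin:
        raise PreprocessError(f"min_max_scale: xmax ({xmax}) < xmin ({xmin})")
    x = np.asarray(x, dtype=float)
    if xmax == xmin:
        logger.warning("min_max_scale: degenerate feature (xmin == xmax == %s)", xmin)
        out = np.zeros_like(x)
    else:
        out = (x - xmin) / (xmax - xmin)
    return float(out) if out.ndim == 0 else out


def one_hot_encode(values, category_order) -> np.ndarray:
    """Binary indicator matrix with columns in ``category_order``."""
    cats = list(category_order)
    arr = np.asarray(values, dtype=object)
    unseen = sorted({v for v in arr if v not in cats})
    if unseen:
        raise PreprocessError(f"one_hot_encode: unseen categor{'ies' if len(unseen) > 1 else 'y'} {unseen}")
    idx = np.array([cats.index(v) for v in arr])
    out = np.zeros((len(arr), len(cats)), dtype=int)
    out[np.arange(len(arr)), idx] = 1
    return out


# ---------------------------------------------------------------------------
# Whole-cohort pipeline
# ---------------------------------------------------------------------------

def preprocess_cohort(cohort: pd.DataFrame, config: PreprocessConfig | None = None,
                      report: PreprocessReport | None = None):
    """Impute and outlier-filter a cohort; estimate scaling/encoding params.

    When ``report`` is given its stored imputation values, fences and
    scaling parameters are re-applied instead of re-estimated, which makes
    a second pass over the pipeline's own output the identity.

    Returns ``(clean_cohort, PreprocessReport)`` with the clean cohort in
    original units; apply :func:`transform_features` for the scaled/encoded
    matrix.
    """
    if len(cohort) == 0:
        raise PreprocessError("preprocess_cohort: empty cohort")
    config = config or PreprocessConfig()
    df = cohort.copy()

    # stage 1: imputation (mean for numeric, mode for categorical)
    imputed_counts: dict[str, int] = {}
    imputation_values: dict[str, object] = {}
    try:
        for col in NUMERIC_COLUMNS:
            n_missing = int(df[col].isna().sum())
            stored = report.imputation_values.get(col) if report else None
            fill = float(stored) if stored is not None else float(df[col].mean())
            if n_missing and stored is None and df[col].notna().sum() == 0:
                raise PreprocessError(f"impute_mean: all values missing in {col!r}")
            df[col] = impute_mean(df[col], fill_value=fill)
            imputation_values[col] = fill
            if n_missing:
                imputed_counts[col] = n_missing
        for col in CATEGORICAL_COLUMNS:
            n_missing = int(df[col].isna().sum())
            stored = report.imputation_values.get(col) if report else None
            if stored is not None:
                fill = stored
            else:
                if df[col].notna().sum() == 0:
                    raise PreprocessError(f"impute_mode: all values missing in {col!r}")
                fill = _mode_of(df[col])
            df[col] = impute_mode(df[col], fill_value=fill)
            imputation_values[col] = fill
            if n_missing:
                imputed_counts[col] = n_missing
    except PreprocessError as exc:
        raise PreprocessError(f"imputation stage: {exc}") from exc

    # stage 2: record-wise IQR outlier removal
    fences: dict[str, tuple[float, float]] = {}
    flagged_by_record: dict[int, list[str]] = {}
    try:
        for col in config.iqr_features:
            stored = report.fences.get(col) if report else None
            _, flagged, f = iqr_filter(df[col].to_numpy(), k=config.iqr_k, fences=stored)
            fences[col] = f
            for pos in flagged:
                flagged_by_record.setdefault(int(pos), []).append(col)
    except PreprocessError as exc:
        raise PreprocessError(f"outlier stage: {exc}") from exc
    removed = [{"id": df["id"].iloc[pos], "features": cols}
               for pos, cols in sorted(flagged_by_record.items())]
    keep_mask = np.ones(len(df), dtype=bool)
    keep_mask[list(flagged_by_record)] = False
    clean = df.iloc[keep_mask].reset_index(drop=True)

    # stage 3/4 parameters: min-max ranges and category orders on survivors
    if report is not None:
        scaling = dict(report.scaling_params)
    else:
        scaling = {col: (float(clean[col].min()), float(clean[col].max()))
                   for col in NUMERIC_COLUMNS}
    encoded = {col: tuple(config.category_orders[col]) for col in CATEGORICAL_COLUMNS}

    new_report = PreprocessReport(
        n_in=len(cohort), n_out=len(clean),
        imputed_cells_by_feature=imputed_counts,
        imputation_values=imputation_values,
        removed_records=removed,
        fences=fences, scaling_params=scaling, encoded_features=encoded,
    )
    assert new_report.n_in == new_report.n_out + len(removed)
    return clean, new_report


def _mode_of(s: pd.Series):
    counts: dict = {}
    for v in s.dropna():
        counts[v] = counts.get(v, 0) + 1
    return max(counts, key=counts.get)


def transform_features(cohort: pd.DataFrame, report: PreprocessReport) -> pd.DataFrame:
    """Scaled + one-hot-encoded model matrix for a clean cohort."""
    out = pd.DataFrame(index=cohort.index)
    for col in NUMERIC_COLUMNS:
        xmin, xmax = report.scaling_params[col]
        out[col] = min_max_scale(cohort[col].to_numpy(), xmin, xmax)
    for col, order in report.encoded_features.items():
        enc = one_hot_encode(cohort[col], order)
        for j, cat in enumerate(order):
            out[f"{col}_{cat}"] = enc[:, j]
    out.insert(0, "id", cohort["id"].to_numpy())
    return out
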