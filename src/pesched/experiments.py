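"""Study designs: convergence comparison, multi-metric summary with
confidence intervals, weight-sensitivity analysis, and algorithm ranking.

All experiments share one cohort, decision space and evaluation budget
(population × iterations) across algorithms so comparisons are fair; a
guard rejects mismatched budgets. Replicate runs differ only in their
seeds, and confidence intervals are normal-approximation
``mean ± z·SD/√n`` half-widths over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import optimize
from .health import (FitnessWeights, MetricNorms, ResponseParams, Schedule,
                     bmr as _bmr)
from .optimize import (ALGORITHMS, DecisionSpace, Grid, OptimizerConfig,
                       OptimizerError, RunResult)

METRICS = ("pe_time_hr_wk", "delta_bmi", "fitness_score",
           "calories_kcal_session", "delta_hr_bpm")


class ExperimentError(ValueError):
    """Invalid experiment setup."""


# ---------------------------------------------------------------------------
# Objective construction
# ---------------------------------------------------------------------------

def make_cohort_objective(cohort: pd.DataFrame, weights: FitnessWeights,
                          params: ResponseParams, norms: MetricNorms):
    """Batch objective: encoded candidates (m, 10) → mean per-student
    weighted fitness (m,). Fully vectorised over candidates × students."""
    if len(cohort) == 0:
        raise ExperimentError("make_cohort_objective: empty cohort")
    w_kg = cohort["weight_kg"].to_numpy(dtype=float)
    h2 = (cohort["height_cm"].to_numpy(dtype=float) / 100.0) ** 2
    bmr_v = _bmr(w_kg, cohort["height_cm"].to_numpy(dtype=float),
                 cohort["age"].to_numpy(dtype=float), cohort["sex"].to_numpy())
    met_m = params.met_matrix()
    bfac = 1.0 + bmr_v / 1000.0
    (bmi_lo, bmi_hi), (f_lo, f_hi) = norms.delta_bmi, norms.delta_f
    (cal_lo, cal_hi), (hr_lo, hr_hi) = norms.calories, norms.delta_hr
    ws = weights.as_array()

    def objective(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        t = X[:, optimize.IDX_T]
        n = X[:, optimize.IDX_N]
        act = X[:, optimize.SL_ACT]
        inten = X[:, optimize.SL_INT]
        met = np.einsum("ma,ai,mi->m", act, met_m, inten)
        cal = met[:, None] * w_kg[None, :] * t[:, None] * bfac[None, :]   # (m, s)
        weekly_kcal = cal * n[:, None]
        d_bmi = np.minimum(params.bmi_cap,
                           params.horizon_weeks * weekly_kcal
                           / params.kcal_per_kg_fat / h2[None, :])
        weekly = n * t
        d_f = params.f_gain_max * (1.0 - np.exp(-params.k_f * weekly * (inten[:, 1] + inten[:, 2])))
        d_hr = params.hr_drop_max * (1.0 - np.exp(-params.k_h * weekly * act[:, 0]))
        score = (ws[0] * np.clip((d_bmi - bmi_lo) / (bmi_hi - bmi_lo), 0, 1)
                 + ws[1] * np.clip((d_f - f_lo) / (f_hi - f_lo), 0, 1)[:, None]
                 + ws[2] * np.clip((cal - cal_lo) / (cal_hi - cal_lo), 0, 1)
                 + ws[3] * np.clip((d_hr - hr_lo) / (hr_hi - hr_lo), 0, 1)[:, None])
        return score.mean(axis=1)

    return objective


def summarize_outcomes(cohort: pd.DataFrame, schedule: Schedule,
                       params: ResponseParams) -> dict:
    """Cohort-mean outcomes of a schedule on the five reported metrics."""
    from .health import predict_outcomes_frame
    out = predict_outcomes_frame(cohort, schedule, params)
    return {
        "pe_time_hr_wk": schedule.weekly_hours,
        "delta_bmi": float(out["delta_bmi"].mean()),
        "fitness_score": float((cohort["fitness_score"] + out["delta_f"]).mean()),
        "calories_kcal_session": float(out["calories"].mean()),
        "delta_hr_bpm": float(out["delta_hr"].mean()),
    }


# ---------------------------------------------------------------------------
# Running algorithms under a shared budget
# ---------------------------------------------------------------------------

def _run_one(algo: str, objective, space: DecisionSpace, grid: Grid | None,
             config: OptimizerConfig) -> RunResult:
    if algo not in ALGORITHMS:
        raise ExperimentError(f"unknown algorithm {algo!r}; choose from {sorted(ALGORITHMS)}")
    if algo == "aco":
        return ALGORITHMS[algo](objective, grid if grid is not None else
                                space.discretize(), config)
    return ALGORITHMS[algo](objective, space, config)


def _budget_guard(configs: dict) -> None:
    budgets = {a: c.population * c.iterations for a, c in configs.items()}
    if len(set(budgets.values())) > 1:
        raise ExperimentError(f"mismatched evaluation budgets across algorithms: {budgets}")


def run_algorithms(cohort: pd.DataFrame, algorithms, space: DecisionSpace,
                   config, weights: FitnessWeights,
                   params: ResponseParams, norms: MetricNorms,
                   seed: int | None = None, grid: Grid | None = None) -> dict:
    """Run each named algorithm once on the cohort objective; fill in the
    cohort-mean outcome summary at each best schedule.

    ``config`` is one shared :class:`OptimizerConfig` or a per-algorithm
    mapping; per-algorithm configs must agree on the population×iterations
    evaluation budget (fair-comparison guard).
    """
    if isinstance(config, OptimizerConfig):
        configs = {a: config for a in algorithms}
    else:
        missing = [a for a in algorithms if a not in config]
        if missing:
            raise ExperimentError(f"run_algorithms: no config for {missing}")
        configs = {a: config[a] for a in algorithms}
    if seed is not None:
        configs = {a: replace(c, seed=seed) for a, c in configs.items()}
    _budget_guard(configs)
    objective = make_cohort_objective(cohort, weights, params, norms)
    results = {}
    for algo in algorithms:
        res = _run_one(algo, objective, space, grid, configs[algo])
        res.outcome_summary = summarize_outcomes(cohort, res.best_schedule, params)
        results[algo] = res
    return results


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def convergence_experiment(cohort: pd.DataFrame, algorithms, space: DecisionSpace,
                           config: OptimizerConfig, weights: FitnessWeights,
                           params: ResponseParams, norms: MetricNorms,
                           seeds=(0,), grid: Grid | None = None) -> pd.DataFrame:
    """Best-so-far trajectories, long format:
    (algorithm, seed, iteration, best_so_far)."""
    rows = []
    for seed in seeds:
        results = run_algorithms(cohort, algorithms, space, config, weights,
                                 params, norms, seed=seed, grid=grid)
        for algo, res in results.items():
            rows.append(pd.DataFrame({
                "algorithm": algo, "seed": seed,
                "iteration": np.arange(1, len(res.trajectory) + 1),
                "best_so_far": res.trajectory,
            }))
    return pd.concat(rows, ignore_index=True)


@dataclass
class SummaryTable:
    """Per-algorithm mean ± CI half-width on the five health metrics."""

    table: pd.DataFrame          # index algorithm; columns metric / metric_hw
    n_replicates: int
    confidence: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_dict(self) -> dict:
        return {"n_replicates": self.n_replicates, "confidence": self.confidence,
                "table": self.table.to_dict(orient="index")}


def summary_experiment(cohort: pd.DataFrame, algorithms, space: DecisionSpace,
                       config: OptimizerConfig, weights: FitnessWeights,
                       params: ResponseParams, norms: MetricNorms,
                       n_replicates: int = 10, confidence: float = 0.95,
                       seeds=None, grid: Grid | None = None) -> SummaryTable:
    """Replicated runs per algorithm; mean and normal-approximation CI
    half-width per metric. ``seeds`` (one per replicate, shared across
    algorithms) defaults to 0..n_replicates−1."""
    if n_replicates < 2:
        raise ExperimentError("summary_experiment: n_replicates must be >= 2")
    if seeds is None:
        seeds = list(range(n_replicates))
    if len(seeds) != n_replicates:
        raise ExperimentError("summary_experiment: len(seeds) must equal n_replicates")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    per_algo: dict[str, list[dict]] = {a: [] for a in algorithms}
    for seed in seeds:
        results = run_algorithms(cohort, algorithms, space, config, weights,
                                 params, norms, seed=seed, grid=grid)
        for algo, res in results.items():
            per_algo[algo].append(res.outcome_summary)
    rows = {}
    for algo in algorithms:
        vals = pd.DataFrame(per_algo[algo])
        row = {}
        for m in METRICS:
            x = vals[m].to_numpy(dtype=float)
            sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
            row[m] = float(x.mean())
            row[f"{m}_hw"] = z * sd / np.sqrt(len(x))
        rows[algo] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[list(algorithms)]
    return SummaryTable(table=table, n_replicates=n_replicates, confidence=confidence)


@dataclass
class SensitivityReport:
    """Effect of perturbing the BMI weight w1 on the optimised metrics.

    Indices are baseline-100 ratios of optimised cohort-mean ΔBMI / ΔF
    under perturbed vs baseline weights; calories and heart-rate reduction
    are reported in natural units. The 0% row is exactly 100/baseline by
    construction.
    """

    table: pd.DataFrame          # index: weight change in percent

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def to_dict(self) -> dict:
        return self.table.to_dict(orient="index")


def perturb_weights(weights: FitnessWeights, delta: float) -> FitnessWeights:
    """Scale w1 by (1+δ) and renormalise w2..w4 proportionally."""
    if delta <= -1.0:
        raise ExperimentError("perturb_weights: delta must be > -100%")
    w1 = weights.w1 * (1.0 + delta)
    if w1 >= 1.0:
        raise ExperimentError(f"perturb_weights: perturbed w1 = {w1:.3f} >= 1")
    rest = 1.0 - weights.w1
    scale = (1.0 - w1) / rest
    return FitnessWeights(w1, weights.w2 * scale, weights.w3 * scale,
                          weights.w4 * scale)


def sensitivity_experiment(cohort: pd.DataFrame, space: DecisionSpace,
                           config: OptimizerConfig, weights: FitnessWeights,
                           params: ResponseParams, norms: MetricNorms,
                           perturbations=(-0.05, 0.05), algorithm: str = "aco",
                           seeds=(0, 1, 2), grid: Grid | None = None) -> SensitivityReport:
    """Weight-sensitivity analysis (same algorithm and seeds at every
    weight setting)."""
    deltas = sorted(set(perturbations) | {0.0})

    def metrics_at(w: FitnessWeights) -> dict:
        acc = {m: 0.0 for m in ("delta_bmi", "delta_f", "calories", "delta_hr")}
        for seed in seeds:
            res = run_algorithms(cohort, [algorithm], space, config, w, params,
                                 norms, seed=seed, grid=grid)[algorithm]
            s = res.outcome_summary
            acc["delta_bmi"] += s["delta_bmi"]
            acc["calories"] += s["calories_kcal_session"]
            acc["delta_hr"] += s["delta_hr_bpm"]
            acc["delta_f"] += s["fitness_score"] - float(cohort["fitness_score"].mean())
        return {k: v / len(seeds) for k, v in acc.items()}

    base = metrics_at(weights)
    rows = {}
    for d in deltas:
        m = base if d == 0.0 else metrics_at(perturb_weights(weights, d))
        rows[round(d * 100, 6)] = {
            "bmi_priority_index": 100.0 * m["delta_bmi"] / base["delta_bmi"],
            "caloric_expenditure_kcal_session": m["calories"],
            "fitness_score_index": 100.0 * m["delta_f"] / base["delta_f"],
            "hr_reduction_bpm": m["delta_hr"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "weight_change_pct"
    return SensitivityReport(table=table)


def rank_algorithms(summary: SummaryTable) -> pd.DataFrame:
    """Per-metric ranking (1 = best). Every metric is higher-is-better;
    ties break alphabetically by algorithm name."""
    t = summary.table
    missing = [m for m in METRICS if m not in t.columns or t[m].isna().any()]
    if missing:
        raise ExperimentError(f"rank_algorithms: missing or incomplete metrics {missing}")
    ranks = pd.DataFrame(index=sorted(t.index), columns=list(METRICS), dtype=int)
    for m in METRICS:
        order = sorted(t.index, key=lambda a: (-t.loc[a, m], a))
        for r, a in enumerate(order, start=1):
            ranks.loc[a, m] = r
    return ranks
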