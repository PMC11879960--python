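# pesched

Metaheuristic optimisation of weekly school physical-education (PE)
schedules against a weighted multi-metric health fitness function.

School PE time is usually allocated by convention rather than by expected
health benefit. `pesched` treats the weekly schedule — number of sessions
`n`, session length `t`, and the activity and intensity mixes — as a
decision vector and searches for the schedule that maximises a scalar
health score over a student cohort. It is aimed at public-health and
operations-research practitioners who want a reproducible, testable
implementation of this study design: synthetic cohort → preprocessing →
health model → six optimisers → comparison/sensitivity experiments.

## The model

For each student, four predicted outcomes of a candidate schedule are
combined into one score:

* **BMI reduction** ΔBMI, from the energy balance of the added weekly
  expenditure (7700 kcal/kg-fat convention, capped);
* **fitness gain** ΔF = F_max·(1 − e^(−k_f·MVPA hours/week));
* **per-session calories** = MET_eff · W · t · (1 + BMR/1000), with
  BMR = 10·W + 6.25·H − 5·A + S (S = +5 male, −161 female) and MET_eff the
  mix-weighted session intensity multiplier;
* **resting-heart-rate drop** ΔHR = HR_max·(1 − e^(−k_h·aerobic hours/week)).

Each metric is min–max normalised against its decision-space bounds and
scalarised as

    f(x) = w₁·ΔBMI′ + w₂·ΔF′ + w₃·Cal′ + w₄·ΔHR′,  w = (0.4, 0.3, 0.2, 0.1)

and the cohort objective is the mean per-student score. Six optimisers —
GA, PSO, ACO, SA, DE and ABC — maximise it under a shared budget
(population 30 × 200 iterations), with an exhaustive-search oracle for
testing on discretised spaces. See `docs/methods.md` for the full model,
calibration and algorithm details.

## Worked example

```python
import pesched as ps

cohort = ps.generate_cohort(ps.CohortSpec(n_students=300, seed=1))
clean, report = ps.preprocess_cohort(cohort)
print(f"cohort: {report.n_in} students, {report.n_out} after outlier removal")

res = ps.run_algorithms(clean, ["aco"], ps.DecisionSpace(),
                        ps.OptimizerConfig(seed=0), ps.FitnessWeights(),
                        ps.ResponseParams(), ps.MetricNorms())["aco"]
s = res.best_schedule
print(f"best fitness: {res.best_fitness:.4f}")
print(f"schedule: {s.n_sessions} sessions x {s.t_session:.2f} h "
      f"= {s.weekly_hours:.2f} h/week")
for k, v in res.outcome_summary.items():
    print(f"  {k}: {v:.2f}")
```

prints

```
cohort: 300 students, 279 after outlier removal
best fitness: 0.7017
schedule: 7 sessions x 1.43 h = 10.00 h/week
  pe_time_hr_wk: 10.00
  delta_bmi: 1.59
  fitness_score: 80.28
  calories_kcal_session: 334.38
  delta_hr_bpm: 8.65
```

Reading: ant colony optimisation allocates the full 10 h/week cap as seven
vigorous, aerobic-dominant ~1.4 h sessions. Over a 12-week term the model
predicts a cohort-mean BMI reduction of 1.59 kg/m², a final fitness score
of 80.3 points (baseline ≈ 60 plus the predicted gain), ≈334 kcal expended
per session, and an 8.7 bpm drop in resting heart rate. The fitness value
0.70 is the normalised weighted score in [0, 1].

The same pipeline is available from the shell:

```bash
pesched run --seed 2 --out runs/demo          # synth -> preprocess -> compare -> sensitivity
pesched optimize --algo aco --out runs/demo
pesched config show                           # effective defaults as YAML
```

Every run directory receives the cohort CSVs, a preprocessing report, the
summary/sensitivity tables (CSV + JSON), convergence trajectories, the
effective config and a MANIFEST — enough to reproduce the run bit for bit.

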