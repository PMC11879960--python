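# Methods

`pesched` evaluates and optimises weekly school physical-education (PE)
schedules against a scalar health-fitness score computed over a student
cohort. This note documents the model, its assumptions and calibration, the
synthetic cohort, the optimisers, and the numerical choices, in enough
detail to reproduce or re-parameterise every result the package prints.

## The decision space

A schedule is the vector

* `n_sessions` — PE sessions per week, integer 1–7;
* `t_session`  — session length, hours, default bounds [0.5, 1.5];
* `activity_mix` — proportions of session time on aerobic, strength, team,
  flexibility and recreational activity (5-simplex);
* `intensity_mix` — proportions at low, moderate, vigorous intensity
  (3-simplex);

subject to a weekly cap `n·t ≤ T_max` (default 10 h/week). The bounds are a
modelling choice, not an observed constraint: 0.5–1.5 h brackets realistic
school periods, and the 10 h cap was chosen so that optimised weekly time
presses against ≈10 h/week, the magnitude reported for programmes of this
kind. Constraints are handled by *repair* — clip `t`, round and clip `n`,
clip negative mix entries and renormalise each simplex to sum 1, and shorten
`t` to `T_max/n` when the cap is exceeded — never by penalty terms, so
fitness values remain comparable across optimisers.

## Per-student outcome model

For a student with weight `W` (kg), height `H` (cm), age `A` and sex-specific
constant `S` (+5 male, −161 female), basal metabolic rate is the linear
Mifflin-style form

    BMR = 10·W + 6.25·H − 5·A + S              [kcal/day]

and per-session expenditure is

    Calories = MET_eff · W · t_session · (1 + BMR/1000)   [kcal]

where `MET_eff = activity_mixᵀ · M · intensity_mix` is the mix-weighted
entry of a 5×3 intensity-multiplier table `M`.

**Calibration of `M`.** The `(1 + BMR/1000)` factor is ≈2.2–2.5 for
school-age students, so the table entries are *session-net* intensity
multipliers rather than instantaneous compendium METs: they absorb within-
session rest and transition time and are scaled so that a vigorous aerobic
1-hour session for a median-build 14-year-old expends ≈280–320 kcal, the
magnitude reported for school PE sessions. Orderings follow field
convention (aerobic > team > strength > recreational > flexibility;
vigorous > moderate > low); defaults run from 1.1 (flexibility, low) to 2.5
(aerobic, vigorous) and are fully overridable through the run config.

**Dose–response layer.** Observed before/after differences are not
available for candidate schedules, so predicted deltas come from a
transparent, monotone, bounded closed form (`ResponseParams`):

* ΔBMI — energy balance: weekly kcal × `horizon_weeks` (default 12, one
  school term) ÷ 7700 kcal/kg fat ÷ height², capped at `bmi_cap`
  (default 2.5 kg/m²);
* ΔF — fitness-score gain: `f_gain_max·(1 − exp(−k_f · weekly MVPA hours))`
  with MVPA hours = weekly hours × (moderate + vigorous share); defaults
  `f_gain_max` 25 points, `k_f` 0.15 per MVPA-hour/week;
* ΔHR — resting-heart-rate drop: `hr_drop_max·(1 − exp(−k_h · weekly
  aerobic hours))`; defaults 10 bpm and 0.2 per aerobic-hour/week, which
  put the optimised drop near 8.6 bpm, the reported scale.

These are population-level curves: a single global parameter set, no
individual heterogeneity in response, no longitudinal dynamics.

## Scalarisation

Raw calories (~10²) would swamp ΔHR (~10⁰), so each metric is min–max
scaled against fixed decision-space bounds (`MetricNorms`; ΔBMI and the two
saturating deltas against their caps, calories against 0–500 kcal) and
clipped to [0, 1], then combined as

    f = w1·ΔBMI′ + w2·ΔF′ + w3·Cal′ + w4·ΔHR′

with default weights 0.4/0.3/0.2/0.1 (BMI first: childhood-obesity
priority). The cohort objective is the mean of per-student scores — the
per-student-then-mean order matters because the response is nonlinear in
height and weight.

A consequence worth knowing: with the default calibration all four metrics
are maximised by the same schedule (vigorous, aerobic-dominant, weekly
hours at the cap), so ±5% weight perturbations move the optimum little or
not at all and the sensitivity indices sit at 100. The direction
inequalities (more BMI weight ⇒ BMI priority ≥ 100, fitness index ≤ 100)
hold, with equality in the fully converged case.

## Synthetic cohort

No real student data ships with the package. `generate_cohort` draws, per
seeded record: integer age uniform on [6, 18]; sex Bernoulli(`sex_ratio`);
height from a sex-conditional piecewise-linear growth mean (knots at ages
6/10/14/18, e.g. 116→176 cm for boys) plus N(0, 5.5 cm); BMI lognormal
around an age-rising median (15.5 kg/m² at 6, +0.5/yr, shape 0.12, clipped
to [13, 40]) so the distribution is right-skewed; weight derived as
`bmi·(H/100)²` so the anthropometrics are exactly consistent; fitness score
N(60, 15) clipped to [5, 100]; resting heart rate declining ~1.2 bpm/yr
from 85 bpm with N(0, 7) noise, clipped to [50, 120]; Dirichlet activity
mix; categorical intensity (25/50/25); and a baseline per-session
expenditure computed with the caloric model itself.

Missingness is injected completely at random and outliers by displacing
cells ≥3.5 IQR from the feature median; both pick an exact count of cells
per feature (`round(rate·n)`) so injected fractions are exact, and both are
logged so the preprocessing stage can be tested against ground truth.

What the generator does **not** emulate: real covariance between fitness,
BMI and activity; informative missingness; measurement error structure;
school-level clustering. Passing tests therefore demonstrate correctness of
the pipeline's mechanics and calibration plausibility, not predictive
validity on real cohorts.

## Preprocessing

Stage order is fixed: mean/mode imputation first (fences are then computed
on complete data), record-wise removal of any record with a feature outside
the Tukey fences `[Q1 − k·IQR, Q3 + k·IQR]` (k = 1.5; quartiles by linear
interpolation of order statistics — the rule the brute-force test oracle
replicates), then min–max scaling parameters and one-hot category orders
estimated on the survivors. Mode-imputation ties break by first occurrence;
degenerate scaling ranges map to 0 with a logged warning. The report stores
imputation values, fences and scaling parameters; re-running the pipeline
on its own output with the stored report is the identity, and
`transform_features` applies the stored transforms to produce the numeric
model matrix. Bounded-by-construction columns (activity proportions,
session counts) are not screened for outliers.

## Optimisers

All six maximise the same batch objective over the 10-dimensional encoded
vector under a shared budget (population 30 × 200 iterations by default;
an explicit guard rejects mismatched budgets in comparisons). Defaults are
standard literature values, overridable per run:

* **GA** — tournament (size 3) selection, per-gene blend crossover
  (p = 0.9), Gaussian mutation (p = 0.1, σ = 0.1 × range), elitism 1.
* **PSO** — inertia 0.7, cognitive = social = 1.5, velocity clamped to
  0.5 × range, positions clipped; particles evolve continuously and are
  repaired only for evaluation.
* **ACO** — works on a discretised view (per-variable level grids); ants
  pick levels with probability ∝ τ^α·η^β (α = β = 1, η uninformative by
  default, user hook provided); evaporation ρ = 0.1; the top 10% of each
  iteration deposit `Q·(f − f_worst)/(f_best − f_worst)` — range-normalised
  so deposits stay positive for negative-valued objectives and vanish when
  there is no fitness signal; τ floored at 1e−12.
* **SA** — as many independent chains as the population (so the budget
  matches), Gaussian proposals (σ = 0.15 × range), Metropolis acceptance
  `exp(−ΔE/T)`, geometric cooling T ← 0.95·T from T₀ = 1.
* **DE** — rand/1/bin, F = 0.5, CR = 0.9, one guaranteed donor component,
  greedy selection.
* **ABC** — food sources = population/2; employed and onlooker phases spend
  exactly one population of evaluations per iteration (a scout
  re-initialisation is charged against the next iteration's onlooker
  budget); abandonment limit 20.

Every run records a non-decreasing best-so-far trajectory (length =
iterations) and the exact evaluation count, bounded by
`population × iterations + population`. A wrapper around the objective
asserts feasibility of every evaluated candidate (bounds, integer session
count, simplex sums to 1e−9, weekly cap).

The `exhaustive_oracle` enumerates every point of a discretised space
(≤10⁶) with deterministic lexicographic tie-breaking; it is the ground
truth for the optimiser tests. The oracle-equivalence benchmark uses seeded
separable concave objectives on a 140-point grid: basin-shaped landscapes
of the kind the per-algorithm recovery checks assume. On deceptive coupled
landscapes (e.g. a `t·n` product valley) the factored ACO representation
and converged populations can settle one grid cell away from the argmax —
a known limitation, not exercised by the default study.

## Experiments and reporting

* **Convergence** — per-algorithm, per-seed best-so-far trajectories in
  long-format CSV.
* **Summary** — replicated runs (default 10; seeds shared across
  algorithms), reporting weekly PE time, cohort-mean ΔBMI, fitness score
  (baseline + ΔF), per-session calories and ΔHR, each as mean ±
  `z·SD/√n` normal-approximation half-width (95% by default).
* **Sensitivity** — the BMI weight w1 is scaled by (1 + δ), δ ∈ {−5%, +5%},
  with w2..w4 renormalised proportionally; the same algorithm (ACO) and
  seeds run at every setting; ΔBMI and ΔF are reported as baseline-100
  indices, calories and ΔHR in natural units. The δ = 0 row is exactly 100
  by construction.
* **Ranking** — per-metric ranks (all metrics higher-is-better), ties
  broken alphabetically.

Reproducibility: one global seed deterministically spawns per-stage and
per-replicate sub-seeds through numpy's `SeedSequence` (all below 2³¹);
every run directory contains the effective config and a manifest.

## Problem sizes

Default pipeline runs use the full 30 × 200 budget per optimisation. The
bundled acceptance script uses a 500-student cohort (the generator's
default is 1,360) and 3 replicates per algorithm; the oracle-equivalence
check runs 100 seeds × 6 algorithms at the full budget on the 140-point
grid. These sizes were chosen as the smallest at which the replicate CIs
and success-rate statements are meaningful.

## Known limitations

* The dose–response layer is a deliberately simple closed form; its caps
  and rates are calibration targets, not estimates from data.
* ΔBMI magnitudes from energy balance over one term (~1.6 kg/m²) are far
  below the ~10-unit reductions sometimes quoted for such programmes; the
  package reports what the stated energy arithmetic yields.
* Because the four metrics share a maximiser under the default calibration,
  weight-sensitivity effects are degenerate (indices pin at 100); a
  response model with competing objectives would be needed to reproduce
  larger swings.
* SA is the weakest explorer at the shared budget, consistent with its
  last-place ranking in comparative studies of this design.
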