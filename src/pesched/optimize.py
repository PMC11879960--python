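"""Six metaheuristics over the weekly-PE-schedule decision space.

All algorithms maximise a batch objective ``f(X) -> (m,)`` over a unified
real-vector encoding of length 10:

    ``[t_session, n_sessions, a1..a5, i1..i3]``

where ``a`` and ``i`` are the activity and intensity simplex coordinates.
Constraints are handled by repair (clip bounds, round the session count,
renormalise simplexes, clamp the weekly-hours cap), never by penalties, so
fitness values stay comparable across algorithms. Ant colony optimisation
and the exhaustive test oracle operate on a discretised view of the same
space.

Every run records the best-so-far fitness per iteration (non-decreasing by
construction) and the exact number of objective evaluations, bounded by
``population × iterations + population``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .health import Schedule

DIM = 10
IDX_T, IDX_N = 0, 1
SL_ACT = slice(2, 7)
SL_INT = slice(7, 10)
SIMPLEX_TOL = 1e-9


class OptimizerError(ValueError):
    """Invalid optimiser configuration or decision space."""


# ---------------------------------------------------------------------------
# Decision space, encoding and repair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionSpace:
    """Bounds and constraints of the schedule decision space.

    Defaults: 0.5–1.5 h sessions, 1–7 sessions/week, 10 h/week cap — a
    reconstruction chosen so reported weekly optima press against ~10 h.
    """

    t_bounds: tuple[float, float] = (0.5, 1.5)
    n_range: tuple[int, int] = (1, 7)
    max_weekly_hours: float = 10.0

    def __post_init__(self) -> None:
        t_min, t_max = self.t_bounds
        if t_min < 0 or t_min > t_max:
            raise OptimizerError(f"DecisionSpace: invalid t_bounds {self.t_bounds}")
        n_min, n_max = self.n_range
        if n_min < 0 or n_min > n_max:
            raise OptimizerError(f"DecisionSpace: invalid n_range {self.n_range}")
        if self.max_weekly_hours < t_max:
            raise OptimizerError(
                f"DecisionSpace: max_weekly_hours ({self.max_weekly_hours}) "
                f"must be >= t_max ({t_max})")

    # -- encoding ----------------------------------------------------------

    def repair(self, X: np.ndarray) -> np.ndarray:
        """Map arbitrary real vectors onto feasible schedules (copy)."""
        X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        X[:, IDX_T] = np.clip(X[:, IDX_T], *self.t_bounds)
        X[:, IDX_N] = np.clip(np.rint(X[:, IDX_N]), *self.n_range)
        for sl, k in ((SL_ACT, 5), (SL_INT, 3)):
            m = np.clip(X[:, sl], 0.0, None)
            s = m.sum(axis=1, keepdims=True)
            uniform = np.full(k, 1.0 / k)
            X[:, sl] = np.where(s > 0, m / np.where(s > 0, s, 1.0), uniform)
        # weekly cap: shorten sessions rather than dropping them
        over = X[:, IDX_T] * X[:, IDX_N] > self.max_weekly_hours
        X[over, IDX_T] = self.max_weekly_hours / X[over, IDX_N]
        return X

    def sample(self, rng: np.random.Generator, m: int) -> np.ndarray:
        """m feasible schedules drawn uniformly (simplexes via Dirichlet(1))."""
        X = np.empty((m, DIM))
        X[:, IDX_T] = rng.uniform(*self.t_bounds, size=m)
        X[:, IDX_N] = rng.integers(self.n_range[0], self.n_range[1] + 1, size=m)
        X[:, SL_ACT] = rng.dirichlet(np.ones(5), size=m)
        X[:, SL_INT] = rng.dirichlet(np.ones(3), size=m)
        return self.repair(X)

    def is_feasible(self, X: np.ndarray, tol: float = SIMPLEX_TOL) -> np.ndarray:
        X = np.atleast_2d(X)
        ok = (X[:, IDX_T] >= self.t_bounds[0] - tol)
        ok &= X[:, IDX_T] <= self.t_bounds[1] + tol
        ok &= np.abs(X[:, IDX_N] - np.rint(X[:, IDX_N])) <= tol
        ok &= (X[:, IDX_N] >= self.n_range[0]) & (X[:, IDX_N] <= self.n_range[1])
        ok &= np.abs(X[:, SL_ACT].sum(axis=1) - 1.0) <= tol
        ok &= np.abs(X[:, SL_INT].sum(axis=1) - 1.0) <= tol
        ok &= np.all(X[:, SL_ACT] >= -tol, axis=1) & np.all(X[:, SL_INT] >= -tol, axis=1)
        ok &= X[:, IDX_T] * X[:, IDX_N] <= self.max_weekly_hours + 1e-6
        return ok

    def decode(self, x: np.ndarray) -> Schedule:
        x = np.asarray(x, dtype=float).ravel()
        return Schedule(
            n_sessions=int(round(x[IDX_N])), t_session=float(x[IDX_T]),
            activity_mix=x[SL_ACT].copy(), intensity_mix=x[SL_INT].copy())

    def discretize(self, t_levels: int = 11, mix_levels: int = 5,
                   mix_values: np.ndarray | None = None) -> "Grid":
        """Discretised view: t on a uniform grid, n on integers, each simplex
        coordinate on ``mix_levels`` levels (repair renormalises).

        ``mix_values`` freezes all eight mix coordinates to the given
        8-vector (single-level variables), which is how small test spaces
        are built.
        """
        t_min, t_max = self.t_bounds
        levels: list[np.ndarray] = [np.linspace(t_min, t_max, t_levels),
                                    np.arange(self.n_range[0], self.n_range[1] + 1, dtype=float)]
        if mix_values is not None:
            mix_values = np.asarray(mix_values, dtype=float).ravel()
            levels += [np.array([v]) for v in mix_values]
        else:
            levels += [np.linspace(0.0, 1.0, mix_levels) for _ in range(8)]
        return Grid(space=self, levels=levels)


@dataclass
class Grid:
    """Per-variable level values of a discretised decision space."""

    space: DecisionSpace
    levels: list    # DIM arrays of level values

    def __post_init__(self) -> None:
        if len(self.levels) != DIM:
            raise OptimizerError(f"Grid: need {DIM} level arrays, got {len(self.levels)}")
        self.levels = [np.asarray(v, dtype=float) for v in self.levels]

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(v) for v in self.levels)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def assemble(self, idx: np.ndarray) -> np.ndarray:
        """Index tuples (m, DIM) -> raw (unrepaired) vectors (m, DIM)."""
        idx = np.atleast_2d(idx)
        return np.column_stack([self.levels[v][idx[:, v]] for v in range(DIM)])

    def snap(self, X: np.ndarray) -> np.ndarray:
        """Nearest grid point per variable (raw values, no repair)."""
        X = np.atleast_2d(X)
        out = np.empty_like(X, dtype=float)
        for v in range(DIM):
            lv = self.levels[v]
            if len(lv) == 1:
                out[:, v] = lv[0]
            else:
                out[:, v] = lv[np.argmin(np.abs(X[:, v][:, None] - lv[None, :]), axis=1)]
        return out


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizerConfig:
    """Shared budget plus per-algorithm hyperparameters.

    Population 30 and 200 iterations are the study's shared budget; the
    remaining defaults are standard literature values, all overridable.
    """

    population: int = 30
    iterations: int = 200
    seed: int = 0
    # GA
    ga_crossover_prob: float = 0.9
    ga_mutation_prob: float = 0.1
    ga_mutation_scale: float = 0.1     # fraction of each variable's range
    ga_tournament: int = 3
    ga_elitism: int = 1
    # PSO
    pso_inertia: float = 0.7
    pso_c1: float = 1.5
    pso_c2: float = 1.5
    pso_vclamp: float = 0.5            # fraction of each variable's range
    # ACO
    aco_alpha: float = 1.0
    aco_beta: float = 1.0
    aco_rho: float = 0.1
    aco_q: float = 1.0
    # SA
    sa_t0: float = 1.0
    sa_gamma: float = 0.95
    sa_chains: int | None = None       # None -> population (shared budget)
    sa_step: float = 0.15              # fraction of each variable's range
    # DE
    de_f: float = 0.5
    de_cr: float = 0.9
    # ABC
    abc_limit: int = 20

    def __post_init__(self) -> None:
        if self.population < 2:
            raise OptimizerError("OptimizerConfig: population must be >= 2")
        if self.iterations < 1:
            raise OptimizerError("OptimizerConfig: iterations must be >= 1")
        for name in ("ga_crossover_prob", "ga_mutation_prob", "de_cr"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise OptimizerError(f"OptimizerConfig: {name} must lie in [0, 1]")
        if not 0.0 < self.aco_rho <= 1.0:
            raise OptimizerError("OptimizerConfig: aco_rho must lie in (0, 1]")
        if not 0.0 < self.sa_gamma < 1.0:
            raise OptimizerError("OptimizerConfig: sa_gamma must lie in (0, 1)")
        if self.sa_t0 <= 0:
            raise OptimizerError("OptimizerConfig: sa_t0 must be > 0")
        if self.sa_chains is not None and self.sa_chains < 1:
            raise OptimizerError("OptimizerConfig: sa_chains must be >= 1")
        if self.abc_limit < 1:
            raise OptimizerError("OptimizerConfig: abc_limit must be >= 1")


@dataclass
class RunResult:
    """Outcome of one optimiser run."""

    algorithm: str
    seed: int
    best_schedule: Schedule
    best_x: np.ndarray
    best_fitness: float
    trajectory: np.ndarray       # best-so-far per iteration
    evaluations: int
    outcome_summary: dict | None = None
    diagnostics: dict | None = None   # per-algorithm debug counters

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "seed": self.seed,
            "best_schedule": self.best_schedule.to_dict(),
            "best_fitness": self.best_fitness,
            "evaluations": self.evaluations,
            "iterations": len(self.trajectory),
            "outcome_summary": self.outcome_summary,
        }


class CountingObjective:
    """Wraps a batch objective: counts evaluations, checks feasibility."""

    def __init__(self, fn, space: DecisionSpace, check: bool = True):
        self.fn = fn
        self.space = space
        self.check = check
        self.evaluations = 0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if self.check:
            ok = self.space.is_feasible(X)
            if not np.all(ok):
                bad = X[~ok][0]
                raise OptimizerError(f"infeasible candidate evaluated: {bad}")
        self.evaluations += len(X)
        f = np.asarray(self.fn(X), dtype=float)
        if f.shape != (len(X),):
            raise OptimizerError(f"objective returned shape {f.shape}, expected ({len(X)},)")
        return f


def _bounds_arrays(space: DecisionSpace) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([space.t_bounds[0], space.n_range[0]] + [0.0] * 8)
    hi = np.array([space.t_bounds[1], space.n_range[1]] + [1.0] * 8)
    return lo, hi


def _finish(name, cfg, obj, best_x, best_f, traj, space,
            diagnostics: dict | None = None) -> RunResult:
    traj = np.asarray(traj, dtype=float)
    assert len(traj) == cfg.iterations and np.all(np.diff(traj) >= 0)
    return RunResult(
        algorithm=name, seed=cfg.seed, best_schedule=space.decode(best_x),
        best_x=np.asarray(best_x, dtype=float).copy(), best_fitness=float(best_f),
        trajectory=traj, evaluations=obj.evaluations, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# Genetic Algorithm
# ---------------------------------------------------------------------------

def run_ga(objective, space: DecisionSpace, config: OptimizerConfig) -> RunResult:
    """Real-valued GA: tournament selection, blend crossover, Gaussian
    mutation, elitism of ``ga_elitism``."""
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    P, lo, hi = config.population, *_bounds_arrays(space)
    span = hi - lo
    X = space.sample(rng, P)
    f = obj(X)
    best = int(np.argmax(f))
    best_x, best_f = X[best].copy(), f[best]
    traj = []
    for _ in range(config.iterations):
        # tournament selection of P parents
        contenders = rng.integers(0, P, size=(P, config.ga_tournament))
        parents = contenders[np.arange(P), np.argmax(f[contenders], axis=1)]
        children = X[parents].copy()
        # pairwise blend crossover
        for a in range(0, P - 1, 2):
            if rng.random() < config.ga_crossover_prob:
                u = rng.random(DIM)
                p, q = children[a].copy(), children[a + 1].copy()
                children[a] = u * p + (1 - u) * q
                children[a + 1] = u * q + (1 - u) * p
        # Gaussian mutation per gene
        mask = rng.random((P, DIM)) < config.ga_mutation_prob
        children = children + mask * rng.normal(0.0, config.ga_mutation_scale, (P, DIM)) * span
        children = space.repair(children)
        # elitism: overwrite the first slots with the current best members
        elite_idx = np.argsort(f)[::-1][:config.ga_elitism]
        children[:config.ga_elitism] = X[elite_idx]
        X = children
        f = obj(X)
        it_best = int(np.argmax(f))
        if f[it_best] > best_f:
            best_x, best_f = X[it_best].copy(), f[it_best]
        traj.append(best_f)
    return _finish("ga", config, obj, best_x, best_f, traj, space)


# ---------------------------------------------------------------------------
# Particle Swarm Optimisation
# ---------------------------------------------------------------------------

def run_pso(objective, space: DecisionSpace, config: OptimizerConfig) -> RunResult:
    """Global-best PSO with inertia, velocity clamping and bound clipping.

    Positions evolve continuously; candidates are repaired (rounded /
    renormalised) only for evaluation.
    """
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    P, (lo, hi) = config.population, _bounds_arrays(space)
    span = hi - lo
    vmax = config.pso_vclamp * span
    X = space.sample(rng, P)
    V = np.zeros((P, DIM))
    f = obj(X)
    pbest_x, pbest_f = X.copy(), f.copy()
    g = int(np.argmax(f))
    best_x, best_f = X[g].copy(), f[g]
    traj = []
    for _ in range(config.iterations):
        r1, r2 = rng.random((P, DIM)), rng.random((P, DIM))
        V = (config.pso_inertia * V
             + config.pso_c1 * r1 * (pbest_x - X)
             + config.pso_c2 * r2 * (best_x[None, :] - X))
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, lo, hi)
        Xr = space.repair(X)
        f = obj(Xr)
        improved = f > pbest_f
        pbest_x[improved], pbest_f[improved] = Xr[improved], f[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > best_f:
            best_x, best_f = pbest_x[g].copy(), pbest_f[g]
        traj.append(best_f)
    return _finish("pso", config, obj, best_x, best_f, traj, space)


# ---------------------------------------------------------------------------
# Ant Colony Optimisation (discretised space)
# ---------------------------------------------------------------------------

def run_aco(objective, space_or_grid, config: OptimizerConfig,
            eta: list | None = None) -> RunResult:
    """ACO over a discretised space: each ant picks one level per variable
    with probability ∝ τ^α · η^β; pheromone evaporates each iteration and
    the iteration's best ants deposit proportionally to (range-normalised)
    fitness. η defaults to uninformative (all ones).
    """
    if isinstance(space_or_grid, DecisionSpace):
        raise OptimizerError("run_aco: requires a discretised space (Grid); "
                             "call space.discretize() first")
    grid: Grid = space_or_grid
    space = grid.space
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    P = config.population
    tau = [np.ones(k) for k in grid.shape]
    if eta is None:
        eta = [np.ones(k) for k in grid.shape]
    eta = [np.asarray(e, dtype=float) for e in eta]
    n_best = max(1, P // 10)
    best_x, best_f = None, -np.inf
    f_lo, f_hi = np.inf, -np.inf
    level_counts = [np.zeros(k, dtype=int) for k in grid.shape]
    traj = []
    for _ in range(config.iterations):
        idx = np.empty((P, DIM), dtype=int)
        for v in range(DIM):
            w = tau[v] ** config.aco_alpha * eta[v] ** config.aco_beta
            p = w / w.sum()
            idx[:, v] = rng.choice(len(p), size=P, p=p)
            np.add.at(level_counts[v], idx[:, v], 1)
        X = space.repair(grid.assemble(idx))
        f = obj(X)
        f_lo, f_hi = min(f_lo, float(f.min())), max(f_hi, float(f.max()))
        it_best = int(np.argmax(f))
        if f[it_best] > best_f:
            best_x, best_f = X[it_best].copy(), f[it_best]
        # evaporation + deposit from the iteration's best ants
        order = np.argsort(f)[::-1][:n_best]
        scale = f_hi - f_lo
        for v in range(DIM):
            tau[v] *= (1.0 - config.aco_rho)
        # no deposit without a fitness signal (scale == 0): complete
        # evaporation on a constant objective then keeps sampling uniform
        for a in order:
            amount = config.aco_q * ((f[a] - f_lo) / scale if scale > 0 else 0.0)
            for v in range(DIM):
                tau[v][idx[a, v]] += amount
        for v in range(DIM):
            np.maximum(tau[v], 1e-12, out=tau[v])
        traj.append(best_f)
    return _finish("aco", config, obj, best_x, best_f, traj, space,
                   diagnostics={"level_counts": level_counts})


# ---------------------------------------------------------------------------
# Simulated Annealing
# ---------------------------------------------------------------------------

def sa_accept(delta_e: float, temperature: float) -> float:
    """Metropolis acceptance probability: ``exp(−ΔE/T)`` for a worsening
    move (ΔE > 0), 1 otherwise."""
    if temperature <= 0:
        raise OptimizerError("sa_accept: temperature must be > 0")
    if delta_e <= 0:
        return 1.0
    return float(np.exp(-delta_e / temperature))


def run_sa(objective, space: DecisionSpace, config: OptimizerConfig) -> RunResult:
    """``sa_chains`` independent annealing chains (default 30, matching the
    shared population budget), Gaussian proposals, geometric cooling
    ``T ← γ·T``."""
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    C, (lo, hi) = config.sa_chains or config.population, _bounds_arrays(space)
    span = hi - lo
    X = space.sample(rng, C)
    f = obj(X)
    best = int(np.argmax(f))
    best_x, best_f = X[best].copy(), f[best]
    T = config.sa_t0
    traj = []
    for _ in range(config.iterations):
        prop = space.repair(X + rng.normal(0.0, config.sa_step, (C, DIM)) * span)
        fp = obj(prop)
        delta = f - fp                       # > 0 when the proposal is worse
        accept = (delta <= 0) | (rng.random(C) < np.exp(-np.maximum(delta, 0.0) / T))
        X[accept], f[accept] = prop[accept], fp[accept]
        it_best = int(np.argmax(f))
        if f[it_best] > best_f:
            best_x, best_f = X[it_best].copy(), f[it_best]
        T *= config.sa_gamma
        traj.append(best_f)
    return _finish("sa", config, obj, best_x, best_f, traj, space)


# ---------------------------------------------------------------------------
# Differential Evolution
# ---------------------------------------------------------------------------

def de_mutate(x_r1, x_r2, x_r3, f_scale: float) -> np.ndarray:
    """DE/rand/1 donor ``v = x_r1 + F·(x_r2 − x_r3)`` (raw; repair is
    applied to the trial vector by the DE loop)."""
    return np.asarray(x_r1, dtype=float) + f_scale * (
        np.asarray(x_r2, dtype=float) - np.asarray(x_r3, dtype=float))


def de_crossover(target, donor, cr: float, rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover: each component comes from the donor with
    probability CR, with one uniformly-chosen component guaranteed from the
    donor so the trial differs from the target."""
    if not 0.0 <= cr <= 1.0:
        raise OptimizerError("de_crossover: CR must lie in [0, 1]")
    target = np.asarray(target, dtype=float)
    donor = np.asarray(donor, dtype=float)
    mask = rng.random(len(target)) < cr
    mask[rng.integers(len(target))] = True
    return np.where(mask, donor, target)


def run_de(objective, space: DecisionSpace, config: OptimizerConfig) -> RunResult:
    """DE/rand/1/bin with greedy selection."""
    if config.population < 4:
        raise OptimizerError("run_de: population must be >= 4 for distinct donors")
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    P = config.population
    X = space.sample(rng, P)
    f = obj(X)
    best = int(np.argmax(f))
    best_x, best_f = X[best].copy(), f[best]
    traj = []
    for _ in range(config.iterations):
        trials = np.empty_like(X)
        for i in range(P):
            r1, r2, r3 = rng.choice([j for j in range(P) if j != i], size=3, replace=False)
            donor = de_mutate(X[r1], X[r2], X[r3], config.de_f)
            trials[i] = de_crossover(X[i], donor, config.de_cr, rng)
        trials = space.repair(trials)
        ft = obj(trials)
        better = ft >= f
        X[better], f[better] = trials[better], ft[better]
        it_best = int(np.argmax(f))
        if f[it_best] > best_f:
            best_x, best_f = X[it_best].copy(), f[it_best]
        traj.append(best_f)
    return _finish("de", config, obj, best_x, best_f, traj, space)


# ---------------------------------------------------------------------------
# Artificial Bee Colony
# ---------------------------------------------------------------------------

def run_abc(objective, space: DecisionSpace, config: OptimizerConfig) -> RunResult:
    """ABC with employed / onlooker / scout phases.

    Food sources number ``population // 2``; employed plus onlooker
    evaluations total ``population`` per iteration, and each scout
    re-initialisation is charged against the next iteration's onlooker
    budget so the overall budget bound holds exactly. Sources failing to
    improve for ``abc_limit`` trials are re-initialised by a scout.
    """
    obj = CountingObjective(objective, space)
    rng = np.random.default_rng(config.seed)
    P = config.population
    S = max(2, P // 2)
    X = space.sample(rng, S)
    f = obj(X)
    trials = np.zeros(S, dtype=int)
    best = int(np.argmax(f))
    best_x, best_f = X[best].copy(), f[best]
    debt = 0                      # scout evaluations owed from last iteration
    scout_events = 0
    traj = []

    def try_neighbor(i: int) -> None:
        nonlocal best_x, best_f
        j = rng.integers(DIM)
        k = rng.integers(S - 1)
        k = k if k < i else k + 1
        v = X[i].copy()
        v[j] = v[j] + rng.uniform(-1.0, 1.0) * (X[i][j] - X[k][j])
        v = space.repair(v)[0]
        fv = obj(v[None, :])[0]
        if fv > f[i]:
            X[i], f[i] = v, fv
            trials[i] = 0
        else:
            trials[i] += 1
        if fv > best_f:
            best_x, best_f = v.copy(), fv

    for _ in range(config.iterations):
        for i in range(S):                       # employed phase
            try_neighbor(i)
        shifted = f - f.min() + 1e-12            # onlooker phase
        p = shifted / shifted.sum()
        n_onlookers = max(0, P - S - debt)
        for i in rng.choice(S, size=n_onlookers, p=p):
            try_neighbor(int(i))
        debt = 0
        worst = int(np.argmax(trials))           # scout phase (at most one)
        if trials[worst] > config.abc_limit:
            X[worst] = space.sample(rng, 1)[0]
            f[worst] = obj(X[worst][None, :])[0]
            trials[worst] = 0
            debt = 1
            scout_events += 1
            if f[worst] > best_f:
                best_x, best_f = X[worst].copy(), f[worst]
        traj.append(best_f)
    return _finish("abc", config, obj, best_x, best_f, traj, space,
                   diagnostics={"scout_events": scout_events})


# ---------------------------------------------------------------------------
# Exhaustive oracle
# ---------------------------------------------------------------------------

MAX_ORACLE_POINTS = 1_000_000


def exhaustive_oracle(objective, grid: Grid, batch: int = 4096):
    """Exact argmax over every grid point (deterministic lexicographic
    tie-break on level indices). Errors if the grid exceeds 10⁶ points."""
    n = grid.n_points
    if n > MAX_ORACLE_POINTS:
        raise OptimizerError(f"exhaustive_oracle: grid has {n} points (> {MAX_ORACLE_POINTS})")
    obj = CountingObjective(objective, grid.space)
    best_f, best_x = -np.inf, None
    ranges = [np.arange(k) for k in grid.shape]
    it = itertools.product(*ranges)
    while True:
        chunk = list(itertools.islice(it, batch))
        if not chunk:
            break
        idx = np.array(chunk, dtype=int)
        X = grid.space.repair(grid.assemble(idx))
        fvals = obj(X)
        j = int(np.argmax(fvals))            # first max = lexicographic tie-break
        if fvals[j] > best_f:
            best_f, best_x = float(fvals[j]), X[j].copy()
    return best_x, best_f


ALGORITHMS = {
    "ga": run_ga, "pso": run_pso, "aco": run_aco,
    "sa": run_sa, "de": run_de, "abc": run_abc,
}
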