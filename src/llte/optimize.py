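"""Constrained shape optimization of the foot design variables.

Minimizes the lower-leg trajectory error over the free design variables
under three constraints: variable bounds, no self-intersection of the thick
geometry, and peak stress below the flexural yield divided by a prescribed
safety factor (default 1.75, covering unmodelled loading).

Constraint handling is by static penalties: candidates outside bounds or
with self-intersecting geometry short-circuit (no structural analysis) to a
large penalty ranked by violation magnitude; stress violations add
``weight * (max_stress/allowable - 1)`` on top of the trajectory error, so
that slightly-overstressed designs still rank by their kinematic quality.

The optimizer is a real-coded genetic algorithm (genes scaled to [0, 1] by
the bounds, tournament selection of size 3, blend crossover, per-gene
Gaussian mutation, single-individual elitism) and is bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analytic import AnalyticFoot, analytic_llte
from .engine import FootModel, PoseSolverOptions, compute_llte, compute_trajectory
from .gait import (NINE_INSTANCE_PERCENTS, ReferenceGait, UserCharacteristics,
                   resample_stance)
from .parametrization import (DesignBounds, GeometryError, check_self_intersection,
                              complete_design, default_bounds, evaluate_geometry)
from .solver import Material

__all__ = [
    "OptimizationConfig",
    "ConstraintReport",
    "OptimizationResult",
    "FEAObjective",
    "AnalyticObjective",
    "evaluate_candidate",
    "optimize_design",
    "grid_search",
    "compare_instance_sets",
    "InstanceSetComparison",
]

_SHORT_CIRCUIT_PENALTY = 1.0e3  # dominates any feasible trajectory error


@dataclass(frozen=True)
class OptimizationConfig:
    population: int = 50
    generations: int = 60
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15  # per gene
    mutation_sigma: float = 0.1  # in [0,1] gene space
    blend_alpha: float = 0.5
    tournament_size: int = 3
    seed: int = 0
    safety_factor: float = 1.75
    stress_penalty_weight: float = 10.0
    elitism: int = 1

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be at least 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.safety_factor < 1.0:
            raise ValueError("safety factor must be >= 1")


@dataclass(frozen=True)
class ConstraintReport:
    max_stress: float  # Pa (nan when not evaluated)
    stress_ok: bool
    self_intersects: bool
    bounds_ok: bool
    failed_frames: int

    @property
    def feasible(self) -> bool:
        return (self.stress_ok and self.bounds_ok
                and not self.self_intersects and self.failed_frames == 0)


@dataclass
class OptimizationResult:
    best_vars: np.ndarray
    best_objective: float
    best_report: ConstraintReport
    history_best: np.ndarray  # per generation
    history_median: np.ndarray
    seed: int
    config: OptimizationConfig


# ---------------------------------------------------------------------------
# objective contexts


class FEAObjective:
    """Full-pipeline objective: 11 design variables -> LLTE via FEA."""

    def __init__(self, user: UserCharacteristics, ref: ReferenceGait,
                 material: Material, percents=NINE_INSTANCE_PERCENTS,
                 bounds: DesignBounds | None = None,
                 n_elements: int = 300, width: float = 0.060,
                 pose_opts: PoseSolverOptions | None = None):
        self.user = user
        self.ref = ref
        self.material = material
        self.percents = tuple(percents)
        self.bounds = bounds or default_bounds(user)
        self.n_elements = n_elements
        self.width = width
        self.pose_opts = pose_opts or PoseSolverOptions()
        self.cases = resample_stance(ref, self.percents)

    def with_percents(self, percents) -> "FEAObjective":
        return FEAObjective(self.user, self.ref, self.material, percents,
                            self.bounds, self.n_elements, self.width, self.pose_opts)

    def geometry_invalid(self, vars_) -> bool:
        try:
            design = complete_design(vars_, self.user)
            geom = evaluate_geometry(design)
        except GeometryError:
            return True
        return bool(check_self_intersection(geom))

    def evaluate_raw(self, vars_):
        design = complete_design(vars_, self.user)
        model = FootModel(design, self.material, self.user,
                          n_elements=self.n_elements, width=self.width)
        traj = compute_trajectory(design, self.material, self.cases, self.user,
                                  opts=self.pose_opts, model=model)
        llte = compute_llte(traj, self.ref, traj.percents)
        stresses = traj.max_stress[np.isfinite(traj.max_stress)]
        max_s = float(stresses.max()) if stresses.size else np.nan
        failed = int(np.sum(~traj.converged))
        return llte.value, max_s, failed


class AnalyticObjective:
    """Reduced objective: 2 thickness scales -> LLTE via the closed-form model."""

    def __init__(self, ref: ReferenceGait, percents=NINE_INSTANCE_PERCENTS,
                 base: AnalyticFoot | None = None,
                 bounds: DesignBounds | None = None,
                 scale_bounds=(0.5, 2.0)):
        self.ref = ref
        self.percents = tuple(percents)
        self.base = base or AnalyticFoot(
            foot_length=ref.foot_length, lower_leg_length=ref.lower_leg_length)
        lo, hi = scale_bounds
        self.lower = np.array([lo, lo])
        self.upper = np.array([hi, hi])
        self.scale_bounds = (lo, hi)

    # DesignBounds-like surface for the GA
    @property
    def bounds(self):
        return self

    def contains(self, v):
        v = np.asarray(v, dtype=float)
        return bool(np.all(v >= self.lower) and np.all(v <= self.upper))

    def violation(self, v):
        v = np.asarray(v, dtype=float)
        return float(np.sum(np.clip(self.lower - v, 0, None))
                     + np.sum(np.clip(v - self.upper, 0, None)))

    def with_percents(self, percents) -> "AnalyticObjective":
        return AnalyticObjective(self.ref, percents, self.base, None,
                                 self.scale_bounds)

    def geometry_invalid(self, vars_) -> bool:
        return False  # the two-beam model cannot self-intersect

    def evaluate_raw(self, vars_):
        foot = replace(self.base, keel_scale=float(vars_[0]),
                       heel_scale=float(vars_[1]))
        llte = analytic_llte(foot, self.ref, self.percents)
        failed = int(np.sum(llte.per_frame_terms[:, 0] >= 100.0))
        return llte.value, np.nan, failed


# ---------------------------------------------------------------------------
# candidate evaluation & GA


def evaluate_candidate(vars_, objective, config: OptimizationConfig,
                       material: Material | None = None):
    """Objective value plus constraint report for one candidate.

    Out-of-bounds and self-intersecting candidates short-circuit (no
    structural analysis) to a penalty larger than any feasible objective,
    ranked by violation magnitude; feasible candidates return the
    trajectory error exactly, plus a stress penalty when the allowable is
    exceeded.
    """
    vars_ = np.asarray(vars_, dtype=float)
    bounds = objective.bounds
    if not bounds.contains(vars_):
        viol = bounds.violation(vars_)
        report = ConstraintReport(np.nan, True, False, False, 0)
        return _SHORT_CIRCUIT_PENALTY * (1.0 + viol), report
    if objective.geometry_invalid(vars_):
        report = ConstraintReport(np.nan, True, True, True, 0)
        return _SHORT_CIRCUIT_PENALTY, report

    llte, max_s, failed = objective.evaluate_raw(vars_)
    mat = material or getattr(objective, "material", None)
    if mat is not None and np.isfinite(max_s):
        allowable = mat.flexural_yield / config.safety_factor
        stress_ok = max_s <= allowable
        penalty = (config.stress_penalty_weight * (max_s / allowable - 1.0)
                   if not stress_ok else 0.0)
    else:
        stress_ok = True
        penalty = 0.0
    report = ConstraintReport(max_stress=max_s, stress_ok=stress_ok,
                              self_intersects=False, bounds_ok=True,
                              failed_frames=failed)
    return llte + penalty, report


def _decode(genes: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    return lower + genes * (upper - lower)


def optimize_design(objective, config: OptimizationConfig,
                    initial_vars=None) -> OptimizationResult:
    """Run the genetic algorithm and return the best feasible design seen.

    Deterministic for a fixed ``config.seed``; the best-so-far objective is
    non-increasing by elitism.  ``initial_vars`` optionally seeds the first
    population with a known baseline design (warm start).  Raises if no
    feasible individual was found, carrying the least-infeasible candidate
    in the exception args.
    """
    rng = np.random.default_rng(config.seed)
    bounds = objective.bounds
    lower = np.asarray(bounds.lower, dtype=float)
    upper = np.asarray(bounds.upper, dtype=float)
    d = lower.size

    pop = rng.random((config.population, d))
    if initial_vars is not None:
        genes = (np.asarray(initial_vars, dtype=float) - lower) / (upper - lower)
        pop[0] = np.clip(genes, 0.0, 1.0)
    cache: dict[bytes, tuple[float, ConstraintReport]] = {}

    def fitness(genes: np.ndarray):
        key = genes.tobytes()
        if key not in cache:
            cache[key] = evaluate_candidate(_decode(genes, lower, upper),
                                            objective, config)
        return cache[key]

    best_genes = None
    best_obj = np.inf
    best_report = None
    incumbent = (np.inf, None, None)  # least-infeasible fallback
    hist_best, hist_med = [], []

    for _gen in range(config.generations):
        scored = [fitness(ind) for ind in pop]
        objs = np.array([s[0] for s in scored])
        for k in range(config.population):
            obj, rep = scored[k]
            if rep.feasible and obj < best_obj:
                best_obj, best_genes, best_report = obj, pop[k].copy(), rep
            if obj < incumbent[0]:
                incumbent = (obj, pop[k].copy(), rep)
        hist_best.append(best_obj if best_genes is not None else float(np.min(objs)))
        hist_med.append(float(np.median(objs)))

        # selection: tournament of size k
        new_pop = []
        if config.elitism and best_genes is not None:
            new_pop.append(best_genes.copy())
        elif config.elitism:
            new_pop.append(pop[int(np.argmin(objs))].copy())
        while len(new_pop) < config.population:
            idx = rng.integers(0, config.population, size=config.tournament_size)
            parent_a = pop[idx[np.argmin(objs[idx])]]
            idx = rng.integers(0, config.population, size=config.tournament_size)
            parent_b = pop[idx[np.argmin(objs[idx])]]
            child = parent_a.copy()
            if rng.random() < config.crossover_rate:
                a = config.blend_alpha
                gamma = rng.random(d) * (1 + 2 * a) - a
                child = parent_a + gamma * (parent_b - parent_a)
            mut = rng.random(d) < config.mutation_rate
            child = child + mut * rng.normal(0.0, config.mutation_sigma, size=d)
            new_pop.append(np.clip(child, 0.0, 1.0))
        pop = np.array(new_pop)

    if best_genes is None:
        raise RuntimeError("no feasible design found",
                           _decode(incumbent[1], lower, upper), incumbent[0])
    return OptimizationResult(
        best_vars=_decode(best_genes, lower, upper),
        best_objective=float(best_obj),
        best_report=best_report,
        history_best=np.array(hist_best),
        history_median=np.array(hist_med),
        seed=config.seed,
        config=config,
    )


def grid_search(objective, config: OptimizationConfig, n: int = 50):
    """Exhaustive grid search over a 2-variable objective (oracle optimum)."""
    bounds = objective.bounds
    lower = np.asarray(bounds.lower, dtype=float)
    upper = np.asarray(bounds.upper, dtype=float)
    if lower.size != 2:
        raise ValueError("grid search supports exactly 2 variables")
    g0 = np.linspace(lower[0], upper[0], n)
    g1 = np.linspace(lower[1], upper[1], n)
    best = (np.inf, None)
    values = np.empty((n, n))
    for i, a in enumerate(g0):
        for j, b in enumerate(g1):
            obj, rep = evaluate_candidate(np.array([a, b]), objective, config)
            values[i, j] = obj if rep.feasible else np.inf
            if rep.feasible and obj < best[0]:
                best = (obj, np.array([a, b]))
    if best[1] is None:
        raise RuntimeError("no feasible grid point")
    return best[1], float(best[0]), values


@dataclass(frozen=True)
class InstanceSetComparison:
    variable_pct_diff: np.ndarray  # per variable, %
    max_variable_pct_diff: float  # %
    llte_pct_diff: float  # % relative difference of fixed-design LLTE
    full_optimum: np.ndarray
    reduced_optimum: np.ndarray


def compare_instance_sets(objective, config: OptimizationConfig,
                          full_percents, reduced_percents,
                          method: str = "grid", grid_n: int = 50) -> InstanceSetComparison:
    """Quantify how well a reduced stance-instance set stands in for the full one.

    Optimizes the same problem under both instance sets (matched seeds /
    identical grids), reports the per-variable percent differences of the
    optima, and evaluates the *full-set* optimal design under both sets to
    get the relative trajectory-error difference.
    """
    obj_full = objective.with_percents(full_percents)
    obj_red = objective.with_percents(reduced_percents)
    if method == "grid":
        v_full, _, _ = grid_search(obj_full, config, grid_n)
        v_red, _, _ = grid_search(obj_red, config, grid_n)
    elif method == "ga":
        v_full = optimize_design(obj_full, config).best_vars
        v_red = optimize_design(obj_red, config).best_vars
    else:
        raise ValueError("method must be 'grid' or 'ga'")
    denom = np.where(np.abs(v_full) > 1e-12, np.abs(v_full), 1e-12)
    var_diff = 100.0 * np.abs(v_red - v_full) / denom
    llte_full, _ = evaluate_candidate(v_full, obj_full, config)
    llte_red, _ = evaluate_candidate(v_full, obj_red, config)
    llte_diff = 100.0 * abs(llte_red - llte_full) / llte_full
    return InstanceSetComparison(
        variable_pct_diff=var_diff,
        max_variable_pct_diff=float(var_diff.max()),
        llte_pct_diff=float(llte_diff),
        full_optimum=v_full,
        reduced_optimum=v_red,
    )
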