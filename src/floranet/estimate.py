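"""Weighted least-squares objective and the three global/local optimizers.

The fit quality of a parameter set p is the weighted sum of squared residuals

    O(p) = sum_i sum_j  w_i * (X_ij - Y_ij(p))**2,     w_i = 1 / mean_j(X_ij)**2

where X is the observed panel, Y(p) the model simulation started from the
panel's first time point, and the per-gene weight is the inverse squared
time-mean of that gene's observations — making each gene's contribution
scale-free.  Genes whose observed mean sits at the positivity floor (e.g. a
knocked-out transcript) carry zero weight.

Optimizers: global-best particle swarm (PSO), self-adaptive evolutionary
programming (EP), and the deterministic Hooke–Jeeves pattern search (HJ).
All three work on a plain box-bounded callable, so they are reusable beyond
ODE fitting; the ``fit_*`` wrappers bind them to a (model, data) pair and
return a :class:`FitResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import odeint

from .models import (
    POSITIVITY_FLOOR,
    Formalism,
    KineticModel,
    ParameterVector,
)
from .simulate import TimeCourse

#: Finite penalty returned when a simulation fails inside the objective; a
#: NaN would poison swarm/personal bests.
SIMULATION_PENALTY = 1e10

#: Solver tolerances used inside the objective (looser than reporting runs:
#: the optimizer only needs residuals to a few digits).
FIT_RTOL = 1e-6
FIT_ATOL = 1e-9


class Objective:
    """Callable O(p) bound to one model and one observed time course.

    The initial state is assembled from the data's first time point: observed
    species start at their first observation; an unobserved FT/FD complex
    starts at the steady-state closure ``k * [FT](0) * [FD]``; unobserved
    independent inputs sit at their configured constant levels.
    """

    def __init__(
        self,
        model: KineticModel,
        data: TimeCourse,
        *,
        observed_species: Sequence[str] | None = None,
        complex_rate: float = 1.0,
        fd_level: float = 1.0,
        phyb_level: float = 1.0,
        rtol: float = FIT_RTOL,
        atol: float = FIT_ATOL,
        penalty: float = SIMULATION_PENALTY,
        mxstep: int = 4000,
    ):
        if data.n_times < 2:
            raise ValueError("objective needs at least 2 time points")
        top = model.topology
        obs = tuple(observed_species) if observed_species else data.species_labels
        missing = [l for l in obs if l not in top.labels]
        if missing:
            raise ValueError(f"data species {missing} not present in the model")
        missing_data = [l for l in obs if l not in data.species_labels]
        if missing_data:
            raise ValueError(f"observed species {missing_data} absent from the data")
        self.model = model
        self.data = data
        self.observed = obs
        self.penalty = float(penalty)
        self.rtol = float(rtol)
        self.atol = float(atol)
        self.mxstep = int(mxstep)
        self._times = data.times
        self._obs_data = np.column_stack([data.column(l) for l in obs])
        self._obs_model_cols = [top.labels.index(l) for l in obs]

        # per-gene weights 1/mean^2; floor-level genes (knockouts) get weight 0
        means = self._obs_data.mean(axis=0)
        nz = means > POSITIVITY_FLOOR
        self.weights = np.zeros_like(means)
        self.weights[nz] = 1.0 / means[nz] ** 2

        # initial full state from the first observed row
        fd_level = float(data.meta.get("fd_level", fd_level))
        phyb_level = float(data.meta.get("phyb_level", phyb_level))
        x0 = np.zeros(top.n_species)
        for s in top.species:
            if s.name in data.species_labels:
                x0[s.index - 1] = data.column(s.name)[0]
            elif s.name == "FTFD_complex" and "FT" in data.species_labels:
                fd0 = data.column("FD")[0] if "FD" in data.species_labels else fd_level
                x0[s.index - 1] = complex_rate * data.column("FT")[0] * fd0
            elif s.name == "FD":
                x0[s.index - 1] = fd_level
            elif s.name == "PHYB":
                x0[s.index - 1] = phyb_level
        self.initial_state = x0
        self._dep0 = model.dependent_positions

        #: residual points entering the fit (weighted genes x times)
        self.n_points = int(np.count_nonzero(nz) * data.n_times)

    # -- simulation (fast path, shared by value/predict) -------------------
    def _simulate(self, pvals: list[float]) -> np.ndarray | None:
        """Full-state trajectory at the data times, or None on failure."""
        x0 = self.initial_state
        dep0 = self._dep0
        xbuf = x0.tolist()
        rhs = self.model.rhs_dependent

        def f(y, _t):
            for k, d in enumerate(dep0):
                xbuf[d] = y[k]
            return rhs(xbuf, pvals)

        import warnings

        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lsoda failure -> finite penalty below
            y, info = odeint(
                f, x0[list(dep0)], self._times,
                rtol=self.rtol, atol=self.atol, mxstep=self.mxstep, full_output=True,
            )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
            return None
        if np.max(np.abs(y)) > 1e9:
            return None
        full = np.tile(x0, (len(self._times), 1))
        full[:, list(dep0)] = np.maximum(y, 0.0)
        return full

    def _coerce(self, params: ParameterVector | Sequence[float]) -> list[float]:
        if isinstance(params, ParameterVector):
            if params.formalism is not self.model.formalism:
                raise ValueError("parameter vector formalism does not match model")
            return params.values.tolist()
        return list(map(float, params))

    def __call__(self, params: ParameterVector | Sequence[float]) -> float:
        full = self._simulate(self._coerce(params))
        if full is None:
            return self.penalty
        pred = full[:, self._obs_model_cols]
        resid = self._obs_data - pred
        return float(np.sum(self.weights * resid**2))

    def predict(self, params: ParameterVector | Sequence[float]) -> TimeCourse:
        """Model trajectory at the data grid, restricted to observed species."""
        full = self._simulate(self._coerce(params))
        if full is None:
            raise RuntimeError("simulation failed at the requested parameters")
        return TimeCourse(
            self._times, self.observed, full[:, self._obs_model_cols],
            self.data.genotype, meta={"predicted": True},
        )

    def residual_stats(self, params: ParameterVector | Sequence[float]) -> tuple[float, float, int]:
        """(weighted O(p), unweighted RSS, number of residual points)."""
        full = self._simulate(self._coerce(params))
        if full is None:
            return self.penalty, self.penalty, self.n_points
        pred = full[:, self._obs_model_cols]
        resid = self._obs_data - pred
        used = self.weights > 0
        return (
            float(np.sum(self.weights * resid**2)),
            float(np.sum(resid[:, used] ** 2)),
            self.n_points,
        )


def weighted_sse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """O(p) on already-simulated matrices (time x gene), same weighting."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted shapes differ")
    means = observed.mean(axis=0)
    w = np.zeros(observed.shape[1])
    nz = means > POSITIVITY_FLOOR
    w[nz] = 1.0 / means[nz] ** 2
    return float(np.sum(w * (observed - predicted) ** 2))


def objective(
    params: ParameterVector | Sequence[float],
    model: KineticModel,
    data: TimeCourse,
    **kwargs,
) -> float:
    """One-shot O(p); build an :class:`Objective` for repeated evaluation."""
    return Objective(model, data, **kwargs)(params)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of one optimizer run."""

    best_params: ParameterVector
    objective: float
    trace: np.ndarray
    optimizer: str
    seed: int | None
    evaluations: int
    converged: bool
    criterion: str
    meta: dict = field(default_factory=dict)


@dataclass
class PSOSettings:
    n_particles: int = 40
    iterations: int = 500
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    velocity_clamp: float = 0.5  # fraction of the box width
    stall_iterations: int = 100
    stall_tol: float = 1e-12


@dataclass
class EPSettings:
    population: int = 50
    generations: int = 500
    tournament_size: int = 10
    sigma_init: float = 0.1  # fraction of the box width


@dataclass
class HJSettings:
    initial_step: float = 0.1  # fraction of the box width
    contraction: float = 0.5
    tolerance: float = 1e-6  # convergence when max step fraction < tolerance
    max_evaluations: int = 100_000


def _check_box(lower: np.ndarray, upper: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1 or lower.size == 0:
        raise ValueError("bounds must be equal-length non-empty 1-D arrays")
    if not np.all(np.isfinite(lower)) or not np.all(np.isfinite(upper)):
        raise ValueError("bounds must be finite")
    if np.any(upper < lower):
        raise ValueError("empty bounds box (upper < lower)")
    return lower, upper


def pso_minimize(
    func: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    seed: int,
    settings: PSOSettings | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int, bool, str]:
    """Global-best PSO over a box; deterministic under ``seed``.

    Two standard refinements of the plain global-best swarm are built in:
    personal/global bests are updated asynchronously (within the sweep over
    particles, so later particles see improvements immediately), and the
    current best particle follows the guaranteed-convergence update — an
    adaptive random search of radius ``rho`` around the global best — which
    prevents the well-known stagnation of a fully collapsed swarm.
    """
    s = settings or PSOSettings()
    lower, upper = _check_box(lower, upper)
    span = upper - lower
    rng = np.random.default_rng(int(seed))
    n, d = s.n_particles, lower.size
    pos = lower + rng.random((n, d)) * span
    vel = (rng.random((n, d)) - 0.5) * span * 0.1
    vmax = s.velocity_clamp * span
    fvals = np.array([func(p) for p in pos])
    evals = n
    pbest, pbest_f = pos.copy(), fvals.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    trace = [gbest_f]
    stall = 0
    rho, succ, fail = 1.0, 0, 0  # guaranteed-convergence search radius state
    for _ in range(s.iterations):
        improved = False
        for i in range(n):
            if i == g:
                # guaranteed-convergence move of the best particle
                vel[i] = (
                    gbest - pos[i]
                    + s.inertia * vel[i]
                    + rho * span * (rng.random(d) - 0.5)
                )
            else:
                r1 = rng.random(d)
                r2 = rng.random(d)
                vel[i] = (
                    s.inertia * vel[i]
                    + s.cognitive * r1 * (pbest[i] - pos[i])
                    + s.social * r2 * (gbest - pos[i])
                )
            np.clip(vel[i], -vmax, vmax, out=vel[i])
            pos[i] = np.clip(pos[i] + vel[i], lower, upper)
            fi = func(pos[i])
            evals += 1
            if fi < pbest_f[i]:
                pbest[i] = pos[i].copy()
                pbest_f[i] = fi
                if fi < gbest_f:
                    gbest, gbest_f, g = pos[i].copy(), float(fi), i
                    improved = True
        if improved:
            succ, fail = succ + 1, 0
            if gbest_f < trace[-1] - s.stall_tol:
                stall = 0
            else:
                stall += 1
        else:
            succ, fail, stall = 0, fail + 1, stall + 1
        if succ > 15:
            rho, succ = rho * 2.0, 0
        if fail > 5:
            rho, fail = max(rho * 0.5, 1e-15), 0
        trace.append(gbest_f)
        if stall >= s.stall_iterations:
            return gbest, gbest_f, np.array(trace), evals, True, (
                f"no improvement > {s.stall_tol:g} for {s.stall_iterations} iterations"
            )
    return gbest, gbest_f, np.array(trace), evals, False, "iteration budget exhausted"


def _reflect(x: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Reflect out-of-box coordinates back inside (repeatedly if needed)."""
    span = upper - lower
    ok = span > 0
    y = x.copy()
    y[~ok] = lower[~ok]
    # map into [0, 2*span) then fold
    z = np.mod(y[ok] - lower[ok], 2 * span[ok])
    z = np.where(z > span[ok], 2 * span[ok] - z, z)
    y[ok] = lower[ok] + z
    return y


def ep_minimize(
    func: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    seed: int,
    settings: EPSettings | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int, bool, str]:
    """Evolutionary programming: self-adaptive Gaussian mutation, (mu + mu)
    survival by round-robin tournament."""
    s = settings or EPSettings()
    lower, upper = _check_box(lower, upper)
    span = upper - lower
    rng = np.random.default_rng(int(seed))
    mu, d = s.population, lower.size
    tau = 1.0 / math.sqrt(2.0 * math.sqrt(d))
    tau_prime = 1.0 / math.sqrt(2.0 * d)
    sigma_floor = 1e-12 * np.maximum(span, 1.0)

    pop = lower + rng.random((mu, d)) * span
    sig = np.tile(s.sigma_init * np.maximum(span, 1e-12), (mu, 1))
    fvals = np.array([func(p) for p in pop])
    evals = mu
    trace = [float(fvals.min())]
    for _ in range(s.generations):
        child = pop + sig * rng.standard_normal((mu, d))
        child = np.array([_reflect(c, lower, upper) for c in child])
        g_global = rng.standard_normal((mu, 1))
        child_sig = np.maximum(
            sig * np.exp(tau_prime * g_global + tau * rng.standard_normal((mu, d))),
            sigma_floor,
        )
        child_f = np.array([func(c) for c in child])
        evals += mu
        all_pop = np.vstack([pop, child])
        all_sig = np.vstack([sig, child_sig])
        all_f = np.concatenate([fvals, child_f])
        # round-robin tournament: wins against q random opponents
        q = s.tournament_size
        opponents = rng.integers(0, 2 * mu, size=(2 * mu, q))
        wins = (all_f[:, None] <= all_f[opponents]).sum(axis=1)
        keep = np.lexsort((all_f, -wins))[:mu]
        pop, sig, fvals = all_pop[keep], all_sig[keep], all_f[keep]
        trace.append(float(fvals.min()))
    return (
        pop[int(np.argmin(fvals))],
        float(fvals.min()),
        np.array(trace),
        evals,
        False,
        "generation budget exhausted",
    )


def hooke_jeeves_minimize(
    func: Callable[[np.ndarray], float],
    lower: Sequence[float],
    upper: Sequence[float],
    start: Sequence[float],
    settings: HJSettings | None = None,
) -> tuple[np.ndarray, float, np.ndarray, int, bool, str]:
    """Deterministic Hooke–Jeeves pattern search (exploratory + pattern moves,
    geometric step contraction)."""
    s = settings or HJSettings()
    lower, upper = _check_box(lower, upper)
    x = np.asarray(start, dtype=float)
    if x.shape != lower.shape:
        raise ValueError("start has wrong dimension")
    if np.any(x < lower) or np.any(x > upper):
        raise ValueError("start lies outside the bounds box")
    span = np.maximum(upper - lower, 1e-30)
    step = s.initial_step * span
    fx = func(x)
    evals = 1
    trace = [fx]

    def explore(base: np.ndarray, fbase: float, step: np.ndarray):
        nonlocal evals
        p = base.copy()
        fp = fbase
        for i in range(p.size):
            for delta in (step[i], -step[i]):
                cand = p.copy()
                cand[i] = np.clip(cand[i] + delta, lower[i], upper[i])
                if cand[i] == p[i]:
                    continue
                fc = func(cand)
                evals += 1
                if fc < fp:
                    p, fp = cand, fc
                    break
        return p, fp

    while np.max(step / span) > s.tolerance and evals < s.max_evaluations:
        nx, fnx = explore(x, fx, step)
        if fnx < fx:
            # pattern move: extrapolate along the successful direction
            while evals < s.max_evaluations:
                px = np.clip(nx + (nx - x), lower, upper)
                x, fx = nx, fnx
                ex, fex = explore(px, func(px), step)
                evals += 1
                if fex < fx:
                    nx, fnx = ex, fex
                else:
                    break
            x, fx = nx, fnx
        else:
            step *= s.contraction
        trace.append(fx)
    converged = np.max(step / span) <= s.tolerance
    reason = "step size below tolerance" if converged else "evaluation budget exhausted"
    return x, fx, np.array(trace), evals, converged, reason


# ---------------------------------------------------------------------------
# model-level wrappers
# ---------------------------------------------------------------------------

def _resolve(
    model: KineticModel | None,
    data: TimeCourse | None,
    objective_fn: Callable | None,
    bounds,
    objective_kwargs: dict,
):
    if objective_fn is None:
        if model is None or data is None:
            raise ValueError("provide either (model, data) or objective=callable")
        objective_fn = Objective(model, data, **objective_kwargs)
    if bounds is None:
        if model is None:
            raise ValueError("bounds are required when no model is given")
        t = model.parameter_template
        bounds = (t.lower, t.upper)
    return objective_fn, np.asarray(bounds[0], float), np.asarray(bounds[1], float)


def _package(
    model: KineticModel | None,
    best: np.ndarray,
    fbest: float,
    trace: np.ndarray,
    optimizer: str,
    seed: int | None,
    evals: int,
    converged: bool,
    criterion: str,
    lower: np.ndarray,
    upper: np.ndarray,
) -> FitResult:
    if model is not None:
        t = model.parameter_template
        pv = ParameterVector(t.names, best, lower, upper, model.formalism)
    else:
        names = tuple(f"p{i}" for i in range(best.size))
        pv = ParameterVector(names, best, lower, upper, Formalism.MASS_ACTION)
    return FitResult(pv, float(fbest), trace, optimizer, seed, evals, converged, criterion)


def fit_pso(
    model: KineticModel | None = None,
    data: TimeCourse | None = None,
    *,
    bounds=None,
    settings: PSOSettings | None = None,
    seed: int = 0,
    objective: Callable | None = None,
    **objective_kwargs,
) -> FitResult:
    """Particle-swarm fit of a model to a time course (or of any callable)."""
    f, lo, hi = _resolve(model, data, objective, bounds, objective_kwargs)
    best, fb, trace, ev, conv, crit = pso_minimize(f, lo, hi, seed, settings)
    return _package(model, best, fb, trace, "pso", seed, ev, conv, crit, lo, hi)


def fit_ep(
    model: KineticModel | None = None,
    data: TimeCourse | None = None,
    *,
    bounds=None,
    settings: EPSettings | None = None,
    seed: int = 0,
    objective: Callable | None = None,
    **objective_kwargs,
) -> FitResult:
    """Evolutionary-programming fit (self-adaptive Gaussian mutation)."""
    f, lo, hi = _resolve(model, data, objective, bounds, objective_kwargs)
    best, fb, trace, ev, conv, crit = ep_minimize(f, lo, hi, seed, settings)
    return _package(model, best, fb, trace, "ep", seed, ev, conv, crit, lo, hi)


def fit_hooke_jeeves(
    model: KineticModel | None = None,
    data: TimeCourse | None = None,
    *,
    bounds=None,
    settings: HJSettings | None = None,
    start: Sequence[float] | None = None,
    objective: Callable | None = None,
    **objective_kwargs,
) -> FitResult:
    """Hooke–Jeeves pattern-search fit (deterministic; default start is the
    center of the bounds box)."""
    f, lo, hi = _resolve(model, data, objective, bounds, objective_kwargs)
    x0 = 0.5 * (lo + hi) if start is None else np.asarray(start, float)
    best, fb, trace, ev, conv, crit = hooke_jeeves_minimize(f, lo, hi, x0, settings)
    return _package(model, best, fb, trace, "hooke_jeeves", None, ev, conv, crit, lo, hi)
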