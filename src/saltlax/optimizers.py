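"""Population metaheuristics for hyperparameter search over box bounds.

Four strategies share one interface: ``nrbo`` (the study's hybrid — a
velocity/position update plus a Newton-Raphson search rule (NRSR) refinement
and a trap-avoidance operator (TAO)), and the comparison baselines ``pso``
(particle swarm), ``ngo`` (northern goshawk) and ``cpo`` (crested
porcupine). All are single-stream seeded, clip every candidate to the
bounds, update personal/global bests only on strict improvement, and return
a monotone best-fitness trace.

The published description of NRBO mixes particle-swarm notation (inertia
``omega_v``, learning factors c1/c2, per-dimension uniform randoms gamma1,
gamma2 — not to be confused with the LSSVM's regularization gamma or density
weight omega) with the Newton-Raphson operators; the default here follows
that hybrid description. ``canonical_nrbo=True`` switches to the canonical
NRBO operator formulas from the optimization literature.

Log-scaled dimensions (multiplicative hyperparameters such as the LSSVM's
gamma and sigma) are searched in log10 space and reported back on the
natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .lssvm import predict, train_lssvm

__all__ = [
    "SearchSpace",
    "OptimizerConfig",
    "OptimizerResult",
    "STRATEGIES",
    "minimize",
    "default_hyper_space",
    "tune_lssvm",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("nrbo", "pso", "ngo", "cpo")


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds with an optional per-dimension log10 scale."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    scale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.lower) != len(self.upper):
            raise ValueError("lower and upper bounds must have equal length")
        scale = self.scale or tuple("linear" for _ in self.lower)
        object.__setattr__(self, "scale", scale)
        if len(scale) != len(self.lower):
            raise ValueError("scale must match the number of dimensions")
        for lo, hi, sc in zip(self.lower, self.upper, scale):
            if sc not in ("linear", "log10"):
                raise ValueError(f"scale must be 'linear' or 'log10', got {sc!r}")
            if not lo < hi:
                raise ValueError(f"require lower < upper, got [{lo}, {hi}]")
            if sc == "log10" and lo <= 0:
                raise ValueError("log10-scaled dimensions require positive lower bound")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array(
            [np.log10(l) if s == "log10" else l for l, s in zip(self.lower, self.scale)]
        )
        hi = np.array(
            [np.log10(u) if s == "log10" else u for u, s in zip(self.upper, self.scale)]
        )
        return lo, hi

    def to_natural(self, z: np.ndarray) -> np.ndarray:
        return np.array(
            [10.0**v if s == "log10" else v for v, s in zip(np.atleast_1d(z), self.scale)]
        )


@dataclass(frozen=True)
class OptimizerConfig:
    """Shared optimizer settings.

    ``inertia``/``c1``/``c2`` drive the velocity update (pso and hybrid
    nrbo); ``df`` is the trap-avoidance probability; ``stagnation`` (if set)
    stops early after that many iterations without improvement.
    """

    strategy: str = "nrbo"
    n_particles: int = 30
    max_iter: int = 200
    seed: int = 0
    inertia: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    df: float = 0.6
    canonical_nrbo: bool = False
    stagnation: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; valid: {STRATEGIES}")
        if self.n_particles < 2:
            raise ValueError("population size must be at least 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if not 0.0 <= self.df <= 1.0:
            raise ValueError("trap-avoidance probability df must lie in [0, 1]")
        if self.n_particles * self.max_iter < 2:
            raise ValueError("evaluation budget N * MaxIt must be at least 2")

    def with_(self, **kwargs) -> "OptimizerConfig":
        return replace(self, **kwargs)


@dataclass
class OptimizerResult:
    """Best-ever position (natural scale), its fitness, the per-iteration
    best-fitness trace and the number of objective evaluations."""

    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    n_evaluations: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.trace) > 0):
            raise ValueError("best-fitness trace must be monotone non-increasing")


class _Problem:
    """Clips, transforms and counts objective evaluations."""

    def __init__(self, objective, space: SearchSpace):
        self.objective = objective
        self.space = space
        self.lo, self.hi = space.internal_bounds()
        self.n_evals = 0

    def clip(self, z: np.ndarray) -> np.ndarray:
        return np.clip(z, self.lo, self.hi)

    def __call__(self, z: np.ndarray) -> float:
        self.n_evals += 1
        val = self.objective(self.space.to_natural(z))
        val = float(val)
        return val if np.isfinite(val) else np.inf


def minimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: OptimizerConfig | None = None,
) -> OptimizerResult:
    """Minimize a black-box fitness over the search space.

    Non-finite objective values are treated as +inf. Deterministic given
    ``config.seed``: a single seeded generator drives every random draw, and
    results do not depend on wall clock or evaluation order tricks.
    """
    config = config or OptimizerConfig()
    rng = np.random.default_rng(config.seed)
    prob = _Problem(objective, space)
    n, d = config.n_particles, space.ndim

    pos = prob.lo + rng.random((n, d)) * (prob.hi - prob.lo)
    fit = np.array([prob(p) for p in pos])
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])

    vel = np.zeros((n, d))
    trace = [gbest_fit]
    since_improve = 0

    step_fns = {
        "pso": _step_pso,
        "nrbo": _step_nrbo_canonical if config.canonical_nrbo else _step_nrbo,
        "ngo": _step_ngo,
        "cpo": _step_cpo,
    }
    step = step_fns[config.strategy]
    state = {"vel": vel, "config": config}

    for t in range(config.max_iter):
        pos, fit = step(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, config.max_iter, state)
        improved = fit < pbest_fit  # strict: ties keep the incumbent
        pbest[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmin(pbest_fit))
        if pbest_fit[g] < gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
            since_improve = 0
        else:
            since_improve += 1
        trace.append(gbest_fit)
        if config.stagnation is not None and since_improve >= config.stagnation:
            break

    return OptimizerResult(
        best_position=space.to_natural(gbest),
        best_fitness=gbest_fit,
        trace=np.array(trace),
        n_evaluations=prob.n_evals,
    )


# --------------------------------------------------------------------------
# strategy steps; each returns the updated (positions, fitnesses)


def _step_pso(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state):
    """Velocity/position rule: v <- w*v + c1*r1*(pbest-x) + c2*r2*(gbest-x)."""
    cfg = state["config"]
    n, d = pos.shape
    r1, r2 = rng.random((n, d)), rng.random((n, d))
    state["vel"] = (
        cfg.inertia * state["vel"] + cfg.c1 * r1 * (pbest - pos) + cfg.c2 * r2 * (gbest - pos)
    )
    new = prob.clip(pos + state["vel"])
    return new, np.array([prob(p) for p in new])


def _delta(t: int, max_iter: int) -> float:
    return (1.0 - 2.0 * (t + 1) / max_iter) ** 5


def _step_nrbo(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state):
    """Hybrid step: the velocity rule, then NRSR refinement and TAO escape.

    NRSR moves a particle along the Newton-like direction implied by the
    population's best and worst members, step size modulated by the decaying
    balance coefficient delta (sign randomized); TAO resamples a particle as
    a random convex mixture of gbest and a random member plus bounded noise
    with probability df.
    """
    cfg = state["config"]
    pos, fit = _step_pso(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state)
    n, d = pos.shape
    delta_mag = abs(_delta(t, max_iter))
    worst = pos[int(np.argmax(fit))]
    best = pos[int(np.argmin(fit))]
    span = prob.hi - prob.lo
    for i in range(n):
        dx = rng.random(d) * np.abs(best - pos[i])
        denom = 2.0 * (worst + best - 2.0 * pos[i])
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        nrsr = rng.standard_normal(d) * (worst - best) * dx / denom
        sign = rng.choice([-1.0, 1.0])
        trial = prob.clip(pos[i] - nrsr + sign * delta_mag * rng.random(d) * (best - pos[i]))
        f_trial = prob(trial)
        if f_trial < fit[i]:
            pos[i], fit[i] = trial, f_trial
        if rng.random() < cfg.df:
            mate = pos[rng.integers(n)]
            u = rng.random()
            noise = delta_mag * 0.5 * span * (rng.random(d) - 0.5)
            tao = prob.clip(u * gbest + (1.0 - u) * mate + noise)
            f_tao = prob(tao)
            if f_tao < fit[i]:
                pos[i], fit[i] = tao, f_tao
    return pos, fit


def _step_nrbo_canonical(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state):
    """Canonical NRBO operators (vector NRSR with rho drift, X1/X2/X3 mix, TAO)."""
    cfg = state["config"]
    n, d = pos.shape
    delta = _delta(t, max_iter)
    order = np.argsort(fit)
    xb, xw = pos[order[0]], pos[order[-1]]
    mean_pos = pos.mean(axis=0)
    new_pos, new_fit = pos.copy(), fit.copy()
    for i in range(n):
        a, b = rng.random(), rng.random()
        r1, r2 = rng.choice(n, size=2, replace=False)
        dx = rng.random(d) * np.abs(xb - pos[i])
        denom = 2.0 * (xw + xb - 2.0 * pos[i])
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        nrsr = rng.standard_normal(d) * (xw - xb) * dx / denom
        rho = a * (xb - pos[i]) + b * (pos[r1] - pos[r2])
        x1 = pos[i] - nrsr + rho
        x2 = xb - nrsr + rho
        r = rng.random()
        x3 = pos[i] - delta * (x2 - x1)
        cand = r * (r * x1 + (1 - r) * x2) + (1 - r) * x3
        if rng.random() < cfg.df:
            theta1 = -1.0 + 2.0 * rng.random()
            theta2 = -0.5 + rng.random()
            beta = rng.random() < 0.5
            mu1 = 3.0 * rng.random() if beta else 1.0
            mu2 = rng.random() if beta else 1.0
            if rng.random() < 0.5:
                cand = cand + theta1 * (mu1 * xb - mu2 * pos[i]) + theta2 * delta * (
                    mu1 * mean_pos - mu2 * pos[i]
                )
            else:
                cand = xb + theta1 * (mu1 * xb - mu2 * pos[i])
        cand = prob.clip(cand)
        f_cand = prob(cand)
        if f_cand < new_fit[i]:
            new_pos[i], new_fit[i] = cand, f_cand
    return new_pos, new_fit


def _step_ngo(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state):
    """Northern goshawk: prey-identification phase then tail-chase phase."""
    n, d = pos.shape
    new_pos, new_fit = pos.copy(), fit.copy()
    for i in range(n):
        k = rng.integers(n - 1)
        k = k if k < i else k + 1  # random prey != i
        r = rng.random(d)
        big_i = float(rng.integers(1, 3))
        if new_fit[k] < new_fit[i]:
            cand = new_pos[i] + r * (new_pos[k] - big_i * new_pos[i])
        else:
            cand = new_pos[i] + r * (new_pos[i] - new_pos[k])
        cand = prob.clip(cand)
        f_cand = prob(cand)
        if f_cand < new_fit[i]:
            new_pos[i], new_fit[i] = cand, f_cand
        radius = 0.02 * (1.0 - (t + 1) / max_iter)
        cand = prob.clip(new_pos[i] + radius * (2.0 * rng.random(d) - 1.0) * new_pos[i])
        f_cand = prob(cand)
        if f_cand < new_fit[i]:
            new_pos[i], new_fit[i] = cand, f_cand
    return new_pos, new_fit


def _step_cpo(prob, rng, pos, fit, pbest, pbest_fit, gbest, t, max_iter, state):
    """Crested porcupine: sight/sound exploration, odor/attack exploitation,
    with the scheme's cyclic population-activity reduction."""
    n, d = pos.shape
    cycles, n_min, tf, alpha = 2, max(2, n // 2), 0.8, 0.2
    period = max(1, max_iter // cycles)
    frac = (t % period) / period
    active = int(round(n_min + (n - n_min) * (1.0 - frac)))
    new_pos, new_fit = pos.copy(), fit.copy()
    fit_sum = np.sum(np.abs(new_fit[np.isfinite(new_fit)])) + 1e-300
    for i in range(active):
        others = [j for j in (rng.integers(n), rng.integers(n), rng.integers(n))]
        u1 = (rng.random(d) > rng.random()).astype(float)
        if rng.random() < rng.random():  # exploration
            if rng.random() < 0.5:  # sight: flash toward a midpoint
                y = (new_pos[i] + new_pos[others[0]]) / 2.0
                cand = new_pos[i] + rng.standard_normal(d) * np.abs(
                    2.0 * rng.random() * gbest - y
                )
            else:  # sound: mix with random members
                y = (new_pos[i] + new_pos[others[0]]) / 2.0
                cand = u1 * new_pos[i] + (1.0 - u1) * (
                    y + rng.random() * (new_pos[others[1]] - new_pos[others[2]])
                )
        else:  # exploitation
            if rng.random() < tf:  # odor diffusion
                st = np.exp(-abs(new_fit[i]) / fit_sum) if np.isfinite(new_fit[i]) else 1.0
                cand = (1.0 - u1) * new_pos[i] + u1 * (
                    new_pos[others[0]]
                    + st * (new_pos[others[1]] - new_pos[others[2]])
                    - rng.random(d) * _delta(t, max_iter) * new_pos[i]
                )
            else:  # physical attack: converge on the best position
                ft = rng.random(d) * (2.0 * rng.random() - 1.0) * (1.0 - (t + 1) / max_iter)
                cand = gbest + (alpha * (1.0 - rng.random()) + rng.random()) * (
                    u1 * gbest - new_pos[i]
                ) - ft * new_pos[i]
        cand = prob.clip(cand)
        f_cand = prob(cand)
        if f_cand < new_fit[i]:
            new_pos[i], new_fit[i] = cand, f_cand
    return new_pos, new_fit


# --------------------------------------------------------------------------
# LSSVM hyperparameter tuning


def default_hyper_space() -> SearchSpace:
    """gamma in [1e-2, 1e4], sigma in [1e-2, 1e2], both log10-scaled."""
    return SearchSpace(lower=(1e-2, 1e-2), upper=(1e4, 1e2), scale=("log10", "log10"))


def tune_lssvm(
    X_train,
    y_train,
    X_test=None,
    y_test=None,
    *,
    weights=None,
    fitness_mode: str = "paper_faithful",
    space: SearchSpace | None = None,
    config: OptimizerConfig | None = None,
    n_folds: int = 5,
) -> tuple[float, float, OptimizerResult]:
    """Search (gamma, sigma) minimizing the selected fitness.

    ``paper_faithful`` scores a candidate by the MSE of a model trained on
    the training rows and evaluated on the held-out test rows — the study's
    protocol, which lets model selection see the test targets (leaky; logged
    as such). ``cv`` scores by k-fold cross-validation MSE on the training
    rows only. Returns (gamma, sigma) on their natural scale.
    """
    space = space or default_hyper_space()
    config = config or OptimizerConfig()
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    w = None if weights is None else np.asarray(weights, dtype=float).ravel()

    if fitness_mode == "paper_faithful":
        if X_test is None or y_test is None:
            raise ValueError("paper_faithful fitness requires a held-out test set")
        logger.info(
            "paper_faithful fitness: hyperparameter selection is driven by the "
            "held-out test MSE (leaky model selection, as published)"
        )
        X_test = np.asarray(X_test, dtype=float)
        y_test = np.asarray(y_test, dtype=float).ravel()

        def fitness(p: np.ndarray) -> float:
            model = train_lssvm(X_train, y_train, gamma=p[0], sigma=p[1], weights=w)
            resid = predict(model, X_test) - y_test
            return float(np.mean(resid**2))

    elif fitness_mode == "cv":
        if n_folds > len(y_train):
            raise ValueError(
                f"fold count {n_folds} exceeds training size {len(y_train)}"
            )
        folds = np.arange(len(y_train)) % n_folds  # deterministic round-robin

        def fitness(p: np.ndarray) -> float:
            errs = []
            for k in range(n_folds):
                tr, te = folds != k, folds == k
                model = train_lssvm(
                    X_train[tr],
                    y_train[tr],
                    gamma=p[0],
                    sigma=p[1],
                    weights=None if w is None else w[tr],
                )
                resid = predict(model, X_train[te]) - y_train[te]
                errs.append(np.mean(resid**2))
            return float(np.mean(errs))

    else:
        raise ValueError(f"fitness_mode must be 'paper_faithful' or 'cv', got {fitness_mode!r}")

    result = minimize(fitness, space, config)
    gamma, sigma = result.best_position
    return float(gamma), float(sigma), result
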