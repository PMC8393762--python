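"""Continuous population-based optimizers: GBO, GWO, and the GBOGWO hybrid.

The Gradient-Based Optimizer (GBO) steers a population with a Newton-inspired
gradient search rule (GSR) and a stochastic local escaping operator (LEO).
The Grey Wolf Optimizer (GWO) pulls each solution toward the three current
best solutions ("alpha", "beta", "gamma") with a linearly decaying step
coefficient.  The hybrid replaces GBO's escape step with a GWO hunt with
probability ``1 - pr`` per member per iteration.

All three runners share one engine and one random-draw protocol so that the
hybrid with ``pr=1`` is bit-identical to plain GBO under the same seed.

Draw protocol (one member update, GBO family), in order:

1. ``r1..r4`` — four distinct member indices, ``rng.choice(N, 4, False)``.
2. GSR scratch: uniforms for ``rho1``, ``rho2``, ``delta``; a length-``dim``
   uniform vector for ``delta_x``; a standard normal for ``xs``; two uniforms
   for ``yp``; two for ``yq``; a standard normal for the GSR itself; one
   uniform each inside ``x1`` and ``x2``.
3. ``ra, rb`` for the convex-style combination of ``x1, x2, x3``.
4. One uniform ``u`` deciding the escape branch against ``pr``.
5. Either the LEO draws (``f1``, ``f2``, ``L1``, three uniforms for
   ``u1..u3``, ``L2``, a member index, a fresh uniform position) or, in the
   hybrid's else-branch, the GWO draws (``q1, q2`` per leader).

Every occurrence of a "rand" symbol consumes a fresh draw; named scalars
(``rho1``, ``rho2``, ``delta``, the GSR) are drawn once per member update and
reused wherever the symbol appears.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSettings",
    "Solution",
    "Population",
    "GBOScratch",
    "SearchResult",
    "OptimizerError",
    "init_population",
    "compute_beta",
    "compute_alpha_coef",
    "compute_rho",
    "gsr_candidates",
    "gbo_combine",
    "leo_step",
    "gwo_coefficients",
    "gwo_hunt",
    "clip_to_bounds",
    "run_gbo",
    "run_gwo",
    "run_gbogwo",
]

Objective = Callable[[np.ndarray], float]


class OptimizerError(ValueError):
    """Raised for invalid search settings or ill-behaved objectives."""


# ---------------------------------------------------------------------------
# settings and containers
# ---------------------------------------------------------------------------


@dataclass
class SearchSettings:
    """Hyperparameters shared by all optimizer variants.

    Defaults follow the standard search settings for the feature-selection
    benchmarks: a symmetric box [-10, 10], 30 members, 50 iterations, escape
    probability 0.75 for the hybrid (0.5 for plain GBO), beta schedule
    endpoints (0.2, 1.2).
    """

    lb: float = -10.0
    ub: float = 10.0
    N: int = 30
    MaxIt: int = 50
    pr: float = 0.75
    beta_min: float = 0.2
    beta_max: float = 1.2
    epsilon: float = 1e-8
    thr: float = 0.0
    lambda_: float = 0.99
    seed: int = 0

    def validate(self) -> None:
        if not self.lb < self.ub:
            raise OptimizerError(f"lb must be < ub, got [{self.lb}, {self.ub}]")
        if self.N < 4:
            raise OptimizerError(
                "population size N must be >= 4 (four distinct indices r1..r4 "
                f"are drawn per update), got N={self.N}"
            )
        if not 0.0 <= self.pr <= 1.0:
            raise OptimizerError(f"pr must lie in [0, 1], got {self.pr}")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise OptimizerError(f"lambda_ must lie in [0, 1], got {self.lambda_}")
        if not self.epsilon > 0:
            raise OptimizerError(f"epsilon must be > 0, got {self.epsilon}")
        if self.MaxIt < 1:
            raise OptimizerError(f"MaxIt must be >= 1, got {self.MaxIt}")


@dataclass
class Solution:
    position: np.ndarray
    fitness: float = math.nan
    mask: np.ndarray | None = None

    def copy(self) -> "Solution":
        return Solution(self.position.copy(), self.fitness,
                        None if self.mask is None else self.mask.copy())


@dataclass
class Population:
    solutions: list[Solution]
    best: Solution
    worst: Solution
    alpha: Solution
    beta_sol: Solution
    gamma: Solution
    iteration: int = 0

    @property
    def size(self) -> int:
        return len(self.solutions)

    def refresh(self) -> None:
        """Recompute best/worst and the three GWO leaders from member fitness."""
        order = sorted(range(self.size), key=lambda i: self.solutions[i].fitness)
        self.best = self.solutions[order[0]].copy()
        self.worst = self.solutions[order[-1]].copy()
        self.alpha = self.best
        self.beta_sol = self.solutions[order[1]].copy()
        self.gamma = self.solutions[order[2]].copy()


@dataclass
class GBOScratch:
    """Intermediate quantities of one GSR candidate construction."""

    rho1: float
    rho2: float
    delta: np.ndarray
    delta_x: np.ndarray
    xs: np.ndarray
    yp: np.ndarray
    yq: np.ndarray
    gsr: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    r: tuple[int, int, int, int] = (0, 0, 0, 0)


@dataclass
class SearchResult:
    best_position: np.ndarray
    best_fitness: float
    fitness_trace: list[float]
    evaluation_count: int
    settings: SearchSettings
    seed: int
    variant: str = "gbo"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "best_position": [float(v) for v in self.best_position],
            "best_fitness": float(self.best_fitness),
            "fitness_trace": [float(v) for v in self.fitness_trace],
            "evaluation_count": int(self.evaluation_count),
            "seed": int(self.seed),
            "settings": {k: (float(v) if isinstance(v, float) else v)
                         for k, v in vars(self.settings).items()},
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def clip_to_bounds(x: np.ndarray, lb: float, ub: float) -> np.ndarray:
    """Element-wise clamp of a position vector into the search box."""
    return np.clip(x, lb, ub)


def compute_beta(It: int, MaxIt: int, beta_min: float = 0.2,
                 beta_max: float = 1.2) -> float:
    """Cubic-decay schedule beta(It) = bmin + (bmax-bmin)*(1-(It/MaxIt)^3)^2.

    beta(0) = beta_max and beta(MaxIt) = beta_min exactly.
    """
    if MaxIt == 0:
        raise OptimizerError("MaxIt must be positive for the beta schedule")
    frac = It / MaxIt
    return beta_min + (beta_max - beta_min) * (1.0 - frac ** 3) ** 2


def compute_alpha_coef(beta: float) -> float:
    """Step-amplitude alpha = |beta * sin(3*pi/2 + sin(beta * 3*pi/2))|."""
    return abs(beta * math.sin(1.5 * math.pi + math.sin(beta * 1.5 * math.pi)))


def compute_rho(alpha_coef: float, rng: np.random.Generator) -> float:
    """rho = 2*rand*alpha - alpha, uniform on [-alpha, +alpha]."""
    return 2.0 * rng.random() * alpha_coef - alpha_coef


def _evaluate(objective: Objective, x: np.ndarray, member: int,
              iteration: int) -> float:
    f = float(objective(x))
    if not math.isfinite(f):
        raise OptimizerError(
            f"objective returned non-finite value {f!r} for member {member} "
            f"at iteration {iteration}"
        )
    return f


def init_population(settings: SearchSettings, dim: int, objective: Objective,
                    rng: np.random.Generator) -> Population:
    """Uniformly sample N positions in the box and evaluate them all."""
    settings.validate()
    if dim < 1:
        raise OptimizerError(f"dim must be >= 1, got {dim}")
    lb, ub = settings.lb, settings.ub
    sols = []
    for i in range(settings.N):
        pos = lb + rng.random(dim) * (ub - lb)
        sols.append(Solution(pos, _evaluate(objective, pos, i, 0)))
    pop = Population(sols, sols[0], sols[0], sols[0], sols[0], sols[0])
    pop.refresh()
    return pop


# ---------------------------------------------------------------------------
# GBO update pieces
# ---------------------------------------------------------------------------


def gsr_candidates(i: int, population: Population, rng: np.random.Generator,
                   settings: SearchSettings, alpha_coef: float,
                   r: Sequence[int]) -> GBOScratch:
    """Build the three GSR candidate vectors x1, x2, x3 for member ``i``.

    ``r`` holds the four distinct member indices r1..r4 already drawn by the
    caller (they precede the scratch draws in the protocol).
    """
    eps = settings.epsilon
    xi = population.solutions[i].position
    xb = population.best.position
    xw = population.worst.position
    xr = [population.solutions[j].position for j in r]

    rho1 = compute_rho(alpha_coef, rng)
    rho2 = compute_rho(alpha_coef, rng)

    delta = 2.0 * rng.random() * np.abs((xr[0] + xr[1] + xr[2] + xr[3]) / 4.0 - xi)
    # the "random vector" multiplying |...| spans the problem dimension
    delta_x = rng.random(xi.shape[0]) * np.abs((xb - xr[0] + delta) / 2.0)

    xs = xi - rng.standard_normal() * rho1 * (2.0 * delta_x * xi) / (xb - xw + eps)
    yp = rng.random() * (xs + xi) / 2.0 + rng.random() * delta_x
    yq = rng.random() * (xs + xi) / 2.0 - rng.random() * delta_x

    gsr = rng.standard_normal() * rho2 * (2.0 * delta_x * xi) / (yp - yq + eps)

    x1 = xi - gsr + rng.random() * rho1 * (xb - xi)
    x2 = xb - gsr + rng.random() * rho2 * (xr[0] - xr[1])
    x3 = xi - rho1 * (x1 - x2)
    return GBOScratch(rho1, rho2, delta, delta_x, xs, yp, yq, gsr,
                      x1, x2, x3, tuple(r))


def gbo_combine(x1: np.ndarray, x2: np.ndarray, x3: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """ra*(rb*x1 + (1-rb)*x2) + (1-ra)*x3 with fresh ra, rb in [0, 1]."""
    ra = rng.random()
    rb = rng.random()
    return ra * (rb * x1 + (1.0 - rb) * x2) + (1.0 - ra) * x3


def leo_step(i: int, population: Population, x1: np.ndarray, x2: np.ndarray,
             settings: SearchSettings, rng: np.random.Generator,
             rho1: float, r: Sequence[int], use_best_base: bool) -> np.ndarray:
    """Local escaping operator: a stochastic jump from xi (or xb).

    new = base + f1*W1 + f2*rho1*W3 + u2*W2/2 with
    W1 = u1*xb - u2*xk, W2 = x_r1 - x_r2, W3 = u3*(x2 - x1);
    f1 ~ U(-1, 1), f2 ~ N(0, 1), L1/L2 ~ Bernoulli(0.5), xk a blend of a
    uniformly chosen member and a fresh uniform position.
    """
    lb, ub = settings.lb, settings.ub
    xi = population.solutions[i].position
    xb = population.best.position
    dim = xi.shape[0]

    f1 = rng.uniform(-1.0, 1.0)
    f2 = rng.standard_normal()
    L1 = int(rng.integers(0, 2))
    u1 = L1 * 2.0 * rng.random() + (1 - L1)
    u2 = L1 * rng.random() + (1 - L1)
    u3 = L1 * rng.random() + (1 - L1)
    L2 = int(rng.integers(0, 2))
    xp = population.solutions[int(rng.integers(0, population.size))].position
    xrand = lb + rng.random(dim) * (ub - lb)
    xk = L2 * xp + (1 - L2) * xrand

    W1 = u1 * xb - u2 * xk
    W2 = population.solutions[r[0]].position - population.solutions[r[1]].position
    W3 = u3 * (x2 - x1)
    base = xb if use_best_base else xi
    return base + f1 * W1 + f2 * rho1 * W3 + u2 * W2 / 2.0


# ---------------------------------------------------------------------------
# GWO update pieces
# ---------------------------------------------------------------------------


def gwo_coefficients(t: int, tmax: int, rng: np.random.Generator
                     ) -> tuple[float, float, float]:
    """Decay b = 2 - 2*t/tmax and one (A, B) coefficient pair.

    B = 2*b*q1 - b lies in [-b, b]; A = 2*q2 lies in [0, 2].
    """
    if tmax == 0:
        raise OptimizerError("tmax must be positive for the GWO decay schedule")
    b = 2.0 - 2.0 * t / tmax
    q1 = rng.random()
    q2 = rng.random()
    return b, 2.0 * q2, 2.0 * b * q1 - b


def gwo_hunt(xi: np.ndarray, alpha: np.ndarray, beta_sol: np.ndarray,
             gamma: np.ndarray, b: float, rng: np.random.Generator
             ) -> np.ndarray:
    """Average of the three leader-attraction positions.

    X_k' = X_k - B_k*|A_k*X_k - xi| with independent (q1, q2) per leader,
    drawn in leader order alpha, beta, gamma (q1 before q2).
    """
    pulls = []
    for leader in (alpha, beta_sol, gamma):
        q1 = rng.random()
        q2 = rng.random()
        B = 2.0 * b * q1 - b
        A = 2.0 * q2
        D = np.abs(A * leader - xi)
        pulls.append(leader - B * D)
    return (pulls[0] + pulls[1] + pulls[2]) / 3.0


# ---------------------------------------------------------------------------
# shared engine
# ---------------------------------------------------------------------------


def _run(objective: Objective, dim: int, settings: SearchSettings,
         variant: str, rng: np.random.Generator | None = None) -> SearchResult:
    settings.validate()
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    pop = init_population(settings, dim, objective, rng)
    nevals = settings.N
    trace: list[float] = []

    for it in range(1, settings.MaxIt + 1):
        pop.iteration = it
        beta = compute_beta(it, settings.MaxIt, settings.beta_min,
                            settings.beta_max)
        alpha_coef = compute_alpha_coef(beta)
        b = 2.0 - 2.0 * it / settings.MaxIt

        for i in range(settings.N):
            if variant == "gwo":
                prop = gwo_hunt(pop.solutions[i].position,
                                pop.alpha.position, pop.beta_sol.position,
                                pop.gamma.position, b, rng)
            else:
                r = [int(v) for v in rng.choice(settings.N, 4, replace=False)]
                scratch = gsr_candidates(i, pop, rng, settings, alpha_coef, r)
                gbo_combine(scratch.x1, scratch.x2, scratch.x3, rng)
                u = rng.random()
                if u < settings.pr:
                    prop = leo_step(i, pop, scratch.x1, scratch.x2, settings,
                                    rng, scratch.rho1, r, use_best_base=False)
                elif variant == "gbo":
                    prop = leo_step(i, pop, scratch.x1, scratch.x2, settings,
                                    rng, scratch.rho1, r, use_best_base=True)
                else:  # hybrid: GWO hunt replaces the escape step
                    prop = gwo_hunt(pop.solutions[i].position,
                                    pop.alpha.position, pop.beta_sol.position,
                                    pop.gamma.position, b, rng)
            prop = clip_to_bounds(prop, settings.lb, settings.ub)
            f = _evaluate(objective, prop, i, it)
            nevals += 1
            if f < pop.solutions[i].fitness:  # keep-better replacement
                pop.solutions[i] = Solution(prop, f)
        pop.refresh()
        trace.append(pop.best.fitness)

    return SearchResult(pop.best.position.copy(), pop.best.fitness, trace,
                        nevals, settings, settings.seed, variant)


def run_gbo(objective: Objective, dim: int, settings: SearchSettings,
            rng: np.random.Generator | None = None) -> SearchResult:
    """Gradient-based optimizer: GSR candidates plus the local escaping step."""
    return _run(objective, dim, settings, "gbo", rng)


def run_gwo(objective: Objective, dim: int, settings: SearchSettings,
            rng: np.random.Generator | None = None) -> SearchResult:
    """Grey wolf optimizer with keep-better replacement."""
    return _run(objective, dim, settings, "gwo", rng)


def run_gbogwo(objective: Objective, dim: int, settings: SearchSettings,
               rng: np.random.Generator | None = None) -> SearchResult:
    """Hybrid: GBO update with the escape step swapped for a GWO hunt with
    probability 1 - pr per member per iteration."""
    return _run(objective, dim, settings, "gbogwo", rng)
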