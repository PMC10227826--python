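"""Population-based optimizers: NVSA and its predecessor BSD.

Both algorithms are differential-evolution variants that evolve an ``N x D``
pattern matrix inside a box-bounded search space.  Each generation a binary
*activation matrix* ``M`` selects, per individual, the fraction of dimensions
that may change (the crossover ratio ``rho``); a *search-scale matrix* ``F``
sets the step size; and a trial matrix ``T`` is built from two inter-individual
permutations and the best-so-far pattern vector.  Greedy one-to-one selection
keeps whichever of parent/trial scores better.

The two algorithms differ in

* how ``rho`` is drawn -- BSD samples one of the three 2nd-degree Bernstein
  polynomials evaluated at a uniform point, while NVSA samples the *normal
  vibration distribution*: ``exp(1/G) + 2 k1 (1 - k1) - exp(1/(G (k4-k5)^2 + P))``
  whose width ``G`` and height ``P`` are themselves drawn uniformly from
  ``[a, b]`` and ``[c, d]`` (defaults 1000, 10000, 3, 5);
* the structure of ``F`` -- BSD broadcasts a single row or column of cubed
  draws, NVSA draws a full independent matrix (cubed uniforms or standard
  normals, branch chosen once per generation by ``u^3 < v``);
* the trial recombination -- BSD couples its mixing weights (``W``/``1-W``,
  ``w*^3``/``1-w*^3``) while NVSA replaces them with four independent draws
  ``s, w1, w2, w3``.

All randomness flows through a single :class:`numpy.random.Generator` per
:func:`optimize` call; the draw order per generation is fixed (activation
matrix, search scale, permutations, trial weights, boundary repairs), so runs
are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "VibrationParams",
    "ObjectiveSpec",
    "OptimizerConfig",
    "Population",
    "RunTrace",
    "initialize_population",
    "update_best",
    "bernstein_rho",
    "vibration_rho",
    "activation_matrix",
    "search_scale_bsd",
    "search_scale_nvsa",
    "permutation_pair",
    "trial_vectors_bsd",
    "trial_vectors_nvsa",
    "boundary_control",
    "greedy_selection",
    "optimize",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Axis-aligned box ``[low_j, up_j]`` for each of ``D`` dimensions."""

    low: np.ndarray
    up: np.ndarray

    def __post_init__(self) -> None:
        low = np.atleast_1d(np.asarray(self.low, dtype=float))
        up = np.atleast_1d(np.asarray(self.up, dtype=float))
        if low.ndim != 1 or up.ndim != 1 or low.shape != up.shape:
            raise ValueError("low and up must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(low)) and np.all(np.isfinite(up))):
            raise ValueError("search-space bounds must be finite")
        if np.any(low > up):
            raise ValueError("every low[j] must be <= up[j]")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "up", up)

    @property
    def D(self) -> int:
        return self.low.size

    def contains(self, X: np.ndarray) -> bool:
        X = np.asarray(X, dtype=float)
        return bool(np.all(X >= self.low) and np.all(X <= self.up))

    @classmethod
    def cube(cls, low: float, up: float, D: int) -> "SearchSpace":
        return cls(np.full(D, float(low)), np.full(D, float(up)))


@dataclass(frozen=True)
class VibrationParams:
    """Control parameters of the normal vibration distribution.

    ``G ~ U(a, b)`` sets the vibration width (larger G = narrower dip),
    ``P ~ U(c, d)`` sets the height of the underlying distribution.
    """

    a: float = 1000.0
    b: float = 10000.0
    c: float = 3.0
    d: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.b):
            raise ValueError("require 0 < a <= b")
        if not (0 < self.c <= self.d):
            raise ValueError("require 0 < c <= d")


@dataclass
class ObjectiveSpec:
    """An objective to minimise over a :class:`SearchSpace`.

    ``evaluate`` maps a D-vector to a scalar.  ``evaluate_batch`` (optional)
    maps an ``N x D`` matrix to an N-vector and is used when present.  If
    ``uses_rng`` is set, both callables accept the run's random generator as a
    second argument (stochastic objectives such as the quartic-noise benchmark).
    """

    evaluate: Callable[..., float]
    space: SearchSpace
    name: str = ""
    evaluate_batch: Callable[..., np.ndarray] | None = None
    uses_rng: bool = False


@dataclass
class OptimizerConfig:
    N: int = 50
    epochs: int = 1000
    algorithm: str = "nvsa"
    vibration: VibrationParams = field(default_factory=VibrationParams)
    seed: int | None = None
    sense: str = "minimize"

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("population size N must be >= 4 "
                             "(permutation constraints need >= 3 non-self indices)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.algorithm not in ("nvsa", "bsd"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.sense not in ("minimize", "maximize"):
            raise ValueError(f"unknown sense {self.sense!r}")


@dataclass
class Population:
    """Pattern matrix with fitness values and the best-so-far record.

    Fitness is always in minimisation sense (a maximised objective is negated
    before it reaches the optimizer).
    """

    P: np.ndarray
    fitP: np.ndarray
    best_sol: float
    best_PV: np.ndarray


@dataclass
class RunTrace:
    """Best objective value after each generation, plus the evaluation count."""

    best_per_iteration: np.ndarray
    evaluations: int

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "iteration": np.arange(1, self.best_per_iteration.size + 1),
            "best_value": self.best_per_iteration,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def initialize_population(space: SearchSpace, N: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Uniform random ``N x D`` matrix inside the search space."""
    if N < 1:
        raise ValueError("N must be >= 1")
    alpha = rng.random((N, space.D))
    return space.low + alpha * (space.up - space.low)


def update_best(pop: Population) -> Population:
    """Refresh the best-so-far record from the current fitness vector.

    The stored best is replaced only on strict improvement; the argmin ties
    break toward the lowest index (numpy's argmin convention).
    """
    if pop.fitP.size == 0:
        raise ValueError("empty population")
    gamma = int(np.argmin(pop.fitP))
    if pop.fitP[gamma] < pop.best_sol:
        pop.best_sol = float(pop.fitP[gamma])
        pop.best_PV = pop.P[gamma].copy()
    return pop


def bernstein_rho(rng: np.random.Generator) -> float:
    """Crossover ratio from the three 2nd-degree Bernstein polynomials."""
    k = int(rng.integers(1, 4))
    beta = float(rng.random())
    if k == 1:
        return (1.0 - beta) ** 2
    if k == 2:
        return 2.0 * beta * (1.0 - beta)
    return beta ** 2


def vibration_rho(vp: VibrationParams, rng: np.random.Generator) -> float:
    """Crossover ratio from the normal vibration distribution, clipped to [0,1].

    Draw order: ``k1..k5 ~ U(0,1)`` as one vector of five.
    """
    k1, k2, k3, k4, k5 = rng.random(5)
    G = vp.a + (vp.b - vp.a) * k3
    Pv = vp.c + (vp.d - vp.c) * k2
    H = np.exp(1.0 / (G * (k4 - k5) ** 2 + Pv))
    rho = np.exp(1.0 / G) + 2.0 * k1 * (1.0 - k1) - H
    return float(min(1.0, max(0.0, rho)))


def activation_matrix(N: int, D: int, rho_source,
                      rng: np.random.Generator,
                      vibration: VibrationParams | None = None) -> np.ndarray:
    """Binary ``N x D`` crossover mask.

    Per row a ratio ``rho`` is drawn and ``max(1, ceil(rho * D))`` randomly
    chosen distinct columns are activated (at least one, so every trial can
    differ from its parent).  ``rho_source`` is ``"bernstein"``, ``"vibration"``
    or a callable ``rng -> float``.
    """
    if N < 1 or D < 1:
        raise ValueError("N and D must be >= 1")
    if rho_source == "bernstein":
        draw = bernstein_rho
    elif rho_source == "vibration":
        vp = vibration if vibration is not None else VibrationParams()
        draw = lambda g: vibration_rho(vp, g)  # noqa: E731
    elif callable(rho_source):
        draw = rho_source
    else:
        raise ValueError(f"unknown rho source {rho_source!r}")

    m = np.array([max(1, int(np.ceil(draw(rng) * D))) for _ in range(N)])
    m = np.minimum(m, D)
    order = np.argsort(rng.random((N, D)), axis=1)
    M = np.zeros((N, D))
    M[np.arange(N)[:, None], order] = (np.arange(D)[None, :] < m[:, None])
    return M


def search_scale_bsd(N: int, D: int, rng: np.random.Generator) -> np.ndarray:
    """BSD search-scale matrix: a single cubed row or column, broadcast.

    With probability branch ``u < v`` all rows are the same nonnegative
    ``eta^3 * |lambda^3|`` row; otherwise all columns are the same ``lambda^3``
    column.  ``u, v`` are drawn once per call.
    """
    if N < 1 or D < 1:
        raise ValueError("N and D must be >= 1")
    u = rng.random()
    v = rng.random()
    if u < v:
        eta = rng.random(D)
        lam = rng.standard_normal(D)
        row = eta ** 3 * np.abs(lam ** 3)
        return np.tile(row, (N, 1))
    lam = rng.standard_normal(N)
    return np.tile((lam ** 3)[:, None], (1, D))


def search_scale_nvsa(N: int, D: int, rng: np.random.Generator) -> np.ndarray:
    """NVSA search-scale matrix: fully independent entries.

    Branch chosen once per call: ``u^3 < v`` gives cubed uniforms in [0,1],
    otherwise standard normals.
    """
    if N < 1 or D < 1:
        raise ValueError("N and D must be >= 1")
    u = rng.random()
    v = rng.random()
    if u ** 3 < v:
        return rng.random((N, D)) ** 3
    return rng.standard_normal((N, D))


def permutation_pair(N: int, rng: np.random.Generator):
    """Two permutations of ``0..N-1`` with ``L1[i] != i`` and ``L1[i] != L2[i]``.

    Rejection sampling; each constraint is satisfied by a whole-permutation
    resample (success probability ~ 1/e per draw).
    """
    if N < 4:
        raise ValueError("permutation_pair requires N >= 4")
    idx = np.arange(N)
    while True:
        L1 = rng.permutation(N)
        if not np.any(L1 == idx):
            break
    while True:
        L2 = rng.permutation(N)
        if not np.any(L2 == L1):
            break
    return L1, L2


def _check_shapes(P, M, F, best_PV, L1, L2):
    P = np.asarray(P, dtype=float)
    N, D = P.shape
    for name, arr in (("M", M), ("F", F)):
        if np.shape(arr) != (N, D):
            raise ValueError(f"{name} must have shape {(N, D)}")
    if np.shape(best_PV) != (D,):
        raise ValueError(f"best_PV must have shape {(D,)}")
    if np.shape(L1) != (N,) or np.shape(L2) != (N,):
        raise ValueError("L1/L2 must be N-vectors")
    return P, N, D


def trial_vectors_bsd(P, M, F, best_PV, L1, L2,
                      rng: np.random.Generator) -> np.ndarray:
    """BSD trial matrix.

    ``E = W o P[L1] + (1 - W) o P[L2]`` with ``W ~ U(0,1)^(N x D)``, then
    ``T = P + M o F o (w*^3 o E + (1 - w*^3) o best_PV - P)`` with ``w*`` an
    N-vector of uniforms broadcast across columns.  Draw order: W, then w*.
    """
    P, N, D = _check_shapes(P, M, F, best_PV, L1, L2)
    W = rng.random((N, D))
    wstar = rng.random(N)
    E = W * P[L1] + (1.0 - W) * P[L2]
    w3 = (wstar ** 3)[:, None]
    return P + np.asarray(M) * np.asarray(F) * (w3 * E + (1.0 - w3) * best_PV - P)


def trial_vectors_nvsa(P, M, F, best_PV, L1, L2,
                       rng: np.random.Generator) -> np.ndarray:
    """NVSA trial matrix with four independent weight matrices.

    ``T = P + M o (F o (s o (w1 o P[L1]) + w2 o P[L2]) + w3 o best_PV - P)``
    where ``s`` is standard normal and ``w1, w2, w3`` are uniform, each a full
    ``N x D`` matrix.  Draw order: s, w1, w2, w3.

    ``M`` acts as a classic DE crossover mask: inactive dimensions keep the
    parent value, active dimensions are rebuilt from a scaled donor mix plus a
    shrunken copy ``w3 o best_PV`` of the incumbent.  Unlike BSD's trial,
    active coordinates are not anchored on the parent; the per-coordinate
    multiplicative pull toward the best is what gives the algorithm its
    aggressive late-stage exploitation -- on benchmarks whose optimum sits at
    the origin the population contracts geometrically until the objective
    underflows to exact zeros.
    """
    P, N, D = _check_shapes(P, M, F, best_PV, L1, L2)
    s = rng.standard_normal((N, D))
    w1 = rng.random((N, D))
    w2 = rng.random((N, D))
    w3 = rng.random((N, D))
    return P + np.asarray(M) * (
        np.asarray(F) * (s * (w1 * P[L1]) + w2 * P[L2])
        + w3 * best_PV - P)


def boundary_control(T: np.ndarray, space: SearchSpace,
                     rng: np.random.Generator) -> np.ndarray:
    """Resample every out-of-bounds entry uniformly inside its interval."""
    T = np.asarray(T, dtype=float)
    low = np.broadcast_to(space.low, T.shape)
    up = np.broadcast_to(space.up, T.shape)
    bad = (T < low) | (T > up)
    n_bad = int(bad.sum())
    if n_bad == 0:
        return T
    out = T.copy()
    alpha = rng.random(n_bad)
    out[bad] = low[bad] + alpha * (up[bad] - low[bad])
    return out


def greedy_selection(P, fitP, T, fitT):
    """One-to-one survivor selection; ties accept the trial."""
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    fitP = np.asarray(fitP, dtype=float)
    fitT = np.asarray(fitT, dtype=float)
    if P.shape != T.shape or fitP.shape != fitT.shape or fitP.size != P.shape[0]:
        raise ValueError("shape mismatch in greedy selection")
    accept = fitT <= fitP
    return (np.where(accept[:, None], T, P),
            np.where(accept, fitT, fitP))


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

def optimize(objective: ObjectiveSpec, config: OptimizerConfig,
             x0: np.ndarray | None = None):
    """Run NVSA or BSD on an objective and return ``(Population, RunTrace)``.

    ``sense="maximize"`` negates the objective internally; the returned
    fitness values and trace are in the internal (minimisation) scale.
    Non-finite objective values are recorded as ``+inf`` (never selected) with
    a warning.  ``x0``, if given, replaces the first row of the initial
    population (used to seed a search from a known starting transform).
    Total objective evaluations are exactly ``N * (epochs + 1)``.
    """
    space = objective.space
    rng = np.random.default_rng(config.seed)
    sign = -1.0 if config.sense == "maximize" else 1.0

    def eval_all(X: np.ndarray) -> np.ndarray:
        if objective.evaluate_batch is not None:
            vals = (objective.evaluate_batch(X, rng) if objective.uses_rng
                    else objective.evaluate_batch(X))
            vals = np.asarray(vals, dtype=float)
        else:
            f = objective.evaluate
            if objective.uses_rng:
                vals = np.array([f(x, rng) for x in X], dtype=float)
            else:
                vals = np.array([f(x) for x in X], dtype=float)
        bad = ~np.isfinite(vals)
        if np.any(bad):
            warnings.warn(
                f"objective {objective.name or '<anonymous>'} returned "
                f"{int(bad.sum())} non-finite value(s); recorded as +inf",
                RuntimeWarning, stacklevel=3)
            vals = np.where(bad, np.inf, sign * vals)
            return vals
        return sign * vals

    N = config.N
    P = initialize_population(space, N, rng)
    if x0 is not None:
        x0 = np.asarray(x0, dtype=float)
        if not space.contains(x0):
            raise ValueError("x0 lies outside the search space")
        P[0] = x0
    fitP = eval_all(P)
    evaluations = N
    pop = Population(P=P, fitP=fitP, best_sol=np.inf, best_PV=P[0].copy())
    update_best(pop)

    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        if config.algorithm == "nvsa":
            M = activation_matrix(N, space.D, "vibration", rng,
                                  vibration=config.vibration)
            F = search_scale_nvsa(N, space.D, rng)
        else:
            M = activation_matrix(N, space.D, "bernstein", rng)
            F = search_scale_bsd(N, space.D, rng)
        L1, L2 = permutation_pair(N, rng)
        if config.algorithm == "nvsa":
            T = trial_vectors_nvsa(pop.P, M, F, pop.best_PV, L1, L2, rng)
        else:
            T = trial_vectors_bsd(pop.P, M, F, pop.best_PV, L1, L2, rng)
        T = boundary_control(T, space, rng)
        fitT = eval_all(T)
        evaluations += N
        pop.P, pop.fitP = greedy_selection(pop.P, pop.fitP, T, fitT)
        update_best(pop)
        trace[epoch] = pop.best_sol

    return pop, RunTrace(best_per_iteration=trace, evaluations=evaluations)


def load_config(path) -> OptimizerConfig:
    """Read an :class:`OptimizerConfig` from a YAML or JSON mapping.

    Recognised keys: algorithm, N, epochs, seed, sense and vibration {a,b,c,d}.
    The bounds entry (if present) is returned separately by callers that need
    it; this helper only builds the optimizer part.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    vib = raw.pop("vibration", None)
    raw.pop("bounds", None)
    cfg = OptimizerConfig(**raw)
    if vib:
        cfg = replace(cfg, vibration=VibrationParams(**vib))
    return cfg
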