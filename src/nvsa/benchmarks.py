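"""The 23 classic single-objective test functions (Yao-style suite).

F1-F13 are the scalable unimodal/multimodal functions at D=30 by default;
F14-F23 are the fixed-dimension functions (foxholes, Kowalik, six-hump camel,
Branin, Goldstein-Price, Hartmann 3/6, Shekel 5/7/10).  Every function is
vectorised over the last axis, so a whole population evaluates in one call.

F7 (quartic with noise) adds a fresh ``U(0,1)`` term per evaluation drawn from
the run's seeded stream, so suite runs stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optimizers import ObjectiveSpec, OptimizerConfig, SearchSpace, optimize

__all__ = ["BenchmarkProblem", "SuiteResult", "make_benchmark", "run_suite",
           "BENCHMARK_IDS"]


# ---------------------------------------------------------------------------
# function definitions (vectorised over the last axis)
# ---------------------------------------------------------------------------

def sphere(X):
    X = np.asarray(X, dtype=float)
    return (X ** 2).sum(-1)


def schwefel_222(X):
    A = np.abs(np.asarray(X, dtype=float))
    return A.sum(-1) + A.prod(-1)


def schwefel_12(X):
    X = np.asarray(X, dtype=float)
    return (np.cumsum(X, axis=-1) ** 2).sum(-1)


def schwefel_221(X):
    return np.abs(np.asarray(X, dtype=float)).max(-1)


def rosenbrock(X):
    X = np.asarray(X, dtype=float)
    return (100.0 * (X[..., 1:] - X[..., :-1] ** 2) ** 2
            + (X[..., :-1] - 1.0) ** 2).sum(-1)


def step(X):
    X = np.asarray(X, dtype=float)
    return (np.floor(X + 0.5) ** 2).sum(-1)


def quartic_noise(X, rng):
    X = np.asarray(X, dtype=float)
    i = np.arange(1, X.shape[-1] + 1)
    return (i * X ** 4).sum(-1) + rng.random(X.shape[:-1])


def schwefel_226(X):
    X = np.asarray(X, dtype=float)
    return -(X * np.sin(np.sqrt(np.abs(X)))).sum(-1)


def rastrigin(X):
    X = np.asarray(X, dtype=float)
    return (X ** 2 - 10.0 * np.cos(2.0 * np.pi * X) + 10.0).sum(-1)


def ackley(X):
    X = np.asarray(X, dtype=float)
    D = X.shape[-1]
    return (-20.0 * np.exp(-0.2 * np.sqrt((X ** 2).sum(-1) / D))
            - np.exp(np.cos(2.0 * np.pi * X).sum(-1) / D) + 20.0 + np.e)


def griewank(X):
    X = np.asarray(X, dtype=float)
    i = np.sqrt(np.arange(1, X.shape[-1] + 1))
    return (X ** 2).sum(-1) / 4000.0 - np.cos(X / i).prod(-1) + 1.0


def _penalty(X, a, k, m):
    return (k * np.where(X > a, (X - a) ** m,
                         np.where(X < -a, (-X - a) ** m, 0.0))).sum(-1)


def penalized1(X):
    X = np.asarray(X, dtype=float)
    D = X.shape[-1]
    y = 1.0 + (X + 1.0) / 4.0
    core = (10.0 * np.sin(np.pi * y[..., 0]) ** 2
            + ((y[..., :-1] - 1.0) ** 2
               * (1.0 + 10.0 * np.sin(np.pi * y[..., 1:]) ** 2)).sum(-1)
            + (y[..., -1] - 1.0) ** 2)
    return np.pi / D * core + _penalty(X, 10.0, 100.0, 4)


def penalized2(X):
    X = np.asarray(X, dtype=float)
    core = (np.sin(3.0 * np.pi * X[..., 0]) ** 2
            + ((X[..., :-1] - 1.0) ** 2
               * (1.0 + np.sin(3.0 * np.pi * X[..., 1:]) ** 2)).sum(-1)
            + (X[..., -1] - 1.0) ** 2
            * (1.0 + np.sin(2.0 * np.pi * X[..., -1]) ** 2))
    return 0.1 * core + _penalty(X, 5.0, 100.0, 4)


_FOX_A = np.array([
    [-32, -16, 0, 16, 32] * 5,
    sum(([v] * 5 for v in (-32, -16, 0, 16, 32)), []),
], dtype=float)


def foxholes(X):
    X = np.asarray(X, dtype=float)
    d = ((X[..., :, None] - _FOX_A) ** 6).sum(-2)  # (..., 25)
    j = np.arange(1, 26)
    return 1.0 / (1.0 / 500.0 + (1.0 / (j + d)).sum(-1))


_KOW_A = np.array([0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
                   0.0456, 0.0342, 0.0323, 0.0235, 0.0246])
_KOW_B = np.array([4.0, 2.0, 1.0, 0.5, 0.25, 1 / 6, 1 / 8, 1 / 10,
                   1 / 12, 1 / 14, 1 / 16])


def kowalik(X):
    X = np.asarray(X, dtype=float)
    x1, x2, x3, x4 = (X[..., i, None] for i in range(4))
    b = _KOW_B
    model = x1 * (b ** 2 + b * x2) / (b ** 2 + b * x3 + x4)
    return ((_KOW_A - model) ** 2).sum(-1)


def camel6(X):
    X = np.asarray(X, dtype=float)
    x, y = X[..., 0], X[..., 1]
    return (4.0 * x ** 2 - 2.1 * x ** 4 + x ** 6 / 3.0
            + x * y - 4.0 * y ** 2 + 4.0 * y ** 4)


def branin(X):
    X = np.asarray(X, dtype=float)
    x, y = X[..., 0], X[..., 1]
    return ((y - 5.1 / (4 * np.pi ** 2) * x ** 2 + 5.0 / np.pi * x - 6.0) ** 2
            + 10.0 * (1.0 - 1.0 / (8 * np.pi)) * np.cos(x) + 10.0)


def goldstein_price(X):
    X = np.asarray(X, dtype=float)
    x, y = X[..., 0], X[..., 1]
    a = 1 + (x + y + 1) ** 2 * (19 - 14 * x + 3 * x ** 2 - 14 * y
                                + 6 * x * y + 3 * y ** 2)
    b = 30 + (2 * x - 3 * y) ** 2 * (18 - 32 * x + 12 * x ** 2 + 48 * y
                                     - 36 * x * y + 27 * y ** 2)
    return a * b


_H3_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_H3_A = np.array([[3.0, 10, 30], [0.1, 10, 35], [3.0, 10, 30], [0.1, 10, 35]])
_H3_P = 1e-4 * np.array([[3689, 1170, 2673], [4699, 4387, 7470],
                         [1091, 8732, 5547], [381, 5743, 8828]])
_H6_A = np.array([[10, 3, 17, 3.5, 1.7, 8],
                  [0.05, 10, 17, 0.1, 8, 14],
                  [3, 3.5, 1.7, 10, 17, 8],
                  [17, 8, 0.05, 10, 0.1, 14]], dtype=float)
_H6_P = 1e-4 * np.array([[1312, 1696, 5569, 124, 8283, 5886],
                         [2329, 4135, 8307, 3736, 1004, 9991],
                         [2348, 1451, 3522, 2883, 3047, 6650],
                         [4047, 8828, 8732, 5743, 1091, 381]])


def _hartmann(X, A, Pm):
    X = np.asarray(X, dtype=float)
    inner = (A * (X[..., None, :] - Pm) ** 2).sum(-1)  # (..., 4)
    return -(_H3_ALPHA * np.exp(-inner)).sum(-1)


def hartmann3(X):
    return _hartmann(X, _H3_A, _H3_P)


def hartmann6(X):
    return _hartmann(X, _H6_A, _H6_P)


_SHEKEL_A = np.array([[4, 4, 4, 4], [1, 1, 1, 1], [8, 8, 8, 8], [6, 6, 6, 6],
                      [3, 7, 3, 7], [2, 9, 2, 9], [5, 5, 3, 3], [8, 1, 8, 1],
                      [6, 2, 6, 2], [7, 3.6, 7, 3.6]], dtype=float)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def shekel(X, m):
    X = np.asarray(X, dtype=float)
    d = ((X[..., None, :] - _SHEKEL_A[:m]) ** 2).sum(-1)  # (..., m)
    return -(1.0 / (d + _SHEKEL_C[:m])).sum(-1)


def shekel5(X):
    return shekel(X, 5)


def shekel7(X):
    return shekel(X, 7)


def shekel10(X):
    return shekel(X, 10)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkProblem:
    id: str
    D: int
    space: SearchSpace
    objective: ObjectiveSpec
    known_optimum: float | None


# id -> (func, (low, up), fixed D or None for scalable, optimum, uses_rng)
_REGISTRY = {
    "F1": (sphere, (-100, 100), None, 0.0, False),
    "F2": (schwefel_222, (-10, 10), None, 0.0, False),
    "F3": (schwefel_12, (-100, 100), None, 0.0, False),
    "F4": (schwefel_221, (-100, 100), None, 0.0, False),
    "F5": (rosenbrock, (-30, 30), None, 0.0, False),
    "F6": (step, (-100, 100), None, 0.0, False),
    "F7": (quartic_noise, (-1.28, 1.28), None, None, True),
    "F8": (schwefel_226, (-500, 500), None, None, False),
    "F9": (rastrigin, (-5.12, 5.12), None, 0.0, False),
    "F10": (ackley, (-32, 32), None, 0.0, False),
    "F11": (griewank, (-600, 600), None, 0.0, False),
    "F12": (penalized1, (-50, 50), None, 0.0, False),
    "F13": (penalized2, (-50, 50), None, 0.0, False),
    "F14": (foxholes, (-65.536, 65.536), 2, 0.998003838, False),
    "F15": (kowalik, (-5, 5), 4, 3.0749e-4, False),
    "F16": (camel6, (-5, 5), 2, -1.0316285, False),
    "F17": (branin, (-5, 15), 2, 0.39788736, False),
    "F18": (goldstein_price, (-2, 2), 2, 3.0, False),
    "F19": (hartmann3, (0, 1), 3, -3.86278, False),
    "F20": (hartmann6, (0, 1), 6, -3.32237, False),
    "F21": (shekel5, (0, 10), 4, -10.1532, False),
    "F22": (shekel7, (0, 10), 4, -10.4029, False),
    "F23": (shekel10, (0, 10), 4, -10.5364, False),
}

BENCHMARK_IDS = tuple(_REGISTRY)


def make_benchmark(fid: str, D_override: int | None = None) -> BenchmarkProblem:
    """Build a classic benchmark problem by id (``"F6"`` or ``"SOP_F6"``).

    Scalable functions (F1-F13) default to D=30; fixed-dimension functions
    (F14-F23) ignore ``D_override``.  Branin uses its usual asymmetric box
    x1 in [-5, 10], x2 in [0, 15].
    """
    key = fid.upper().removeprefix("SOP_")
    if key not in _REGISTRY:
        raise KeyError(f"unknown benchmark id {fid!r}")
    func, (lo, hi), fixed_D, opt, uses_rng = _REGISTRY[key]
    if fixed_D is None:
        D = int(D_override) if D_override else 30
    else:
        D = fixed_D
    if key == "F17":
        space = SearchSpace(np.array([-5.0, 0.0]), np.array([10.0, 15.0]))
    else:
        space = SearchSpace.cube(lo, hi, D)
    if uses_rng:
        spec = ObjectiveSpec(evaluate=lambda x, rng: float(func(x, rng)),
                             evaluate_batch=func, space=space,
                             name=f"SOP_{key}", uses_rng=True)
    else:
        spec = ObjectiveSpec(evaluate=lambda x: float(func(x)),
                             evaluate_batch=func, space=space,
                             name=f"SOP_{key}")
    return BenchmarkProblem(id=f"SOP_{key}", D=D, space=space,
                            objective=spec, known_optimum=opt)


@dataclass
class SuiteResult:
    """Per-run best values and their per-problem mean/std over R runs."""

    records: pd.DataFrame   # columns problem, run, best_value
    summary: pd.DataFrame   # columns problem, mean, std
    runs: int


def run_suite(problems, config: OptimizerConfig, runs: int,
              out_csv=None) -> SuiteResult:
    """Run each problem ``runs`` times with seeds ``config.seed + run``.

    Mirrors the benchmark protocol (50 particles, 1000 iterations, 30 runs
    at full scale); mean and standard deviation of the final best values are
    the performance indicators.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    base_seed = config.seed if config.seed is not None else 0
    rows = []
    for prob in problems:
        for r in range(runs):
            cfg = OptimizerConfig(N=config.N, epochs=config.epochs,
                                  algorithm=config.algorithm,
                                  vibration=config.vibration,
                                  seed=base_seed + r, sense=config.sense)
            pop, _ = optimize(prob.objective, cfg)
            rows.append({"problem": prob.id, "run": r,
                         "best_value": pop.best_sol})
    records = pd.DataFrame(rows)
    grouped = records.groupby("problem", sort=False)["best_value"]
    summary = pd.DataFrame({
        "problem": list(grouped.groups),
        "mean": grouped.mean().values,
        "std": (grouped.std(ddof=1).fillna(0.0).values if runs > 1
                else np.zeros(len(grouped))),
    })
    if out_csv is not None:
        records.to_csv(out_csv, index=False)
    return SuiteResult(records=records, summary=summary, runs=runs)
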