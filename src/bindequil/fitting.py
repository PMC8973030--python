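"""Least-squares estimation of concentrations and dissociation constants.

The estimator mirrors a slider-driven search: candidate parameter values
live on a discrete grid of two-significant-figure positions per decade
(mantissa 1.0–9.9 in steps of 0.1) spanning 1e-9 to 1e-1 mol/L.  Three
grid strategies are provided — an exhaustive single pass, a coarse-then-
fine two-pass search, and an iterative coordinate descent from an
initial guess — plus a continuous refiner that polishes the grid optimum
in log-parameter space with a bounded quasi-Newton minimizer.

Residuals are computed on the y-scale the user selected (relative
fraction or absolute concentration), unweighted.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import equilibria
from .curves import evaluate_point
from .equilibria import SystemSpec, ThermoContext, assoc_const, gibbs_energy
from .errors import ConfigurationError, DataParseError, NumericalFailureError

__all__ = [
    "DataPoint",
    "FitProblem",
    "FitResult",
    "SliderGrid",
    "parse_data",
    "ssr",
    "fit_single_pass",
    "fit_two_pass",
    "fit_iterative",
    "fit_continuous",
]


@dataclass(frozen=True)
class DataPoint:
    """One observation: axis value x (mol/L) and observed y."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise DataParseError(f"non-finite data point ({self.x!r}, {self.y!r})")


_NUMBER = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?$")


def parse_data(text: str) -> list[DataPoint]:
    """Parse pasted two-column data into points.

    Each non-blank row holds two numbers — plain decimals or E notation
    ("0.00028" and "2.8e-4" are the same value) — separated by
    whitespace and/or commas.  A malformed row raises
    :class:`DataParseError` naming the offending row.
    """
    points: list[DataPoint] = []
    row_no = 0
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        row_no += 1
        fields = [f for f in re.split(r"[,\s]+", line) if f]
        if len(fields) != 2 or not all(_NUMBER.match(f) for f in fields):
            raise DataParseError(
                f"row {row_no}: expected two numbers, got {line!r}"
            )
        points.append(DataPoint(float(fields[0]), float(fields[1])))
    return points


@dataclass(frozen=True)
class SliderGrid:
    """Discrete parameter positions emulating two-digit slider labels.

    Positions are m × 10^e for every mantissa m and decade e, plus the
    upper decade boundary.  The coarse pass visits only a quarter-decade
    subset of mantissas.
    """

    exp_min: int = -9
    exp_max: int = -1
    mantissa_step: float = 0.1
    coarse_mantissas: tuple[float, ...] = (1.0, 1.8, 3.2, 5.6)

    def positions(self, coarse: bool = False) -> np.ndarray:
        if coarse:
            mantissas = np.array(self.coarse_mantissas)
        else:
            n = round((10.0 - 1.0) / self.mantissa_step)
            mantissas = 1.0 + self.mantissa_step * np.arange(n)
        vals = [
            round(m, 10) * 10.0**e
            for e in range(self.exp_min, self.exp_max)
            for m in mantissas
        ]
        vals.append(10.0**self.exp_max)
        return np.array(vals)

    @property
    def lo(self) -> float:
        return 10.0**self.exp_min

    @property
    def hi(self) -> float:
        return 10.0**self.exp_max


@dataclass(frozen=True)
class FitProblem:
    """A least-squares problem tying data to one model curve.

    ``model`` is a fully parameterized system spec serving as the
    template; values of parameters named in ``free_params`` are ignored
    and replaced by search candidates.  ``target_curve`` names the
    species curve compared against the data; ``x_variable`` and
    ``y_mode`` have the same meaning as in a sweep.
    """

    model: SystemSpec
    target_curve: str
    data: Sequence[DataPoint]
    free_params: tuple[str, ...]
    x_variable: tuple[str, str] = ("total", "P")
    y_mode: str = "relative-linear"

    def __post_init__(self) -> None:
        if not self.free_params:
            raise ConfigurationError("at least one free parameter required")
        if not self.data:
            raise ConfigurationError("at least one data point required")
        names = {f.name for f in dataclasses.fields(self.model)}
        unknown = set(self.free_params) - names
        if unknown:
            raise ConfigurationError(
                f"{type(self.model).__name__} has no parameter(s) {sorted(unknown)}"
            )

    def with_params(self, values: Mapping[str, float]) -> SystemSpec:
        return dataclasses.replace(self.model, **dict(values))


@dataclass(frozen=True)
class FitResult:
    """Best-fit parameter values with the achieved SSR and derived thermo."""

    params: Mapping[str, float]
    ssr: float
    method: str
    n_evaluations: int = 0
    n_iterations: int = 0
    K_A: Mapping[str, float] = field(default_factory=dict)
    delta_G: Mapping[str, float] = field(default_factory=dict)
    notes: tuple[str, ...] = ()


def ssr(problem: FitProblem, values: Mapping[str, float]) -> float:
    """Sum of squared residuals of the model curve against the data.

    The curve is evaluated through the same path a sweep uses, so the
    objective is exactly the plotted curve.
    """
    system = problem.with_params(values)
    total = 0.0
    for pt in problem.data:
        yhat = evaluate_point(
            system, problem.x_variable, pt.x, problem.y_mode, problem.target_curve
        )
        total += (yhat - pt.y) ** 2
    return total


def _finish(
    problem: FitProblem,
    params: dict[str, float],
    ssr_value: float,
    method: str,
    n_eval: int,
    n_iterations: int = 0,
    notes: tuple[str, ...] = (),
) -> FitResult:
    ctx = ThermoContext()
    ka = {
        name: assoc_const(v) for name, v in params.items() if name.startswith("K_D")
    }
    dg = {
        name: gibbs_energy(v, ctx)
        for name, v in params.items()
        if name.startswith("K_D")
    }
    return FitResult(
        params=params,
        ssr=ssr_value,
        method=method,
        n_evaluations=n_eval,
        n_iterations=n_iterations,
        K_A=ka,
        delta_G=dg,
        notes=notes,
    )


def _grid_search(
    problem: FitProblem,
    axes: Sequence[np.ndarray],
) -> tuple[dict[str, float], float, int]:
    """Minimize SSR over the Cartesian product of per-parameter axes.

    Ties break toward the lexicographically smallest parameter tuple,
    which the ascending iteration order with a strict '<' provides.
    """
    best_vals: dict[str, float] | None = None
    best = math.inf
    n_eval = 0
    for combo in itertools.product(*axes):
        vals = dict(zip(problem.free_params, combo))
        s = ssr(problem, vals)
        n_eval += 1
        if s < best:
            best, best_vals = s, vals
    assert best_vals is not None
    return best_vals, best, n_eval


def fit_single_pass(
    problem: FitProblem, grid: SliderGrid | None = None
) -> FitResult:
    """Exhaustive search of every grid position combination.

    Always finds the global grid optimum; cost grows as positions^k for
    k free parameters, so at most three are allowed.
    """
    grid = grid or SliderGrid()
    if len(problem.free_params) > 3:
        raise ConfigurationError("single-pass search supports at most 3 free parameters")
    pos = grid.positions()
    vals, best, n_eval = _grid_search(problem, [pos] * len(problem.free_params))
    return _finish(problem, vals, best, "single_pass", n_eval)


def fit_two_pass(problem: FitProblem, grid: SliderGrid | None = None) -> FitResult:
    """Coarse scan, then a full-resolution scan near the coarse optimum.

    The fine pass covers every grid position within one decade of each
    coarse winner.  Much cheaper than a single pass but can settle on a
    wrong basin when the SSR landscape is multimodal; the result is
    flagged when the fine pass hit the window edge.
    """
    grid = grid or SliderGrid()
    if len(problem.free_params) > 3:
        raise ConfigurationError("two-pass search supports at most 3 free parameters")
    k = len(problem.free_params)
    coarse_pos = grid.positions(coarse=True)
    coarse_vals, coarse_ssr, n1 = _grid_search(problem, [coarse_pos] * k)

    full = grid.positions()
    axes = []
    for name in problem.free_params:
        c = coarse_vals[name]
        axes.append(full[(full >= c / 10.0) & (full <= c * 10.0)])
    vals, best, n2 = _grid_search(problem, axes)

    notes: tuple[str, ...] = ()
    for name, axis in zip(problem.free_params, axes):
        v = vals[name]
        if len(axis) and (v == axis[0] or v == axis[-1]):
            if v not in (full[0], full[-1]):
                notes = ("fine-pass optimum at search-window edge; "
                         "landscape may be multimodal",)
    assert best <= coarse_ssr + 1e-30
    return _finish(problem, vals, best, "two_pass", n1 + n2, notes=notes)


def fit_iterative(
    problem: FitProblem,
    initial: Mapping[str, float],
    grid: SliderGrid | None = None,
    max_iter: int = 10_000,
) -> FitResult:
    """Coordinate descent over neighbouring grid positions.

    From the initial guess, repeatedly move any free parameter to an
    adjacent grid position whenever that lowers the SSR, until no
    single-parameter move improves — a local minimum of the discretized
    landscape.  Converges quickly when the guess is near a minimum, but
    only to the local one.
    """
    grid = grid or SliderGrid()
    pos = grid.positions()
    idx = {
        name: int(np.argmin(np.abs(pos - initial[name])))
        for name in problem.free_params
    }
    current = {name: pos[i] for name, i in idx.items()}
    best = ssr(problem, current)
    n_eval = 1
    for it in range(max_iter):
        improved = False
        for name in problem.free_params:
            for step in (-1, 1):
                j = idx[name] + step
                if not (0 <= j < len(pos)):
                    continue
                trial = dict(current)
                trial[name] = pos[j]
                s = ssr(problem, trial)
                n_eval += 1
                if s < best:
                    best, current, improved = s, trial, True
                    idx[name] = j
        if not improved:
            return _finish(
                problem, current, best, "iterative", n_eval, n_iterations=it + 1
            )
    raise NumericalFailureError(
        f"iterative search did not converge within {max_iter} sweeps"
    )


def fit_continuous(
    problem: FitProblem,
    initial: Mapping[str, float] | None = None,
    grid: SliderGrid | None = None,
) -> FitResult:
    """Continuous local minimization of the SSR in log-parameter space.

    Starts from the supplied guess (default: the single-pass grid
    optimum) and refines with L-BFGS-B bounded to the grid's span.  The
    result's SSR never exceeds the starting point's.
    """
    grid = grid or SliderGrid()
    if not 1 <= len(problem.free_params) <= 3:
        raise ConfigurationError("continuous fit supports 1-3 free parameters")
    if initial is None:
        start = fit_single_pass(problem, grid)
        init_vals = dict(start.params)
        n_eval0 = start.n_evaluations
    else:
        init_vals = {k: float(initial[k]) for k in problem.free_params}
        n_eval0 = 0

    names = list(problem.free_params)
    x0 = np.log10([init_vals[n] for n in names])
    bounds = [(math.log10(grid.lo), math.log10(grid.hi))] * len(names)

    f0 = ssr(problem, init_vals)
    if f0 == 0.0:  # already a perfect fit; nothing to refine
        return _finish(problem, init_vals, 0.0, "continuous", n_eval0)

    # Normalize by the starting SSR so stopping tolerances are scale-free:
    # absolute SSR magnitudes vary over many decades with the data units.
    def objective(logx: np.ndarray) -> float:
        return ssr(problem, dict(zip(names, 10.0**logx))) / f0

    res = minimize(
        objective, x0, method="Nelder-Mead", bounds=bounds,
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
    )
    if res.fun <= 1.0:
        vals = dict(zip(names, 10.0 ** np.asarray(res.x)))
        best = float(res.fun) * f0
    else:  # keep best-so-far if the polish failed to improve
        vals, best = init_vals, f0
    if not res.success and res.fun > 1.0:
        raise NumericalFailureError(
            f"continuous refinement failed: {res.message}; best-so-far SSR {best}"
        )
    return _finish(
        problem, vals, best, "continuous",
        n_eval0 + int(res.nfev), n_iterations=int(res.nit),
    )
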