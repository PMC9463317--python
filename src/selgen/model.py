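"""Economic model of fertility: income vs substitution effects of human capital.

The model family here formalises why traits that raise labour-market earnings
can be selected either for or against.  A person derives utility from income
and from children; childrearing costs time, so the opportunity cost of a child
rises with the wage (the *substitution effect*, fertility-decreasing), while a
higher income also makes children more affordable (the *income effect*,
fertility-increasing).  Under CRRA utility the balance of the two is governed
by the curvature parameter ``sigma``: at ``sigma = 1`` (log utility) they
cancel exactly, below 1 the substitution effect dominates.

Two variants are implemented:

* a one-period model, ``U = u(Y) + a N`` with ``Y = (1 - b N) W``, which
  admits closed-form marginal analysis (:func:`marginal_benefit_one_period`,
  :func:`cross_partial_decomposition`);
* a two-period model with an education choice ``s`` that raises the period-2
  wage ``w(s, h) = s h``, solved numerically by :func:`solve_two_period`.

:func:`check_predictions` sweeps the two-period model over a parameter grid
and verifies five comparative-statics predictions about the fertility-human
capital gradient ``dN*/dh``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "AgentParams",
    "SolverConfig",
    "SweepConfig",
    "OnePeriodSolution",
    "TwoPeriodChoice",
    "CrossPartial",
    "PredictionReport",
    "InfeasibleModelError",
    "crra_utility",
    "crra_marginal_utility",
    "crra_second_derivative",
    "marginal_benefit_one_period",
    "cross_partial_decomposition",
    "solve_one_period",
    "solve_two_period",
    "fertility_human_capital_gradient",
    "check_predictions",
]

#: below this distance from 1, sigma is treated as log utility
_LOG_SIGMA_TOL = 1e-9


class InfeasibleModelError(ValueError):
    """No feasible allocation with strictly positive incomes exists."""


@dataclass(frozen=True)
class AgentParams:
    """Preference and technology parameters of one agent.

    Parameters
    ----------
    a : float
        Strength of the preference for children (utils per child), > 0.
    b : float
        Time cost of raising one child, as a fraction of a period, in (0, 1).
    sigma : float
        CRRA curvature of the utility of income, > 0; ``sigma = 1`` is log
        utility, where income and substitution effects cancel.
    h : float
        Human capital: the return to education in the period-2 wage
        ``w(s, h) = s h``, > 0.
    W : float
        Wage in the one-period model (period-1 wages in the two-period model
        are normalised to 1), > 0.
    """

    a: float
    b: float
    sigma: float
    h: float = 1.0
    W: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be > 0, got {self.a}")
        if not (0.0 < self.b < 1.0):
            raise ValueError(f"b must be in (0, 1), got {self.b}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if not (self.h > 0):
            raise ValueError(f"h must be > 0, got {self.h}")
        if not (self.W > 0):
            raise ValueError(f"W must be > 0, got {self.W}")

    def replace(self, **changes) -> "AgentParams":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return AgentParams(**kwargs)


@dataclass(frozen=True)
class SolverConfig:
    """Numerical controls for :func:`solve_two_period`.

    ``n_grid_s`` points seed the outer one-dimensional search over education
    time; the best bracket is then polished by bounded scalar minimisation to
    ``tol`` on utility.  Incomes are kept at or above ``income_floor`` because
    CRRA utility is unbounded below (sigma >= 1) or has an infinite derivative
    (sigma < 1) as income approaches zero.
    """

    n_grid_s: int = 1025
    tol: float = 1e-9
    income_floor: float = 1e-9
    corner_tol: float = 1e-6


@dataclass(frozen=True)
class OnePeriodSolution:
    """Optimal choice in the one-period model."""

    N_star: float
    Y: float
    utility: float


@dataclass(frozen=True)
class TwoPeriodChoice:
    """Optimal allocation in the two-period model.

    ``corner_N1`` flags agents who postpone all fertility to period 2;
    ``corner_s`` flags an education choice pinned at a bound of [0, 1].
    """

    N1: float
    N2: float
    s: float
    Y1: float
    Y2: float
    utility: float
    corner_N1: bool
    corner_s: bool

    @property
    def N_total(self) -> float:
        return self.N1 + self.N2


@dataclass(frozen=True)
class CrossPartial:
    """Decomposition of d2U/dNdW into substitution and income effects."""

    substitution: float
    income: float
    total: float


def crra_utility(y, sigma: float):
    """Constant-relative-risk-aversion utility ``u(y) = (y^(1-sigma) - 1)/(1 - sigma)``.

    Returns the log limit when ``sigma`` is within ``1e-9`` of 1.  Strictly
    increasing and strictly concave on ``y > 0`` for every ``sigma > 0``.

    Raises
    ------
    ValueError
        If ``y <= 0`` (utility undefined; for sigma >= 1 the limit is -inf)
        or ``sigma <= 0``.
    """
    y = np.asarray(y, dtype=float)
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if np.any(y <= 0):
        raise ValueError("CRRA utility requires strictly positive income")
    if abs(sigma - 1.0) < _LOG_SIGMA_TOL:
        out = np.log(y)
    else:
        out = (y ** (1.0 - sigma) - 1.0) / (1.0 - sigma)
    return out if out.ndim else float(out)


def crra_marginal_utility(y, sigma: float):
    """Marginal utility ``u'(y) = y^(-sigma)`` (valid for all sigma > 0)."""
    y = np.asarray(y, dtype=float)
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if np.any(y <= 0):
        raise ValueError("marginal utility requires strictly positive income")
    out = y ** (-sigma)
    return out if out.ndim else float(out)


def crra_second_derivative(y, sigma: float):
    """Second derivative ``u''(y) = -sigma * y^(-sigma - 1)``."""
    y = np.asarray(y, dtype=float)
    if not (sigma > 0):
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if np.any(y <= 0):
        raise ValueError("second derivative requires strictly positive income")
    out = -sigma * y ** (-sigma - 1.0)
    return out if out.ndim else float(out)


def marginal_benefit_one_period(p: AgentParams, N: float) -> float:
    """Marginal benefit of an extra child, ``dU/dN = -b W u'(Y) + a``.

    ``Y = (1 - b N) W`` is income after the time cost of ``N`` children.
    Strictly decreasing in ``N`` for sigma > 0.
    """
    if p.b * N >= 1.0:
        raise ValueError(f"bN = {p.b * N} >= 1: no labour time left")
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    Y = (1.0 - p.b * N) * p.W
    return p.a - p.b * p.W * crra_marginal_utility(Y, p.sigma)


def cross_partial_decomposition(p: AgentParams, N: float) -> CrossPartial:
    """Effect of a wage rise on the marginal benefit of a child.

    ``d2U/dNdW = -b u'(Y)  [substitution]  - b Y u''(Y)  [income]``.

    Under CRRA the sum collapses to ``b (sigma - 1) Y^(-sigma)``: negative for
    sigma < 1 (substitution dominates), exactly zero at log utility, positive
    for sigma > 1.
    """
    Y = (1.0 - p.b * N) * p.W
    if Y <= 0:
        raise ValueError(f"income Y = {Y} must be strictly positive")
    substitution = -p.b * crra_marginal_utility(Y, p.sigma)
    income = -p.b * Y * crra_second_derivative(Y, p.sigma)
    return CrossPartial(substitution, income, substitution + income)


def solve_one_period(p: AgentParams) -> OnePeriodSolution:
    """Maximise ``u((1 - bN) W) + a N`` over ``N >= 0`` in closed form.

    The objective is strictly concave in N, so the first-order condition
    ``u'(Y) = a / (b W)`` pins the optimal income ``Y* = (a/(bW))^(-1/sigma)``;
    the corner ``N = 0`` binds when ``Y*`` would exceed full-time income W.
    """
    y_star = (p.a / (p.b * p.W)) ** (-1.0 / p.sigma)
    y_star = min(max(y_star, 1e-12), p.W)
    N = (1.0 - y_star / p.W) / p.b
    if N < 0:
        N, y_star = 0.0, p.W
    U = float(crra_utility(y_star, p.sigma)) + p.a * N
    return OnePeriodSolution(N_star=N, Y=y_star, utility=U)


# ---------------------------------------------------------------------------
# two-period model
# ---------------------------------------------------------------------------

def _period1_best(p: AgentParams, s, eps: float):
    """Closed-form optimum of u(1 - s - b N1) + a N1 over feasible N1, fixed s.

    Concave in N1; interior FOC is u'(Y1) = a/b.  Vectorised over s.
    """
    s = np.asarray(s, dtype=float)
    full_income = 1.0 - s  # N1 = 0
    y_foc = (p.a / p.b) ** (-1.0 / p.sigma)
    Y1 = np.clip(np.minimum(y_foc, full_income), eps, None)
    N1 = np.maximum((full_income - Y1) / p.b, 0.0)
    util = crra_utility(np.maximum(Y1, eps), p.sigma) + p.a * N1
    return N1, Y1, util


def _period2_best(p: AgentParams, s, eps: float):
    """Closed-form optimum of u((1 - b N2) s h) + a N2, fixed s.

    Interior FOC is u'(Y2) = a / (b s h).
    """
    s = np.asarray(s, dtype=float)
    wage = s * p.h  # full-time period-2 income
    y_foc = (p.a / (p.b * wage)) ** (-1.0 / p.sigma)
    Y2 = np.clip(np.minimum(y_foc, wage), eps, None)
    N2 = np.maximum((1.0 - Y2 / wage) / p.b, 0.0)
    util = crra_utility(np.maximum(Y2, eps), p.sigma) + p.a * N2
    return N2, Y2, util


def _two_period_value(p: AgentParams, s, eps: float):
    _, _, u1 = _period1_best(p, s, eps)
    _, _, u2 = _period2_best(p, s, eps)
    return u1 + u2


def solve_two_period(p: AgentParams, cfg: SolverConfig | None = None) -> TwoPeriodChoice:
    """Maximise ``u(Y1) + u(Y2) + a (N1 + N2)`` subject to per-period budgets.

    Budgets (no borrowing, period-1 wage normalised to 1):
    ``Y1 = 1 - s - b N1`` and ``Y2 = (1 - b N2) s h``, with ``N1, N2 >= 0``
    and ``s in [0, 1]``.

    For fixed education time ``s`` the problem separates into two strictly
    concave one-dimensional subproblems with closed-form solutions, so the
    solver reduces to a one-dimensional search over ``s``: a dense grid locates
    the global basin (the value function can be kinked at corner transitions),
    then bounded scalar minimisation polishes the optimum.

    Raises
    ------
    InfeasibleModelError
        If no ``s`` admits strictly positive incomes in both periods.
    """
    cfg = cfg or SolverConfig()
    eps = cfg.income_floor
    # Y2 = s*h*(1 - b*N2) >= eps requires s >= eps/h; Y1 >= eps requires s <= 1 - eps.
    s_lo = max(eps / p.h, eps)
    s_hi = 1.0 - eps
    if s_lo >= s_hi:
        raise InfeasibleModelError(
            f"no education time s in [0, 1] yields positive incomes (h={p.h})"
        )
    grid = np.linspace(s_lo, s_hi, cfg.n_grid_s)
    vals = _two_period_value(p, grid, eps)
    if not np.all(np.isfinite(vals)):
        raise InfeasibleModelError("two-period objective non-finite on the whole grid")
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda s: -float(_two_period_value(p, s, eps)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise RuntimeError(f"two-period solver failed to converge: {res.message}")
    s_star, best = float(res.x), -float(res.fun)
    if best < vals[i]:  # polished point must not be worse than its seed
        s_star, best = float(grid[i]), float(vals[i])
    N1, Y1, _ = _period1_best(p, s_star, eps)
    N2, Y2, _ = _period2_best(p, s_star, eps)
    return TwoPeriodChoice(
        N1=float(N1),
        N2=float(N2),
        s=s_star,
        Y1=float(Y1),
        Y2=float(Y2),
        utility=best,
        corner_N1=bool(N1 < cfg.corner_tol),
        corner_s=bool(s_star - s_lo < cfg.corner_tol or s_hi - s_star < cfg.corner_tol),
    )


def fertility_human_capital_gradient(
    p: AgentParams,
    delta: float = 1e-3,
    cfg: SolverConfig | None = None,
) -> float:
    """Central finite difference of total fertility ``N* = N1* + N2*`` in ``h``.

    The sign of this gradient is the model's core comparative static: negative
    when the substitution effect of human capital dominates.  ``delta`` should
    comfortably exceed the solver's noise in ``N*`` (see ``SolverConfig.tol``).
    """
    if delta <= 0 or p.h - delta <= 0:
        raise ValueError("delta must be positive and smaller than h")
    hi = solve_two_period(p.replace(h=p.h + delta), cfg)
    lo = solve_two_period(p.replace(h=p.h - delta), cfg)
    return (hi.N_total - lo.N_total) / (2.0 * delta)


# ---------------------------------------------------------------------------
# prediction sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Parameter grids for the comparative-statics prediction sweep.

    The predictions are claimed for sigma below, but close to, 1 — the regime
    where the substitution effect dominates at low incomes and fades as income
    rises.  ``noise_floor`` is the gradient magnitude below which sign claims
    are suppressed (numerical noise from the solver and finite differencing).
    """

    a_grid: tuple[float, ...] = (0.3, 0.6, 1.0)
    b_grid: tuple[float, ...] = (0.05, 0.1, 0.15)
    sigma_grid: tuple[float, ...] = (0.8, 0.875, 0.95)
    h_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
    delta: float = 1e-3
    noise_floor: float = 5e-4
    s_tol: float = 1e-3


@dataclass
class PredictionReport:
    """Outcome of the five comparative-statics predictions over a sweep.

    ``passed[k]`` is True iff ``counterexamples[k]`` is empty.  Each
    counterexample records the parameter point(s) and gradients involved.
    ``evaluations`` holds one row per grid point: (a, b, sigma, h, N1, N2,
    s, gradient, corner_N1).
    """

    passed: dict[int, bool] = field(default_factory=dict)
    counterexamples: dict[int, list] = field(default_factory=dict)
    n_checks: dict[int, int] = field(default_factory=dict)
    evaluations: list = field(default_factory=list)
    infeasible_points: list = field(default_factory=list)

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.evaluations,
            columns=["a", "b", "sigma", "h", "N1", "N2", "s", "gradient", "corner_N1"],
        )

    def summary_frame(self):
        import pandas as pd

        rows = [
            {
                "prediction": k,
                "passed": self.passed[k],
                "n_checks": self.n_checks[k],
                "n_counterexamples": len(self.counterexamples[k]),
            }
            for k in sorted(self.passed)
        ]
        return pd.DataFrame(rows)


_PREDICTIONS = {
    1: "dN*/dh negative",
    2: "weaker at higher h",
    3: "more negative at larger b",
    4: "weaker at higher education s*",
    5: "weaker among those starting fertility in period 2",
}


def check_predictions(
    sweep: SweepConfig | None = None,
    solver_cfg: SolverConfig | None = None,
) -> PredictionReport:
    """Evaluate the five comparative-statics predictions over a parameter sweep.

    1. The fertility-human capital gradient dN*/dh is negative: no grid point
       has a gradient above the noise floor, and at least one is below minus
       the floor (so a uniformly-zero gradient, as at log utility, fails).
    2. |dN*/dh| is weakly decreasing along each h-grid line.
    3. dN*/dh decreases (more negative) along each b-grid line, comparing
       points in the same fertility regime (same N1-corner status): across a
       corner transition the composition effect of prediction 5 takes over.
    4. Across agents differing only in h, the agent with the larger optimal
       education s* has the smaller |dN*/dh| (education variation across
       people is attributed to human capital, matching the empirical split by
       realized education; variation in the child-preference a moves education
       and fertility together and is not covered by the prediction).
    5. Within each (a, b, sigma) slice, mean |dN*/dh| among corner solutions
       (N1* = 0, fertility postponed to period 2) is smaller than among
       interior solutions.

    All comparisons use the sweep's noise floor as slack, because gradients
    are finite differences of a numerically-solved optimum.
    """
    sweep = sweep or SweepConfig()
    report = PredictionReport()
    floor = sweep.noise_floor

    results: dict[tuple, dict] = {}
    for a, b, sigma, h in itertools.product(
        sweep.a_grid, sweep.b_grid, sweep.sigma_grid, sweep.h_grid
    ):
        p = AgentParams(a=a, b=b, sigma=sigma, h=h)
        try:
            sol = solve_two_period(p, solver_cfg)
            grad = fertility_human_capital_gradient(p, sweep.delta, solver_cfg)
        except InfeasibleModelError as exc:
            report.infeasible_points.append(((a, b, sigma, h), str(exc)))
            continue
        results[(a, b, sigma, h)] = {"sol": sol, "grad": grad}
        report.evaluations.append(
            (a, b, sigma, h, sol.N1, sol.N2, sol.s, grad, sol.corner_N1)
        )

    for k in _PREDICTIONS:
        report.counterexamples[k] = []
        report.n_checks[k] = 0

    # prediction 1: no significantly positive gradient, at least one negative
    any_negative = False
    for key, r in results.items():
        report.n_checks[1] += 1
        if r["grad"] > floor:
            report.counterexamples[1].append((key, r["grad"]))
        if r["grad"] < -floor:
            any_negative = True
    if not any_negative and results:
        report.counterexamples[1].append(("no gradient below the noise floor", None))

    # prediction 2: |gradient| decreasing in h along grid lines
    for a, b, sigma in itertools.product(sweep.a_grid, sweep.b_grid, sweep.sigma_grid):
        line = [
            (h, results[(a, b, sigma, h)]["grad"])
            for h in sweep.h_grid
            if (a, b, sigma, h) in results
        ]
        for (h1, g1), (h2, g2) in zip(line, line[1:]):
            report.n_checks[2] += 1
            if abs(g2) > abs(g1) + floor:
                report.counterexamples[2].append(((a, b, sigma, h1, h2), (g1, g2)))

    # prediction 3: gradient more negative at larger b, within a fertility regime
    for a, sigma, h in itertools.product(sweep.a_grid, sweep.sigma_grid, sweep.h_grid):
        line = [
            (b, results[(a, b, sigma, h)]["grad"], results[(a, b, sigma, h)]["sol"].corner_N1)
            for b in sweep.b_grid
            if (a, b, sigma, h) in results
        ]
        for (b1, g1, c1), (b2, g2, c2) in zip(line, line[1:]):
            if c1 != c2:
                continue
            report.n_checks[3] += 1
            if g2 > g1 + floor:
                report.counterexamples[3].append(((a, sigma, h, b1, b2), (g1, g2)))

    # prediction 4: higher optimal education -> weaker gradient, across agents
    # whose education differs because their human capital h differs
    def _pairs_varying_h():
        for a, b, sigma in itertools.product(
            sweep.a_grid, sweep.b_grid, sweep.sigma_grid
        ):
            keys = [
                (a, b, sigma, h) for h in sweep.h_grid if (a, b, sigma, h) in results
            ]
            yield from itertools.combinations(keys, 2)

    for k1, k2 in _pairs_varying_h():
        s1, s2 = results[k1]["sol"].s, results[k2]["sol"].s
        if abs(s1 - s2) <= sweep.s_tol:
            continue
        if s1 < s2:
            k1, k2 = k2, k1  # k1 now has the higher education
        report.n_checks[4] += 1
        g_hi = abs(results[k1]["grad"])
        g_lo = abs(results[k2]["grad"])
        if g_hi > g_lo + floor:
            report.counterexamples[4].append(((k1, k2), (g_hi, g_lo)))

    # prediction 5: corner (N1*=0) agents have weaker gradients than interior
    # agents within the same (a, b, sigma) slice
    for a, b, sigma in itertools.product(sweep.a_grid, sweep.b_grid, sweep.sigma_grid):
        corner = [
            abs(results[(a, b, sigma, h)]["grad"])
            for h in sweep.h_grid
            if (a, b, sigma, h) in results and results[(a, b, sigma, h)]["sol"].corner_N1
        ]
        interior = [
            abs(results[(a, b, sigma, h)]["grad"])
            for h in sweep.h_grid
            if (a, b, sigma, h) in results
            and not results[(a, b, sigma, h)]["sol"].corner_N1
        ]
        if not corner or not interior:
            continue
        report.n_checks[5] += 1
        if float(np.mean(corner)) > float(np.mean(interior)) + floor:
            report.counterexamples[5].append(
                ((a, b, sigma), (float(np.mean(corner)), float(np.mean(interior))))
            )

    for k in _PREDICTIONS:
        report.passed[k] = len(report.counterexamples[k]) == 0
    return report
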