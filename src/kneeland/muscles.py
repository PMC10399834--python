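"""Static optimization of muscle forces.

Minimizes the sum of cubed muscle stresses sum_i (x_i / PCSA_i)^3 subject
to joint moment equilibrium [R]{x} = {M} and physiological bounds
x_p <= x <= x_max (passive force as lower bound, maximum active plus
passive as upper).  The primary solver is a smooth NLP (SLSQP) followed by
an exact KKT polish that solves the dual multipliers and recovers the
forces from the closed-form stationarity relation; a seeded real-coded
genetic algorithm with a local polish is provided as a cross-check.
An outer fixed-point loop couples the optimizer to a joint model that
returns passive reaction moments under the applied muscle forces,
iterating until the update to the required moments falls below a
tolerance (1 N*m by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize


@dataclass
class OptimizationProblem:
    lever_arms: np.ndarray     # (n_dof, n_muscles), m
    targets: np.ndarray        # (n_dof,), N*m
    pcsa: np.ndarray           # (n_muscles,), cm^2
    x_passive: np.ndarray      # (n_muscles,), N
    x_max: np.ndarray          # (n_muscles,), N

    def __post_init__(self) -> None:
        self.lever_arms = np.atleast_2d(np.asarray(self.lever_arms, float))
        self.targets = np.atleast_1d(np.asarray(self.targets, float))
        self.pcsa = np.atleast_1d(np.asarray(self.pcsa, float))
        self.x_passive = np.atleast_1d(np.asarray(self.x_passive, float))
        self.x_max = np.atleast_1d(np.asarray(self.x_max, float))
        nd, nm = self.lever_arms.shape
        if (len(self.targets) != nd or len(self.pcsa) != nm
                or len(self.x_passive) != nm or len(self.x_max) != nm):
            raise ValueError("inconsistent problem dimensions")
        if np.any(self.pcsa <= 0):
            raise ValueError("PCSA must be positive")
        if np.any(self.x_passive > self.x_max):
            raise ValueError("x_passive must not exceed x_max")

    @property
    def n_dof(self) -> int:
        return self.lever_arms.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.lever_arms.shape[1]


@dataclass
class MuscleSolution:
    forces: np.ndarray
    objective: float
    equality_residual: float      # max |Rx - M|, N*m
    iterations: int
    converged: bool
    method: str = "nlp"
    trace: list = field(default_factory=list)


class InfeasibleProblem(ValueError):
    pass


def _objective(x, pcsa):
    return float(np.sum((x / pcsa) ** 3))


def _grad(x, pcsa):
    return 3.0 * x ** 2 / pcsa ** 3


def check_feasible(prob: OptimizationProblem) -> np.ndarray:
    """LP feasibility pre-pass; returns a feasible point or raises
    :class:`InfeasibleProblem` with a certificate."""
    nm = prob.n_muscles
    res = linprog(c=np.zeros(nm), A_eq=prob.lever_arms, b_eq=prob.targets,
                  bounds=list(zip(prob.x_passive, prob.x_max)),
                  method="highs")
    if not res.success:
        reach_lo = prob.lever_arms @ np.where(prob.lever_arms.sum(0) > 0,
                                              prob.x_passive, prob.x_max)
        raise InfeasibleProblem(
            "no muscle forces within bounds satisfy the moment equality; "
            f"targets {prob.targets}, LP status: {res.message}; example "
            f"reachable moment {prob.lever_arms @ prob.x_passive} .. "
            f"{prob.lever_arms @ prob.x_max} (componentwise envelope "
            f"{reach_lo})")
    return res.x


def _kkt_polish(prob: OptimizationProblem, x: np.ndarray, tol: float):
    """Recover x from the dual: stationarity gives
    3 x_i^2 / A_i^3 = (R^T nu)_i on inactive bounds, i.e.
    x_i = clip(A_i^(3/2) sqrt(max((R^T nu)_i, 0) / 3), x_p, x_max).
    Solve R x(nu) = M for the n_dof multipliers."""
    from scipy.optimize import least_squares

    R, M, A = prob.lever_arms, prob.targets, prob.pcsa

    def x_of_nu(nu):
        s = R.T @ nu
        xi = A ** 1.5 * np.sqrt(np.maximum(s, 0.0) / 3.0)
        return np.clip(xi, prob.x_passive, prob.x_max)

    free = (x > prob.x_passive + 1e-9) & (x < prob.x_max - 1e-9)
    g = _grad(x, A)
    nu0 = (np.linalg.lstsq(R[:, free].T, g[free], rcond=None)[0]
           if free.sum() >= prob.n_dof else np.zeros(prob.n_dof))
    sol = least_squares(lambda nu: R @ x_of_nu(nu) - M, nu0,
                        xtol=3e-16, ftol=3e-16, gtol=3e-16)
    xn = x_of_nu(sol.x)
    scale = max(1.0, float(np.abs(M).max()))
    if np.abs(R @ xn - M).max() / scale < 1e-9:
        return xn
    return x


def solve(prob: OptimizationProblem, tol_moment: float = 1e-6,
          method: str = "nlp", seed: int = 0) -> MuscleSolution:
    """Minimize the cubed-stress objective under equilibrium and bounds.

    ``tol_moment`` is the accepted equality band (N*m).  ``method`` is
    'nlp' (primary) or 'genetic' (cross-check GA with local polish).
    """
    x_feas = check_feasible(prob)
    R, M, A = prob.lever_arms, prob.targets, prob.pcsa

    # square system: the equality determines the point
    if prob.n_dof == prob.n_muscles:
        x = np.linalg.solve(R, M)
        if np.any(x < prob.x_passive - 1e-9) or np.any(x > prob.x_max + 1e-9):
            raise InfeasibleProblem("unique equality solution violates bounds")
        return MuscleSolution(x, _objective(x, A), 0.0, 0, True, method)

    if method == "genetic":
        x0, nit = _genetic(prob, seed)
    elif method == "nlp":
        x0, nit = x_feas, 0
    else:
        raise ValueError("method must be 'nlp' or 'genetic'")

    res = minimize(
        lambda x: _objective(x, A), x0, jac=lambda x: _grad(x, A),
        method="SLSQP",
        bounds=list(zip(prob.x_passive, prob.x_max)),
        constraints=[{"type": "eq", "fun": lambda x: R @ x - M,
                      "jac": lambda x: R}],
        options={"maxiter": 500, "ftol": 1e-14})
    x = np.clip(res.x, prob.x_passive, prob.x_max)
    x = _kkt_polish(prob, x, tol_moment)
    resid = float(np.abs(R @ x - M).max())
    converged = resid <= tol_moment
    return MuscleSolution(x, _objective(x, A), resid,
                          nit + int(res.nit), converged, method)


def _genetic(prob: OptimizationProblem, seed: int, pop: int = 60,
             gens: int = 120):
    """Real-coded GA over the bound box with a quadratic equality penalty;
    returns the best individual (to be polished locally)."""
    rng = np.random.default_rng(seed)
    R, M, A = prob.lever_arms, prob.targets, prob.pcsa
    lo, hi = prob.x_passive, prob.x_max
    span = np.maximum(hi - lo, 1e-12)
    scale = max(float(np.abs(M).max()), 1.0)
    penalty = 1e4 / scale ** 2

    def fitness(P):
        obj = np.sum((P / A) ** 3, axis=1)
        viol = np.sum((P @ R.T - M) ** 2, axis=1)
        return obj + penalty * viol

    P = lo + rng.random((pop, len(lo))) * span
    for _ in range(gens):
        fit_ = fitness(P)
        order = np.argsort(fit_)
        P = P[order]
        elite = P[: pop // 5]
        # tournament parents + blend crossover + gaussian mutation
        i = rng.integers(0, pop // 2, size=(pop - len(elite), 2))
        w = rng.random((pop - len(elite), 1))
        children = w * P[i[:, 0]] + (1 - w) * P[i[:, 1]]
        mut = rng.standard_normal(children.shape) * 0.05 * span
        mask = rng.random(children.shape) < 0.2
        children = np.clip(children + mask * mut, lo, hi)
        P = np.vstack([elite, children])
    fit_ = fitness(P)
    return P[int(np.argmin(fit_))], gens


def kkt_residuals(prob: OptimizationProblem, sol: MuscleSolution,
                  atol: float = 1e-9):
    """(stationarity, complementarity) residuals, scaled by the objective
    gradient magnitude."""
    x, R, A = sol.forces, prob.lever_arms, prob.pcsa
    g = _grad(x, A)
    scale = max(float(np.abs(g).max()), 1e-12)
    lower = x <= prob.x_passive + 1e-7
    upper = x >= prob.x_max - 1e-7
    free = ~(lower | upper)
    nu = np.linalg.lstsq(R[:, free].T, g[free], rcond=None)[0] if \
        free.sum() >= prob.n_dof else np.linalg.lstsq(R.T, g, rcond=None)[0]
    lag = g - R.T @ nu
    stat = float(np.abs(lag[free]).max() / scale) if free.any() else 0.0
    # active lower bounds need lag >= 0 (multiplier), upper need lag <= 0
    comp = 0.0
    if lower.any():
        comp = max(comp, float(np.maximum(-lag[lower], 0.0).max()) / scale)
    if upper.any():
        comp = max(comp, float(np.maximum(lag[upper], 0.0).max()) / scale)
    return stat, comp


# ------------------------------------------------------------- coupling loop

def iterative_coupling(joint, profile_targets: np.ndarray,
                       prob: OptimizationProblem, tol: float = 1.0,
                       max_iter: int = 50, method: str = "nlp",
                       seed: int = 0):
    """Fixed-point muscle-force / joint-reaction loop.

    ``joint`` exposes ``reaction_moments(forces) -> (n_dof,)`` (passive
    moments generated under the applied muscle loads, added to the
    external targets) and optionally ``lever_arms(forces)`` returning an
    updated lever-arm matrix.  Iterates solve -> apply -> update targets
    until the required-moment update is below ``tol`` (N*m).  Returns
    (solution, residual trace).
    """
    from dataclasses import replace as _replace

    M_ext = np.asarray(profile_targets, dtype=float)
    M = M_ext.copy()
    trace = []
    sol = None
    for it in range(1, max_iter + 1):
        prob_it = _replace(prob, targets=M)
        if hasattr(joint, "lever_arms"):
            prob_it = _replace(prob_it, lever_arms=np.atleast_2d(
                joint.lever_arms(sol.forces if sol is not None
                                 else np.zeros(prob.n_muscles))))
        sol = solve(prob_it, method=method, seed=seed)
        M_new = M_ext + np.asarray(joint.reaction_moments(sol.forces), float)
        resid = float(np.abs(M_new - M).max())
        trace.append(resid)
        if not np.isinf(tol) and resid >= tol:
            M = M_new
            continue
        sol.converged = True
        return sol, trace
    sol.converged = False
    return sol, trace
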