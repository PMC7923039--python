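"""Uniform, deterministic contract over LP and QP back-ends.

Linear programs are solved by GLPK (via swiglpk), which retains the simplex
basis inside a :class:`GlpkProblem` instance so that a sequence of related
solves — flux variability analysis and metabolite flux minimization change
only the objective between solves — is warm-started.  Warm starts never
change the reported optimum, only the iteration count.  A scipy
``linprog``/HiGHS back-end is provided for independent cross-checking.

Quadratic programs (minimization of metabolic adjustment) are solved with
OSQP at tight tolerances with solution polishing.

No back-end used here is randomized, so results are reproducible without
seeds.  Infinite bounds are passed to the back-ends natively (GLPK bound
types, scipy/OSQP ``inf``); no finite capping is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

import swiglpk as glpk

glpk.glp_term_out(glpk.GLP_OFF)

__all__ = [
    "OPTIMAL",
    "INFEASIBLE",
    "UNBOUNDED",
    "SolverError",
    "SolverResult",
    "LinearProblem",
    "QuadraticProblem",
    "GlpkProblem",
    "solve_lp",
    "solve_qp",
]

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

#: absolute feasibility tolerance on constraint residuals
FEASIBILITY_TOL = 1e-9
#: relative agreement required between back-ends on optimal objectives
OBJECTIVE_RTOL = 1e-6


class SolverError(RuntimeError):
    """A back-end failed outright (distinct from infeasible/unbounded)."""


@dataclass
class SolverResult:
    status: str
    x: np.ndarray | None = None
    objective: float | None = None


@dataclass
class LinearProblem:
    """min/max  c @ x  s.t.  row_lb <= A x <= row_ub,  col_lb <= x <= col_ub.

    Equality constraints are ranged rows with ``row_lb == row_ub``.
    """

    objective: np.ndarray
    sense: str  # "max" | "min"
    A: sp.spmatrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    col_lb: np.ndarray
    col_ub: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.objective)
        m = self.A.shape[0]
        if self.A.shape[1] != n or len(self.col_lb) != n or len(self.col_ub) != n:
            raise ValueError("inconsistent column dimensions")
        if len(self.row_lb) != m or len(self.row_ub) != m:
            raise ValueError("inconsistent row dimensions")
        if self.sense not in ("max", "min"):
            raise ValueError(f"sense must be max or min: {self.sense!r}")


@dataclass
class QuadraticProblem:
    """min  0.5 x' P x + q @ x  s.t.  row_lb <= A x <= row_ub, bounds.

    ``P`` must be symmetric positive semidefinite.
    """

    P: sp.spmatrix
    q: np.ndarray
    A: sp.spmatrix
    row_lb: np.ndarray
    row_ub: np.ndarray
    col_lb: np.ndarray
    col_ub: np.ndarray


def _bound_type(lb: float, ub: float) -> tuple[int, float, float]:
    lo, up = not math.isinf(lb), not math.isinf(ub)
    if lo and up:
        return (glpk.GLP_FX if lb == ub else glpk.GLP_DB), lb, ub
    if lo:
        return glpk.GLP_LO, lb, 0.0
    if up:
        return glpk.GLP_UP, 0.0, ub
    return glpk.GLP_FR, 0.0, 0.0


class GlpkProblem:
    """A GLPK LP whose objective and bounds can be edited between solves.

    The simplex basis persists across solves, so editing only the objective
    (or a few bounds) and re-solving is warm-started.  ``solve(warm=False)``
    resets to a standard basis for a cold solve.
    """

    def __init__(
        self,
        A: sp.spmatrix,
        row_lb: np.ndarray,
        row_ub: np.ndarray,
        col_lb: np.ndarray,
        col_ub: np.ndarray,
    ) -> None:
        m, n = A.shape
        self.n = n
        self.lp = glpk.glp_create_prob()
        if m:
            glpk.glp_add_rows(self.lp, m)
        if n:
            glpk.glp_add_cols(self.lp, n)
        for i in range(m):
            t, lo, up = _bound_type(float(row_lb[i]), float(row_ub[i]))
            glpk.glp_set_row_bnds(self.lp, i + 1, t, lo, up)
        for j in range(n):
            t, lo, up = _bound_type(float(col_lb[j]), float(col_ub[j]))
            glpk.glp_set_col_bnds(self.lp, j + 1, t, lo, up)
        coo = sp.coo_matrix(A)
        ne = coo.nnz
        ia, ja = glpk.intArray(ne + 1), glpk.intArray(ne + 1)
        ar = glpk.doubleArray(ne + 1)
        for k in range(ne):
            ia[k + 1] = int(coo.row[k]) + 1
            ja[k + 1] = int(coo.col[k]) + 1
            ar[k + 1] = float(coo.data[k])
        glpk.glp_load_matrix(self.lp, ne, ia, ja, ar)
        self._parm = glpk.glp_smcp()
        glpk.glp_init_smcp(self._parm)
        self._parm.msg_lev = glpk.GLP_MSG_OFF
        self._parm.presolve = glpk.GLP_OFF
        self._obj_nonzero: set[int] = set()
        self._has_basis = False

    def __del__(self) -> None:  # pragma: no cover - interpreter teardown
        try:
            glpk.glp_delete_prob(self.lp)
        except Exception:
            pass

    def set_objective(self, coefficients: dict[int, float] | np.ndarray, sense: str) -> None:
        """Replace the objective.  ``coefficients`` maps 0-based column
        indices to values (or is a dense vector)."""
        glpk.glp_set_obj_dir(
            self.lp, glpk.GLP_MAX if sense == "max" else glpk.GLP_MIN
        )
        if isinstance(coefficients, np.ndarray):
            coefficients = {j: float(c) for j, c in enumerate(coefficients) if c != 0.0}
        for j in self._obj_nonzero - set(coefficients):
            glpk.glp_set_obj_coef(self.lp, j + 1, 0.0)
        for j, c in coefficients.items():
            glpk.glp_set_obj_coef(self.lp, j + 1, float(c))
        self._obj_nonzero = set(coefficients)

    def set_col_bounds(self, j: int, lb: float, ub: float) -> None:
        t, lo, up = _bound_type(float(lb), float(ub))
        glpk.glp_set_col_bnds(self.lp, j + 1, t, lo, up)

    def solve(self, warm: bool = True) -> SolverResult:
        if not warm or not self._has_basis:
            glpk.glp_std_basis(self.lp)
        ret = glpk.glp_simplex(self.lp, self._parm)
        if ret != 0 and warm and self._has_basis:
            # degenerate stale basis: retry cold before giving up
            glpk.glp_std_basis(self.lp)
            ret = glpk.glp_simplex(self.lp, self._parm)
        if ret != 0:
            raise SolverError(f"GLPK simplex failed with code {ret}")
        self._has_basis = True
        status = glpk.glp_get_status(self.lp)
        if status == glpk.GLP_OPT:
            x = np.array([glpk.glp_get_col_prim(self.lp, j + 1) for j in range(self.n)])
            return SolverResult(OPTIMAL, x, float(glpk.glp_get_obj_val(self.lp)))
        if status in (glpk.GLP_NOFEAS, glpk.GLP_INFEAS):
            return SolverResult(INFEASIBLE)
        if status == glpk.GLP_UNBND:
            return SolverResult(UNBOUNDED)
        raise SolverError(f"GLPK returned unexpected status {status}")


def _solve_lp_glpk(problem: LinearProblem) -> SolverResult:
    inst = GlpkProblem(problem.A, problem.row_lb, problem.row_ub, problem.col_lb, problem.col_ub)
    inst.set_objective(problem.objective, problem.sense)
    return inst.solve(warm=False)


def _solve_lp_scipy(problem: LinearProblem) -> SolverResult:
    from scipy.optimize import linprog

    sign = -1.0 if problem.sense == "max" else 1.0
    eq = problem.row_lb == problem.row_ub
    A = sp.csr_matrix(problem.A)
    A_eq = A[eq] if eq.any() else None
    b_eq = problem.row_lb[eq] if eq.any() else None
    A_ub_parts, b_ub_parts = [], []
    ineq = ~eq
    if ineq.any():
        Ai = A[ineq]
        lo, hi = problem.row_lb[ineq], problem.row_ub[ineq]
        fin_hi = np.isfinite(hi)
        if fin_hi.any():
            A_ub_parts.append(Ai[fin_hi])
            b_ub_parts.append(hi[fin_hi])
        fin_lo = np.isfinite(lo)
        if fin_lo.any():
            A_ub_parts.append(-Ai[fin_lo])
            b_ub_parts.append(-lo[fin_lo])
    A_ub = sp.vstack(A_ub_parts) if A_ub_parts else None
    b_ub = np.concatenate(b_ub_parts) if b_ub_parts else None
    bounds = [
        (None if math.isinf(l) else l, None if math.isinf(u) else u)
        for l, u in zip(problem.col_lb, problem.col_ub)
    ]
    res = linprog(
        sign * problem.objective,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return SolverResult(OPTIMAL, np.asarray(res.x), float(sign * res.fun))
    if res.status == 2:
        return SolverResult(INFEASIBLE)
    if res.status == 3:
        return SolverResult(UNBOUNDED)
    raise SolverError(f"scipy linprog failed: {res.message}")


_LP_BACKENDS = {"glpk": _solve_lp_glpk, "scipy": _solve_lp_scipy}


def solve_lp(problem: LinearProblem, backend: str = "glpk") -> SolverResult:
    """Solve a linear program (cold start) with the selected back-end."""
    try:
        fn = _LP_BACKENDS[backend]
    except KeyError:
        raise SolverError(f"unknown LP backend {backend!r}") from None
    return fn(problem)


def solve_qp(problem: QuadraticProblem) -> SolverResult:
    """Solve a convex QP with OSQP (polished, tight tolerances)."""
    import osqp

    n = len(problem.q)
    A_full = sp.vstack([sp.csc_matrix(problem.A), sp.eye(n, format="csc")], format="csc")
    l = np.concatenate([problem.row_lb, problem.col_lb])
    u = np.concatenate([problem.row_ub, problem.col_ub])
    prob = osqp.OSQP()
    prob.setup(
        sp.csc_matrix(problem.P),
        np.asarray(problem.q, dtype=float),
        A_full,
        l,
        u,
        eps_abs=1e-10,
        eps_rel=1e-10,
        eps_prim_inf=1e-9,
        eps_dual_inf=1e-9,
        max_iter=200000,
        polishing=True,
        verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if status.startswith("solved"):
        x = np.asarray(res.x)
        return SolverResult(OPTIMAL, x, float(res.info.obj_val))
    if "infeasible" in status and "dual" not in status:
        return SolverResult(INFEASIBLE)
    if "dual infeasible" in status:
        return SolverResult(UNBOUNDED)
    raise SolverError(f"OSQP failed: {status}")
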