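"""Reaction-centric flux optimizations.

* :func:`fba` — flux balance analysis: maximize or minimize one reaction
  flux subject to steady state ``S v = 0`` and the scenario bounds.
* :func:`fva` — flux variability analysis with the objective constrained to
  a fraction γ of its optimum; all per-reaction LPs re-use a single GLPK
  problem instance so the simplex basis is warm-started between solves
  (the fastFVA strategy).  Results are identical to cold-started solves.
* :func:`moma` — minimization of metabolic adjustment: the quadratic
  program ``min Σ_j (v_j - w_j)^2`` over the perturbed feasible set, i.e.
  the feasible flux vector closest (Euclidean, over all reactions) to a
  reference distribution w.
* :func:`knockout_scan`, :func:`batch_fba`, :func:`compare_fluxes` —
  screening and reporting utilities on top of the above.

All optimizations run iterative dead-end reduction first by default; this
never changes an optimum, only the problem size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import INF, MetabolicModel, ModelError, Scenario, build_stoich_matrix
from .reduction import find_dead_ends, reduce_scenario
from .solvers import (
    INFEASIBLE,
    OPTIMAL,
    UNBOUNDED,
    GlpkProblem,
    LinearProblem,
    QuadraticProblem,
    SolverError,
    solve_lp,
    solve_qp,
)

__all__ = [
    "FluxDistribution",
    "VariabilityResult",
    "FluxComparison",
    "fba",
    "fva",
    "moma",
    "knockout_scan",
    "batch_fba",
    "compare_fluxes",
]

STEADY_STATE_TOL = 1e-6


@dataclass
class FluxDistribution:
    """One steady-state flux vector (mmol gCDW^-1 h^-1 by convention).

    For FBA results ``objective_value`` is the optimized reaction flux; for
    MOMA results it is the squared Euclidean distance to the reference.
    """

    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    status: str = OPTIMAL

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def get(self, rxn_id: str, default: float = 0.0) -> float:
        return self.fluxes.get(rxn_id, default)

    def as_series(self) -> pd.Series:
        return pd.Series(self.fluxes, name="flux")


@dataclass
class VariabilityResult:
    """Per-reaction flux ranges at objective fraction γ (None = unconstrained)."""

    ranges: dict[str, tuple[float, float]]
    fraction: float | None

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.ranges.items()],
            columns=["reaction", "min_flux", "max_flux"],
        ).set_index("reaction")


def _apply_reduction(model: MetabolicModel, scenario: Scenario, reduce: bool) -> Scenario:
    if not reduce:
        return scenario
    report = find_dead_ends(model, scenario)
    return reduce_scenario(model, scenario, report) if report else scenario


def _lp_parts(model: MetabolicModel, scenario: Scenario):
    smat = build_stoich_matrix(model)
    lb, ub = scenario.bounds_arrays(model)
    m = smat.shape[0]
    return smat, np.zeros(m), np.zeros(m), lb, ub


def _relaxed_objective_row(direction: str, optimum: float, fraction: float):
    """Row bounds keeping the objective within fraction γ of its optimum.

    For maximization the flux must stay >= γ·z (z >= 0) or >= z/γ (z < 0);
    for minimization the mirror image.  γ = 1 pins the optimum exactly.
    """
    if direction == "max":
        lo = fraction * optimum if optimum >= 0 else optimum / fraction
        return lo, INF
    hi = optimum / fraction if optimum >= 0 else fraction * optimum
    return -INF, hi


def fba(
    model: MetabolicModel,
    scenario: Scenario,
    reduce: bool = True,
    backend: str = "glpk",
) -> FluxDistribution:
    """Flux balance analysis.

    Returns a :class:`FluxDistribution` with status ``optimal``,
    ``infeasible`` or ``unbounded``; fluxes are populated only when optimal
    (reactions blocked by dead-end reduction report zero flux).
    """
    obj_rxn, direction = scenario.validate_objective(model)
    scen = _apply_reduction(model, scenario, reduce)
    smat, row_lb, row_ub, lb, ub = _lp_parts(model, scen)
    c = np.zeros(len(model.reactions))
    c[smat.col_index[obj_rxn]] = 1.0
    problem = LinearProblem(c, direction, smat.S, row_lb, row_ub, lb, ub)
    res = solve_lp(problem, backend=backend)
    if res.status != OPTIMAL:
        return FluxDistribution(status=res.status)
    if smat.residual(res.x) > STEADY_STATE_TOL:
        raise SolverError("steady-state residual exceeds tolerance")
    fluxes = {rid: float(res.x[j]) for rid, j in smat.col_index.items()}
    return FluxDistribution(fluxes, float(res.objective), OPTIMAL)


def fva(
    model: MetabolicModel,
    scenario: Scenario,
    fraction: float | None = 0.95,
    reactions: Sequence[str] | None = None,
    reduce: bool = True,
) -> VariabilityResult:
    """Flux variability analysis (warm-started).

    With ``fraction`` γ the objective flux is constrained to stay within γ
    of its FBA optimum before each reaction is minimized and maximized.
    ``fraction=None`` drops the objective constraint entirely (used e.g.
    for MOMA solution-space reduction) and requires no objective.
    """
    if fraction is not None and not 0.0 < fraction <= 1.0:
        raise ModelError(f"fraction must be in (0, 1]: {fraction}")
    scen = _apply_reduction(model, scenario, reduce)
    smat, row_lb, row_ub, lb, ub = _lp_parts(model, scen)
    rows = [smat.S]
    row_lb, row_ub = list(row_lb), list(row_ub)
    if fraction is not None:
        obj_rxn, direction = scenario.validate_objective(model)
        base = fba(model, scen, reduce=False)
        if base.status != OPTIMAL:
            raise SolverError(f"FBA is {base.status}; cannot run FVA")
        lo, hi = _relaxed_objective_row(direction, base.objective_value, fraction)
        c_obj = np.zeros((1, len(model.reactions)))
        c_obj[0, smat.col_index[obj_rxn]] = 1.0
        rows.append(sp.csr_matrix(c_obj))
        row_lb.append(lo)
        row_ub.append(hi)
    A = sp.vstack(rows, format="csr")
    inst = GlpkProblem(A, np.array(row_lb), np.array(row_ub), lb, ub)
    targets = list(reactions) if reactions is not None else model.reaction_ids
    ranges: dict[str, tuple[float, float]] = {}
    for rid in targets:
        j = smat.col_index.get(rid)
        if j is None:
            raise ModelError(f"unknown reaction: {rid}")
        vals = []
        for sense in ("min", "max"):
            inst.set_objective({j: 1.0}, sense)
            res = inst.solve(warm=True)
            if res.status == OPTIMAL:
                vals.append(float(res.objective))
            elif res.status == UNBOUNDED:
                vals.append(-INF if sense == "min" else INF)
            else:
                raise SolverError(f"FVA subproblem for {rid} is {res.status}")
        ranges[rid] = (vals[0], vals[1])
    return VariabilityResult(ranges, fraction)


def moma(
    model: MetabolicModel,
    perturbed_scenario: Scenario,
    wildtype: FluxDistribution | Mapping[str, float],
    fva_reduce: bool = False,
    reduce: bool = True,
) -> FluxDistribution:
    """Minimization of metabolic adjustment.

    Finds the flux vector of the perturbed scenario closest (squared
    Euclidean distance over **all** reactions) to the wild-type
    distribution.  With ``fva_reduce`` the variable boxes are first
    tightened to the perturbed model's unconstrained FVA ranges, which
    shrinks the QP without changing its optimum.  The returned
    ``objective_value`` is the squared distance.
    """
    w_map = wildtype.fluxes if isinstance(wildtype, FluxDistribution) else dict(wildtype)
    missing = [r.id for r in model.reactions if r.id not in w_map]
    if missing:
        raise ModelError(f"wildtype distribution misses reactions: {missing[:5]}")
    scen = _apply_reduction(model, perturbed_scenario, reduce)
    smat, row_lb, row_ub, lb, ub = _lp_parts(model, scen)
    if fva_reduce:
        var = fva(model, scen, fraction=None, reduce=False)
        for rid, (lo, hi) in var.ranges.items():
            j = smat.col_index[rid]
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
    n = len(model.reactions)
    w = np.array([w_map[r.id] for r in model.reactions])
    P = sp.eye(n, format="csc") * 2.0
    q = -2.0 * w
    res = solve_qp(QuadraticProblem(P, q, smat.S, row_lb, row_ub, lb, ub))
    if res.status != OPTIMAL:
        return FluxDistribution(status=res.status)
    distance_sq = float(np.sum((res.x - w) ** 2))
    fluxes = {rid: float(res.x[j]) for rid, j in smat.col_index.items()}
    return FluxDistribution(fluxes, distance_sq, OPTIMAL)


def knockout_scan(
    model: MetabolicModel,
    scenario: Scenario,
    reactions: Iterable[str],
    method: str = "fba",
) -> pd.DataFrame:
    """Single-reaction knockout screen.

    Each reaction in turn is fixed to zero flux and the scenario objective
    re-evaluated with FBA, or with MOMA against the unperturbed FBA
    solution as wild type.  Returns a frame indexed by reaction with the
    re-evaluated objective flux and solver status.  The input scenario is
    not modified.
    """
    if method not in ("fba", "moma"):
        raise ModelError(f"unknown knockout method: {method}")
    obj_rxn, _ = scenario.validate_objective(model)
    wildtype = fba(model, scenario) if method == "moma" else None
    if wildtype is not None and wildtype.status != OPTIMAL:
        raise SolverError(f"wild-type FBA is {wildtype.status}")
    records = []
    for rid in reactions:
        if not model.has_reaction(rid):
            raise ModelError(f"unknown reaction: {rid}")
        ko = scenario.with_knockout(rid)
        if method == "fba":
            sol = fba(model, ko)
        else:
            sol = moma(model, ko, wildtype)
        value = sol.get(obj_rxn) if sol.status == OPTIMAL else np.nan
        records.append((rid, value, sol.status))
    return pd.DataFrame(records, columns=["reaction", "objective_value", "status"]).set_index(
        "reaction"
    )


def batch_fba(
    model: MetabolicModel, scenarios: Sequence[Scenario]
) -> pd.DataFrame:
    """Independent FBA per scenario, aggregated into one table.

    A failing scenario (infeasible, unbounded, or structurally invalid)
    is recorded in its row and never aborts the batch.
    """
    records = []
    for i, scen in enumerate(scenarios):
        label = scen.name or f"scenario_{i}"
        try:
            sol = fba(model, scen)
            row = {"scenario": label, "status": sol.status, "objective": sol.objective_value}
            row.update(sol.fluxes)
        except (ModelError, SolverError) as exc:
            row = {"scenario": label, "status": f"error: {exc}", "objective": None}
        records.append(row)
    columns = ["scenario", "status", "objective"] + model.reaction_ids
    return pd.DataFrame(records, columns=columns if records else ["scenario", "status", "objective"])


@dataclass
class FluxComparison:
    """Per-reaction comparison of two flux distributions (scatter data)."""

    table: pd.DataFrame  # columns: flux_a, flux_b, difference; index: reaction
    tolerance: float

    @property
    def differing(self) -> list[str]:
        return list(self.table.index[self.table["difference"].abs() > self.tolerance])

    @property
    def n_differing(self) -> int:
        return len(self.differing)

    def scatter_points(self) -> np.ndarray:
        return self.table[["flux_a", "flux_b"]].to_numpy()

    def plot(self, ax=None):
        """Comparative scatter plot of the two distributions."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pts = self.scatter_points()
        ax.scatter(pts[:, 0], pts[:, 1], s=12)
        lims = [pts.min() - 0.5, pts.max() + 0.5] if len(pts) else [0, 1]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("flux a")
        ax.set_ylabel("flux b")
        return ax


def compare_fluxes(
    a: FluxDistribution | Mapping[str, float],
    b: FluxDistribution | Mapping[str, float],
    tolerance: float = 1e-6,
) -> FluxComparison:
    """Pair two flux distributions reaction by reaction.

    Raises if the reaction sets differ (the distributions must come from
    the same model).
    """
    fa = a.fluxes if isinstance(a, FluxDistribution) else dict(a)
    fb = b.fluxes if isinstance(b, FluxDistribution) else dict(b)
    if set(fa) != set(fb):
        raise ModelError("flux distributions cover different reaction sets")
    rows = {rid: (fa[rid], fb[rid], fb[rid] - fa[rid]) for rid in fa}
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["flux_a", "flux_b", "difference"]
    )
    table.index.name = "reaction"
    return FluxComparison(table, tolerance)
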