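"""Independent brute-force oracles used to validate the optimizers.

Every function here formulates the optimization from scratch and solves it
cold with scipy (linprog/HiGHS for LPs, SLSQP for the MOMA QP), bypassing
the package's solver layer, warm starts and dead-end preprocessing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import linprog, minimize

from fluxnode import Scenario, build_stoich_matrix, to_irreversible


def _linprog_parts(model, scenario):
    smat = build_stoich_matrix(model)
    lb, ub = scenario.bounds_arrays(model)
    bounds = [
        (None if math.isinf(l) else l, None if math.isinf(u) else u)
        for l, u in zip(lb, ub)
    ]
    return smat, bounds


def _solve(c, sense, smat, bounds, extra_ub=None):
    sign = -1.0 if sense == "max" else 1.0
    A_ub, b_ub = (None, None)
    if extra_ub is not None:
        A_ub, b_ub = extra_ub
    res = linprog(
        sign * np.asarray(c),
        A_eq=smat.S if smat.shape[0] else None,
        b_eq=np.zeros(smat.shape[0]) if smat.shape[0] else None,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
    )
    if res.status == 0:
        return sign * res.fun, res.x
    if res.status == 3:
        return (-math.inf if sense == "min" else math.inf), None
    if res.status == 2:
        return None, None
    raise RuntimeError(f"oracle linprog failed: {res.message}")


def oracle_fba(model, scenario):
    """Cold scipy FBA optimum (None if infeasible, ±inf if unbounded)."""
    obj_rxn, direction = scenario.validate_objective(model)
    smat, bounds = _linprog_parts(model, scenario)
    c = np.zeros(len(model.reactions))
    c[smat.col_index[obj_rxn]] = 1.0
    value, _ = _solve(c, direction, smat, bounds)
    return value


def _objective_cut(model, scenario, fraction, smat):
    """A_ub/b_ub rows keeping the objective within fraction of its optimum."""
    if fraction is None:
        return None, None
    obj_rxn, direction = scenario.validate_objective(model)
    z = oracle_fba(model, scenario)
    row = np.zeros((1, smat.shape[1]))
    row[0, smat.col_index[obj_rxn]] = 1.0
    if direction == "max":
        target = fraction * z if z >= 0 else z / fraction
        return -row, np.array([-target])  # v_obj >= target
    target = z / fraction if z >= 0 else fraction * z
    return row, np.array([target])  # v_obj <= target


def oracle_fva(model, scenario, fraction=0.95, reactions=None):
    """Per-reaction cold min/max LPs."""
    smat, bounds = _linprog_parts(model, scenario)
    A_ub, b_ub = _objective_cut(model, scenario, fraction, smat)
    extra = (A_ub, b_ub) if A_ub is not None else None
    out = {}
    for rid in reactions if reactions is not None else model.reaction_ids:
        c = np.zeros(len(model.reactions))
        c[smat.col_index[rid]] = 1.0
        lo, _ = _solve(c, "min", smat, bounds, extra)
        hi, _ = _solve(c, "max", smat, bounds, extra)
        out[rid] = (lo, hi)
    return out


def oracle_mfm(model, scenario, fraction=0.95, metabolites=None):
    """Per-metabolite cold LPs on a freshly split model."""
    split_model, mapping, split_scen = to_irreversible(model, scenario)
    smat, bounds = _linprog_parts(split_model, split_scen)
    obj_rxn, direction = scenario.validate_objective(model)
    z = oracle_fba(model, scenario)
    row = np.zeros((1, smat.shape[1]))
    if obj_rxn in mapping:
        fwd, bwd = mapping[obj_rxn]
        row[0, smat.col_index[fwd]] = 1.0
        row[0, smat.col_index[bwd]] = -1.0
    else:
        row[0, smat.col_index[obj_rxn]] = 1.0
    if direction == "max":
        target = fraction * z if z >= 0 else z / fraction
        extra = (-row, np.array([-target]))
    else:
        target = z / fraction if z >= 0 else fraction * z
        extra = (row, np.array([target]))
    targets = metabolites or [m.id for m in model.metabolites if not m.boundary]
    out = {}
    for mid in targets:
        c = np.zeros(len(split_model.reactions))
        for j, rxn in enumerate(split_model.reactions):
            coef = rxn.stoichiometry.get(mid, 0.0)
            if coef > 0:
                c[j] = coef
        value, _ = _solve(c, "min", smat, bounds, extra)
        out[mid] = max(value, 0.0)
    return out


def oracle_moma(model, scenario, wildtype):
    """Cold SLSQP solution of min ||v - w||^2 over the scenario's feasible set."""
    smat, _ = _linprog_parts(model, scenario)
    lb, ub = scenario.bounds_arrays(model)
    w = np.array([wildtype[r.id] for r in model.reactions])
    S = smat.S.toarray()
    x0 = np.clip(w, np.where(np.isinf(lb), -1e3, lb), np.where(np.isinf(ub), 1e3, ub))
    cons = [{"type": "eq", "fun": lambda v: S @ v}] if S.shape[0] else []
    res = minimize(
        lambda v: np.sum((v - w) ** 2),
        x0,
        jac=lambda v: 2 * (v - w),
        bounds=list(zip(lb, ub)),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        raise RuntimeError(f"oracle SLSQP failed: {res.message}")
    return res.x, float(np.sum((res.x - w) ** 2))


def compare_ranges(a: dict, b: dict, tol: float = 1e-6) -> float:
    """Max abs deviation between two FVA-style range dicts; infinities must
    match exactly."""
    worst = 0.0
    assert set(a) == set(b)
    for rid in a:
        for x, y in zip(a[rid], b[rid]):
            if math.isinf(x) or math.isinf(y):
                assert x == y, f"{rid}: {x} vs {y}"
            else:
                worst = max(worst, abs(x - y))
    return worst
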