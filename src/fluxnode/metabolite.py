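"""Metabolite-centric analyses: metabolite flux minimization (MFM),
essentiality ranking, and split-ratio analysis.

MFM answers, per metabolite m: how much flux *must* flow through the node m
when the network is required to keep its objective within a fraction γ of
the FBA optimum?  The producing flux of m is a linear function of the
reaction fluxes only after all reversible reactions are split into
irreversible pairs (all fluxes nonnegative):

    p_m(v) = Σ_j max(S[m, j], 0) · v_j .

MFM minimizes p_m for every metabolite over the γ-constrained feasible set;
a minimum of (numerically) zero means the metabolite is non-essential for
near-optimal operation of the objective.  Like flux variability analysis,
the scan re-uses one LP instance with warm-started simplex solves.

Split-ratio analysis describes one *realized* flux state: for a metabolite
m, each reaction's contribution to the production (or consumption) of m,
as absolute flux and as a percentage of the node's turnover.  Reversible
reactions contribute according to their net flux sign.  Because FBA optima
need not be unique, split ratios describe the particular solution supplied,
not the model per se.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .analysis import FluxDistribution, STEADY_STATE_TOL, _apply_reduction, _relaxed_objective_row, fba
from .model import (
    INF,
    MetabolicModel,
    ModelError,
    Scenario,
    build_stoich_matrix,
    to_irreversible,
)
from .solvers import OPTIMAL, GlpkProblem, SolverError

__all__ = [
    "MetaboliteFluxReport",
    "SplitRatioTable",
    "MetaboliteSplit",
    "producing_flux_coefficients",
    "mfm",
    "essential_partition",
    "rank_metabolites",
    "split_ratios",
]

#: minimal producing flux above which a metabolite counts as essential
ESSENTIALITY_TOL = 1e-9
#: contributions below this are omitted from split-ratio listings
CONTRIBUTION_TOL = 1e-9


@dataclass
class MetaboliteFluxReport:
    """Minimal producing flux per metabolite at objective fraction γ."""

    minimal_flux: dict[str, float]
    fraction: float
    tolerance: float = ESSENTIALITY_TOL

    def __getitem__(self, met_id: str) -> float:
        return self.minimal_flux[met_id]

    def is_essential(self, met_id: str) -> bool:
        return self.minimal_flux[met_id] > self.tolerance

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, v, v > self.tolerance) for m, v in self.minimal_flux.items()],
            columns=["metabolite", "minimal_producing_flux", "essential"],
        ).set_index("metabolite")


def producing_flux_coefficients(
    model_irrev: MetabolicModel, metabolite: str
) -> np.ndarray:
    """Coefficient vector c with p_m(v) = c @ v on an irreversible model.

    Entry j is ``S[m, j]`` where positive, else 0.  The metabolite must be a
    non-boundary member of the model.
    """
    met = model_irrev.metabolite(metabolite)
    if met.boundary:
        raise ModelError(f"{metabolite} is a boundary metabolite")
    coefs = np.zeros(len(model_irrev.reactions))
    for j, rxn in enumerate(model_irrev.reactions):
        c = rxn.stoichiometry.get(metabolite, 0.0)
        if c > 0:
            coefs[j] = c
    return coefs


def mfm(
    model: MetabolicModel,
    scenario: Scenario,
    fraction: float = 0.95,
    metabolites: Sequence[str] | None = None,
    reduce: bool = True,
) -> MetaboliteFluxReport:
    """Metabolite flux minimization.

    Procedure: (1) FBA, then constrain the objective flux to stay within
    fraction γ of the optimum; (2) split reversible reactions so producing
    fluxes are linear; (3) minimize each metabolite's producing flux in
    turn, warm-starting from the previous basis.
    """
    if not 0.0 < fraction <= 1.0:
        raise ModelError(f"fraction must be in (0, 1]: {fraction}")
    obj_rxn, direction = scenario.validate_objective(model)
    scen = _apply_reduction(model, scenario, reduce)
    base = fba(model, scen, reduce=False)
    if base.status != OPTIMAL:
        raise SolverError(f"FBA is {base.status}; cannot run MFM")
    split_model, mapping, split_scen = to_irreversible(model, scen)
    smat = build_stoich_matrix(split_model)
    lb, ub = split_scen.bounds_arrays(split_model)
    # objective-fraction row in terms of split fluxes (net flux if split)
    obj_coefs: dict[int, float] = {}
    if obj_rxn in mapping:
        fwd, bwd = mapping[obj_rxn]
        obj_coefs[smat.col_index[fwd]] = 1.0
        obj_coefs[smat.col_index[bwd]] = -1.0
    else:
        obj_coefs[smat.col_index[obj_rxn]] = 1.0
    lo, hi = _relaxed_objective_row(direction, base.objective_value, fraction)
    n = len(split_model.reactions)
    row = sp.csr_matrix(
        ([c for c in obj_coefs.values()], ([0] * len(obj_coefs), list(obj_coefs))),
        shape=(1, n),
    )
    A = sp.vstack([smat.S, row], format="csr")
    row_lb = np.concatenate([np.zeros(smat.shape[0]), [lo]])
    row_ub = np.concatenate([np.zeros(smat.shape[0]), [hi]])
    inst = GlpkProblem(A, row_lb, row_ub, lb, ub)

    if metabolites is None:
        targets = [m.id for m in model.metabolites if not m.boundary]
    else:
        targets = []
        for mid in metabolites:
            if model.metabolite(mid).boundary:
                raise ModelError(f"{mid} is a boundary metabolite")
            targets.append(mid)

    minimal: dict[str, float] = {}
    for mid in targets:
        coefs = producing_flux_coefficients(split_model, mid)
        inst.set_objective(coefs, "min")
        res = inst.solve(warm=True)
        if res.status != OPTIMAL:
            raise SolverError(f"MFM subproblem for {mid} is {res.status}")
        minimal[mid] = max(float(res.objective), 0.0)
    return MetaboliteFluxReport(minimal, fraction)


def essential_partition(
    report: MetaboliteFluxReport, tolerance: float = ESSENTIALITY_TOL
) -> tuple[list[str], list[str]]:
    """Split a report into (essential, non-essential) metabolite ids.

    Non-essential iff the minimal producing flux is ≤ tolerance; the two
    lists are disjoint, exhaustive, and sorted.
    """
    essential = sorted(m for m, v in report.minimal_flux.items() if v > tolerance)
    non_essential = sorted(m for m, v in report.minimal_flux.items() if v <= tolerance)
    return essential, non_essential


def rank_metabolites(report: MetaboliteFluxReport) -> list[tuple[str, float]]:
    """Metabolites ordered by minimal producing flux, descending; ties are
    broken lexicographically by id for determinism."""
    return sorted(report.minimal_flux.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class MetaboliteSplit:
    """Producer/consumer breakdown for one metabolite node."""

    turnover: float
    producers: list[tuple[str, float, float]] = field(default_factory=list)  # (rxn, flux, %)
    consumers: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class SplitRatioTable:
    entries: dict[str, MetaboliteSplit]

    def __getitem__(self, met_id: str) -> MetaboliteSplit:
        return self.entries[met_id]

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for mid, split in self.entries.items():
            for rxn, flux, pct in split.producers:
                rows.append((mid, split.turnover, rxn, "producer", flux, pct))
            for rxn, flux, pct in split.consumers:
                rows.append((mid, split.turnover, rxn, "consumer", flux, pct))
        return pd.DataFrame(
            rows,
            columns=["metabolite", "turnover", "reaction", "direction", "flux", "percent"],
        )


def split_ratios(
    model: MetabolicModel,
    fluxes: FluxDistribution | Mapping[str, float],
    metabolites: Sequence[str] | None = None,
) -> SplitRatioTable:
    """Split-ratio analysis of one flux state.

    For each metabolite, reaction j produces ``S[m, j] * v_j`` of m when
    that product is positive and consumes ``|S[m, j] * v_j|`` when
    negative; percentages are relative to the producing (resp. consuming)
    total.  The supplied fluxes must satisfy steady state; metabolites with
    zero turnover get empty producer/consumer lists.
    """
    fmap = fluxes.fluxes if isinstance(fluxes, FluxDistribution) else dict(fluxes)
    smat = build_stoich_matrix(model)
    v = np.array([fmap.get(r.id, 0.0) for r in model.reactions])
    if smat.residual(v) > 10 * STEADY_STATE_TOL:
        raise ModelError("flux distribution violates steady state")
    targets = (
        [model.metabolite(m).id for m in metabolites]
        if metabolites is not None
        else model.metabolite_ids
    )
    entries: dict[str, MetaboliteSplit] = {}
    for mid in targets:
        producers: list[tuple[str, float]] = []
        consumers: list[tuple[str, float]] = []
        for rxn in model.reactions:
            coef = rxn.stoichiometry.get(mid)
            if coef is None:
                continue
            contrib = coef * fmap.get(rxn.id, 0.0)
            if contrib > CONTRIBUTION_TOL:
                producers.append((rxn.id, contrib))
            elif contrib < -CONTRIBUTION_TOL:
                consumers.append((rxn.id, -contrib))
        turnover = sum(f for _, f in producers)
        consumed = sum(f for _, f in consumers)
        split = MetaboliteSplit(turnover=turnover)
        if turnover > CONTRIBUTION_TOL:
            split.producers = [(r, f, 100.0 * f / turnover) for r, f in producers]
        if consumed > CONTRIBUTION_TOL:
            split.consumers = [(r, f, 100.0 * f / consumed) for r, f in consumers]
        entries[mid] = split
    return SplitRatioTable(entries)
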