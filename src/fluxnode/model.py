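"""Core domain types for constraint-based metabolic models.

A :class:`MetabolicModel` is a bipartite structure of metabolites and
stoichiometric reactions.  Simulation constraints (flux bounds and the
objective) live in a separate :class:`Scenario`, so that the same network can
be run under many environmental conditions without touching the model file.

The steady-state assumption underlying all analyses in this package is
``S @ v = 0`` for every non-boundary metabolite, where ``S`` is the
stoichiometric matrix (rows = metabolites, columns = reactions) and ``v`` is
the flux vector in mmol gCDW^-1 h^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "Scenario",
    "StoichiometricMatrix",
    "ModelError",
    "build_stoich_matrix",
    "to_irreversible",
    "merge_split_fluxes",
]

INF = math.inf


class ModelError(ValueError):
    """Raised for structurally invalid models or scenarios."""


@dataclass
class Metabolite:
    """A chemical species node.

    ``boundary`` metabolites sit outside the system boundary: they carry no
    steady-state balance row and may accumulate or deplete freely.
    """

    id: str
    name: str = ""
    boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ModelError(f"metabolite id must be a non-empty token: {self.id!r}")
        if not self.name:
            self.name = self.id


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite ids to signed coefficients: negative
    for substrates, positive for products.  An exchange reaction has one
    empty side (e.g. pure uptake ``-> A`` with stoichiometry ``{A: +1}``).
    ``delta_g`` is an optional reaction Gibbs free energy in kJ/mol used by
    the directionality-assignment tool.
    """

    id: str
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    delta_g: float | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ModelError(f"reaction id must be a non-empty token: {self.id!r}")
        for met, coef in self.stoichiometry.items():
            if coef == 0:
                raise ModelError(f"reaction {self.id}: zero coefficient for {met}")

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def is_exchange(self) -> bool:
        """True if one side of the reaction is empty."""
        return not self.substrates or not self.products


class MetabolicModel:
    """Ordered collections of metabolites and reactions with id lookup."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        name: str = "",
    ) -> None:
        self.name = name
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self._met_index:
            raise ModelError(f"duplicate metabolite id: {met.id}")
        self._met_index[met.id] = len(self.metabolites)
        self.metabolites.append(met)
        return met

    def add_reaction(self, rxn: Reaction, register_metabolites: bool = True) -> Reaction:
        if rxn.id in self._rxn_index:
            raise ModelError(f"duplicate reaction id: {rxn.id}")
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                if not register_metabolites:
                    raise ModelError(
                        f"reaction {rxn.id} references unknown metabolite {met_id}"
                    )
                self.add_metabolite(Metabolite(met_id))
        self._rxn_index[rxn.id] = len(self.reactions)
        self.reactions.append(rxn)
        return rxn

    # -- lookup -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise ModelError(f"unknown metabolite: {met_id}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise ModelError(f"unknown reaction: {rxn_id}") from None

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self.reactions)

    def __len__(self) -> int:
        return len(self.reactions)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            (replace(m) for m in self.metabolites),
            (
                Reaction(r.id, dict(r.stoichiometry), r.reversible, r.delta_g, r.annotation)
                for r in self.reactions
            ),
            name=self.name,
        )

    def summary(self) -> str:
        n_rev = sum(r.reversible for r in self.reactions)
        n_ex = sum(r.is_exchange for r in self.reactions)
        return (
            f"{self.name or 'model'}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions ({n_rev} reversible, {n_ex} exchange)"
        )

    def __repr__(self) -> str:
        return f"<MetabolicModel {self.summary()}>"


@dataclass
class Scenario:
    """Flux bounds and objective for one simulation condition.

    Bounds are sparse: a reaction absent from both maps gets the
    reversibility-derived default at application time — ``[0, +inf)`` for
    irreversible reactions, ``(-inf, +inf)`` for reversible ones.
    """

    lower_bound: dict[str, float] = field(default_factory=dict)
    upper_bound: dict[str, float] = field(default_factory=dict)
    objective: tuple[str, str] | None = None  # (reaction id, "max" | "min")
    name: str = ""

    def copy(self) -> "Scenario":
        return Scenario(dict(self.lower_bound), dict(self.upper_bound), self.objective, self.name)

    def set_objective(self, rxn_id: str, direction: str = "max") -> None:
        if direction not in ("max", "min"):
            raise ModelError(f"objective direction must be max or min: {direction!r}")
        self.objective = (rxn_id, direction)

    def bounds_for(self, rxn: Reaction) -> tuple[float, float]:
        lb = self.lower_bound.get(rxn.id, -INF if rxn.reversible else 0.0)
        ub = self.upper_bound.get(rxn.id, INF)
        if lb > ub:
            raise ModelError(f"reaction {rxn.id}: lower bound {lb} exceeds upper bound {ub}")
        return lb, ub

    def bounds_arrays(self, model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
        """Dense (lb, ub) vectors in the model's reaction order; validates."""
        for rxn_id in set(self.lower_bound) | set(self.upper_bound):
            if not model.has_reaction(rxn_id):
                raise ModelError(f"scenario bounds unknown reaction: {rxn_id}")
        pairs = [self.bounds_for(r) for r in model.reactions]
        lb = np.array([p[0] for p in pairs])
        ub = np.array([p[1] for p in pairs])
        return lb, ub

    def validate_objective(self, model: MetabolicModel) -> tuple[str, str]:
        if self.objective is None:
            raise ModelError("scenario has no objective")
        rxn_id, direction = self.objective
        if not model.has_reaction(rxn_id):
            raise ModelError(f"objective reaction not in model: {rxn_id}")
        return rxn_id, direction

    def with_knockout(self, rxn_ids: str | Iterable[str]) -> "Scenario":
        """Return a copy with the given reactions fixed to zero flux."""
        if isinstance(rxn_ids, str):
            rxn_ids = [rxn_ids]
        out = self.copy()
        for rid in rxn_ids:
            out.lower_bound[rid] = 0.0
            out.upper_bound[rid] = 0.0
        return out


@dataclass
class StoichiometricMatrix:
    """Sparse stoichiometric matrix over non-boundary metabolites."""

    S: sp.csr_matrix
    row_index: dict[str, int]  # metabolite id -> row
    col_index: dict[str, int]  # reaction id -> column

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape

    def residual(self, v: np.ndarray) -> float:
        """Max-norm of S @ v (steady-state violation)."""
        if self.S.shape[0] == 0:
            return 0.0
        return float(np.abs(self.S @ v).max())


def build_stoich_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S with one row per non-boundary metabolite, one column per
    reaction; ``S[m, j]`` is the signed coefficient of metabolite m in
    reaction j."""
    rows = [m.id for m in model.metabolites if not m.boundary]
    row_index = {mid: i for i, mid in enumerate(rows)}
    col_index = {r.id: j for j, r in enumerate(model.reactions)}
    data, ri, ci = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            i = row_index.get(met_id)
            if i is not None:
                ri.append(i)
                ci.append(j)
                data.append(coef)
    S = sp.csr_matrix(
        (data, (ri, ci)), shape=(len(rows), len(model.reactions)), dtype=float
    )
    return StoichiometricMatrix(S, row_index, col_index)


def to_irreversible(
    model: MetabolicModel, scenario: Scenario | None = None
) -> tuple[MetabolicModel, dict[str, tuple[str, str]], Scenario | None]:
    """Split every reversible reaction r into an irreversible pair.

    ``r_fwd`` keeps the stoichiometry, ``r_bwd`` negates it; the net flux of
    the original reaction is ``v_fwd - v_bwd``.  Irreversible reactions are
    kept as-is.  Returns ``(split_model, mapping, split_scenario)`` where
    ``mapping`` is ``{original id: (fwd id, bwd id)}``.  If a scenario is
    given its bounds are split accordingly: ``v in [lb, ub]`` becomes
    ``v_fwd in [max(lb,0), max(ub,0)]`` and ``v_bwd in [max(-ub,0), max(-lb,0)]``.
    """
    split = MetabolicModel(name=model.name)
    for m in model.metabolites:
        split.add_metabolite(replace(m))
    mapping: dict[str, tuple[str, str]] = {}
    for r in model.reactions:
        if not r.reversible:
            split.add_reaction(
                Reaction(r.id, dict(r.stoichiometry), False, r.delta_g, r.annotation)
            )
            continue
        fwd, bwd = f"{r.id}_fwd", f"{r.id}_bwd"
        if model.has_reaction(fwd) or model.has_reaction(bwd):
            raise ModelError(f"split-id collision for reversible reaction {r.id}")
        mapping[r.id] = (fwd, bwd)
        split.add_reaction(Reaction(fwd, dict(r.stoichiometry), False, r.delta_g, r.annotation))
        split.add_reaction(
            Reaction(bwd, {m: -c for m, c in r.stoichiometry.items()}, False, r.delta_g, r.annotation)
        )

    split_scen: Scenario | None = None
    if scenario is not None:
        split_scen = Scenario(name=scenario.name)
        for r in model.reactions:
            lb, ub = scenario.bounds_for(r)
            if r.id in mapping:
                fwd, bwd = mapping[r.id]
                split_scen.lower_bound[fwd] = max(lb, 0.0)
                split_scen.upper_bound[fwd] = max(ub, 0.0)
                split_scen.lower_bound[bwd] = max(-ub, 0.0)
                split_scen.upper_bound[bwd] = max(-lb, 0.0)
            else:
                if r.id in scenario.lower_bound:
                    split_scen.lower_bound[r.id] = lb
                if r.id in scenario.upper_bound:
                    split_scen.upper_bound[r.id] = ub
        if scenario.objective is not None:
            obj_rxn, direction = scenario.objective
            if obj_rxn in mapping:
                # net objective handled by callers that build the LP directly
                split_scen.objective = (mapping[obj_rxn][0], direction)
            else:
                split_scen.objective = scenario.objective
    return split, mapping, split_scen


def merge_split_fluxes(
    fluxes: Mapping[str, float], mapping: Mapping[str, tuple[str, str]]
) -> dict[str, float]:
    """Map a flux vector of the split model back to net fluxes (v_fwd - v_bwd)."""
    out: dict[str, float] = {}
    split_ids = {sid for pair in mapping.values() for sid in pair}
    for rid, val in fluxes.items():
        if rid not in split_ids:
            out[rid] = val
    for rid, (fwd, bwd) in mapping.items():
        out[rid] = fluxes.get(fwd, 0.0) - fluxes.get(bwd, 0.0)
    return out
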