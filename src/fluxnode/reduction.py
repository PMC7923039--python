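"""Iterative dead-end analysis.

A non-boundary metabolite is a dead end if, considering only the reaction
directions admissible under the current bounds, it cannot be both produced
and consumed — or if it is touched by at most one reaction (a single
reaction, reversible or not, can never balance a metabolite on its own at
steady state).  Every reaction touching a dead-end metabolite provably
carries zero flux in every steady-state solution, so its bounds can be
fixed to zero.  Blocking reactions can create new dead ends, hence the
analysis iterates to a fixpoint; this shrinks the solution space of every
downstream optimization without changing any optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import MetabolicModel, ModelError, Scenario

__all__ = ["DeadEndIteration", "DeadEndReport", "find_dead_ends", "reduce_scenario"]


@dataclass
class DeadEndIteration:
    dead_metabolites: set[str]
    blocked_reactions: set[str]


@dataclass
class DeadEndReport:
    iterations: list[DeadEndIteration] = field(default_factory=list)

    @property
    def total_blocked(self) -> set[str]:
        out: set[str] = set()
        for it in self.iterations:
            out |= it.blocked_reactions
        return out

    @property
    def total_dead(self) -> set[str]:
        out: set[str] = set()
        for it in self.iterations:
            out |= it.dead_metabolites
        return out

    def __bool__(self) -> bool:
        return bool(self.iterations)


def _admissible(lb: float, ub: float) -> tuple[bool, bool]:
    """(forward admissible, backward admissible) under bounds [lb, ub]."""
    return ub > 0.0, lb < 0.0


def find_dead_ends(model: MetabolicModel, scenario: Scenario) -> DeadEndReport:
    """Iterate dead-end detection to a fixpoint.

    Directionality is bounds-aware: a reversible reaction constrained to
    ``[0, ub]`` by the scenario counts as forward-only.  Metabolites with no
    reactions at all are reported as dead ends in iteration 1.  Terminates
    after at most ``#metabolites`` iterations.
    """
    bounds = {r.id: scenario.bounds_for(r) for r in model.reactions}
    dead: set[str] = set()
    blocked: set[str] = set()
    report = DeadEndReport()
    while True:
        new_dead: set[str] = set()
        new_blocked: set[str] = set()
        touching: dict[str, set[str]] = {}
        producible: set[str] = set()
        consumable: set[str] = set()
        for rxn in model.reactions:
            if rxn.id in blocked:
                continue
            fwd, bwd = _admissible(*bounds[rxn.id])
            if not fwd and not bwd:
                continue
            for met, coef in rxn.stoichiometry.items():
                touching.setdefault(met, set()).add(rxn.id)
                if (coef > 0 and fwd) or (coef < 0 and bwd):
                    producible.add(met)
                if (coef < 0 and fwd) or (coef > 0 and bwd):
                    consumable.add(met)
        for met in model.metabolites:
            if met.boundary or met.id in dead:
                continue
            rxns = touching.get(met.id, set())
            if len(rxns) <= 1 or met.id not in producible or met.id not in consumable:
                new_dead.add(met.id)
                new_blocked |= rxns - blocked
        if not new_dead:
            break
        dead |= new_dead
        blocked |= new_blocked
        for rid in new_blocked:
            bounds[rid] = (0.0, 0.0)
        report.iterations.append(DeadEndIteration(new_dead, new_blocked))
    return report


def reduce_scenario(
    model: MetabolicModel, scenario: Scenario, report: DeadEndReport
) -> Scenario:
    """Return a copy of ``scenario`` with all blocked reactions fixed to
    ``[0, 0]``; every other bound is unchanged."""
    for rid in report.total_blocked:
        if not model.has_reaction(rid):
            raise ModelError(f"dead-end report references unknown reaction: {rid}")
    out = scenario.copy()
    for rid in report.total_blocked:
        out.lower_bound[rid] = 0.0
        out.upper_bound[rid] = 0.0
    return out
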