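"""Model-quality utilities: synonym-based name normalization, automated
plausibility checking, and reaction-directionality assignment from Gibbs
free energies.

Misspelled metabolite names or unrecognized synonyms silently split one
chemical species into several disconnected network nodes — a frequent and
hard-to-spot reconstruction error.  :func:`normalize_names` rewrites every
metabolite to its recommended name using a user-supplied dictionary and
merges nodes that collapse onto the same name.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from .analysis import fba
from .model import MetabolicModel, Metabolite, ModelError, Reaction, Scenario
from .reduction import find_dead_ends
from .solvers import OPTIMAL, UNBOUNDED

__all__ = [
    "SynonymTable",
    "PlausibilityFinding",
    "PlausibilityReport",
    "normalize_names",
    "check_plausibility",
    "assign_directionality",
]


def _canon(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


class SynonymTable:
    """Functional map from synonym to recommended metabolite name.

    Matching is case-insensitive after whitespace normalization; every
    recommended name maps to itself.  No fuzzy matching is attempted.
    """

    def __init__(self, mapping: dict[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for syn, rec in (mapping or {}).items():
            self.add(syn, rec)

    def add(self, synonym: str, recommended: str) -> None:
        key = _canon(synonym)
        existing = self._map.get(key)
        if existing is not None and existing != recommended:
            raise ModelError(
                f"synonym {synonym!r} maps to both {existing!r} and {recommended!r}"
            )
        self._map[key] = recommended
        self._map.setdefault(_canon(recommended), recommended)

    def lookup(self, name: str) -> str | None:
        return self._map.get(_canon(name))

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, text: str) -> "SynonymTable":
        """Two tab-separated columns: synonym, recommended name."""
        table = cls()
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ModelError(f"synonym TSV line {lineno}: expected 2 columns")
            table.add(parts[0], parts[1])
        return table


def _id_token(name: str) -> str:
    """Recommended names may contain spaces; ids must be tokens."""
    return re.sub(r"\s+", "_", name.strip())


def normalize_names(
    model: MetabolicModel, table: SynonymTable
) -> tuple[MetabolicModel, list[str]]:
    """Replace every metabolite matching a synonym by its recommended name.

    Metabolites that collapse onto the same recommended name are merged:
    their stoichiometric entries are summed per reaction, and the merge is
    logged.  An entry cancelling to exactly zero is removed with a warning
    in the log.  The operation is idempotent.
    """
    log: list[str] = []
    new_id: dict[str, str] = {}
    target_info: dict[str, tuple[str, bool]] = {}  # new id -> (name, boundary)
    seen_targets: dict[str, list[str]] = {}
    for met in model.metabolites:
        rec = table.lookup(met.id) or table.lookup(met.name)
        if rec is None:
            nid, nname = met.id, met.name
        else:
            nid, nname = _id_token(rec), rec
            if nid != met.id:
                log.append(f"rename: {met.id} -> {nid}")
        new_id[met.id] = nid
        seen_targets.setdefault(nid, []).append(met.id)
        if nid in target_info:
            target_info[nid] = (nname, target_info[nid][1] and met.boundary)
        else:
            target_info[nid] = (nname, met.boundary)
    for nid, sources in seen_targets.items():
        if len(sources) > 1:
            log.append(f"merge: {' + '.join(sources)} -> {nid}")

    out = MetabolicModel(name=model.name)
    for nid, (nname, boundary) in target_info.items():
        out.add_metabolite(Metabolite(nid, nname, boundary))
    for rxn in model.reactions:
        stoich: dict[str, float] = {}
        for mid, coef in rxn.stoichiometry.items():
            nid = new_id[mid]
            stoich[nid] = stoich.get(nid, 0.0) + coef
        for mid in [m for m, c in stoich.items() if c == 0.0]:
            log.append(
                f"warning: reaction {rxn.id}: {mid} cancels to zero after merge, removed"
            )
            del stoich[mid]
        out.add_reaction(
            Reaction(rxn.id, stoich, rxn.reversible, rxn.delta_g, rxn.annotation),
            register_metabolites=False,
        )
    return out, log


@dataclass
class PlausibilityFinding:
    severity: str  # "error" | "warning"
    code: str
    subject: str
    message: str


@dataclass
class PlausibilityReport:
    findings: list[PlausibilityFinding] = field(default_factory=list)

    def add(self, severity: str, code: str, subject: str, message: str) -> None:
        self.findings.append(PlausibilityFinding(severity, code, subject, message))

    def sort(self) -> None:
        self.findings.sort(key=lambda f: (f.code, f.subject))

    @property
    def errors(self) -> list[PlausibilityFinding]:
        return [f for f in self.findings if f.severity == "error"]

    def by_code(self, code: str) -> list[PlausibilityFinding]:
        return [f for f in self.findings if f.code == code]


def _default_uptakes(model: MetabolicModel, scenario: Scenario) -> list[str]:
    """Exchange reactions able to import under the scenario bounds."""
    ups = []
    for rxn in model.reactions:
        if not rxn.is_exchange:
            continue
        lb, ub = scenario.bounds_for(rxn)
        imports = (rxn.products and not rxn.substrates and ub > 0) or (
            rxn.substrates and not rxn.products and lb < 0
        )
        if imports:
            ups.append(rxn.id)
    return ups


def _canonical_stoich(rxn: Reaction) -> tuple | None:
    """Stoichiometry normalized up to scaling and sign, for duplicate
    detection: divide by the coefficient of the lexicographically first
    metabolite."""
    if not rxn.stoichiometry:
        return None
    first = min(rxn.stoichiometry)
    ref = rxn.stoichiometry[first]
    return tuple(sorted((m, round(c / ref, 9)) for m, c in rxn.stoichiometry.items()))


def check_plausibility(
    model: MetabolicModel,
    scenario: Scenario,
    uptake_reactions: list[str] | None = None,
) -> PlausibilityReport:
    """Automated plausibility checks.

    * ``FREE_LUNCH`` (error): with every uptake closed, the objective must
      be exactly zero — growth without any substrate reveals an erroneous
      internal source.  ``uptake_reactions`` declares the medium; by
      default all import-capable exchange reactions are closed (an
      erroneous one-sided generator can then only be caught if the true
      uptakes are declared explicitly).
    * ``DUPLICATE_REACTION`` (warning): identical stoichiometry up to
      scaling and sign.
    * ``DEAD_END_METABOLITE`` / ``BLOCKED_REACTION`` (warning): from the
      iterative dead-end analysis.
    * ``UNBOUNDED_OBJECTIVE`` (warning): the scenario admits infinite
      objective flux.

    Findings are deterministically ordered by (code, subject).
    """
    report = PlausibilityReport()

    # (a) free-lunch test
    if scenario.objective is not None:
        ups = uptake_reactions if uptake_reactions is not None else _default_uptakes(model, scenario)
        closed = scenario.copy()
        for rid in ups:
            rxn = model.reaction(rid)
            lb, ub = scenario.bounds_for(rxn)
            if rxn.products and not rxn.substrates:
                closed.lower_bound[rid] = min(lb, 0.0)
                closed.upper_bound[rid] = 0.0
            else:
                closed.lower_bound[rid] = 0.0
                closed.upper_bound[rid] = max(ub, 0.0)
        sol = fba(model, closed)
        if sol.status == OPTIMAL and abs(sol.objective_value) > 1e-6:
            report.add(
                "error",
                "FREE_LUNCH",
                scenario.objective[0],
                f"objective reaches {sol.objective_value:.6g} with all uptakes closed",
            )
        elif sol.status == UNBOUNDED:
            report.add(
                "error",
                "FREE_LUNCH",
                scenario.objective[0],
                "objective unbounded with all uptakes closed",
            )

    # (b) duplicate reactions
    groups: dict[tuple, list[str]] = {}
    for rxn in model.reactions:
        key = _canonical_stoich(rxn)
        if key is not None:
            groups.setdefault(key, []).append(rxn.id)
    for ids in groups.values():
        for a, b in itertools.combinations(ids, 2):
            report.add(
                "warning",
                "DUPLICATE_REACTION",
                a,
                f"stoichiometry identical to {b} up to scaling/sign",
            )

    # (c) dead ends
    dead = find_dead_ends(model, scenario)
    for it_no, it in enumerate(dead.iterations, start=1):
        for mid in sorted(it.dead_metabolites):
            report.add(
                "warning", "DEAD_END_METABOLITE", mid, f"dead end in iteration {it_no}"
            )
        for rid in sorted(it.blocked_reactions):
            report.add(
                "warning", "BLOCKED_REACTION", rid, f"blocked in iteration {it_no}"
            )

    # (d) unbounded scenario
    if scenario.objective is not None:
        sol = fba(model, scenario)
        if sol.status == UNBOUNDED:
            report.add(
                "warning",
                "UNBOUNDED_OBJECTIVE",
                scenario.objective[0],
                "objective flux is unbounded under the scenario",
            )
    report.sort()
    return report


def assign_directionality(
    model: MetabolicModel,
    delta_g: dict[str, float],
    threshold: float = 30.0,
) -> tuple[MetabolicModel, list[str]]:
    """Assign reaction directionality from reaction Gibbs free energies.

    ΔG < -threshold (kJ/mol): irreversible forward; ΔG > +threshold: the
    stoichiometry is reversed and the reaction made irreversible;
    |ΔG| <= threshold: reversible.  Reactions without a ΔG entry are left
    untouched.  Supplied values are taken as already transformed to the
    conditions of interest.
    """
    for rid in delta_g:
        if not model.has_reaction(rid):
            raise ModelError(f"delta G supplied for unknown reaction: {rid}")
    out = model.copy()
    log: list[str] = []
    for rxn in out.reactions:
        if rxn.id not in delta_g:
            continue
        dg = delta_g[rxn.id]
        rxn.delta_g = dg
        if dg < -threshold:
            if rxn.reversible:
                log.append(f"{rxn.id}: dG={dg:g} -> irreversible forward")
            rxn.reversible = False
        elif dg > threshold:
            rxn.stoichiometry = {m: -c for m, c in rxn.stoichiometry.items()}
            rxn.reversible = False
            log.append(f"{rxn.id}: dG={dg:g} -> reversed and irreversible")
        else:
            if not rxn.reversible:
                log.append(f"{rxn.id}: dG={dg:g} -> reversible")
            rxn.reversible = True
    return out, log
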