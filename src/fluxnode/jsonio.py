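"""COBRA-style JSON model interchange (single-objective subset).

The accepted dialect is the de-facto COBRA JSON schema: top-level
``metabolites`` and ``reactions`` lists, each reaction carrying a
``metabolites`` coefficient map, ``lower_bound``/``upper_bound``, and an
``objective_coefficient``.  Exactly one reaction may have a nonzero
objective coefficient (taken as a maximization target); gene/GPR fields
are ignored.
"""

from __future__ import annotations

import json
import math
import os

from .model import INF, MetabolicModel, Metabolite, ModelError, Reaction, Scenario

__all__ = ["convert_json", "model_to_json"]

#: conventional finite stand-ins for unbounded fluxes in COBRA JSON files
_JSON_BIG = 1000.0


def convert_json(path_or_text: str) -> tuple[MetabolicModel, Scenario]:
    """Load a COBRA-style JSON model (path or raw JSON text)."""
    text = path_or_text
    if not path_or_text.lstrip().startswith("{") and os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError(f"not valid JSON: {exc}") from None
    if "reactions" not in data:
        raise ModelError("JSON model lacks a 'reactions' key")
    model = MetabolicModel(name=data.get("id", ""))
    for met in data.get("metabolites", []):
        model.add_metabolite(
            Metabolite(
                met["id"],
                met.get("name", "") or met["id"],
                bool(met.get("boundary_condition", False)),
            )
        )
    scen = Scenario(name=model.name)
    objective_rxns: list[str] = []
    for rx in data["reactions"]:
        lb = float(rx.get("lower_bound", 0.0))
        ub = float(rx.get("upper_bound", _JSON_BIG))
        stoich = {m: float(c) for m, c in rx.get("metabolites", {}).items()}
        model.add_reaction(Reaction(rx["id"], stoich, reversible=lb < 0))
        scen.lower_bound[rx["id"]] = lb
        scen.upper_bound[rx["id"]] = ub
        if float(rx.get("objective_coefficient", 0.0)) != 0.0:
            objective_rxns.append(rx["id"])
    if len(objective_rxns) > 1:
        raise ModelError(
            f"multi-objective JSON models are unsupported: {objective_rxns}"
        )
    if objective_rxns:
        scen.objective = (objective_rxns[0], "max")
    return model, scen


def model_to_json(model: MetabolicModel, scenario: Scenario | None = None) -> str:
    """Serialize to COBRA-style JSON.  Infinite bounds are written as the
    conventional ±1000."""
    scen = scenario or Scenario()

    def clip(v: float) -> float:
        if math.isinf(v):
            return _JSON_BIG if v > 0 else -_JSON_BIG
        return v

    obj_rxn = scen.objective[0] if scen.objective else None
    data = {
        "id": model.name or "fluxnode_model",
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": "c",
                "boundary_condition": m.boundary,
            }
            for m in model.metabolites
        ],
        "reactions": [],
        "genes": [],
        "compartments": {"c": "cytosol"},
        "version": "1",
    }
    for r in model.reactions:
        lb, ub = scen.bounds_for(r)
        data["reactions"].append(
            {
                "id": r.id,
                "name": r.id,
                "metabolites": dict(r.stoichiometry),
                "lower_bound": clip(lb),
                "upper_bound": clip(ub),
                "gene_reaction_rule": "",
                "objective_coefficient": 1.0 if r.id == obj_rxn else 0.0,
            }
        )
    return json.dumps(data, indent=1)
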