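"""SBML import/export (Level 2, and Level 3 with the fbc extension).

Export writes L3v1 + fbc v2 documents with per-reaction flux-bound
parameters and a single active flux objective, and runs the libSBML
consistency check.  Import accepts both plain L2 (reversible flags and
boundaryCondition only; bounds fall back to reversibility defaults) and
L3 + fbc (bounds and objective populate the returned scenario).
"""

from __future__ import annotations

import math
import warnings

import libsbml

from .model import INF, MetabolicModel, Metabolite, ModelError, Reaction, Scenario

__all__ = ["import_sbml", "import_sbml_string", "export_sbml", "export_sbml_string"]


class SBMLError(ModelError):
    """Unreadable or invalid SBML, carrying libSBML diagnostics."""


def _document_errors(doc: libsbml.SBMLDocument) -> list[str]:
    msgs = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            msgs.append(f"{err.getSeverityAsString()}: {err.getMessage().strip()}")
    return msgs


def _from_document(doc: libsbml.SBMLDocument) -> tuple[MetabolicModel, Scenario]:
    errors = _document_errors(doc)
    if errors:
        raise SBMLError("invalid SBML: " + "; ".join(errors[:5]))
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLError("SBML document contains no model")
    model = MetabolicModel(name=sbml_model.getId() or sbml_model.getName())
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        model.add_metabolite(
            Metabolite(sp.getId(), sp.getName() or sp.getId(), bool(sp.getBoundaryCondition()))
        )
    scen = Scenario(name=model.name)
    fbc = sbml_model.getPlugin("fbc")
    for i in range(sbml_model.getNumReactions()):
        rx = sbml_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        reversible = bool(rx.getReversible())
        model.add_reaction(
            Reaction(rx.getId(), stoich, reversible), register_metabolites=False
        )
        rplug = rx.getPlugin("fbc")
        if rplug is not None:
            for getter, target, default in (
                (rplug.getLowerFluxBound, scen.lower_bound, -INF if reversible else 0.0),
                (rplug.getUpperFluxBound, scen.upper_bound, INF),
            ):
                pid = getter()
                if pid:
                    param = sbml_model.getParameter(pid)
                    if param is not None:
                        value = param.getValue()
                        if value != default:
                            target[rx.getId()] = value
    if fbc is not None and fbc.getNumObjectives() > 0:
        obj = fbc.getActiveObjective() or fbc.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            fo = obj.getFluxObjective(0)
            direction = "max" if obj.getType() == "maximize" else "min"
            scen.objective = (fo.getReaction(), direction)
    if scen.objective is None:
        warnings.warn("SBML model defines no flux objective; scenario has none")
    return model, scen


def import_sbml(path: str) -> tuple[MetabolicModel, Scenario]:
    """Read an SBML file into a model and (possibly partial) scenario."""
    doc = libsbml.readSBML(path)
    return _from_document(doc)


def import_sbml_string(text: str) -> tuple[MetabolicModel, Scenario]:
    doc = libsbml.readSBMLFromString(text)
    return _from_document(doc)


def _bound_value(v: float) -> float:
    return v  # libSBML serializes IEEE infinities as INF/-INF


def export_sbml_string(model: MetabolicModel, scenario: Scenario | None = None) -> str:
    """Serialize to an L3v1 + fbc v2 document and validate it."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel()
    sm.setId(model.name or "fluxnode_model")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    comp = sm.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    comp.setSize(1.0)
    for met in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment("c")
        sp.setBoundaryCondition(met.boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
    scen = scenario or Scenario()
    bound_params: dict[float, str] = {}

    def _param_for(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sm.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rxn in model.reactions:
        rx = sm.createReaction()
        rx.setId(rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coef in rxn.substrates.items():
            ref = rx.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(coef)
            ref.setConstant(True)
        for mid, coef in rxn.products.items():
            ref = rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(coef)
            ref.setConstant(True)
        lb, ub = scen.bounds_for(rxn)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_param_for(lb))
        rplug.setUpperFluxBound(_param_for(ub))
    if scen.objective is not None:
        rxn_id, direction = scen.objective
        obj = mplug.createObjective()
        obj.setId("obj")
        obj.setType("maximize" if direction == "max" else "minimize")
        fo = obj.createFluxObjective()
        fo.setReaction(rxn_id)
        fo.setCoefficient(1.0)
        mplug.setActiveObjectiveId("obj")
    doc.checkConsistency()
    errors = _document_errors(doc)
    if errors:
        raise SBMLError("generated SBML failed validation: " + "; ".join(errors[:5]))
    return libsbml.writeSBMLToString(doc)


def export_sbml(model: MetabolicModel, scenario: Scenario | None, path: str) -> None:
    text = export_sbml_string(model, scenario)
    with open(path, "w") as fh:
        fh.write(text)
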