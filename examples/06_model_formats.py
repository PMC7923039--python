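"""Model interchange: plain reaction lists, SBML (L3 + fbc), COBRA JSON.

The plain dialect keeps the network human-editable; the scenario file
keeps simulation constraints separate from the model; SBML and JSON
connect to the wider constraint-based-modeling ecosystem.
"""

from fluxnode import (
    convert_json,
    export_sbml_string,
    fba,
    import_sbml_string,
    make_fixture,
    model_to_json,
    write_reaction_file,
    write_scenario_file,
)

model, scenario = make_fixture("TOY_YIELD")
print("reaction file:")
print(write_reaction_file(model))
print("scenario file:")
print(write_scenario_file(scenario))

xml = export_sbml_string(model, scenario)
m2, s2 = import_sbml_string(xml)
print(f"SBML round trip: {m2.summary()}, objective {s2.objective}")

m3, s3 = convert_json(model_to_json(model, scenario))
print(f"JSON round trip: {m3.summary()}")
print(f"FBA after both journeys: {fba(m3, s3).objective_value:.1f} "
      "(the 2:1 stoichiometry halves the uptake bound of 10)")
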