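"""Flux balance analysis on a human-readable reaction list.

Builds a three-reaction linear chain from plain text, attaches a scenario
(uptake bound + objective), and solves for the optimal steady-state flux
distribution.
"""

from fluxnode import fba, parse_reaction_file, parse_scenario_file

model = parse_reaction_file(
    """
    upt  : -> glc        # glucose uptake across the boundary
    conv : glc -> pyr    # lumped glycolysis
    bio  : pyr ->        # biomass drain
    """
)
scenario = parse_scenario_file("OBJ max bio\nUB upt 10")

solution = fba(model, scenario)
print(model.summary())
print(f"status: {solution.status}")
print(f"objective (bio): {solution.objective_value:.4f} mmol/gCDW/h")
for rxn_id, flux in solution.fluxes.items():
    print(f"  {rxn_id:5s} {flux:8.4f}")
# Every reaction carries 10 flux units: the chain is saturated by the
# uptake bound, which caps growth at 10 mmol/gCDW/h.
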