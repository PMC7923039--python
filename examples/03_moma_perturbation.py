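"""Minimization of metabolic adjustment (MOMA) after a gene knockout.

A freshly perturbed strain has had no time to re-evolve optimality, so
instead of re-running FBA we look for the feasible flux state *closest*
(Euclidean) to the wild type — a quadratic program.
"""

from fluxnode import compare_fluxes, fba, make_fixture, moma

model, scenario = make_fixture("TOY_BRANCH")
wildtype = fba(model, scenario)
print("wild type:", {k: round(v, 3) for k, v in wildtype.fluxes.items()})

knockout = scenario.with_knockout("r1")
mutant = moma(model, knockout, wildtype, fva_reduce=True)
print("MOMA mutant:", {k: round(v, 3) for k, v in mutant.fluxes.items()})
print(f"squared distance to wild type: {mutant.objective_value:.3f}")
# The knockout forces exB to zero; the closest compromise reroutes
# 10/3 units through the alternative branch instead of shutting down.

cmp = compare_fluxes(wildtype, mutant)
print(f"reactions that changed: {sorted(cmp.differing)}")
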