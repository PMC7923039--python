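"""Dead-end analysis and model curation utilities.

A metabolite that cannot be both produced and consumed pins every adjacent
reaction to zero flux; blocking those reactions can create new dead ends,
so the analysis iterates.  The curation helpers catch common
reconstruction mistakes: synonym-split metabolites, duplicate reactions,
and erroneous internal sources ("free lunch").
"""

from fluxnode import (
    SynonymTable,
    Scenario,
    assign_directionality,
    check_plausibility,
    find_dead_ends,
    make_fixture,
    normalize_names,
    parse_reaction_file,
)

model, scenario = make_fixture("TOY_DEAD")
report = find_dead_ends(model, scenario)
for i, it in enumerate(report.iterations, start=1):
    print(f"iteration {i}: dead {sorted(it.dead_metabolites)}, "
          f"blocked {sorted(it.blocked_reactions)}")
# The by-product D has no consumer, which transitively kills the whole chain.

sloppy = parse_reaction_file("r1 : dextrose -> pyruvate\nr2 : glucose -> pyruvate")
table = SynonymTable({"glucose": "D-glucose", "dextrose": "D-glucose"})
clean, log = normalize_names(sloppy, table)
print("\nname normalization:", *log, sep="\n  ")

leaky = parse_reaction_file("upt : -> A\nconv : A -> B\ngen : -> B\nbio : B ->")
scen = Scenario(upper_bound={"upt": 10.0}, objective=("bio", "max"))
findings = check_plausibility(leaky, scen, uptake_reactions=["upt"])
print("\nplausibility findings:")
for f in findings.findings:
    print(f"  [{f.severity}] {f.code} {f.subject}: {f.message}")

rev = parse_reaction_file("hexokinase : glc -> g6p")
directed, log = assign_directionality(rev, {"hexokinase": -17.0}, threshold=30.0)
print("\ndirectionality:", log or "within threshold -> set reversible")
print("hexokinase reversible:", directed.reaction("hexokinase").reversible)
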