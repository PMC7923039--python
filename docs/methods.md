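# Methods

## Model, scenario, steady state

A model is a bipartite structure of metabolites and stoichiometric
reactions; simulation constraints live in a separate scenario (per-reaction
flux bounds and one objective), so one network can be simulated under many
conditions without touching the model file.  All analyses assume steady
state, `S v = 0`, over the non-boundary metabolites; boundary metabolites
(SBML `boundaryCondition`) carry no balance row and may accumulate freely.
Default bounds derive from reversibility: `[0, +inf)` for irreversible
reactions, `(-inf, +inf)` for reversible ones.  Compartments are encoded as
metabolite-id suffixes (`atp_c`, `atp_e`); there is no first-class
compartment object.  Fluxes are reported in mmol gCDW⁻¹ h⁻¹ by convention;
the mathematics is unit-agnostic.

Infinite bounds are kept as IEEE infinities end to end: GLPK receives them
as free/one-sided bound types, scipy and OSQP accept `inf` natively, so no
finite capping constant is needed anywhere.

## Solver layer

LPs: GLPK (default) behind a stateful problem object that retains the
simplex basis, and scipy `linprog`/HiGHS as an independent cold back-end.
QPs: OSQP with `eps_abs = eps_rel = 1e-10` and solution polishing.
Tolerances: 1e-9 absolute on constraint residuals, 1e-6 relative on
objectives; a returned FBA distribution is additionally checked to satisfy
`‖S v‖∞ ≤ 1e-6`.  No back-end is randomized, so results carry no seeds.
Degenerate LP optima are back-end-dependent vertices: only the objective
value and quantities derived from it are contractual; reported flux vectors
are *one* optimal solution (see split ratios below).

Warm starts are the fastFVA mechanism: FVA and MFM build their feasible
region once (steady-state rows plus the objective-fraction row) and then
only swap the objective vector between solves, so GLPK re-enters the
simplex from the previous basis.  Warm and cold solves must and do agree to
1e-6; the test suite enforces this against naive per-problem scipy LPs.

## Dead-end reduction

A non-boundary metabolite is a dead end if, under the directions admissible
given the current bounds (a reversible reaction clamped to `[0, ub]` counts
as forward-only), it cannot be both produced and consumed — or if it is
touched by at most one reaction.  The second clause is not redundant: an
isolated reversible reaction `A <-> B` can formally produce and consume
both metabolites, yet no nonzero steady flux balances them; a metabolite in
a single reaction forces that reaction to zero outright.  Both rules are
conservative (every blocked reaction provably carries zero flux in every
steady state), so fixing blocked reactions to `[0, 0]` and iterating to a
fixpoint (at most one iteration per metabolite) never changes any optimum —
an invariance the suite checks for FBA, FVA and MFM on all fixtures and on
random models.  Reduction runs by default before every optimization and can
be disabled per call.

## FVA and the objective-fraction constraint

With optimum `z` of a maximization objective, the γ-constraint is
`v_obj ≥ γ·z` for `z ≥ 0` and `v_obj ≥ z/γ` for `z < 0` (mirrored for
minimization), so relaxation always moves *away* from the optimum and γ = 1
pins it exactly.  `fraction=None` drops the constraint entirely; this
unconstrained variant supplies the provably optimum-preserving box
tightening used by MOMA's `fva_reduce` option (the boxes circumscribe the
feasible polyhedron, so intersecting them changes nothing).  γ is always
recorded in reports.

## MOMA

The perturbed flux state is the Euclidean projection of the wild-type
distribution onto the perturbed feasible set: `min Σ_j (v_j − w_j)²` over
**all** reactions, internal and exchange alike — the simplest faithful
reading of "closest flux distribution", and the convention assumed
throughout.  The reported objective value is the squared distance; the
identity perturbation therefore returns the wild type with distance zero
(to solver precision), and distance is zero iff the wild type remains
feasible.  Knockout screens with `method="moma"` use the unperturbed FBA
solution as the wild type and report the objective reaction's flux in the
projected state.

## MFM and essentiality

Producing fluxes are only linear in the fluxes once every reversible
reaction is split into an irreversible pair (`v = v_fwd − v_bwd`,
both nonnegative); MFM therefore operates on the split network, with the
γ-constraint written on the net objective flux.  The per-metabolite
minimum is clipped at zero (the true value is nonnegative by
construction; solvers may return −1e-12).  A metabolite is essential when
its minimum exceeds 1e-9 absolute — the tolerance is exposed, and the
essential/non-essential partition plus a descending ranking (ties broken
lexicographically by id, for determinism) are derived views of the same
report.  Lowering γ enlarges the feasible set, so minimal fluxes are
non-increasing and the non-essential count non-decreasing — a monotonicity
the acceptance tests verify on every fixture.

## Split ratios and the graph view

Split ratios describe one realized solution, on net fluxes: reaction j
produces `S[m,j]·v_j` of m when positive, consumes the absolute value when
negative (a reversible reaction contributes per its net sign).
Contributions below 1e-9 are omitted; percentages are taken against the
producing and consuming totals separately, which both equal the node's
turnover at steady state.  Because FBA vertices are non-unique, split
ratios inherit that non-uniqueness; CLI reports embed solver and γ
provenance so a result can be reproduced bit-wise.  The bipartite graph
export labels metabolite nodes with turnover and edges with percentages,
flags subnetworks with flux below a tolerance as inactive, and can condense
maximal chains of single-predecessor/single-successor nodes into one dashed
edge (branch points and endpoints always survive; isolated cycles are left
alone).

## Curation

Name normalization is dictionary-based and exact after case-folding,
trimming and whitespace collapsing — no fuzzy matching; merges triggered by
two metabolites collapsing onto one recommended name sum their
coefficients per reaction, removing (and logging) exact cancellations.  The
operation is idempotent.  The free-lunch check closes the *declared* medium
(an explicit uptake list) or, by default, every import-capable one-sided
exchange reaction, then requires the objective optimum to be exactly zero.
Declaring the medium explicitly is strictly stronger: an erroneous internal
generator is itself a one-sided reaction, so a purely structural default
would close it too and mask the error.  Duplicate detection canonicalizes
stoichiometries up to scaling and sign — note this intentionally flags
mirror-image exchange pairs as well.  Directionality assignment treats
supplied reaction Gibbs energies as already transformed: below −30 kJ/mol
(default, adjustable) the reaction becomes irreversible forward, above
+30 kJ/mol it is reversed and made irreversible, in between it is
reversible.  Mass/charge balancing is out of scope.

## Fixtures and the random-model generator

The named fixtures are minimal networks with hand-derivable optima (linear
chain: 10; 2:1 yield: 5; dead-end chain: 0; branch: 10; prephenate branch:
0.6624) used both as documentation and as oracle anchors.  The prephenate
fixture encodes an aromatic-biosynthesis branch point with a 0.72-unit
turnover splitting 8%/92% between the amino-acid and antibiotic-sink
branches, so the worked example doubles as a regression test.  The random
generator builds a guaranteed-feasible backbone (uptake → chain → objective
sink, uptake bounded at 10) plus extra conversions with substrate
coefficient in {1, 2} and product coefficient never exceeding it (equal
when reversible); a unit "mass" argument then rules out flux-generating
cycles, so every generated model is feasible with a bounded positive
optimum.  These generated networks exercise solver paths (loops, reversible
splits, dead ends), not biological realism: they have no biomass
composition, compartments, or cofactor coupling, so green tests certify the
algorithms and formats, not any particular organism model.  Desk-scale
problem sizes (≤ 10 metabolites × 15 reactions, 20 random instances) keep
the whole suite in seconds while still covering every code path; all sizes
and seeds are fixed in one place.

Downloading the two published genome-scale models behind the optional
`fetch_published_model` helper requires network access; nothing in the
default suite or the acceptance script depends on it.

## Known limitations

Gene–protein–reaction logic, MILP-based strain design, thermodynamic
feasibility constraints, gap filling and MATLAB export are out of scope.
FBA-derived flux vectors (and thus split ratios) are one representative
optimum; no parsimonious post-processing is applied silently.  The SBML
writer emits L3v1 + fbc v2 only (the reader also accepts L2); annotations
and notes are not mined.
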