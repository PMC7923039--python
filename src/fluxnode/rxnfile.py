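"""Human-readable reaction-list and scenario file dialects.

Reaction file (``.rxn``), one reaction per line::

    # comment
    upt  : -> A
    conv : 2 A -> B          # irreversible, coefficient 2
    iso  : A <-> B           # reversible

Grammar: ``id : lhs -> rhs`` or ``id : lhs <-> rhs``; each side is a
``+``-joined list of terms ``[coef] metabolite`` with an optional positive
real coefficient (default 1); an empty side denotes an exchange across the
system boundary.  ``#`` starts a comment; whitespace is insignificant.

Scenario file (``.scen``), line-oriented directives::

    OBJ max bio
    LB  upt 0
    UB  upt 10       # -inf / inf accepted
"""

from __future__ import annotations

from .model import INF, MetabolicModel, Reaction, Scenario

__all__ = [
    "ParseError",
    "parse_reaction_file",
    "write_reaction_file",
    "parse_scenario_file",
    "write_scenario_file",
]


class ParseError(ValueError):
    """Malformed reaction or scenario text; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


def _strip_comment(line: str) -> str:
    idx = line.find("#")
    return line if idx < 0 else line[:idx]


def _parse_side(text: str, sign: float, lineno: int) -> dict[str, float]:
    stoich: dict[str, float] = {}
    text = text.strip()
    if not text:
        return stoich
    for term in text.split("+"):
        parts = term.split()
        if not parts:
            raise ParseError(lineno, "empty term between '+' separators")
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ParseError(lineno, f"non-numeric coefficient {parts[0]!r}") from None
            met = parts[1]
        else:
            raise ParseError(lineno, f"cannot parse term {term.strip()!r}")
        if coef <= 0:
            raise ParseError(lineno, f"coefficient must be positive: {coef}")
        stoich[met] = stoich.get(met, 0.0) + sign * coef
    return stoich


def parse_reaction_file(text: str, name: str = "") -> MetabolicModel:
    """Parse the reaction dialect into a model.

    Metabolites are registered on first mention, in order of appearance.
    ``->`` marks an irreversible reaction, ``<->`` a reversible one.
    A metabolite appearing on both sides is summed to its net coefficient;
    exact cancellation drops it from the reaction.
    """
    model = MetabolicModel(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if ":" not in line:
            raise ParseError(lineno, "missing ':' separator between id and reaction")
        rxn_id, _, body = line.partition(":")
        rxn_id = rxn_id.strip()
        if not rxn_id:
            raise ParseError(lineno, "empty reaction id")
        if model.has_reaction(rxn_id):
            raise ParseError(lineno, f"duplicate reaction id {rxn_id!r}")
        if "<->" in body:
            lhs, _, rhs = body.partition("<->")
            reversible = True
        elif "->" in body:
            lhs, _, rhs = body.partition("->")
            reversible = False
        else:
            raise ParseError(lineno, "missing '->' or '<->' arrow")
        stoich = _parse_side(lhs, -1.0, lineno)
        for met, coef in _parse_side(rhs, +1.0, lineno).items():
            stoich[met] = stoich.get(met, 0.0) + coef
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        try:
            model.add_reaction(Reaction(rxn_id, stoich, reversible))
        except ValueError as exc:
            raise ParseError(lineno, str(exc)) from None
    return model


def _format_side(terms: dict[str, float]) -> str:
    parts = []
    for met, coef in terms.items():
        if coef == 1.0:
            parts.append(met)
        else:
            coef_s = f"{coef:g}"
            parts.append(f"{coef_s} {met}")
    return " + ".join(parts)


def write_reaction_file(model: MetabolicModel) -> str:
    """Serialize a model to the reaction dialect; reparsing reproduces it."""
    lines = [f"# reaction file: {model.summary()}"]
    for r in model.reactions:
        arrow = "<->" if r.reversible else "->"
        lines.append(f"{r.id} : {_format_side(r.substrates)} {arrow} {_format_side(r.products)}".replace("  ", " "))
    return "\n".join(lines) + "\n"


def _parse_bound(token: str, lineno: int) -> float:
    tok = token.lower()
    if tok in ("inf", "+inf", "infinity"):
        return INF
    if tok == "-inf":
        return -INF
    try:
        return float(token)
    except ValueError:
        raise ParseError(lineno, f"non-numeric bound {token!r}") from None


def parse_scenario_file(text: str, name: str = "") -> Scenario:
    """Parse scenario directives (OBJ / LB / UB) into a :class:`Scenario`.

    Validation against a model (unknown reactions, LB > UB, missing
    objective) is deferred to application time, so a scenario can be parsed
    independently of any model.
    """
    scen = Scenario(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        parts = line.split()
        directive = parts[0].upper()
        if directive == "OBJ":
            if len(parts) != 3 or parts[1].lower() not in ("max", "min"):
                raise ParseError(lineno, "expected 'OBJ max|min <reaction>'")
            if scen.objective is not None:
                raise ParseError(lineno, "duplicate OBJ directive")
            scen.objective = (parts[2], parts[1].lower())
        elif directive in ("LB", "UB"):
            if len(parts) != 3:
                raise ParseError(lineno, f"expected '{directive} <reaction> <value>'")
            value = _parse_bound(parts[2], lineno)
            target = scen.lower_bound if directive == "LB" else scen.upper_bound
            if parts[1] in target:
                raise ParseError(lineno, f"duplicate {directive} for {parts[1]!r}")
            target[parts[1]] = value
        else:
            raise ParseError(lineno, f"unknown directive {parts[0]!r}")
    return scen


def _format_bound(value: float) -> str:
    if value == INF:
        return "inf"
    if value == -INF:
        return "-inf"
    return f"{value:g}"


def write_scenario_file(scenario: Scenario) -> str:
    lines = ["# scenario file"]
    if scenario.objective is not None:
        rxn, direction = scenario.objective
        lines.append(f"OBJ {direction} {rxn}")
    for rid, val in scenario.lower_bound.items():
        lines.append(f"LB {rid} {_format_bound(val)}")
    for rid, val in scenario.upper_bound.items():
        lines.append(f"UB {rid} {_format_bound(val)}")
    return "\n".join(lines) + "\n"
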