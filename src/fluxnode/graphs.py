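"""Bipartite metabolite/reaction graph export of a flux solution.

The network is rendered as a directed bipartite graph: metabolite nodes
(labelled with their turnover in mmol gCDW^-1 h^-1) and reaction nodes;
edges follow the realized flux direction and are labelled with the split
percentages of the adjacent metabolite.  Parts of the network carrying no
flux are flagged inactive (drawn grey in DOT output).  Linear chains —
runs of nodes without branch points — can be condensed into a single
dashed edge to de-clutter large maps.

Node keys are namespaced (``met:<id>`` / ``rxn:<id>``) so a metabolite and
a reaction may share an id.
"""

from __future__ import annotations

import json

import networkx as nx

from .analysis import FluxDistribution
from .metabolite import SplitRatioTable
from .model import MetabolicModel, ModelError

__all__ = [
    "build_bipartite_graph",
    "condense_linear_chains",
    "export_bipartite_graph",
    "graph_to_dot",
]

ACTIVE_TOL = 1e-9


def build_bipartite_graph(
    model: MetabolicModel,
    fluxes: FluxDistribution,
    ratios: SplitRatioTable,
    active_tolerance: float = ACTIVE_TOL,
) -> nx.DiGraph:
    """Assemble the labelled bipartite graph for one flux state."""
    G = nx.DiGraph()
    pct: dict[tuple[str, str, str], float] = {}
    for mid, split in ratios.entries.items():
        for rxn, _, p in split.producers:
            pct[(mid, rxn, "producer")] = p
        for rxn, _, p in split.consumers:
            pct[(mid, rxn, "consumer")] = p
    for met in model.metabolites:
        split = ratios.entries.get(met.id)
        turnover = split.turnover if split else 0.0
        G.add_node(
            f"met:{met.id}",
            kind="metabolite",
            id=met.id,
            label=f"{met.name}\n{turnover:.4g}",
            turnover=float(turnover),
            active=bool(turnover > active_tolerance),
        )
    for rxn in model.reactions:
        v = fluxes.get(rxn.id, 0.0)
        active = abs(v) > active_tolerance
        G.add_node(
            f"rxn:{rxn.id}",
            kind="reaction",
            id=rxn.id,
            label=rxn.annotation or rxn.id,
            flux=float(v),
            active=bool(active),
        )
        forward = v >= 0  # inactive reactions drawn in canonical direction
        for mid, coef in rxn.stoichiometry.items():
            consumed = (coef < 0) == forward
            if consumed:
                u, w, role = f"met:{mid}", f"rxn:{rxn.id}", "consumer"
            else:
                u, w, role = f"rxn:{rxn.id}", f"met:{mid}", "producer"
            p = pct.get((mid, rxn.id, role), 0.0)
            G.add_edge(
                u,
                w,
                percent=float(p),
                label=f"{p:.1f}%" if active else "",
                flux=abs(float(v)),
                active=bool(active),
                condensed=False,
            )
    return G


def condense_linear_chains(G: nx.DiGraph) -> nx.DiGraph:
    """Collapse maximal paths whose interior nodes have exactly one
    predecessor and one successor into a single condensed edge.

    Branch points and endpoints are preserved; isolated cycles are left
    untouched.  The condensed edge records the chain members and carries
    the flux of the first replaced edge.
    """
    H = G.copy()
    interior = {n for n in H if H.in_degree(n) == 1 and H.out_degree(n) == 1}
    visited: set[str] = set()
    for node in list(interior):
        if node in visited:
            continue
        # walk back to the start of this chain
        start = node
        while True:
            pred = next(iter(H.predecessors(start)))
            if pred in interior and pred != node:
                start = pred
            else:
                break
        if next(iter(H.predecessors(start))) == node and node != start:
            continue  # pure cycle, nothing to condense against
        chain = [start]
        cur = start
        while True:
            succ = next(iter(H.successors(cur)))
            if succ in interior and succ != start:
                chain.append(succ)
                cur = succ
            else:
                break
        visited.update(chain)
        head = next(iter(H.predecessors(chain[0])))
        tail = next(iter(H.successors(chain[-1])))
        if head == tail or head in chain or tail in chain:
            continue
        first_edge = H.get_edge_data(head, chain[0], default={})
        flux = first_edge.get("flux", 0.0)
        active = all(H.nodes[n].get("active", True) for n in chain)
        H.remove_nodes_from(chain)
        H.add_edge(
            head,
            tail,
            condensed=True,
            members="|".join(chain),
            flux=float(flux),
            percent=100.0,
            label=f"{len(chain)} condensed",
            active=bool(active),
        )
    return H


def _dot_quote(s: str) -> str:
    return '"' + s.replace('"', r"\"").replace("\n", r"\n") + '"'


def graph_to_dot(G: nx.DiGraph) -> str:
    lines = ["digraph fluxnet {", "  rankdir=LR;"]
    for n, data in G.nodes(data=True):
        shape = "box" if data.get("kind") == "reaction" else "ellipse"
        color = "grey" if not data.get("active", True) else (
            "lightblue" if data.get("kind") == "reaction" else "darkblue"
        )
        attrs = f"label={_dot_quote(data.get('label', n))} shape={shape} color={_dot_quote(color)}"
        lines.append(f"  {_dot_quote(n)} [{attrs}];")
    for u, w, data in G.edges(data=True):
        style = "dashed" if data.get("condensed") else "solid"
        color = "grey" if not data.get("active", True) else "black"
        attrs = (
            f"label={_dot_quote(data.get('label', ''))} style={style} color={_dot_quote(color)}"
        )
        lines.append(f"  {_dot_quote(u)} -> {_dot_quote(w)} [{attrs}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def _graph_to_graphml(G: nx.DiGraph) -> str:
    return "\n".join(nx.generate_graphml(G)) + "\n"


def _graph_to_json(G: nx.DiGraph) -> str:
    return json.dumps(nx.node_link_data(G, edges="links"), indent=1)


_WRITERS = {"dot": graph_to_dot, "graphml": _graph_to_graphml, "json": _graph_to_json}


def export_bipartite_graph(
    model: MetabolicModel,
    fluxes: FluxDistribution,
    ratios: SplitRatioTable,
    format: str = "dot",
    active_tolerance: float = ACTIVE_TOL,
    condense: bool = False,
    path: str | None = None,
) -> str:
    """Serialize the bipartite flux graph to dot / graphml / json text.

    If ``path`` is given the text is also written there.
    """
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ModelError(f"unknown graph format {format!r}") from None
    G = build_bipartite_graph(model, fluxes, ratios, active_tolerance)
    if condense:
        G = condense_linear_chains(G)
    text = writer(G)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
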