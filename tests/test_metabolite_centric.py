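"""Metabolite flux minimization, essentiality, split ratios and the
bipartite graph view."""

import numpy as np
import pytest

from fluxnode import (
    ModelError,
    build_bipartite_graph,
    condense_linear_chains,
    essential_partition,
    export_bipartite_graph,
    fba,
    make_fixture,
    mfm,
    producing_flux_coefficients,
    rank_metabolites,
    split_ratios,
    to_irreversible,
)
from fluxnode.analysis import FluxDistribution
from fluxnode.metabolite import MetaboliteFluxReport
from oracles import oracle_mfm

FIXTURES = ("TOY_LIN", "TOY_BRANCH", "TOY_YIELD", "TOY_DEAD", "TOY_REV",
            "PREPHENATE_BRANCH")


class TestProducingFluxCoefficients:
    def test_single_producer(self):
        model, _ = make_fixture("TOY_LIN")
        coefs = producing_flux_coefficients(model, "B")
        assert dict(zip(model.reaction_ids, coefs)) == {"upt": 0, "conv": 1.0, "bio": 0}

    def test_stoichiometric_coefficient_carried(self):
        model, _ = make_fixture("TOY_YIELD")
        b = producing_flux_coefficients(model, "B")
        a = producing_flux_coefficients(model, "A")
        assert dict(zip(model.reaction_ids, b))["conv"] == 1.0
        assert dict(zip(model.reaction_ids, a))["upt"] == 1.0

    def test_only_positive_entries_after_split(self):
        model, _ = make_fixture("TOY_REV")
        split, mapping, _ = to_irreversible(model)
        coefs = dict(zip(split.reaction_ids, producing_flux_coefficients(split, "B")))
        assert coefs["iso_fwd"] == 1.0
        assert coefs["iso_bwd"] == 0.0

    def test_unknown_and_boundary_rejected(self):
        model, _ = make_fixture("TOY_LIN")
        with pytest.raises(ModelError):
            producing_flux_coefficients(model, "ghost")
        model.metabolite("A").boundary = True
        with pytest.raises(ModelError, match="boundary"):
            producing_flux_coefficients(model, "A")


class TestMFM:
    def test_branch_essentiality_pattern(self):
        """With exB pinned to >= 9.5, both A and B must carry 9.5 units of
        producing flux while C is dispensable."""
        model, scen = make_fixture("TOY_BRANCH")
        report = mfm(model, scen, fraction=0.95)
        assert report["C"] == pytest.approx(0.0, abs=1e-9)
        assert report["B"] == pytest.approx(9.5, abs=1e-9)
        assert report["A"] == pytest.approx(9.5, abs=1e-9)
        assert not report.is_essential("C")
        assert report.is_essential("A")

    def test_full_flux_at_gamma_one(self):
        model, scen = make_fixture("TOY_LIN")
        report = mfm(model, scen, fraction=1.0)
        assert report["A"] == pytest.approx(10.0, abs=1e-9)
        assert report["B"] == pytest.approx(10.0, abs=1e-9)

    def test_fraction_validation(self):
        model, scen = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="fraction"):
            mfm(model, scen, fraction=0.0)

    def test_matches_cold_oracle_on_fixtures_and_random_models(self, random_models):
        for model, scen in [make_fixture(n) for n in FIXTURES] + random_models:
            mine = mfm(model, scen, fraction=0.95, reduce=False)
            ref = oracle_mfm(model, scen, fraction=0.95)
            for mid, val in ref.items():
                assert mine[mid] == pytest.approx(val, abs=1e-6), (model.name, mid)

    def test_relaxing_gamma_never_increases_minimal_flux(self):
        """The γ-constrained feasible set grows as γ drops, so every
        metabolite's minimum is non-increasing and the non-essential count
        non-decreasing (1.0 -> 0.95 -> 0.10)."""
        for name in ("TOY_BRANCH", "TOY_LIN", "PREPHENATE_BRANCH"):
            model, scen = make_fixture(name)
            reports = [mfm(model, scen, fraction=g) for g in (1.0, 0.95, 0.10)]
            for tight, loose in zip(reports, reports[1:]):
                for mid in tight.minimal_flux:
                    assert loose[mid] <= tight[mid] + 1e-9
                n_tight = len(essential_partition(tight)[1])
                n_loose = len(essential_partition(loose)[1])
                assert n_loose >= n_tight

    def test_metabolite_subset(self):
        model, scen = make_fixture("TOY_BRANCH")
        report = mfm(model, scen, metabolites=["C"])
        assert set(report.minimal_flux) == {"C"}


class TestEssentialPartition:
    def test_branch_partition(self):
        model, scen = make_fixture("TOY_BRANCH")
        essential, non_essential = essential_partition(mfm(model, scen, 0.95))
        assert non_essential == ["C"]
        assert essential == ["A", "B"]

    def test_all_zero_report(self):
        report = MetaboliteFluxReport({"a": 0.0, "b": 0.0}, 0.95)
        essential, non_essential = essential_partition(report)
        assert essential == [] and non_essential == ["a", "b"]

    def test_threshold_semantics(self):
        report = MetaboliteFluxReport({"a": 0.5, "b": 2.0}, 0.95)
        essential, non_essential = essential_partition(report, tolerance=5.0)
        assert essential == [] and set(non_essential) == {"a", "b"}


class TestRanking:
    def test_descending_with_lexicographic_ties(self):
        model, scen = make_fixture("TOY_BRANCH")
        ranked = rank_metabolites(mfm(model, scen, 0.95))
        assert [m for m, _ in ranked] == ["A", "B", "C"]
        assert ranked[0][1] == pytest.approx(9.5)

    def test_empty_report(self):
        assert rank_metabolites(MetaboliteFluxReport({}, 0.95)) == []

    def test_all_equal_values_sorted_by_id(self):
        report = MetaboliteFluxReport({"z": 1.0, "a": 1.0, "m": 1.0}, 0.95)
        assert [m for m, _ in rank_metabolites(report)] == ["a", "m", "z"]


class TestSplitRatios:
    def test_branch_percentages(self):
        model, _ = make_fixture("TOY_BRANCH")
        v = FluxDistribution({"upt": 10.0, "r1": 6.0, "r2": 4.0, "exB": 6.0, "exC": 4.0})
        table = split_ratios(model, v)
        a = table["A"]
        assert a.turnover == pytest.approx(10.0)
        assert dict((r, p) for r, _, p in a.consumers) == pytest.approx(
            {"r1": 60.0, "r2": 40.0}
        )
        assert a.producers == [("upt", 10.0, 100.0)]

    def test_linear_chain_all_hundred_percent(self):
        model, scen = make_fixture("TOY_LIN")
        table = split_ratios(model, fba(model, scen))
        for mid in ("A", "B"):
            split = table[mid]
            assert split.turnover == pytest.approx(10.0)
            assert [p for _, _, p in split.producers] == [pytest.approx(100.0)]
            assert [p for _, _, p in split.consumers] == [pytest.approx(100.0)]

    def test_prephenate_branch_eight_ninety_two(self):
        """The engineered aromatic branch point: 8% of prephenate continues
        towards phenylalanine, 92% feeds the antibiotic sink."""
        model, scen = make_fixture("PREPHENATE_BRANCH")
        table = split_ratios(model, fba(model, scen))
        pre = table["prephenate"]
        assert pre.turnover == pytest.approx(0.72, abs=1e-9)
        pct = {r: p for r, _, p in pre.consumers}
        assert pct["pdt"] == pytest.approx(8.0, abs=1e-6)
        assert pct["tda_syn"] == pytest.approx(92.0, abs=1e-6)

    def test_conservation_and_percent_sums(self, random_models):
        """Steady state: producer totals equal consumer totals and each
        side's percentages sum to 100 whenever turnover is nonzero."""
        cases = [make_fixture(n) for n in FIXTURES] + random_models[:5]
        for model, scen in cases:
            sol = fba(model, scen)
            if sol.status != "optimal":
                continue
            table = split_ratios(model, sol)
            for mid, split in table.entries.items():
                produced = sum(f for _, f, _ in split.producers)
                consumed = sum(f for _, f, _ in split.consumers)
                assert produced == pytest.approx(consumed, abs=1e-6), (model.name, mid)
                if split.turnover > 1e-9:
                    assert sum(p for _, _, p in split.producers) == pytest.approx(100.0, abs=1e-6)
                    assert sum(p for _, _, p in split.consumers) == pytest.approx(100.0, abs=1e-6)

    def test_reversible_contributes_by_net_sign(self):
        model, _ = make_fixture("TOY_REV")
        backward = FluxDistribution({"upt": 0.0, "iso": 0.0, "bio": 0.0})
        table = split_ratios(model, backward)
        assert table["A"].producers == [] and table["A"].consumers == []

    def test_steady_state_violation_rejected(self):
        model, _ = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="steady state"):
            split_ratios(model, FluxDistribution({"upt": 10.0, "conv": 0.0, "bio": 0.0}))


class TestGraphExport:
    def _branch_graph(self):
        model, scen = make_fixture("TOY_BRANCH")
        sol = fba(model, scen)
        return model, sol, split_ratios(model, sol)

    def test_node_counts_and_classes(self):
        model, scen = make_fixture("TOY_LIN")
        sol = fba(model, scen)
        G = build_bipartite_graph(model, sol, split_ratios(model, sol))
        kinds = [d["kind"] for _, d in G.nodes(data=True)]
        assert kinds.count("metabolite") == 2 and kinds.count("reaction") == 3
        assert all(d["active"] for _, d in G.nodes(data=True))

    def test_inactive_subgraph_flagged(self):
        model, sol, ratios = self._branch_graph()
        G = build_bipartite_graph(model, sol, ratios)
        assert not G.nodes["rxn:r2"]["active"]
        assert not G.nodes["met:C"]["active"]
        assert G.nodes["rxn:r1"]["active"]

    def test_dot_output_parses_back(self):
        import re

        model, sol, ratios = self._branch_graph()
        text = export_bipartite_graph(model, sol, ratios, format="dot")
        assert text.startswith("digraph")
        nodes = re.findall(r'^\s+"[^"]+" \[', text, flags=re.M)
        edges = re.findall(r'^\s+"[^"]+" -> "[^"]+"', text, flags=re.M)
        assert len(nodes) == len(model.metabolites) + len(model.reactions)
        assert len(edges) == sum(len(r.stoichiometry) for r in model.reactions)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        model, sol, ratios = self._branch_graph()
        path = tmp_path / "net.graphml"
        export_bipartite_graph(model, sol, ratios, format="graphml", path=str(path))
        H = nx.read_graphml(path)
        assert len(H) == len(model.metabolites) + len(model.reactions)

    def test_unknown_format_rejected(self):
        model, sol, ratios = self._branch_graph()
        with pytest.raises(ModelError, match="unknown graph format"):
            export_bipartite_graph(model, sol, ratios, format="svg")


class TestCondenseLinearChains:
    def test_linear_chain_collapses_to_single_edge(self):
        model, scen = make_fixture("TOY_LIN")
        sol = fba(model, scen)
        G = build_bipartite_graph(model, sol, split_ratios(model, sol))
        H = condense_linear_chains(G)
        assert set(H.nodes) == {"rxn:upt", "rxn:bio"}
        assert H.get_edge_data("rxn:upt", "rxn:bio")["condensed"]

    def test_branch_point_preserved(self):
        model, scen = make_fixture("TOY_BRANCH")
        sol = fba(model, scen)
        G = build_bipartite_graph(model, sol, split_ratios(model, sol))
        H = condense_linear_chains(G)
        assert "met:A" in H.nodes  # degree-3 branch metabolite survives

    def test_no_interior_degree_two_nodes_is_identity(self):
        import networkx as nx

        G = nx.DiGraph()
        G.add_edge("a", "b")
        G.add_edge("a", "c")
        H = condense_linear_chains(G)
        assert set(H.edges) == set(G.edges)
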