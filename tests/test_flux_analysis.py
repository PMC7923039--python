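"""FBA, warm-started FVA, MOMA, knockout scan, batch FBA and comparisons,
validated against cold-start brute-force oracles."""

import numpy as np
import pytest

from fluxnode import (
    ModelError,
    Scenario,
    batch_fba,
    compare_fluxes,
    fba,
    fva,
    knockout_scan,
    make_fixture,
    moma,
)
from oracles import compare_ranges, oracle_fva, oracle_moma

FIXTURES = ("TOY_LIN", "TOY_BRANCH", "TOY_YIELD", "TOY_DEAD", "TOY_REV",
            "PREPHENATE_BRANCH")


class TestFBA:
    @pytest.mark.parametrize(
        "name, expected",
        [("TOY_LIN", 10.0), ("TOY_YIELD", 5.0), ("TOY_DEAD", 0.0),
         ("TOY_BRANCH", 10.0), ("TOY_REV", 10.0), ("PREPHENATE_BRANCH", 0.6624)],
    )
    def test_fixture_optima(self, name, expected):
        model, scen = make_fixture(name)
        sol = fba(model, scen)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(expected, abs=1e-6)

    def test_missing_objective_rejected(self):
        model, _ = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="no objective"):
            fba(model, Scenario())

    def test_infeasible_scenario_reported(self):
        model, scen = make_fixture("TOY_LIN")
        scen.lower_bound["bio"] = 20.0  # demands more than the uptake allows
        assert fba(model, scen).status == "infeasible"

    def test_objective_invariant_under_reaction_reordering(self):
        model, scen = make_fixture("TOY_BRANCH")
        from fluxnode import MetabolicModel

        reordered = MetabolicModel(
            [m for m in model.metabolites], list(reversed(model.reactions)),
        )
        assert fba(reordered, scen).objective_value == pytest.approx(
            fba(model, scen).objective_value, abs=1e-9
        )


class TestFVA:
    def test_branch_fully_constrained_at_gamma_one(self):
        model, scen = make_fixture("TOY_BRANCH")
        var = fva(model, scen, fraction=1.0)
        assert var["r2"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_branch_slack_at_gamma_095(self):
        model, scen = make_fixture("TOY_BRANCH")
        var = fva(model, scen, fraction=0.95)
        assert var["r2"] == pytest.approx((0.0, 0.5), abs=1e-9)
        assert var["exB"] == pytest.approx((9.5, 10.0), abs=1e-9)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_fraction_out_of_range(self, fraction):
        model, scen = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="fraction"):
            fva(model, scen, fraction=fraction)

    def test_warm_start_matches_cold_oracle_on_fixtures(self):
        for name in FIXTURES:
            model, scen = make_fixture(name)
            mine = fva(model, scen, fraction=0.95, reduce=False)
            ref = oracle_fva(model, scen, fraction=0.95)
            assert compare_ranges(mine.ranges, ref) <= 1e-6, name

    def test_fba_flux_lies_within_ranges_and_gamma_monotonicity(self):
        model, scen = make_fixture("TOY_BRANCH")
        loose = fva(model, scen, fraction=0.95)
        tight = fva(model, scen, fraction=1.0)
        constrained = fba(model, scen)
        for rid in model.reaction_ids:
            lo95, hi95 = loose[rid]
            lo100, hi100 = tight[rid]
            assert lo95 - 1e-9 <= lo100 and hi100 <= hi95 + 1e-9
            assert lo100 - 1e-9 <= constrained[rid] <= hi100 + 1e-9

    def test_reaction_subset(self):
        model, scen = make_fixture("TOY_BRANCH")
        var = fva(model, scen, fraction=0.95, reactions=["r2"])
        assert set(var.ranges) == {"r2"}


class TestMOMA:
    def test_identity_perturbation_returns_wildtype(self):
        model, scen = make_fixture("TOY_BRANCH")
        wt = fba(model, scen)
        sol = moma(model, scen, wt)
        assert sol.status == "optimal"
        assert sol.objective_value <= 1e-9  # squared distance

    def test_knockout_matches_closed_form(self):
        """KO of r1 forces exB = 0; the closest feasible state routes
        u = upt = r2 = exC with min (u-10)^2 + 2u^2 + 200, i.e. u = 10/3
        and squared distance 800/3."""
        model, scen = make_fixture("TOY_BRANCH")
        wt = fba(model, scen)
        sol = moma(model, scen.with_knockout("r1"), wt)
        u = 10.0 / 3.0
        expected = {"upt": u, "r1": 0.0, "r2": u, "exB": 0.0, "exC": u}
        for rid, val in expected.items():
            assert sol[rid] == pytest.approx(val, abs=1e-5), rid
        assert sol.objective_value == pytest.approx(800.0 / 3.0, abs=1e-5)

    def test_matches_independent_qp_oracle(self):
        model, scen = make_fixture("TOY_BRANCH")
        wt = fba(model, scen)
        sol = moma(model, scen.with_knockout("r1"), wt)
        x_ref, d_ref = oracle_moma(model, scen.with_knockout("r1"), wt.fluxes)
        assert sol.objective_value == pytest.approx(d_ref, abs=1e-6)

    def test_fva_reduction_does_not_change_the_optimum(self, random_models):
        cases = [make_fixture(n) for n in FIXTURES]
        for model, scen in cases + random_models[:5]:
            wt = fba(model, scen)
            if wt.status != "optimal":
                continue
            ko = scen.with_knockout(model.reaction_ids[1])
            plain = moma(model, ko, wt)
            reduced = moma(model, ko, wt, fva_reduce=True)
            assert plain.status == reduced.status
            if plain.status == "optimal":
                assert plain.objective_value == pytest.approx(
                    reduced.objective_value, abs=1e-6
                )

    def test_incomplete_wildtype_rejected(self):
        model, scen = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="misses"):
            moma(model, scen, {"upt": 10.0})

    def test_distance_zero_iff_wildtype_feasible(self):
        model, scen = make_fixture("TOY_BRANCH")
        wt = fba(model, scen)
        tightened = scen.copy()
        tightened.upper_bound["upt"] = 8.0  # wild type (upt=10) now infeasible
        sol = moma(model, tightened, wt)
        assert sol.objective_value > 1e-3


class TestKnockoutScan:
    def test_fba_scan_on_branch(self):
        model, scen = make_fixture("TOY_BRANCH")
        table = knockout_scan(model, scen, ["r1", "r2", "upt"], method="fba")
        assert table.loc["r1", "objective_value"] == pytest.approx(0.0, abs=1e-9)
        assert table.loc["r2", "objective_value"] == pytest.approx(10.0, abs=1e-9)
        assert table.loc["upt", "objective_value"] == pytest.approx(0.0, abs=1e-9)

    def test_knockout_of_blocked_reaction_is_neutral(self):
        model, scen = make_fixture("TOY_DEAD")
        base = fba(model, scen).objective_value
        table = knockout_scan(model, scen, ["conv"], method="fba")
        assert table.loc["conv", "objective_value"] == pytest.approx(base, abs=1e-9)

    def test_moma_scan_reports_objective_flux(self):
        model, scen = make_fixture("TOY_BRANCH")
        table = knockout_scan(model, scen, ["r1"], method="moma")
        assert table.loc["r1", "objective_value"] == pytest.approx(0.0, abs=1e-5)

    def test_unknown_reaction_rejected(self):
        model, scen = make_fixture("TOY_LIN")
        with pytest.raises(ModelError, match="unknown reaction"):
            knockout_scan(model, scen, ["ghost"])

    def test_original_scenario_untouched(self):
        model, scen = make_fixture("TOY_BRANCH")
        before = (dict(scen.lower_bound), dict(scen.upper_bound))
        knockout_scan(model, scen, ["r1"])
        assert (scen.lower_bound, scen.upper_bound) == before


class TestBatchFBA:
    def test_independent_scenarios(self):
        model, scen = make_fixture("TOY_LIN")
        low = scen.copy()
        low.upper_bound["upt"] = 4.0
        table = batch_fba(model, [scen, low])
        assert list(table["objective"]) == pytest.approx([10.0, 4.0])

    def test_failing_row_does_not_abort(self):
        model, scen = make_fixture("TOY_LIN")
        bad = scen.copy()
        bad.lower_bound["bio"] = 99.0
        table = batch_fba(model, [scen, bad, scen])
        assert list(table["status"]) == ["optimal", "infeasible", "optimal"]
        assert table["objective"].iloc[0] == pytest.approx(10.0)

    def test_empty_batch(self):
        model, _ = make_fixture("TOY_LIN")
        assert len(batch_fba(model, [])) == 0


class TestCompareFluxes:
    def test_identity_has_no_differences(self):
        model, scen = make_fixture("TOY_BRANCH")
        sol = fba(model, scen)
        assert compare_fluxes(sol, sol).n_differing == 0

    def test_single_difference_detected(self):
        a = {"r1": 1.0, "r2": 2.0}
        b = {"r1": 1.0, "r2": 4.0}
        cmp = compare_fluxes(a, b)
        assert cmp.differing == ["r2"]
        assert cmp.table.loc["r2", "difference"] == pytest.approx(2.0)

    def test_wildtype_vs_moma_differing_set(self):
        model, scen = make_fixture("TOY_BRANCH")
        wt = fba(model, scen)
        ko = moma(model, scen.with_knockout("r1"), wt)
        cmp = compare_fluxes(wt, ko, tolerance=1e-6)
        assert set(cmp.differing) == {"upt", "r1", "r2", "exB", "exC"}

    def test_mismatched_reaction_sets_rejected(self):
        with pytest.raises(ModelError, match="different reaction sets"):
            compare_fluxes({"a": 1.0}, {"b": 1.0})
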