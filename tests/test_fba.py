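"""LP engine: FBA, uptake minimisation, NGAM calibration, virtual carbon, FVA."""

import numpy as np
import pandas as pd
import pytest

from _oracles import fva_by_vertex_enumeration
from ptsflux.fba import (
    LPError,
    MetabolicNetwork,
    NetworkError,
    Reaction,
    add_virtual_carbon,
    calibrate_ngam,
    fva,
    fva_relative_range,
    minimize_substrate_uptake,
    parse_reaction_equation,
    read_network_tsv,
    solve_fba,
    write_network_tsv,
)


def chain_network(uptake_bound=10.0):
    """uptake -> A -> B -> biomass, one-to-one stoichiometry."""
    return MetabolicNetwork([
        Reaction("EX_A", {"A": 1.0}, 0.0, uptake_bound),
        Reaction("A_to_B", {"A": -1.0, "B": 1.0}, 0.0, 1e6),
        Reaction("biomass", {"B": -1.0}, 0.0, 1e6),
    ], biomass_id="biomass")


def atp_network():
    """Substrate yields biomass (10 S each) or ATP (2 per S); NGAM burns ATP.

    Minimal uptake at growth mu with maintenance m is 10 mu + m / 2, an
    affine function with known coefficients.
    """
    return MetabolicNetwork([
        Reaction("EX_S", {"S": 1.0}, 0.0, 1e6),
        Reaction("to_bm", {"S": -10.0, "bm": 1.0}, 0.0, 1e6),
        Reaction("biomass", {"bm": -1.0}, 0.0, 1e6),
        Reaction("S_to_atp", {"S": -1.0, "atp": 2.0}, 0.0, 1e6),
        Reaction("ngam", {"atp": -1.0}, 0.0, 1e6),
    ], biomass_id="biomass", ngam_id="ngam")


class TestParsing:
    @pytest.mark.parametrize("eq,stoich,rev", [
        ("2 A + B -> C", {"A": -2.0, "B": -1.0, "C": 1.0}, False),
        ("A <-> B", {"A": -1.0, "B": 1.0}, True),
        ("-> X", {"X": 1.0}, False),
        ("1.5 A -> 0.5 B + C", {"A": -1.5, "B": 0.5, "C": 1.0}, False),
    ])
    def test_equations(self, eq, stoich, rev):
        got, reversible = parse_reaction_equation(eq)
        assert got == stoich and reversible == rev

    def test_bad_equation(self):
        with pytest.raises(NetworkError):
            parse_reaction_equation("A + B = C")

    def test_bounds_must_be_ordered(self):
        with pytest.raises(NetworkError):
            Reaction("r", {"A": 1.0}, 1.0, 0.0)


class TestSolveFba:
    def test_two_metabolite_node_is_forced_by_balances(self):
        # input ra into Pyr, drain rb, conversion rc Pyr -> PEP, drain rd;
        # fixing ra and rd forces rc = rd and rb = ra - rc by hand algebra
        net = MetabolicNetwork([
            Reaction("ra", {"Pyr": 1.0}, 5.0, 5.0),
            Reaction("rb", {"Pyr": -1.0}, 0.0, 1e6),
            Reaction("rc", {"Pyr": -1.0, "PEP": 1.0}, 0.0, 1e6),
            Reaction("rd", {"PEP": -1.0}, 2.0, 2.0),
        ])
        sol = solve_fba(net, "rb", "max")
        assert sol.ok
        assert sol["rc"] == pytest.approx(2.0, abs=1e-9)
        assert sol["rb"] == pytest.approx(3.0, abs=1e-9)

    def test_linear_chain_growth_equals_uptake_bound(self):
        sol = solve_fba(chain_network(10.0), "biomass", "max")
        assert sol.ok and sol.objective == pytest.approx(10.0)

    def test_mass_balance_and_bounds_hold(self, toy_network):
        sol = solve_fba(toy_network, "biomass", "max")
        S, _, rids = toy_network.stoichiometric_matrix()
        assert np.max(np.abs(S @ sol.fluxes.to_numpy())) < 1e-9
        for r in toy_network.reactions:
            assert r.lb - 1e-9 <= sol[r.id] <= r.ub + 1e-9

    def test_infeasible_demand_is_reported_not_zeroed(self):
        net = chain_network(1.0).with_bounds("biomass", 5.0, 5.0)
        sol = solve_fba(net, "EX_A", "min")
        assert sol.status == "infeasible"
        assert np.isnan(sol.objective)


class TestUptakeMinimisation:
    def test_minimal_uptake_follows_the_yield(self):
        # 10 substrate per biomass: growth 0.2 -> uptake 2.0
        sol = minimize_substrate_uptake(atp_network(), 0.2, "EX_S")
        assert sol.ok and sol.objective == pytest.approx(2.0, abs=1e-9)

    def test_zero_growth_zero_maintenance_needs_nothing(self):
        sol = minimize_substrate_uptake(atp_network(), 0.0, "EX_S")
        assert sol.objective == pytest.approx(0.0, abs=1e-9)

    def test_zero_growth_with_maintenance_needs_ngam_over_yield(self):
        net = atp_network().set_ngam(3.0)
        sol = minimize_substrate_uptake(net, 0.0, "EX_S")
        assert sol.objective == pytest.approx(3.0 / 2.0, abs=1e-9)


class TestNgamCalibration:
    def test_affine_inverse_is_recovered(self):
        # uptake(m) = 10 mu + m/2  =>  m = 2 (uptake - 10 mu)
        net, mu, target = atp_network(), 0.3, 4.4
        m = calibrate_ngam(net, mu, target, "EX_S")
        assert m == pytest.approx(2 * (target - 10 * mu), rel=1e-5)
        check = minimize_substrate_uptake(net.set_ngam(m), mu, "EX_S")
        assert check.objective == pytest.approx(target, rel=1e-6)

    def test_measured_minimum_gives_zero_maintenance(self):
        assert calibrate_ngam(atp_network(), 0.2, 2.0, "EX_S") == 0.0

    def test_unreachable_target_raises(self):
        with pytest.raises(NetworkError, match="below"):
            calibrate_ngam(atp_network(), 0.2, 1.0, "EX_S")

    def test_monotone_in_measured_uptake(self):
        net = atp_network()
        values = [calibrate_ngam(net, 0.2, u, "EX_S") for u in (2.5, 3.0, 4.0)]
        assert values == sorted(values)
        assert values[0] < values[-1]


class TestVirtualCarbon:
    def base_net(self):
        return MetabolicNetwork([
            Reaction("gly_drain", {"gly": -1.0}, 1.0, 1.0),
            Reaction("ala_drain", {"ala": -1.0}, 2.0, 2.0),
        ])

    def test_carbon_count_stoichiometry(self):
        net = add_virtual_carbon(self.base_net(), {"gly": 2, "ala": 3})
        assert net.reaction("carbon_to_gly").stoich == {"carbon": -2.0, "gly": 1.0}
        assert net.reaction("carbon_to_ala").stoich == {"carbon": -3.0, "ala": 1.0}

    def test_minimised_carbon_equals_demand_times_counts(self):
        net = add_virtual_carbon(self.base_net(), {"gly": 2, "ala": 3})
        sol = solve_fba(net, "EX_carbon", "min")
        # demands: 1 gly (2 C) + 2 ala (3 C each) = 8 carbon
        assert sol.ok and sol.objective == pytest.approx(8.0, abs=1e-9)

    def test_absent_amino_acid_is_named(self):
        with pytest.raises(NetworkError, match="trp"):
            add_virtual_carbon(self.base_net(), {"trp": 11})

    def test_counts_must_be_positive_integers(self):
        with pytest.raises(NetworkError):
            add_virtual_carbon(self.base_net(), {"gly": 2.5})


class TestFva:
    def redundant_network(self):
        """Two parallel routes A -> B: the classic alternate-optima case."""
        return MetabolicNetwork([
            Reaction("EX_A", {"A": 1.0}, 4.0, 4.0),
            Reaction("path1", {"A": -1.0, "B": 1.0}, 0.0, 3.0),
            Reaction("path2", {"A": -1.0, "B": 1.0}, 0.0, 3.0),
            Reaction("biomass", {"B": -1.0}, 0.0, 1e6),
        ], biomass_id="biomass")

    def test_matches_vertex_enumeration_oracle(self):
        net = self.redundant_network()
        res = fva(net, "biomass", sense="max")
        lo, hi, rids = fva_by_vertex_enumeration(net, "biomass", 4.0)
        table = res.table.set_index("reaction")
        for j, rid in enumerate(rids):
            assert table.loc[rid, "min"] == pytest.approx(lo[j], abs=1e-6)
            assert table.loc[rid, "max"] == pytest.approx(hi[j], abs=1e-6)
        # the redundancy is spanned: each path ranges over [1, 3]
        assert table.loc["path1", "min"] == pytest.approx(1.0, abs=1e-6)
        assert table.loc["path1", "max"] == pytest.approx(3.0, abs=1e-6)

    def test_forced_reaction_has_degenerate_range(self):
        net = self.redundant_network()
        res = fva(net, "biomass", sense="max").table.set_index("reaction")
        assert res.loc["EX_A", "min"] == pytest.approx(res.loc["EX_A", "max"],
                                                       abs=1e-8)

    def test_sandwich_holds_for_every_reaction(self, toy_network):
        net = toy_network.with_bounds("biomass", 0.5, 0.5)
        res = fva(net, "EX_caa", sense="min")
        t = res.table
        assert ((t["min"] <= t["nominal"] + 1e-7)
                & (t["nominal"] <= t["max"] + 1e-7)).all()

    def test_objective_stays_at_optimum_at_the_extremes(self):
        net = self.redundant_network()
        res = fva(net, "biomass", sense="max")
        t = res.table.set_index("reaction")
        assert t.loc["biomass", "min"] == pytest.approx(4.0, abs=1e-7)
        assert t.loc["biomass", "max"] == pytest.approx(4.0, abs=1e-7)


class TestRelativeRange:
    @pytest.mark.parametrize("triple,expected", [
        ((6.32, 6.18, 6.35), 2.7),
        ((1.83, 1.68, 1.85), 9.3),
        ((4.00, 3.96, 4.01), 1.3),   # 1.25 rounds up, not to even
        ((3.73, 3.68, 3.78), 2.7),
        ((4.69, 4.59, 4.71), 2.6),
        ((1.47, 1.36, 1.49), 8.8),
        ((2.93, 2.90, 2.97), 2.4),
        ((2.64, 2.61, 2.68), 2.7),
    ])
    def test_printed_summary_values(self, triple, expected):
        nominal, vmin, vmax = triple
        assert fva_relative_range(nominal, vmin, vmax) == expected

    def test_degenerate_range_is_zero(self):
        assert fva_relative_range(1.7, 1.7, 1.7) == 0.0

    def test_zero_nominal_is_flagged(self):
        with pytest.raises(ZeroDivisionError):
            fva_relative_range(0.0, -1.0, 1.0)


class TestNetworkIO:
    def test_tsv_round_trip(self, toy_network, tmp_path):
        path = tmp_path / "net.tsv"
        write_network_tsv(toy_network, path)
        back = read_network_tsv(path)
        assert back.reaction_ids == toy_network.reaction_ids
        assert back.biomass_id == toy_network.biomass_id
        assert back.ngam_id == toy_network.ngam_id
        for r in toy_network.reactions:
            b = back.reaction(r.id)
            assert b.stoich == r.stoich
            assert (b.lb, b.ub) == (r.lb, r.ub)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tequation\tlb\tub\nr1\tA = B\t0\t1\n")
        with pytest.raises(NetworkError, match="line 2"):
            read_network_tsv(path)


class TestSbmlImport:
    def test_round_trip_through_sbml(self, tmp_path):
        cobra = pytest.importorskip("cobra")
        model = cobra.Model("tiny")
        a = cobra.Metabolite("A", compartment="c")
        b = cobra.Metabolite("B", compartment="c")
        ex = cobra.Reaction("EX_A", lower_bound=0.0, upper_bound=10.0)
        ex.add_metabolites({a: 1.0})
        conv = cobra.Reaction("A_to_B", lower_bound=0.0, upper_bound=1000.0)
        conv.add_metabolites({a: -1.0, b: 1.0})
        growth = cobra.Reaction("biomass", lower_bound=0.0, upper_bound=1000.0)
        growth.add_metabolites({b: -1.0})
        model.add_reactions([ex, conv, growth])
        model.objective = "biomass"
        path = tmp_path / "tiny.xml"
        cobra.io.write_sbml_model(model, str(path))

        from ptsflux.fba import read_network_sbml
        net = read_network_sbml(path)
        assert set(net.reaction_ids) == {"EX_A", "A_to_B", "biomass"}
        assert net.biomass_id == "biomass"
        sol = solve_fba(net, "biomass", "max")
        assert sol.ok and sol.objective == pytest.approx(10.0)
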