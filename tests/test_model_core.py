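"""model_core: I/O round trips, GPR semantics, FBA/FVA/knockout contracts."""

from __future__ import annotations

import itertools
import json

import numpy as np
import pytest

from slscreen.errors import ConfigurationError, ModelParseError
from slscreen.model_core import (
    MetabolicNetwork,
    evaluate_gpr,
    fba_optimize,
    fva,
    gpr_canonical,
    knockout_growth,
    parse_gpr,
    read_model,
    write_model,
)
from slscreen.synth_data import PathSpec, PrecursorSpec, ToyNetworkSpec, make_toy_network

from conftest import linprog_fba

CHAIN_JSON = {
    "metabolites": ["X_c", "Y_c"],
    "reactions": [
        {"id": "EX_in", "stoich": {"X_c": 1.0}, "lb": 0.0, "ub": 10.0, "gpr": ""},
        {"id": "R1", "stoich": {"X_c": -1.0, "Y_c": 1.0}, "lb": 0.0, "ub": 1000.0, "gpr": "g1"},
        {"id": "BIOMASS", "stoich": {"Y_c": -1.0}, "lb": 0.0, "ub": 1000.0, "gpr": ""},
    ],
    "genes": ["g1"],
    "objective": "BIOMASS",
}


@pytest.fixture()
def chain_path(tmp_path):
    path = tmp_path / "chain.json"
    path.write_text(json.dumps(CHAIN_JSON))
    return path


class TestReadModel:
    def test_json_fixture_loads(self, chain_path):
        network = read_model(chain_path)
        assert len(network.reaction_ids) == 3
        assert network.objective_reaction == "BIOMASS"
        assert network.gene_ids == ["g1"]

    def test_missing_objective_is_configuration_error(self, tmp_path):
        doc = {k: v for k, v in CHAIN_JSON.items() if k != "objective"}
        path = tmp_path / "noobj.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ConfigurationError):
            read_model(path)

    def test_malformed_json_names_element(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"][1]["stoich"] = {"MISSING_c": 1.0}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelParseError, match="MISSING_c"):
            read_model(path)

    def test_sbml_without_fbc_is_parse_error(self, tmp_path):
        plain_sbml = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="m">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="X_c" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false" fast="false">
        <listOfProducts><speciesReference species="X_c" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        path = tmp_path / "plain.xml"
        path.write_text(plain_sbml)
        with pytest.raises(ModelParseError, match="FBC"):
            read_model(path)

    def test_inconsistent_bounds_rejected(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"][0]["lb"] = 5.0
        doc["reactions"][0]["ub"] = -5.0
        path = tmp_path / "flipped.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ConfigurationError, match="bound"):
            read_model(path)


@pytest.mark.parametrize("dialect,suffix", [("json", ".json"), ("sbml", ".xml")])
def test_round_trip_preserves_model(tmp_path, dialect, suffix):
    """Stoichiometry, bounds and GPR semantics survive write → read."""
    spec = ToyNetworkSpec(
        precursors=(
            PrecursorSpec("A", (PathSpec(5.0, ("g1", "g2")), PathSpec(3.0, ("g3",)))),
            PrecursorSpec("B", (PathSpec(4.0, ("g2",)),)),
        ),
        core_genes=("g0",),
    )
    network, _ = make_toy_network(spec)
    path = tmp_path / f"model{suffix}"
    write_model(network, path, dialect)
    back = read_model(path, dialect)
    assert back.metabolite_ids == network.metabolite_ids
    assert set(back.reaction_ids) == set(network.reaction_ids)
    for rid in network.reaction_ids:
        orig, new = network.reaction(rid), back.reaction(rid)
        assert new.bounds == pytest.approx(orig.bounds)
        assert {m.id: c for m, c in new.metabolites.items()} == {
            m.id: c for m, c in orig.metabolites.items()
        }
        assert gpr_canonical(new.gpr) == gpr_canonical(orig.gpr)
    assert back.objective_reaction == network.objective_reaction


class TestGPR:
    def test_grammar_and_precedence(self):
        tree = gpr_canonical(parse_gpr("gA and (gB or gC)"))
        assert tree == ("and", frozenset({"gA", ("or", frozenset({"gB", "gC"}))}))
        # AND binds tighter than OR
        loose = gpr_canonical(parse_gpr("gA and gB or gC"))
        assert loose == ("or", frozenset({("and", frozenset({"gA", "gB"})), "gC"}))

    @pytest.mark.parametrize(
        "rule,deleted,expected",
        [
            ("gA and gB", {"gA"}, False),
            ("gA or gB", {"gA"}, True),
            ("", {"gA", "gB"}, True),
        ],
    )
    def test_boolean_identities(self, rule, deleted, expected):
        assert evaluate_gpr(rule, deleted) is expected

    @pytest.mark.parametrize(
        "rule",
        [
            "a and b",
            "a or b or c",
            "(a or b) and (c or d)",
            "a and (b or (c and d)) or e",
            "(a and b) or (b and c) or (d and e)",
        ],
    )
    def test_matches_exhaustive_truth_table(self, rule):
        """GPR evaluation agrees with direct boolean evaluation for every
        deletion pattern over ≤ 5 genes."""
        genes = sorted(set(rule.replace("(", " ").replace(")", " ").split()) - {"and", "or"})
        parsed = parse_gpr(rule)
        for pattern in itertools.product([False, True], repeat=len(genes)):
            deleted = {g for g, dead in zip(genes, pattern) if dead}
            env = {g: g not in deleted for g in genes}
            assert evaluate_gpr(parsed, deleted) == eval(rule, {}, env)


class TestFBA:
    def test_bound_limited_chain(self, chain_path):
        state = fba_optimize(read_model(chain_path))
        assert state.is_optimal
        assert state.objective_value == pytest.approx(10.0, abs=1e-6)
        assert state.fluxes["BIOMASS"] == pytest.approx(state.objective_value, abs=1e-6)

    def test_no_input_no_growth(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"][0]["ub"] = 0.0
        path = tmp_path / "closed.json"
        path.write_text(json.dumps(doc))
        state = fba_optimize(read_model(path))
        assert state.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_two_parallel_paths(self, two_path_network):
        # hand LP: both 5-unit paths saturate, biomass = 10
        state = fba_optimize(two_path_network)
        assert state.objective_value == pytest.approx(10.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_linprog(self, seed):
        """cobra's optimum equals a scipy-HiGHS LP built from raw S, bounds."""
        from slscreen.synth_data import random_toy_spec

        network, _ = make_toy_network(random_toy_spec(seed))
        state = fba_optimize(network)
        assert state.objective_value == pytest.approx(linprog_fba(network), abs=1e-6)


class TestKnockout:
    def test_empty_deletion_is_wild_type(self, two_path_network):
        wt = fba_optimize(two_path_network).objective_value
        assert knockout_growth(two_path_network, set()) == pytest.approx(wt, abs=1e-9)

    def test_blocking_only_biomass_route(self, chain_path):
        network = read_model(chain_path)
        assert knockout_growth(network, {"g1"}) == pytest.approx(0.0, abs=1e-9)

    def test_single_path_deletion(self, two_path_network):
        assert knockout_growth(two_path_network, {"g1"}) == pytest.approx(5.0, abs=1e-6)

    def test_unknown_gene_warns_and_is_noop(self, two_path_network):
        wt = fba_optimize(two_path_network).objective_value
        with pytest.warns(UserWarning, match="absent"):
            growth = knockout_growth(two_path_network, {"not_a_gene"})
        assert growth == pytest.approx(wt, abs=1e-9)

    def test_monotone_restriction(self, demo_bundle):
        """Deleting more genes never increases the optimum (A ⊆ B ⇒ g(B) ≤ g(A))."""
        network = demo_bundle.network
        rng = np.random.default_rng(0)
        genes = network.gene_ids
        for _ in range(25):
            a = set(rng.choice(genes, size=rng.integers(0, 4), replace=False))
            extra = set(rng.choice(genes, size=rng.integers(1, 3), replace=False))
            b = a | extra
            assert knockout_growth(network, b) <= knockout_growth(network, a) + 1e-6


class TestFVA:
    def test_dead_end_reaction_is_blocked(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["metabolites"].append("DEAD_c")
        doc["reactions"].append(
            {"id": "R_DEAD", "stoich": {"X_c": -1.0, "DEAD_c": 1.0},
             "lb": 0.0, "ub": 100.0, "gpr": ""}
        )
        path = tmp_path / "dead.json"
        path.write_text(json.dumps(doc))
        ranges = fva(read_model(path), ["R_DEAD"], fraction_of_optimum=0.0)
        assert ranges["R_DEAD"] == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_objective_pinned_at_full_fraction(self, two_path_network):
        ranges = fva(two_path_network, ["BIOMASS"], fraction_of_optimum=1.0)
        assert ranges["BIOMASS"] == pytest.approx((10.0, 10.0), abs=1e-6)

    def test_parallel_paths_full_range(self, two_path_network):
        # hand LP: with no objective floor each path spans its capacity
        ranges = fva(two_path_network, ["P_A_1", "P_A_2"], fraction_of_optimum=0.0)
        assert ranges["P_A_1"] == pytest.approx((0.0, 5.0), abs=1e-6)
        assert ranges["P_A_2"] == pytest.approx((0.0, 5.0), abs=1e-6)
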