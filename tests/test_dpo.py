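"""Rule parsing/validation, matching, application and derivations."""

import random

import pytest

from enzmech.chemgraph import MolGraph, State, state_union
from enzmech.dpo import (
    RuleError,
    StaleMatchError,
    apply_rule,
    derive_all,
    find_matches,
    invert_rule,
    parse_rule,
    validate_rule,
    write_rule,
)
from enzmech.fixtures import fixture_molecule, fixture_rule, toy_chemistry
from oracle import count_monomorphisms

PROTON_TRANSFER = """rule [
  ruleID "pt"
  left [
    node [ id 0 label "O" ]
    node [ id 2 label "N" ]
    edge [ source 0 target 1 label "-" ]
  ]
  context [ node [ id 1 label "H" ] ]
  right [
    node [ id 0 label "O-" ]
    node [ id 2 label "N+" ]
    edge [ source 1 target 2 label "-" ]
  ]
]"""

# O1-H + O2 -> O1(-) + O2(+)-H : charge-conserving proton hop between oxygens
AUTOPROTOLYSIS = """rule [
  ruleID "auto"
  left [
    node [ id 0 label "O" ]
    node [ id 2 label "O" ]
    edge [ source 0 target 1 label "-" ]
  ]
  context [ node [ id 1 label "H" ] ]
  right [
    node [ id 0 label "O-" ]
    node [ id 2 label "O+" ]
    edge [ source 1 target 2 label "-" ]
  ]
]"""

ALL_FIXTURE_RULES = [
    "pt_o_to_n", "pt_n_to_o", "pt_o_to_o", "enolate_form",
    "nucleophilic_addition", "oxyanion_collapse", "alkoxide_addition",
    "fig1_rule",
]


class TestRuleParsing:
    def test_proton_transfer_action(self):
        p = parse_rule(PROTON_TRANSFER)
        assert len(p.bond_changes()) == 2  # one broken, one formed
        assert len(p.charge_changes()) == 2
        assert p.action_nodes() == {0, 1, 2}

    def test_atom_conservation_enforced(self):
        bad = """rule [
          ruleID "bad"
          left [ node [ id 0 label "O" ] ]
          right [ node [ id 0 label "O" ] node [ id 1 label "H" ] ]
        ]"""
        with pytest.raises(RuleError, match="conservation"):
            parse_rule(bad)

    def test_charge_imbalance_reported(self):
        bad = """rule [
          ruleID "bad"
          left [ node [ id 0 label "O+" ] ]
          right [ node [ id 0 label "O" ] ]
        ]"""
        with pytest.raises(RuleError, match="charge not conserved"):
            parse_rule(bad)

    def test_empty_action_reported(self):
        p = parse_rule(PROTON_TRANSFER)
        frozen = type(p)(
            rule_id="noop",
            left_nodes=p.left_nodes,
            right_nodes=p.left_nodes,
            left_edges=p.left_edges,
            right_edges=p.left_edges,
        )
        report = validate_rule(frozen)
        assert not report.ok
        assert any("empty action" in v for v in report.violations)

    @pytest.mark.parametrize("name", ALL_FIXTURE_RULES)
    def test_all_shipped_rules_validate_and_round_trip(self, name):
        p = fixture_rule(name)
        assert validate_rule(p).ok
        again = parse_rule(write_rule(p))
        assert again.left_nodes == p.left_nodes
        assert again.right_edges == p.right_edges


class TestInversion:
    @pytest.mark.parametrize("name", ALL_FIXTURE_RULES)
    def test_involution(self, name):
        p = fixture_rule(name)
        assert write_rule(invert_rule(invert_rule(p))) == write_rule(p)

    def test_inverse_moves_proton_back(self, water, ammonia):
        p = parse_rule(PROTON_TRANSFER)
        g = State([water, ammonia])
        tr = derive_all([p], g)[0]
        inv = invert_rule(p)
        back_keys = {
            apply_rule(inv, m, tr.target_state).key
            for m in find_matches(inv, tr.target_state)
        }
        assert g.key in back_keys

    def test_reversibility_on_toy_chemistries(self, multistep_toys):
        for toy in multistep_toys:
            g = toy.query().initial_state()
            for p in toy.rules:
                inv = invert_rule(p)
                for tr in derive_all([p], g):
                    back = {
                        apply_rule(inv, m, tr.target_state).key
                        for m in find_matches(inv, tr.target_state)
                    }
                    assert g.key in back


class TestMatching:
    def test_absent_element_means_no_match(self, water):
        p = parse_rule(PROTON_TRANSFER.replace('label "N', 'label "P'))
        assert find_matches(p, State([water, water.copy()])) == []

    def test_match_count_equals_exhaustive_oracle_on_two_waters(self, water):
        p = parse_rule(AUTOPROTOLYSIS)
        g = State([water, water.copy()])
        from enzmech.dpo import _expand_state

        host = _expand_state(g)
        assert len(find_matches(p, g)) == count_monomorphisms(
            p.left_graph(), host
        )

    def test_matches_span_molecule_copies(self, water):
        # the two pattern oxygens must land in distinct molecules here
        p = parse_rule(AUTOPROTOLYSIS)
        g = State([water, water.copy()])
        for m in find_matches(p, g):
            mols = {m.mapping[0][:2], m.mapping[2][:2]}
            assert len(mols) == 2

    def test_parallel_bond_match_excluded(self):
        # forming a second O-H bond between already-bonded atoms is invalid
        p = parse_rule(
            """rule [
              ruleID "pb"
              left [
                node [ id 0 label "O" ]
                node [ id 1 label "H" ]
              ]
              context [ ]
              right [
                node [ id 0 label "O-" ]
                node [ id 1 label "H+" ]
                edge [ source 0 target 1 label "-" ]
              ]
            ]"""
        )
        water = fixture_molecule("water")
        matches = find_matches(p, State([water]))
        # O has two H partners, both already bonded: no valid embedding
        assert matches == []

    def test_deterministic_order(self, water, ammonia):
        p = parse_rule(PROTON_TRANSFER)
        g = State([water, ammonia])
        a = [m.digest for m in find_matches(p, g)]
        b = [m.digest for m in find_matches(p, g)]
        assert a == b == sorted(a)


class TestApplication:
    def test_identity_match_on_exact_left_state(self):
        # applying to the state made of exactly L's molecules yields R's
        p = fixture_rule("pt_o_to_o")
        lg = p.left_graph()
        left_state = State(
            [
                MolGraph(lg.subgraph(c).copy())
                for c in __import__("networkx").connected_components(lg)
            ]
        )
        rg = p.right_graph()
        right_state = State(
            [
                MolGraph(rg.subgraph(c).copy())
                for c in __import__("networkx").connected_components(rg)
            ]
        )
        keys = {
            apply_rule(p, m, left_state).key
            for m in find_matches(p, left_state)
        }
        assert right_state.key in keys

    def test_composition_preserved_over_random_fixture_triples(self, multistep_toys):
        rng = random.Random(0)
        checked = 0
        for toy in multistep_toys:
            frontier = [toy.query().initial_state()]
            for _ in range(4):
                nxt = []
                for g in frontier:
                    for p in toy.rules:
                        for m in find_matches(p, g):
                            h = apply_rule(p, m, g)
                            assert h.composition() == g.composition()
                            checked += 1
                            if rng.random() < 0.7:
                                nxt.append(h)
                frontier = nxt[:6]
        assert checked >= 120  # sanity floor: the sweep actually exercised many triples

    def test_stale_match_rejected(self, water, ammonia, hydroxide):
        p = parse_rule(PROTON_TRANSFER)
        g = State([water, ammonia])
        m = find_matches(p, g)[0]
        other = State([hydroxide, ammonia])
        with pytest.raises(StaleMatchError):
            apply_rule(p, m, other)


class TestDeriveAll:
    def test_no_rules_no_transitions(self, water):
        assert derive_all([], State([water])) == []

    def test_symmetric_matches_dedup_to_one_transition(self, water, ammonia):
        # both water hydrogens give isomorphic products: 1 transition, 2 witnesses
        p = parse_rule(PROTON_TRANSFER)
        ts = derive_all([p], State([water, ammonia]))
        assert len(ts) == 1
        assert len(ts[0].witnesses) == 2

    def test_target_key_set_equals_naive_double_loop(self, multistep_toys):
        for toy in multistep_toys:
            g = toy.query().initial_state()
            naive = set()
            for p in toy.rules:
                for m in find_matches(p, g):
                    naive.add(apply_rule(p, m, g).key)
            assert {t.target for t in derive_all(toy.rules, g)} == naive

    def test_byte_stable_across_runs(self, toy_his_ser):
        g = toy_his_ser.query().initial_state()
        ts1 = derive_all(toy_his_ser.rules, g)
        ts2 = derive_all(toy_his_ser.rules, g)
        assert [(t.source, t.target, t.witnesses) for t in ts1] == [
            (t.source, t.target, t.witnesses) for t in ts2
        ]

    def test_transitions_preserve_total_charge(self, toy_glu):
        g = toy_glu.query().initial_state()
        for t in derive_all(toy_glu.rules, g):
            assert t.target_state.composition()[1] == g.composition()[1]
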