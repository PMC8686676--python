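"""Reaction centers, context-guided abstraction, filters, atom tracking."""

import networkx as nx
import pytest

from enzmech.dpo import apply_rule, find_matches, validate_rule
from enzmech.fixtures import default_patterns, toy_chemistry
from enzmech.ruleextract import (
    ExtractionConfig,
    ReactionStep,
    StepError,
    extract_rule,
    filter_step,
    load_step,
    reaction_center,
    save_step,
    track_atoms,
)

POLICIES = ("action", "topology", "default", "maximal")


def g_from(atoms, bonds):
    g = nx.Graph()
    for a, el, ch, *rest in atoms:
        g.add_node(
            a, element=el, charge=ch, residue=(rest[0] if rest else ""), role=""
        )
    for u, v, o in bonds:
        g.add_edge(u, v, order=o)
    return g


@pytest.fixture(scope="module")
def proton_step():
    """Methanol O-H deprotonated by ammonia; explicit hydrogens."""
    educts = g_from(
        [("C", "C", 0), ("O", "O", 0), ("H", "H", 0),
         ("h1", "H", 0), ("h2", "H", 0), ("h3", "H", 0),
         ("N", "N", 0), ("n1", "H", 0), ("n2", "H", 0), ("n3", "H", 0)],
        [("C", "O", "-"), ("O", "H", "-"), ("C", "h1", "-"), ("C", "h2", "-"),
         ("C", "h3", "-"), ("N", "n1", "-"), ("N", "n2", "-"), ("N", "n3", "-")],
    )
    products = g_from(
        [("C", "C", 0), ("O", "O", -1), ("H", "H", 0),
         ("h1", "H", 0), ("h2", "H", 0), ("h3", "H", 0),
         ("N", "N", 1), ("n1", "H", 0), ("n2", "H", 0), ("n3", "H", 0)],
        [("C", "O", "-"), ("C", "h1", "-"), ("C", "h2", "-"), ("C", "h3", "-"),
         ("N", "H", "-"), ("N", "n1", "-"), ("N", "n2", "-"), ("N", "n3", "-")],
    )
    return ReactionStep(
        educts=educts,
        products=products,
        atom_map={n: n for n in educts.nodes},
        mechanism_id="toy",
        step_index=1,
    )


@pytest.fixture(scope="module")
def spectator_water_step(proton_step):
    """Same step with an untouched water molecule on both sides."""
    educts = proton_step.educts.copy()
    products = proton_step.products.copy()
    amap = dict(proton_step.atom_map)
    for g in (educts, products):
        g.add_node("wO", element="O", charge=0, residue="", role="")
        g.add_node("wH1", element="H", charge=0, residue="", role="")
        g.add_node("wH2", element="H", charge=0, residue="", role="")
        g.add_edge("wO", "wH1", order="-")
        g.add_edge("wO", "wH2", order="-")
    amap.update({"wO": "wO", "wH1": "wH1", "wH2": "wH2"})
    return ReactionStep(
        educts=educts, products=products, atom_map=amap,
        mechanism_id="toy", step_index=1,
    )


class TestReactionCenter:
    def test_identity_step_has_empty_center(self, proton_step):
        g = proton_step.educts
        step = ReactionStep(
            educts=g, products=g.copy(), atom_map={n: n for n in g.nodes}
        )
        c = reaction_center(step)
        assert not c.atoms and not c.bond_changes and not c.charge_changes

    def test_proton_transfer_center(self, proton_step):
        c = reaction_center(proton_step)
        assert c.atoms == {"O", "H", "N"}
        kinds = sorted(k for _, _, k in c.bond_changes)
        assert kinds == ["broken", "formed"]
        assert len(c.charge_changes) == 2

    def test_non_bijective_map_rejected(self, proton_step):
        amap = dict(proton_step.atom_map)
        del amap["h1"]
        step = ReactionStep(
            educts=proton_step.educts,
            products=proton_step.products,
            atom_map=amap,
        )
        with pytest.raises(StepError, match="bijection"):
            reaction_center(step)

    def test_worked_example_center_equals_rule_action(self, toy_fig1):
        c = reaction_center(toy_fig1.step)
        assert set(c.atoms) == set(toy_fig1.rule.action_nodes())


class TestExtraction:
    def test_action_only_rule_is_three_atoms(self, proton_step):
        r = extract_rule(proton_step, ExtractionConfig.for_policy("action"))
        assert set(r.left_nodes) == {"O", "H", "N"}

    def test_local_topology_adds_all_center_neighbors(self, proton_step):
        r = extract_rule(proton_step, ExtractionConfig.for_policy("topology"))
        neighbors = set()
        for a in ("O", "H", "N"):
            neighbors |= set(proton_step.educts.adj[a])
            neighbors |= set(proton_step.products.adj[a])
        assert set(r.left_nodes) == {"O", "H", "N"} | neighbors

    def test_context_nested_and_matches_antimonotone(self, proton_step, toy_fig1):
        patterns = default_patterns()
        for step in (proton_step, toy_fig1.step):
            rules = [
                extract_rule(step, ExtractionConfig.for_policy(p, patterns))
                for p in POLICIES
            ]
            for small, big in zip(rules, rules[1:]):
                assert set(small.left_nodes) <= set(big.left_nodes)
            # anti-monotone match sets: adding context can only restrict
            # where the action may fire.  Raw match counts may grow with
            # context (automorphic hydrogens multiply embeddings), so the
            # comparison is on distinct reaction-center images.
            gE = step.educt_state()
            action = sorted(rules[0].action_nodes(), key=str)
            images = [
                {tuple(m.mapping[v] for v in action) for m in find_matches(r, gE)}
                for r in rules
            ]
            for small, big in zip(images, images[1:]):
                assert big <= small
            assert images[-1], "maximal rule must still fire on its own step"

    @pytest.mark.parametrize("policy", POLICIES)
    def test_round_trip_on_originating_step(self, proton_step, spectator_water_step,
                                            toy_fig1, policy):
        patterns = default_patterns()
        for step in (proton_step, spectator_water_step, toy_fig1.step):
            r = extract_rule(step, ExtractionConfig.for_policy(policy, patterns))
            assert validate_rule(r).ok
            gE, gP = step.educt_state(), step.product_state()
            assert any(
                apply_rule(r, m, gE).key == gP.key for m in find_matches(r, gE)
            ), f"{policy} rule does not reproduce its own step"

    def test_spectator_molecule_dropped_from_rule(self, spectator_water_step):
        r = extract_rule(
            spectator_water_step,
            ExtractionConfig.for_policy("maximal", default_patterns()),
        )
        assert not any(str(a).startswith("w") for a in r.left_nodes)

    def test_pattern_guideline_pulls_in_whole_group(self, toy_fig1):
        # with patterns on, the ester O-methyl carbon (not a center
        # neighbor) joins the context; without patterns it is absent
        with_pat = extract_rule(
            toy_fig1.step, ExtractionConfig.for_policy("default", default_patterns())
        )
        without = extract_rule(toy_fig1.step, ExtractionConfig.for_policy("topology"))
        assert "m3" in with_pat.left_nodes
        assert "m3" not in without.left_nodes

    def test_side_chain_guideline_includes_whole_residues(self, toy_fig1):
        r = extract_rule(
            toy_fig1.step, ExtractionConfig.for_policy("default", default_patterns())
        )
        educts = toy_fig1.step.educts
        for a, d in educts.nodes(data=True):
            if d["residue"]:
                assert a in r.left_nodes, f"residue atom {a} missing from context"

    def test_every_context_atom_is_attributed(self, toy_fig1):
        r = extract_rule(
            toy_fig1.step, ExtractionConfig.for_policy("default", default_patterns())
        )
        attribution = r.provenance["context_attribution"]
        assert set(attribution) == set(map(str, r.left_nodes))
        assert all(reasons for reasons in attribution.values())

    def test_shipped_worked_example_rule_is_reproduced(self, toy_fig1):
        r = extract_rule(
            toy_fig1.step, ExtractionConfig.for_policy("default", default_patterns())
        )
        assert set(r.left_nodes) == set(toy_fig1.rule.left_nodes)
        assert r.left_edges == toy_fig1.rule.left_edges
        assert r.right_edges == toy_fig1.rule.right_edges


class TestFilters:
    def test_metal_step_rejected(self):
        g = g_from([("Z", "Zn", 2)], [])
        step = ReactionStep(educts=g, products=g.copy(), atom_map={"Z": "Z"})
        acc = filter_step(step)
        assert (acc.accepted, acc.reason) == (False, "metal")

    def test_radical_step_rejected(self, proton_step):
        step = ReactionStep(
            educts=proton_step.educts,
            products=proton_step.products,
            atom_map=proton_step.atom_map,
            radical=True,
        )
        acc = filter_step(step)
        assert (acc.accepted, acc.reason) == (False, "radical")

    def test_clean_organic_step_accepted(self, proton_step):
        assert filter_step(proton_step).accepted

    def test_rejected_step_cannot_be_extracted(self, proton_step):
        step = ReactionStep(
            educts=proton_step.educts,
            products=proton_step.products,
            atom_map=proton_step.atom_map,
            radical=True,
        )
        with pytest.raises(StepError, match="radical"):
            extract_rule(step)

    def test_blocklist_is_configurable(self):
        g = g_from([("Z", "Zn", 2)], [])
        step = ReactionStep(educts=g, products=g.copy(), atom_map={"Z": "Z"})
        permissive = ExtractionConfig(
            organic_elements=frozenset({"Zn"}), patterns=()
        )
        assert filter_step(step, permissive).accepted


class TestTrackAtoms:
    def _reverse(self, step):
        inv = {v: u for u, v in step.atom_map.items()}
        return ReactionStep(
            educts=step.products,
            products=step.educts,
            atom_map=inv,
            mechanism_id=step.mechanism_id,
            step_index=step.step_index + 1,
        )

    def test_consistent_mechanism_passes_without_repairs(self, spectator_water_step):
        steps = [spectator_water_step, self._reverse(spectator_water_step)]
        report = track_atoms(steps)
        assert report.ok and not report.excluded and report.repairs == []

    def test_omitted_spectator_is_propagated(self, proton_step, spectator_water_step):
        # step 1 carries water; the "curated" step 2 forgot it
        steps = [spectator_water_step, self._reverse(proton_step)]
        report = track_atoms(steps)
        assert report.ok and report.repairs
        prod0 = report.steps[0].product_state()
        educ1 = report.steps[1].educt_state()
        assert prod0.counts() == educ1.counts()

    def test_unbalanced_step_excludes_mechanism(self, proton_step):
        amap = dict(proton_step.atom_map)
        del amap["h1"]
        broken = ReactionStep(
            educts=proton_step.educts,
            products=proton_step.products,
            atom_map=amap,
        )
        report = track_atoms([broken, self._reverse(proton_step)])
        assert report.excluded and not report.ok

    def test_irreconcilable_chain_excluded(self, proton_step, toy_glu):
        # a mechanism whose second step concerns entirely different molecules
        other = toy_glu.query().initial_state()
        g = nx.Graph()
        for key, idx, mol in other.instances():
            for a, d in mol.graph.nodes(data=True):
                g.add_node((key, idx, a), **dict(d))
            for u, v, d in mol.graph.edges(data=True):
                g.add_edge((key, idx, u), (key, idx, v), order=d["order"])
        alien = ReactionStep(
            educts=g, products=g.copy(), atom_map={n: n for n in g.nodes}
        )
        # composition can never match: different element totals per side pair
        report = track_atoms([proton_step, alien])
        assert report.excluded


class TestStepIO:
    def test_json_bundle_round_trip(self, toy_fig1):
        bundle = save_step(toy_fig1.step)
        again = load_step(bundle)
        assert again.educt_state().key == toy_fig1.step.educt_state().key
        assert again.product_state().key == toy_fig1.step.product_state().key
        assert reaction_center(again).atoms == reaction_center(toy_fig1.step).atoms

    def test_annotations_restored(self, toy_fig1):
        again = load_step(save_step(toy_fig1.step))
        residues = {
            d["residue"]
            for _, d in again.educts.nodes(data=True)
            if d["residue"]
        }
        assert residues == {"His#1", "Ser#1"}
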