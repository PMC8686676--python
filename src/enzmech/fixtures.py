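"""Shipped toy chemistries, residue library and randomized generators.

Everything here exists so that the rewriting, state-space and search
machinery is exercisable without any database download: small molecules
and rules in the same GML dialect a user would write, an amino-acid
side-chain library (side chains are methyl-capped at the backbone
truncation), a worked single-step example with its abstracted rule, and
seeded random-molecule generators for canonicalization oracles.

Expected outcomes of the toy chemistries are *documented*, never encoded
as ground truth: the test suite recomputes them with brute-force oracles.
"""

from __future__ import annotations

import itertools
import json
import random
from collections.abc import Mapping
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx

from .chemgraph import MolGraph, State, parse_molecule
from .dpo import Rule, parse_rule
from .mechsearch import MechanismQuery
from .ruleextract import FunctionalPattern, ReactionStep, load_patterns, load_step

__all__ = [
    "ToyChemistry",
    "AminoAcidLibrary",
    "toy_chemistry",
    "TOY_NAMES",
    "amino_acid_library",
    "fixture_molecule",
    "fixture_rule",
    "default_patterns",
    "random_molecule",
    "scramble_isomorphic",
    "polyol_chain",
]

TOY_NAMES = (
    "proton_transfer",
    "glu_tautomerization",
    "his_ser_acyl_transfer",
    "fig1_step",
    "branching_ladder",
)


def _data():
    return resources.files("enzmech") / "data"


def fixture_molecule(name: str) -> MolGraph:
    """Load a shipped molecule by name (see ``data/molecules``)."""
    return parse_molecule((_data() / "molecules" / f"{name}.gml").read_text())


def fixture_rule(name: str) -> Rule:
    """Load a shipped rule by name (see ``data/rules``)."""
    return parse_rule((_data() / "rules" / f"{name}.gml").read_text())


def default_patterns() -> list[FunctionalPattern]:
    """The shipped functional-pattern set (a small, user-extensible default:
    common functional groups, rings and small molecules)."""
    with resources.as_file(_data() / "patterns") as p:
        return load_patterns(p)


# ---------------------------------------------------------------------------
# Amino-acid side-chain library
# ---------------------------------------------------------------------------

class AminoAcidLibrary(Mapping):
    """Maps an amino-acid label to its side-chain tautomer graphs.

    Tautomers of one amino acid (e.g. the two neutral protonation states
    of the histidine imidazole) share a label; :meth:`resolve` normalizes
    a tautomer name to its parent label.  Residue labels unknown to the
    library resolve to themselves.
    """

    def __init__(self, entries: list[tuple[str, str, MolGraph]]):
        self._entries = entries
        self._by_label: dict[str, list[MolGraph]] = {}
        self._name_to_label: dict[str, str] = {}
        self._by_name: dict[str, MolGraph] = {}
        for label, name, mol in entries:
            self._by_label.setdefault(label, []).append(mol)
            self._name_to_label[name] = label
            self._by_name[name] = mol

    def __getitem__(self, label: str) -> list[MolGraph]:
        return self._by_label[label]

    def __iter__(self):
        return iter(self._by_label)

    def __len__(self) -> int:
        return len(self._by_label)

    def resolve(self, name_or_label: str) -> str:
        return self._name_to_label.get(name_or_label, name_or_label)

    def tautomer(self, name: str) -> MolGraph:
        """Fetch one tautomer graph by its tautomer name (e.g. ``His-t1``)."""
        return self._by_name[name]

    def annotated(self, name: str, instance: int = 1) -> MolGraph:
        """A tautomer graph with all atoms annotated ``Label#instance``."""
        label = self.resolve(name)
        return self._by_name.get(name, self._by_label[label][0]).with_residue(
            f"{label}#{instance}"
        )


def amino_acid_library() -> AminoAcidLibrary:
    """Load the shipped side-chain library (Ser, Cys, Thr, Asp, Glu, Lys,
    Tyr, Arg and two His tautomers)."""
    base = _data() / "amino_acids"
    manifest = json.loads((base / "manifest.json").read_text())
    entries = []
    for item in manifest["amino_acids"]:
        mol = parse_molecule((base / item["file"]).read_text())
        entries.append((item["label"], item["name"], mol))
    return AminoAcidLibrary(entries)


# ---------------------------------------------------------------------------
# Toy chemistries
# ---------------------------------------------------------------------------

@dataclass
class ToyChemistry:
    """A self-contained chemistry: rules plus named states.

    ``states`` has entries ``educts``, ``products`` and ``catalyst``;
    ``description`` documents the expected behavior (verified by oracle
    computation in the tests, not asserted from here).  The worked
    single-step fixture additionally carries ``step`` and ``rule``.
    """

    name: str
    rules: list[Rule]
    states: dict[str, State]
    description: str
    step: ReactionStep | None = None
    rule: Rule | None = None
    library: AminoAcidLibrary | None = None

    def query(self, mode: str = "minimal", **kwargs) -> MechanismQuery:
        return MechanismQuery(
            educts=self.states["educts"],
            products=self.states["products"],
            catalyst=self.states["catalyst"],
            rules=self.rules,
            mode=mode,
            library=self.library,
            **kwargs,
        )


def polyol_chain(n_sites: int, deprotonated: tuple[int, ...] = ()) -> MolGraph:
    """A methyl-capped polyol chain CH3-(CHOH)_{n-1}-CH2OH with ``n_sites``
    hydroxyls, all mutually distinguishable by distance from the cap.

    ``deprotonated`` lists 1-based site indices whose hydroxyl is an
    alkoxide (O-, no H).
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    g = nx.Graph()

    def add(name, element, charge=0):
        g.add_node(name, element=element, charge=charge, residue="", role="")

    hc = itertools.count()

    def add_h(parent, n):
        for _ in range(n):
            h = f"h{next(hc)}"
            add(h, "H")
            g.add_edge(parent, h, order="-")

    add("c0", "C")
    add_h("c0", 3)
    prev = "c0"
    for i in range(1, n_sites + 1):
        c, o = f"c{i}", f"o{i}"
        add(c, "C")
        add(o, "O", -1 if i in deprotonated else 0)
        g.add_edge(prev, c, order="-")
        g.add_edge(c, o, order="-")
        add_h(c, 1 if i < n_sites else 2)
        if i not in deprotonated:
            add_h(o, 1)
        prev = c
    return MolGraph(nx.convert_node_labels_to_integers(g, ordering="sorted"))


def _protonated_ammonia() -> MolGraph:
    return MolGraph.from_atoms(
        [(0, "N", 1), (1, "H", 0), (2, "H", 0), (3, "H", 0), (4, "H", 0)],
        [(0, i, "-") for i in range(1, 5)],
    )


def toy_chemistry(name: str) -> ToyChemistry:
    """Return one of the shipped toy chemistries by name.

    ``proton_transfer``
        Water-mediated proton transfer from methanol to methylamine.
        Two rules, three named states; the direct acid-base reaction is a
        one-step route, and a two-step water-catalyzed relay exists.
    ``glu_tautomerization``
        Keto-enol tautomerization of acetaldehyde assisted by a glutamate
        side chain acting as proton shuttle: hydrogen abstraction forms an
        enolate, reprotonation at oxygen gives the enol.  Two-step cycle,
        catalyzed exclusively by the single glutamate.
    ``his_ser_acyl_transfer``
        Transesterification of methyl formate with ethanol through a
        covalent serine-ester intermediate, His/Ser jointly catalytic: a
        five-step addition/elimination x2 cycle in which the histidine is
        restored mid-trace and reused.
    ``fig1_step``
        The worked single-step example: concerted serine activation by
        histidine with nucleophilic attack on a methyl-ester substrate,
        shipped as an atom-mapped step plus the rule abstracted from it.
    ``branching_ladder``
        A deliberately combinatorial chemistry (18 distinguishable
        hydroxyl sites on two polyol chains, three ammonia bases) whose
        depth-3 space has ~1e3 states; used for scale exercises.
    """
    lib = amino_acid_library()
    if name == "proton_transfer":
        return ToyChemistry(
            name=name,
            rules=[fixture_rule("pt_o_to_n"), fixture_rule("pt_o_to_o")],
            states={
                "educts": State(
                    [fixture_molecule("methanol"), fixture_molecule("methylamine")]
                ),
                "products": State(
                    [fixture_molecule("methoxide"), fixture_molecule("methylammonium")]
                ),
                "catalyst": State([fixture_molecule("water")]),
            },
            description=(
                "Proton transfer from methanol to methylamine.  The direct "
                "acid-base step gives a one-step (noncatalytic) route; with "
                "water as catalyst a two-step relay exists (water protonates "
                "the amine, methanol reprotonates the hydroxide)."
            ),
            library=lib,
        )
    if name == "glu_tautomerization":
        return ToyChemistry(
            name=name,
            rules=[fixture_rule("enolate_form"), fixture_rule("pt_o_to_o")],
            states={
                "educts": State([fixture_molecule("acetaldehyde")]),
                "products": State([fixture_molecule("vinyl_alcohol")]),
                "catalyst": State([lib.annotated("Glu", 1)]),
            },
            description=(
                "Glutamate-assisted keto-enol tautomerization: the "
                "carboxylate abstracts an alpha proton (enolate forms), then "
                "the protonated glutamate reprotonates the enolate oxygen.  "
                "Expected: a minimal trace of length 2, classified sAA(Glu)."
            ),
            library=lib,
        )
    if name == "his_ser_acyl_transfer":
        return ToyChemistry(
            name=name,
            rules=[
                fixture_rule("nucleophilic_addition"),
                fixture_rule("oxyanion_collapse"),
                fixture_rule("pt_o_to_n"),
                fixture_rule("alkoxide_addition"),
            ],
            states={
                "educts": State(
                    [fixture_molecule("methyl_formate"), fixture_molecule("ethanol")]
                ),
                "products": State(
                    [fixture_molecule("ethyl_formate"), fixture_molecule("methanol")]
                ),
                "catalyst": State(
                    [lib.annotated("His-t1", 1), lib.annotated("Ser", 1)]
                ),
            },
            description=(
                "His/Ser-catalyzed transesterification of methyl formate "
                "with ethanol via a covalent serine-formate intermediate: "
                "(1) concerted His-assisted serine attack, (2) oxyanion "
                "collapse releasing methanol, (3) His deprotonates ethanol, "
                "(4) ethoxide attacks the serine ester, (5) collapse "
                "releases serine and ethyl formate.  Expected: a length-5 "
                "multiAA {His, Ser} trace with His restored after step 2 "
                "and reused; a shorter His-only base-catalyzed route also "
                "exists."
            ),
            library=lib,
        )
    if name == "fig1_step":
        step = load_step(_data() / "steps" / "fig1_step.json")
        rule = fixture_rule("fig1_rule")
        return ToyChemistry(
            name=name,
            rules=[rule],
            states={
                "educts": step.educt_state(),
                "products": step.product_state(),
                "catalyst": State(
                    [lib.annotated("His-t1", 1), lib.annotated("Ser", 1)]
                ),
            },
            description=(
                "Worked single step: histidine abstracts the serine hydroxyl "
                "proton while the serine oxygen attacks a methyl-ester "
                "carbonyl, yielding the covalent serine-substrate adduct "
                "with a tetrahedral oxyanion and a protonated imidazolium.  "
                "Applying the shipped rule to the educt state reproduces the "
                "product state; the rule's action atoms equal the step's "
                "reaction center."
            ),
            step=step,
            rule=rule,
            library=lib,
        )
    if name == "branching_ladder":
        ammonia = fixture_molecule("ammonia")
        chain_a = polyol_chain(10)
        chain_b = polyol_chain(8)
        return ToyChemistry(
            name=name,
            rules=[fixture_rule("pt_o_to_n"), fixture_rule("pt_n_to_o")],
            states={
                "educts": State([chain_a, chain_b, ammonia]),
                "products": State(
                    [polyol_chain(10, deprotonated=(1,)), chain_b.copy(),
                     _protonated_ammonia()]
                ),
                "catalyst": State(
                    [ammonia.with_residue("Amm#1"), ammonia.with_residue("Amm#2")]
                ),
            },
            description=(
                "Scale exercise: two polyol chains with 18 mutually "
                "distinguishable hydroxyl sites and three ammonia bases.  "
                "Each forward step moves one hydroxyl proton onto a free "
                "ammonia, so the depth-3 space is exactly the sets of at "
                "most three deprotonated sites: C(18,0)+C(18,1)+C(18,2)+"
                "C(18,3) = 988 states."
            ),
            library=lib,
        )
    raise ValueError(f"unknown toy chemistry {name!r}; known: {TOY_NAMES}")


# ---------------------------------------------------------------------------
# Random generators (canonicalization oracles, invariant sweeps)
# ---------------------------------------------------------------------------

#: Degree caps used by the random generator, by element (best effort).
_DEGREE_CAPS = {"H": 1, "O": 2, "N": 3, "C": 4, "S": 2, "P": 4}

_DEFAULT_WEIGHTS = {"C": 5, "H": 4, "O": 3, "N": 2}


def random_molecule(
    seed: int,
    n_atoms: int,
    element_weights: dict[str, float] | None = None,
) -> MolGraph:
    """A connected random molecule, reproducible for a fixed seed.

    Atoms are attached sequentially to a random earlier atom with spare
    valence (degree caps per element, best effort); double bonds and unit
    charges appear with small probability where plausible.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    weights = element_weights or _DEFAULT_WEIGHTS
    rng = random.Random(seed)
    elements = list(weights)
    wts = [weights[e] for e in elements]
    g = nx.Graph()

    def cap(v):
        return _DEGREE_CAPS.get(g.nodes[v]["element"], 4)

    for i in range(n_atoms):
        el = rng.choices(elements, weights=wts)[0]
        charge = 0
        if el in ("O", "N") and rng.random() < 0.08:
            charge = rng.choice((-1, 1)) if el == "N" else -1
        g.add_node(i, element=el, charge=charge, residue="", role="")
        if i == 0:
            continue
        candidates = [v for v in range(i) if g.degree(v) < cap(v)]
        if not candidates:  # fully saturated so far: best effort, least loaded
            candidates = sorted(range(i), key=g.degree)[:1]
        u = rng.choice(candidates)
        order = "-"
        if (
            el in ("C", "N", "O")
            and g.nodes[u]["element"] in ("C", "N", "O")
            and cap(u) - g.degree(u) >= 2
            and _DEGREE_CAPS.get(el, 4) >= 2
            and rng.random() < 0.12
        ):
            order = "="
        g.add_edge(u, i, order=order)
    return MolGraph(g)


def scramble_isomorphic(m: MolGraph, seed: int) -> MolGraph:
    """Permute atom ids and insertion order; the result is isomorphic to
    the input (the canonicalization oracle's adversary)."""
    rng = random.Random(seed)
    nodes = list(m.graph.nodes)
    perm = nodes[:]
    rng.shuffle(perm)
    mapping = dict(zip(nodes, perm))
    g = nx.Graph()
    shuffled = nodes[:]
    rng.shuffle(shuffled)
    for v in shuffled:
        g.add_node(mapping[v], **dict(m.graph.nodes[v]))
    edges = list(m.graph.edges(data=True))
    rng.shuffle(edges)
    for u, v, d in edges:
        g.add_edge(mapping[u], mapping[v], order=d["order"])
    return MolGraph(g)
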