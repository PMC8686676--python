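"""Abstraction of rewrite rules from atom-mapped elementary reaction steps.

An elementary step (an arrow-pushing diagram in curated mechanism
databases) is a maximally refined rule: educt and product graphs are
complete molecules related by an explicit atom map.  Abstraction keeps the
*action* (the reaction center: atoms with changed bonds or charges) and
adds context following three guidelines:

1. *Local topology* -- atoms and bonds directly connected to the reaction
   center are retained; they distinguish e.g. a methyl group from a chain.
2. *Functional patterns* -- a configurable library of common functional
   groups, rings and small molecules is embedded into both the educt and
   product graphs; any match intersecting the center contributes all of
   its atoms.
3. *Active amino acids* -- if any atom of an annotated residue intersects
   the center, the whole side chain is included.

Molecules sharing no atom with the reaction center are dropped from the
rule entirely.  Steps that rely on metal ions (elements outside an organic
allowlist) or on radical single-electron chemistry (an input metadata
flag; the graph model cannot represent such species) are rejected before
extraction.  Mechanisms whose steps do not chain (molecules appearing or
disappearing between consecutive steps, an artifact of human-oriented
curation) are repaired by spectator propagation where possible and
excluded otherwise.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .chemgraph import (
    ChemGraphError,
    MolGraph,
    State,
    parse_graph,
    write_graph,
)
from .dpo import Rule, validate_rule

__all__ = [
    "DEFAULT_ORGANIC_ELEMENTS",
    "ReactionStep",
    "FunctionalPattern",
    "ExtractionConfig",
    "ReactionCenter",
    "Acceptance",
    "TrackReport",
    "StepError",
    "reaction_center",
    "extract_rule",
    "filter_step",
    "track_atoms",
    "load_step",
    "save_step",
    "load_patterns",
]

#: Elements a cofactor-free organic step may contain.  Everything outside
#: this allowlist counts as metal-ion chemistry and disqualifies the step;
#: the list is configurable per extraction.
DEFAULT_ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)


class StepError(ChemGraphError):
    """Invalid reaction step or rejected extraction."""


# ---------------------------------------------------------------------------
# Reaction steps
# ---------------------------------------------------------------------------

@dataclass
class ReactionStep:
    """An atom-mapped elementary reaction step.

    ``educts`` and ``products`` are possibly disconnected graphs with
    explicit hydrogens; ``atom_map`` maps educt atom ids to product atom
    ids, is injective and element-preserving where defined, and is a
    bijection for any well-formed step (partial maps are tolerated so that
    :func:`track_atoms` can diagnose unbalanced curation artifacts).
    """

    educts: nx.Graph
    products: nx.Graph
    atom_map: dict
    mechanism_id: str = ""
    step_index: int = 0
    tags: tuple[str, ...] = ()
    radical: bool = False

    def __post_init__(self):
        seen = set()
        for u, v in self.atom_map.items():
            if u not in self.educts:
                raise StepError(f"atom map source {u!r} not an educt atom")
            if v not in self.products:
                raise StepError(f"atom map target {v!r} not a product atom")
            if v in seen:
                raise StepError(f"atom map not injective at {v!r}")
            seen.add(v)
            if (
                self.educts.nodes[u]["element"]
                != self.products.nodes[v]["element"]
            ):
                raise StepError(
                    f"atom map changes element at {u!r} -> {v!r}"
                )

    def is_bijective(self) -> bool:
        return (
            len(self.atom_map) == self.educts.number_of_nodes()
            and len(self.atom_map) == self.products.number_of_nodes()
        )

    def educt_state(self) -> State:
        return _graph_to_state(self.educts)

    def product_state(self) -> State:
        return _graph_to_state(self.products)

    def elements(self) -> set[str]:
        return {
            d["element"]
            for g in (self.educts, self.products)
            for _, d in g.nodes(data=True)
        }


def _graph_to_state(g: nx.Graph) -> State:
    mols = []
    for comp in nx.connected_components(g):
        index = {n: i for i, n in enumerate(sorted(comp, key=str))}
        cg = nx.Graph()
        for n, i in index.items():
            cg.add_node(i, **dict(g.nodes[n]))
        for u, v, d in g.subgraph(comp).edges(data=True):
            cg.add_edge(index[u], index[v], order=d["order"])
        mols.append(MolGraph(cg))
    return State(mols)


# ---------------------------------------------------------------------------
# Reaction center
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionCenter:
    """Atoms undergoing electronic displacement or bond rearrangement."""

    atoms: frozenset
    bond_changes: tuple[tuple[object, object, str], ...]  # (u, v, kind)
    charge_changes: tuple[tuple[object, int, int], ...]  # (u, old, new)


def reaction_center(step: ReactionStep) -> ReactionCenter:
    """Compute the reaction center of a step from its atom map.

    Bond changes are labeled ``broken``, ``formed`` or ``order-changed``;
    charge changes are per-atom.  The step's atom map must be a bijection.
    """
    if not step.is_bijective():
        raise StepError("atom map is not a bijection: cannot compute center")
    inv = {v: u for u, v in step.atom_map.items()}
    atoms: set = set()
    bond_changes: list[tuple] = []
    charge_changes: list[tuple] = []
    for u in step.educts.nodes:
        cu = step.educts.nodes[u]["charge"]
        cv = step.products.nodes[step.atom_map[u]]["charge"]
        if cu != cv:
            charge_changes.append((u, cu, cv))
            atoms.add(u)
    for u, v, d in step.educts.edges(data=True):
        pu, pv = step.atom_map[u], step.atom_map[v]
        if not step.products.has_edge(pu, pv):
            bond_changes.append((u, v, "broken"))
            atoms.update((u, v))
        elif step.products.edges[pu, pv]["order"] != d["order"]:
            bond_changes.append((u, v, "order-changed"))
            atoms.update((u, v))
    for pu, pv in step.products.edges:
        u, v = inv[pu], inv[pv]
        if not step.educts.has_edge(u, v):
            bond_changes.append((u, v, "formed"))
            atoms.update((u, v))
    key = lambda t: (str(t[0]), str(t[1]))
    return ReactionCenter(
        atoms=frozenset(atoms),
        bond_changes=tuple(sorted(bond_changes, key=key)),
        charge_changes=tuple(sorted(charge_changes, key=key)),
    )


# ---------------------------------------------------------------------------
# Functional patterns and extraction configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunctionalPattern:
    """A named connected pattern graph (optionally with charge wildcards)."""

    name: str
    graph: nx.Graph

    def __post_init__(self):
        if self.graph.number_of_nodes() == 0:
            raise StepError(f"pattern {self.name!r} is empty")
        if self.graph.number_of_nodes() > 12:
            raise StepError(f"pattern {self.name!r} exceeds 12 atoms")
        if not nx.is_connected(self.graph):
            raise StepError(f"pattern {self.name!r} is disconnected")


@dataclass
class ExtractionConfig:
    """Context policy for rule abstraction.

    The three boolean knobs correspond to the three context guidelines and
    exist for ablation; ``maximal`` overrides them with full molecules.
    """

    patterns: Sequence[FunctionalPattern] = ()
    organic_elements: frozenset[str] = DEFAULT_ORGANIC_ELEMENTS
    local_topology: bool = True
    use_patterns: bool = True
    whole_side_chain: bool = True
    maximal: bool = False

    @classmethod
    def for_policy(
        cls, policy: str, patterns: Sequence[FunctionalPattern] = ()
    ) -> "ExtractionConfig":
        """Preset policies: ``action`` (center only), ``topology`` (center
        plus immediate surroundings), ``default`` (all three guidelines),
        ``maximal`` (complete molecules)."""
        if policy == "action":
            return cls(patterns=(), local_topology=False, use_patterns=False,
                       whole_side_chain=False)
        if policy == "topology":
            return cls(patterns=(), local_topology=True, use_patterns=False,
                       whole_side_chain=False)
        if policy == "default":
            return cls(patterns=tuple(patterns))
        if policy == "maximal":
            return cls(patterns=tuple(patterns), maximal=True)
        raise ValueError(f"unknown policy {policy!r}")


@dataclass(frozen=True)
class Acceptance:
    accepted: bool
    reason: str | None = None  # "metal" | "radical"


def filter_step(step: ReactionStep, cfg: ExtractionConfig | None = None) -> Acceptance:
    """Admission filter: reject metal-dependent and radical steps."""
    cfg = cfg or ExtractionConfig()
    offending = sorted(step.elements() - cfg.organic_elements)
    if offending:
        return Acceptance(False, "metal")
    if step.radical:
        return Acceptance(False, "radical")
    return Acceptance(True, None)


# ---------------------------------------------------------------------------
# Rule extraction
# ---------------------------------------------------------------------------

def _pattern_matches(pattern: FunctionalPattern, host: nx.Graph) -> list[dict]:
    """Monomorphisms of a pattern into a host graph (pattern -> host)."""

    def node_match(h, p):
        if h["element"] != p["element"]:
            return False
        return p["charge"] is None or h["charge"] == p["charge"]

    def edge_match(h, p):
        return h["order"] == p["order"]

    gm = nxiso.GraphMatcher(
        host, pattern.graph, node_match=node_match, edge_match=edge_match
    )
    return [
        {pv: hv for hv, pv in m.items()} for m in gm.subgraph_monomorphisms_iter()
    ]


def extract_rule(
    step: ReactionStep,
    cfg: ExtractionConfig | None = None,
    rule_id: str | None = None,
) -> Rule:
    """Abstract a rule from a step by the three context guidelines.

    The rule's node set is the reaction center plus the configured context,
    restricted to educt molecules sharing at least one atom with the
    center; left/right attributes and edges are the induced subgraphs of
    the educt/product sides.  Provenance records the step identity and the
    guideline(s) responsible for every context atom.
    """
    cfg = cfg or ExtractionConfig()
    acc = filter_step(step, cfg)
    if not acc.accepted:
        raise StepError(f"step rejected by admission filter: {acc.reason}")
    center = reaction_center(step)
    if not center.atoms:
        raise StepError("empty reaction center: step changes nothing")
    inv = {v: u for u, v in step.atom_map.items()}

    # molecules (educt components) sharing no atom with the center are dropped
    kept_atoms: set = set()
    for comp in nx.connected_components(step.educts):
        if comp & center.atoms:
            kept_atoms |= comp
    if not center.atoms <= kept_atoms:  # pragma: no cover - defensive
        raise StepError("reaction-center atom outside every kept molecule")

    attribution: dict[object, set[str]] = {a: {"action"} for a in center.atoms}

    def attribute(atoms: Iterable, reason: str):
        for a in atoms:
            if a in kept_atoms:
                attribution.setdefault(a, set()).add(reason)

    if cfg.maximal:
        attribute(kept_atoms, "maximal")
    else:
        if cfg.local_topology:
            for a in center.atoms:
                attribute(step.educts.adj[a], "local-topology")
                for pn in step.products.adj[step.atom_map[a]]:
                    attribute([inv[pn]], "local-topology")
        if cfg.use_patterns:
            center_products = {step.atom_map[a] for a in center.atoms}
            for pat in cfg.patterns:
                for m in _pattern_matches(pat, step.educts):
                    image = set(m.values())
                    if image & center.atoms:
                        attribute(image, f"pattern:{pat.name}:educt")
                for m in _pattern_matches(pat, step.products):
                    image = set(m.values())
                    if image & center_products:
                        attribute(
                            [inv[a] for a in image], f"pattern:{pat.name}:product"
                        )
        if cfg.whole_side_chain:
            active_residues = {
                step.educts.nodes[a]["residue"]
                for a in center.atoms
                if step.educts.nodes[a].get("residue")
            }
            if active_residues:
                attribute(
                    (
                        a
                        for a in kept_atoms
                        if step.educts.nodes[a].get("residue") in active_residues
                    ),
                    "side-chain",
                )

    selected = set(attribution)
    left_nodes = {
        a: (step.educts.nodes[a]["element"], step.educts.nodes[a]["charge"])
        for a in selected
    }
    right_nodes = {
        a: (
            step.products.nodes[step.atom_map[a]]["element"],
            step.products.nodes[step.atom_map[a]]["charge"],
        )
        for a in selected
    }
    left_edges = {}
    for u, v, d in step.educts.subgraph(selected).edges(data=True):
        e = (u, v) if str(u) <= str(v) else (v, u)
        left_edges[e] = d["order"]
    right_edges = {}
    sel_products = {step.atom_map[a] for a in selected}
    for pu, pv, d in step.products.subgraph(sel_products).edges(data=True):
        u, v = inv[pu], inv[pv]
        e = (u, v) if str(u) <= str(v) else (v, u)
        right_edges[e] = d["order"]

    # every connected piece of L must contain a center atom, otherwise a
    # dropped molecule leaked into the context
    lg = nx.Graph()
    lg.add_nodes_from(selected)
    lg.add_edges_from(left_edges)
    for comp in nx.connected_components(lg):
        if not comp & center.atoms:
            raise StepError(
                "context component without reaction-center atom "
                f"(atoms {sorted(map(str, comp))}): dropped-molecule bookkeeping bug"
            )

    rid = rule_id or (
        f"{step.mechanism_id or 'step'}:{step.step_index}"
    )
    rule = Rule(
        rule_id=rid,
        left_nodes=left_nodes,
        right_nodes=right_nodes,
        left_edges=left_edges,
        right_edges=right_edges,
        provenance={
            "mechanism": step.mechanism_id,
            "step": step.step_index,
            "process": ",".join(step.tags),
            "context_attribution": {
                str(a): tuple(sorted(r)) for a, r in sorted(
                    attribution.items(), key=lambda x: str(x[0])
                )
            },
        },
    )
    report = validate_rule(rule)
    if not report.ok:
        raise StepError(
            "extracted rule fails validation: " + "; ".join(report.violations)
        )
    return rule


# ---------------------------------------------------------------------------
# Atom tracking across a mechanism
# ---------------------------------------------------------------------------

@dataclass
class TrackReport:
    ok: bool
    excluded: bool
    repairs: list[str]
    steps: list[ReactionStep]


def _component_keys(g: nx.Graph) -> Counter:
    return Counter(m.key for m in _graph_to_state(g).molecules())


def _add_spectator(step: ReactionStep, mol: MolGraph, n: int) -> ReactionStep:
    """Return a copy of ``step`` with ``mol`` added untouched to both sides."""
    educts = step.educts.copy()
    products = step.products.copy()
    atom_map = dict(step.atom_map)
    prefix = f"sp{n}"
    for a, d in mol.graph.nodes(data=True):
        eid, pid = f"{prefix}e{a}", f"{prefix}p{a}"
        educts.add_node(eid, **dict(d))
        products.add_node(pid, **dict(d))
        atom_map[eid] = pid
    for u, v, d in mol.graph.edges(data=True):
        educts.add_edge(f"{prefix}e{u}", f"{prefix}e{v}", order=d["order"])
        products.add_edge(f"{prefix}p{u}", f"{prefix}p{v}", order=d["order"])
    return ReactionStep(
        educts=educts,
        products=products,
        atom_map=atom_map,
        mechanism_id=step.mechanism_id,
        step_index=step.step_index,
        tags=step.tags,
        radical=step.radical,
    )


def track_atoms(steps: Sequence[ReactionStep]) -> TrackReport:
    """Sanity-check a mechanism by tracking molecules across its steps.

    Consecutive steps must chain: step i's product composition must equal
    step i+1's educt composition at whole-molecule granularity.  Molecules
    present on one side only are propagated as untouched spectators when
    that reconciles the chain; a mechanism with a genuinely unbalanced
    step, or one that still fails to chain after repair, is excluded.
    """
    steps = list(steps)
    repairs: list[str] = []
    for s in steps:
        if (
            not s.is_bijective()
            or _elements_of(s.educts) != _elements_of(s.products)
        ):
            return TrackReport(
                ok=False,
                excluded=True,
                repairs=[
                    f"step {s.step_index}: unbalanced (atom map is not a "
                    "bijection between sides)"
                ],
                steps=steps,
            )

    counter = 0
    changed = True
    sweep = 0
    while changed and sweep < 2 * len(steps) + 2:
        changed = False
        sweep += 1
        for i in range(len(steps) - 1):
            prod = _graph_to_state(steps[i].products)
            educ = _graph_to_state(steps[i + 1].educts)
            pk, ek = Counter(prod.counts()), Counter(educ.counts())
            missing_next = pk - ek  # in i's products, absent from i+1's educts
            missing_prev = ek - pk  # in i+1's educts, absent from i's products
            if missing_next and missing_prev:
                # the two steps disagree about the same matter: a molecule
                # was transformed without a step accounting for it; adding
                # spectators would double-count atoms, so give up
                return TrackReport(
                    ok=False,
                    excluded=True,
                    repairs=repairs
                    + [
                        f"steps {steps[i].step_index} -> "
                        f"{steps[i + 1].step_index}: two-sided molecule "
                        "mismatch, not repairable by spectator propagation"
                    ],
                    steps=steps,
                )
            for key, n in sorted(missing_next.items()):
                mol = prod.instance(key, 0)
                for _ in range(n):
                    steps[i + 1] = _add_spectator(steps[i + 1], mol, counter)
                    counter += 1
                repairs.append(
                    f"step {steps[i + 1].step_index}: propagated {n} "
                    f"spectator molecule(s) forward from step "
                    f"{steps[i].step_index}"
                )
                changed = True
            for key, n in sorted(missing_prev.items()):
                mol = educ.instance(key, 0)
                for j in range(i, -1, -1):
                    for _ in range(n):
                        steps[j] = _add_spectator(steps[j], mol, counter)
                        counter += 1
                repairs.append(
                    f"steps <= {steps[i].step_index}: propagated {n} "
                    f"spectator molecule(s) backward from step "
                    f"{steps[i + 1].step_index}"
                )
                changed = True

    for i in range(len(steps) - 1):
        if Counter(_component_keys(steps[i].products)) != Counter(
            _component_keys(steps[i + 1].educts)
        ):
            return TrackReport(
                ok=False,
                excluded=True,
                repairs=repairs
                + [
                    f"steps {steps[i].step_index} -> {steps[i + 1].step_index}: "
                    "compositions still differ after spectator propagation"
                ],
                steps=steps,
            )
    return TrackReport(ok=True, excluded=False, repairs=repairs, steps=steps)


def _elements_of(g: nx.Graph) -> Counter:
    return Counter(d["element"] for _, d in g.nodes(data=True))


# ---------------------------------------------------------------------------
# Step and pattern I/O
# ---------------------------------------------------------------------------

def load_step(source: "str | Path | Mapping") -> ReactionStep:
    """Load a step from a JSON bundle (path, JSON text or mapping).

    Keys: ``educt_gml``, ``product_gml``, ``atom_map`` (list of id pairs),
    optional ``annotations`` (educt node id -> residue string), ``flags``
    (``{"radical": bool}``), ``tags``, ``mechanism_id``, ``step_index``.
    """
    if isinstance(source, Mapping):
        data = source
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and not source.lstrip().startswith(("{", "["))
    ):
        data = json.loads(Path(source).read_text())
    else:
        data = json.loads(str(source))
    educts = parse_graph(data["educt_gml"])
    products = parse_graph(data["product_gml"])
    atom_map = {u: v for u, v in data["atom_map"]}
    for key, residue in (data.get("annotations") or {}).items():
        nid = int(key) if str(key).lstrip("-").isdigit() else key
        if nid not in educts:
            raise StepError(f"annotation references unknown atom {key!r}")
        educts.nodes[nid]["residue"] = str(residue)
        if nid in atom_map:
            products.nodes[atom_map[nid]]["residue"] = str(residue)
    return ReactionStep(
        educts=educts,
        products=products,
        atom_map=atom_map,
        mechanism_id=str(data.get("mechanism_id", "")),
        step_index=int(data.get("step_index", 0)),
        tags=tuple(data.get("tags", ())),
        radical=bool((data.get("flags") or {}).get("radical", False)),
    )


def save_step(step: ReactionStep) -> dict:
    """Serialize a step to the JSON bundle format of :func:`load_step`."""
    annotations = {
        str(a): d["residue"]
        for a, d in step.educts.nodes(data=True)
        if d.get("residue")
    }
    return {
        "educt_gml": write_graph(step.educts),
        "product_gml": write_graph(step.products),
        "atom_map": [[u, v] for u, v in sorted(step.atom_map.items(), key=lambda x: str(x[0]))],
        "annotations": annotations,
        "flags": {"radical": step.radical},
        "tags": list(step.tags),
        "mechanism_id": step.mechanism_id,
        "step_index": step.step_index,
    }


def load_patterns(directory: "str | Path") -> list[FunctionalPattern]:
    """Load a pattern library: a directory of GML patterns with a
    ``manifest.json`` of ``{"patterns": [{"name": ..., "file": ...}]}``."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    out = []
    for entry in manifest["patterns"]:
        g = parse_graph(
            (directory / entry["file"]).read_text(), allow_wildcard=True
        )
        out.append(FunctionalPattern(name=entry["name"], graph=g))
    return out
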