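"""Double-pushout rewriting of chemical states.

A rule is an atom-conserving span ``L <- K -> R`` over a single shared node
set: the injections are identities after identifying atoms across sides, so
a rule is stored as left/right attributes (element, charge) and left/right
edge sets over common node ids.  Elements never change; only charges and
bonds may.  The *action* is the minimal sub-rule (changed charges plus
broken/formed/re-ordered bonds); every invariant node or bond refines the
action as *context*.

Because rules neither create nor delete atoms, the DPO dangling condition
reduces to a parallel-bond check: a match is rejected if forming an R-bond
would create a second bond between an atom pair already bonded in the host.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from networkx.algorithms import isomorphism as nxiso

from .chemgraph import (
    BOND_ORDERS,
    ChemGraphError,
    MolGraph,
    ParseError,
    State,
    format_label,
    parse_gml,
    parse_label,
)

__all__ = [
    "Rule",
    "Match",
    "Transition",
    "RuleError",
    "StaleMatchError",
    "ValidationReport",
    "parse_rule",
    "write_rule",
    "validate_rule",
    "invert_rule",
    "find_matches",
    "apply_rule",
    "derive_all",
]


class RuleError(ChemGraphError):
    """Structurally invalid rule."""


class StaleMatchError(ChemGraphError):
    """Match does not fit the state it is applied to."""


def _norm_edge(u, v):
    return (u, v) if str(u) <= str(v) else (v, u)


@dataclass(frozen=True)
class Rule:
    """An atom-conserving DPO rule over a shared node set.

    ``left_nodes``/``right_nodes`` map node id -> (element, charge);
    ``left_edges``/``right_edges`` map a normalized node pair -> bond order.
    """

    rule_id: str
    left_nodes: Mapping[object, tuple[str, int]]
    right_nodes: Mapping[object, tuple[str, int]]
    left_edges: Mapping[tuple, str]
    right_edges: Mapping[tuple, str]
    provenance: Mapping[str, object] = field(default_factory=dict)

    # -- derived views -----------------------------------------------------

    @property
    def nodes(self) -> tuple:
        return tuple(sorted(self.left_nodes, key=str))

    def charge_changes(self) -> dict:
        """node -> (left charge, right charge) for nodes whose charge flips."""
        return {
            v: (self.left_nodes[v][1], self.right_nodes[v][1])
            for v in self.left_nodes
            if self.left_nodes[v][1] != self.right_nodes[v][1]
        }

    def bond_changes(self) -> dict:
        """edge -> (left order or None, right order or None) for changed bonds."""
        out = {}
        for e in set(self.left_edges) | set(self.right_edges):
            lo = self.left_edges.get(e)
            ro = self.right_edges.get(e)
            if lo != ro:
                out[e] = (lo, ro)
        return out

    def action_nodes(self) -> set:
        """The reaction center: atoms with a charge change or an incident
        bond change."""
        nodes = set(self.charge_changes())
        for (u, v) in self.bond_changes():
            nodes.add(u)
            nodes.add(v)
        return nodes

    def invariant_nodes(self) -> set:
        return set(self.left_nodes) - self.action_nodes()

    def invariant_edges(self) -> dict:
        return {
            e: o for e, o in self.left_edges.items()
            if self.right_edges.get(e) == o
        }

    def left_graph(self) -> nx.Graph:
        return self._side_graph(self.left_nodes, self.left_edges)

    def right_graph(self) -> nx.Graph:
        return self._side_graph(self.right_nodes, self.right_edges)

    @staticmethod
    def _side_graph(nodes, edges) -> nx.Graph:
        g = nx.Graph()
        for v, (el, ch) in nodes.items():
            g.add_node(v, element=el, charge=ch, residue="", role="")
        for (u, v), o in edges.items():
            g.add_edge(u, v, order=o)
        return g

    def invert(self) -> "Rule":
        """Swap left and right patterns; an involution."""
        prov = dict(self.provenance)
        prov["inverted"] = not prov.get("inverted", False)
        return Rule(
            rule_id=self.rule_id,
            left_nodes=dict(self.right_nodes),
            right_nodes=dict(self.left_nodes),
            left_edges=dict(self.right_edges),
            right_edges=dict(self.left_edges),
            provenance=prov,
        )

    def __repr__(self) -> str:
        return f"<Rule {self.rule_id!r}: {len(self.left_nodes)} atoms>"


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_rule(p: Rule) -> ValidationReport:
    """Check atom conservation, charge balance, simple-graph sides and a
    nonempty action; violations are collected, not raised."""
    v: list[str] = []
    if set(p.left_nodes) != set(p.right_nodes):
        v.append("atom not conserved: node sets of L and R differ")
    else:
        for n in p.left_nodes:
            if p.left_nodes[n][0] != p.right_nodes[n][0]:
                v.append(f"element of atom {n} changes between L and R")
    lq = sum(c for _, c in p.left_nodes.values())
    rq = sum(c for _, c in p.right_nodes.values())
    if lq != rq:
        v.append(f"charge not conserved: L sums to {lq:+d}, R to {rq:+d}")
    for side, nodes, edges in (
        ("L", p.left_nodes, p.left_edges),
        ("R", p.right_nodes, p.right_edges),
    ):
        for (a, b), o in edges.items():
            if a == b:
                v.append(f"{side}: self-loop on atom {a}")
            if a not in nodes or b not in nodes:
                v.append(f"{side}: bond {a}-{b} references undeclared atom")
            if o not in BOND_ORDERS:
                v.append(f"{side}: invalid bond order {o!r} on {a}-{b}")
    if not p.action_nodes():
        v.append("empty action: L and R are identical")
    return ValidationReport(tuple(v))


def invert_rule(p: Rule) -> Rule:
    return p.invert()


# ---------------------------------------------------------------------------
# Rule GML I/O: rule [ ruleID "…" left [ … ] context [ … ] right [ … ] ]
# ---------------------------------------------------------------------------

def parse_rule(text: str) -> Rule:
    """Parse and validate a rule in the left/context/right GML dialect.

    Nodes in ``context`` hold on both sides; a node appearing in ``left``
    must also appear in ``right`` (atom conservation) and may change charge.
    Context edges are invariant; left-only edges are broken, right-only
    edges are formed.
    """
    entries = parse_gml(text)
    rule_entries = [e for e in entries if e[0] == "rule"]
    if len(rule_entries) == 1 and isinstance(rule_entries[0][1], list):
        entries = rule_entries[0][1]
    rule_id = "rule"
    blocks: dict[str, list] = {}
    provenance: dict[str, object] = {}
    for key, value, line in entries:
        if key == "ruleID":
            rule_id = str(value)
        elif key in ("left", "context", "right"):
            if key in blocks:
                raise ParseError(f"duplicate {key!r} block", line)
            if not isinstance(value, list):
                raise ParseError(f"{key!r} must be a block", line)
            blocks[key] = value
        elif key in ("source", "process", "comment", "mechanism", "step"):
            provenance[key] = value
        else:
            raise ParseError(f"unexpected key {key!r} in rule", line)
    for want in ("left", "right"):
        blocks.setdefault(want, [])
    blocks.setdefault("context", [])

    def read_block(block):
        nodes: dict[object, tuple[str, int]] = {}
        edges: dict[tuple, str] = {}
        for key, value, line in block:
            fields = {k: v for k, v, _ in value} if isinstance(value, list) else {}
            if key == "node":
                if "id" not in fields or "label" not in fields:
                    raise ParseError("node needs 'id' and 'label'", line)
                nid = fields["id"]
                if nid in nodes:
                    raise ParseError(f"duplicate node id {nid}", line)
                el, ch = parse_label(str(fields["label"]), line=line)
                nodes[nid] = (el, ch)
            elif key == "edge":
                for want in ("source", "target", "label"):
                    if want not in fields:
                        raise ParseError(f"edge needs '{want}'", line)
                o = str(fields["label"])
                if o not in BOND_ORDERS:
                    raise ParseError(f"unknown bond label {o!r}", line)
                e = _norm_edge(fields["source"], fields["target"])
                if e[0] == e[1]:
                    raise ParseError(f"self-loop on node {e[0]}", line)
                if e in edges:
                    raise ParseError(f"duplicate bond {e[0]}-{e[1]}", line)
                edges[e] = o
            else:
                raise ParseError(f"unexpected key {key!r} in rule block", line)
        return nodes, edges

    ln, le = read_block(blocks["left"])
    cn, ce = read_block(blocks["context"])
    rn, re_ = read_block(blocks["right"])

    for nid in cn:
        if nid in ln or nid in rn:
            raise RuleError(
                f"node {nid} declared both in context and in left/right"
            )
    if set(ln) != set(rn):
        missing = set(ln) ^ set(rn)
        raise RuleError(
            "atom conservation violated: node(s) "
            f"{sorted(map(str, missing))} present on only one side"
        )
    for e in ce:
        if e in le or e in re_:
            raise RuleError(f"edge {e} declared both in context and in left/right")

    left_nodes = {**cn, **ln}
    right_nodes = {**cn, **rn}
    left_edges = {**ce, **le}
    right_edges = {**ce, **re_}
    for side_edges, side_nodes, side in (
        (left_edges, left_nodes, "left"),
        (right_edges, right_nodes, "right"),
    ):
        for (a, b) in side_edges:
            if a not in side_nodes or b not in side_nodes:
                raise RuleError(f"{side} bond {a}-{b} references undeclared atom")

    rule = Rule(
        rule_id=rule_id,
        left_nodes=left_nodes,
        right_nodes=right_nodes,
        left_edges=left_edges,
        right_edges=right_edges,
        provenance=provenance,
    )
    report = validate_rule(rule)
    if not report.ok:
        raise RuleError(
            f"rule {rule_id!r} invalid: " + "; ".join(report.violations)
        )
    return rule


def write_rule(p: Rule) -> str:
    """Deterministic serialization in the left/context/right dialect."""
    changes = p.charge_changes()
    bond = p.bond_changes()
    ctx_nodes = [v for v in p.nodes if v not in changes]
    chg_nodes = [v for v in p.nodes if v in changes]
    lines = ["rule [", f'  ruleID "{p.rule_id}"']
    for k in sorted(p.provenance):
        # only scalar provenance survives serialization (derived bookkeeping
        # such as per-atom context attribution stays in memory)
        if k == "inverted" or not isinstance(p.provenance[k], (str, int)):
            continue
        lines.append(f'  {k} "{p.provenance[k]}"')
    if p.provenance.get("inverted"):
        lines.append('  comment "inverted"')

    def node_line(v, nodes, indent="    "):
        el, ch = nodes[v]
        return f'{indent}node [ id {v} label "{format_label(el, ch)}" ]'

    def edge_line(e, o, indent="    "):
        return f'{indent}edge [ source {e[0]} target {e[1]} label "{o}" ]'

    lines.append("  left [")
    for v in chg_nodes:
        lines.append(node_line(v, p.left_nodes))
    for e in sorted(bond, key=lambda e: (str(e[0]), str(e[1]))):
        if bond[e][0] is not None:
            lines.append(edge_line(e, bond[e][0]))
    lines.append("  ]")
    lines.append("  context [")
    for v in ctx_nodes:
        lines.append(node_line(v, p.left_nodes))
    for e in sorted(p.invariant_edges(), key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(edge_line(e, p.left_edges[e]))
    lines.append("  ]")
    lines.append("  right [")
    for v in chg_nodes:
        lines.append(node_line(v, p.right_nodes))
    for e in sorted(bond, key=lambda e: (str(e[0]), str(e[1]))):
        if bond[e][1] is not None:
            lines.append(edge_line(e, bond[e][1]))
    lines.append("  ]")
    lines.append("]")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Match:
    """An injective, label-respecting embedding of a rule's L into the
    instance-expanded atoms of a state.

    ``mapping`` sends each rule node to a host atom ``(molecule key,
    instance index, atom id)``.
    """

    rule: Rule
    mapping: Mapping[object, tuple[str, int, object]]

    @property
    def digest(self) -> str:
        parts = [
            f"{v}>{k}[{i}].{a}"
            for v, (k, i, a) in sorted(self.mapping.items(), key=lambda x: str(x[0]))
        ]
        return ";".join(parts)

    def touched_instances(self) -> set[tuple[str, int]]:
        return {(k, i) for (k, i, _) in self.mapping.values()}


def _expand_state(g: State) -> nx.Graph:
    """Disjoint union of all molecule instances; nodes are
    (key, instance, atom) triples carrying the atom attributes."""
    host = nx.Graph()
    for key, idx, mol in g.instances():
        for a, d in mol.graph.nodes(data=True):
            host.add_node((key, idx, a), **d)
        for u, v, d in mol.graph.edges(data=True):
            host.add_edge((key, idx, u), (key, idx, v), order=d["order"])
    return host


def _node_match(host_attrs, patt_attrs) -> bool:
    if host_attrs["element"] != patt_attrs["element"]:
        return False
    pc = patt_attrs["charge"]
    return pc is None or host_attrs["charge"] == pc


def _edge_match(host_attrs, patt_attrs) -> bool:
    return host_attrs["order"] == patt_attrs["order"]


def _component_matches(host: nx.Graph, comp: nx.Graph) -> list[dict]:
    """All monomorphisms of one connected pattern component into the host,
    as pattern-node -> host-node dicts, deterministically ordered."""
    gm = nxiso.GraphMatcher(host, comp, node_match=_node_match, edge_match=_edge_match)
    comp_nodes = sorted(comp.nodes, key=str)
    out = []
    for m in gm.subgraph_monomorphisms_iter():
        inv = {pv: hv for hv, pv in m.items()}
        out.append(inv)
    out.sort(key=lambda m: tuple(str(m[v]) for v in comp_nodes))
    return out


def find_matches(p: Rule, g: State) -> list[Match]:
    """Enumerate all matches of ``p``'s left pattern in state ``g``.

    Embeddings may span multiple molecule instances (including distinct
    copies of the same molecule type).  Matches whose application would
    create a parallel bond are excluded.  Matches related by an
    automorphism of L are kept; state-level deduplication happens in
    :func:`derive_all`.  The result order is deterministic.
    """
    host = _expand_state(g)
    left = p.left_graph()
    components = sorted(
        (left.subgraph(c).copy() for c in nx.connected_components(left)),
        key=lambda c: (-c.number_of_nodes(), min(str(v) for v in c.nodes)),
    )
    per_comp = []
    for comp in components:
        ms = _component_matches(host, comp)
        if not ms:
            return []
        per_comp.append(ms)

    matches: list[Match] = []

    def combine(i: int, used: set, acc: dict):
        if i == len(per_comp):
            matches.append(Match(rule=p, mapping=dict(acc)))
            return
        for m in per_comp[i]:
            image = set(m.values())
            if image & used:
                continue
            acc.update(m)
            combine(i + 1, used | image, acc)
            for k in m:
                del acc[k]

    combine(0, set(), {})

    # parallel-bond (gluing) check: forming an R-only bond between host
    # atoms that are already bonded outside the match image is invalid
    valid = []
    for m in matches:
        ok = True
        for (u, v), (lo, ro) in p.bond_changes().items():
            if lo is None and ro is not None:
                hu, hv = m.mapping[u], m.mapping[v]
                if host.has_edge(hu, hv):
                    ok = False
                    break
        if ok:
            valid.append(m)
    valid.sort(key=lambda m: m.digest)
    return valid


def _check_match(p: Rule, m: Match, g: State) -> None:
    counts = g.counts()
    for v, (key, idx, atom) in m.mapping.items():
        if counts.get(key, 0) <= idx:
            raise StaleMatchError(f"match references missing molecule {key}[{idx}]")
        mol = g.instance(key, idx)
        if atom not in mol.graph.nodes:
            raise StaleMatchError(f"match references missing atom {atom}")
        el, ch = p.left_nodes[v]
        d = mol.graph.nodes[atom]
        if d["element"] != el or d["charge"] != ch:
            raise StaleMatchError(
                f"atom {atom} no longer matches pattern node {v}"
            )
    for (u, v), o in p.left_edges.items():
        ku, iu, au = m.mapping[u]
        kv, iv, av = m.mapping[v]
        if (ku, iu) != (kv, iv):
            continue
        mol = g.instance(ku, iu)
        if not mol.graph.has_edge(au, av) or mol.graph.edges[au, av]["order"] != o:
            raise StaleMatchError(f"bond {u}-{v} no longer matches")


def apply_rule(p: Rule, m: Match, g: State) -> State:
    """Apply rule ``p`` at match ``m``: delete L-only bonds, form R-only
    bonds, rewrite orders and charges, re-partition into molecules.

    Untouched molecule instances (and their canonical keys) carry over;
    atom annotations propagate through the rewrite.  The composition
    vector is preserved by construction.
    """
    _check_match(p, m, g)
    touched = m.touched_instances()

    # rebuild only the touched instances
    sub = nx.Graph()
    for (key, idx) in touched:
        mol = g.instance(key, idx)
        for a, d in mol.graph.nodes(data=True):
            sub.add_node((key, idx, a), **dict(d))
        for u, v, d in mol.graph.edges(data=True):
            sub.add_edge((key, idx, u), (key, idx, v), order=d["order"])

    for v, (lq, rq) in p.charge_changes().items():
        sub.nodes[m.mapping[v]]["charge"] = rq
    for (u, v), (lo, ro) in p.bond_changes().items():
        hu, hv = m.mapping[u], m.mapping[v]
        if lo is not None and ro is None:
            sub.remove_edge(hu, hv)
        elif lo is None and ro is not None:
            sub.add_edge(hu, hv, order=ro)
        else:
            sub.edges[hu, hv]["order"] = ro

    mols: list[MolGraph] = []
    for key, idx, mol in g.instances():
        if (key, idx) not in touched:
            mols.append(mol)
    for comp in nx.connected_components(sub):
        index = {n: i for i, n in enumerate(sorted(comp, key=str))}
        cg = nx.Graph()
        for n, i in index.items():
            cg.add_node(i, **dict(sub.nodes[n]))
        for u, v, d in sub.subgraph(comp).edges(data=True):
            cg.add_edge(index[u], index[v], order=d["order"])
        mols.append(MolGraph(cg))
    return State(mols)


@dataclass(frozen=True)
class Transition:
    """A direct derivation between states, with rule/match witnesses."""

    source: str
    target: str
    witnesses: tuple[tuple[str, str], ...]  # (rule_id, match digest)
    target_state: State | None = None

    def __repr__(self) -> str:
        return f"<Transition {len(self.witnesses)} witness(es)>"


def derive_all(rules: Sequence[Rule], g: State) -> list[Transition]:
    """All one-step derivations from ``g``, one Transition per distinct
    target state key, witnesses aggregated, ordered by target key."""
    targets: dict[str, State] = {}
    witnesses: dict[str, list[tuple[str, str]]] = {}
    for p in rules:
        for m in find_matches(p, g):
            h = apply_rule(p, m, g)
            targets.setdefault(h.key, h)
            witnesses.setdefault(h.key, []).append((p.rule_id, m.digest))
    return [
        Transition(
            source=g.key,
            target=k,
            witnesses=tuple(sorted(set(witnesses[k]))),
            target_state=targets[k],
        )
        for k in sorted(targets)
    ]
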