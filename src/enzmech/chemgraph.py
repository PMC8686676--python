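"""Chemical graph model: molecules, states, canonical keys and GML-dialect I/O.

Molecules are connected, simple, undirected graphs.  A node is an atom
carrying a chemical element symbol and an integer formal charge; an edge is
a bond carrying one of four orders (single ``-``, double ``=``, triple
``#``, aromatic ``:``).  Hydrogens are always explicit atoms: the model
never infers implicit hydrogens.  A *state* is a multiset of molecules --
the "test tube" in which rewriting takes place; its atomic composition is
invariant under every operation defined in this package.

Atoms may additionally carry a *residue* annotation (e.g. ``"His#1"``) and
a free-form *role* tag.  Annotations ride along through rewriting but never
influence matching or canonical keys unless explicitly requested.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "BOND_ORDERS",
    "MAX_ABS_CHARGE",
    "ChemGraphError",
    "ParseError",
    "MolGraph",
    "State",
    "parse_molecule",
    "parse_graph",
    "write_molecule",
    "canonical_key",
    "state_union",
    "state_embeds",
    "parse_state_manifest",
    "format_label",
    "parse_label",
]

#: The four bond orders of the model, in increasing precedence order.
BOND_ORDERS = ("-", "=", "#", ":")

#: Formal charges outside this magnitude are rejected as encoding errors.
MAX_ABS_CHARGE = 4

_ELEMENT_RE = re.compile(r"^[A-Z][a-z]?[a-z]?$")


class ChemGraphError(ValueError):
    """Invalid chemical graph or state."""


class ParseError(ChemGraphError):
    """Malformed GML-dialect text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Atom labels: element symbol plus charge suffix ("N+", "O-", "Fe2+", "C").
# A trailing "*" denotes a charge wildcard (patterns only, charge=None).
# ---------------------------------------------------------------------------

def format_label(element: str, charge: int | None) -> str:
    if charge is None:
        return element + "*"
    if charge == 0:
        return element
    sign = "+" if charge > 0 else "-"
    mag = abs(charge)
    return element + (sign if mag == 1 else f"{mag}{sign}")


def parse_label(label: str, *, allow_wildcard: bool = False, line: int | None = None):
    """Split an atom label into ``(element, charge)``; charge ``None`` = wildcard."""
    m = re.fullmatch(r"([A-Z][a-z]{0,2})(?:(\d*)([+-])|(\*))?", label)
    if not m:
        raise ParseError(f"malformed atom label {label!r}", line)
    element = m.group(1)
    if m.group(4):
        if not allow_wildcard:
            raise ParseError(f"charge wildcard not allowed here: {label!r}", line)
        return element, None
    if m.group(3):
        mag = int(m.group(2)) if m.group(2) else 1
        charge = mag if m.group(3) == "+" else -mag
    else:
        charge = 0
    if abs(charge) > MAX_ABS_CHARGE:
        raise ParseError(
            f"charge {charge:+d} outside accepted range [-{MAX_ABS_CHARGE}, {MAX_ABS_CHARGE}]",
            line,
        )
    return element, charge


# ---------------------------------------------------------------------------
# GML-dialect tokenizer / parser
# ---------------------------------------------------------------------------

def _tokenize(text: str):
    tokens: list[tuple[str, object, int]] = []  # (kind, value, line)
    i, line, n = 0, 1, len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            i += 1
        elif c in " \t\r":
            i += 1
        elif c == "#":
            while i < n and text[i] != "\n":
                i += 1
        elif c == '"':
            j = text.find('"', i + 1)
            if j < 0:
                raise ParseError("unterminated string", line)
            tokens.append(("str", text[i + 1 : j], line))
            line += text.count("\n", i, j)
            i = j + 1
        elif c in "[]":
            tokens.append((c, c, line))
            i += 1
        else:
            j = i
            while j < n and text[j] not in ' \t\r\n[]"#':
                j += 1
            word = text[i:j]
            try:
                tokens.append(("int", int(word), line))
            except ValueError:
                tokens.append(("id", word, line))
            i = j
    return tokens


def _parse_entries(tokens, pos, depth=0):
    """Parse ``key value`` pairs until ``]`` or end; values may be blocks."""
    entries: list[tuple[str, object, int]] = []
    while pos < len(tokens):
        kind, value, line = tokens[pos]
        if kind == "]":
            if depth == 0:
                raise ParseError("unmatched ']'", line)
            return entries, pos + 1
        if kind != "id":
            raise ParseError(f"expected a key, got {value!r}", line)
        key = value
        pos += 1
        if pos >= len(tokens):
            raise ParseError(f"key {key!r} has no value", line)
        vkind, vvalue, vline = tokens[pos]
        if vkind == "[":
            sub, pos = _parse_entries(tokens, pos + 1, depth + 1)
            entries.append((key, sub, vline))
        elif vkind in ("int", "str", "id"):
            entries.append((key, vvalue, vline))
            pos += 1
        else:
            raise ParseError(f"unexpected {vvalue!r} after key {key!r}", vline)
    if depth:
        raise ParseError("unexpected end of input inside a block", tokens[-1][2])
    return entries, pos


def parse_gml(text: str):
    """Parse GML-dialect text into a nested list of (key, value, line) entries."""
    entries, _ = _parse_entries(_tokenize(text), 0)
    return entries


def _entries_to_nx(entries, *, allow_wildcard=False) -> nx.Graph:
    g = nx.Graph()
    for key, value, line in entries:
        if key == "node":
            if not isinstance(value, list):
                raise ParseError("node must be a block", line)
            fields = {k: v for k, v, _ in value}
            if "id" not in fields or "label" not in fields:
                raise ParseError("node needs 'id' and 'label'", line)
            nid = fields["id"]
            if g.has_node(nid):
                raise ParseError(f"duplicate node id {nid}", line)
            element, charge = parse_label(
                str(fields["label"]), allow_wildcard=allow_wildcard, line=line
            )
            if not _ELEMENT_RE.match(element):
                raise ParseError(f"invalid element symbol {element!r}", line)
            g.add_node(
                nid,
                element=element,
                charge=charge,
                residue=str(fields.get("residue", "")),
                role=str(fields.get("role", "")),
            )
        elif key == "edge":
            if not isinstance(value, list):
                raise ParseError("edge must be a block", line)
            fields = {k: v for k, v, _ in value}
            for want in ("source", "target", "label"):
                if want not in fields:
                    raise ParseError(f"edge needs '{want}'", line)
            u, v, order = fields["source"], fields["target"], str(fields["label"])
            if order not in BOND_ORDERS:
                raise ParseError(
                    f"unknown bond label {order!r} (expected one of {'/'.join(BOND_ORDERS)})",
                    line,
                )
            if u == v:
                raise ParseError(f"self-loop on node {u}", line)
            for x in (u, v):
                if not g.has_node(x):
                    raise ParseError(f"edge endpoint {x} is not a declared node", line)
            if g.has_edge(u, v):
                raise ParseError(f"duplicate bond between {u} and {v}", line)
            g.add_edge(u, v, order=order)
        else:
            raise ParseError(f"unexpected key {key!r} in graph block", line)
    return g


def _unwrap_graph(entries):
    named = [e for e in entries if e[0] in ("graph", "pattern")]
    if len(named) == 1 and isinstance(named[0][1], list):
        return named[0][1]
    return entries


def parse_graph(text: str, *, allow_wildcard: bool = False) -> nx.Graph:
    """Parse a possibly disconnected graph in the GML dialect into networkx."""
    return _entries_to_nx(_unwrap_graph(parse_gml(text)), allow_wildcard=allow_wildcard)


# ---------------------------------------------------------------------------
# Canonical labeling: color refinement + individualization/backtracking
# ---------------------------------------------------------------------------

def _refine(adj, colors):
    """Stable (1-dimensional Weisfeiler-Leman) color refinement."""
    ncolors = len(set(colors.values()))
    while True:
        sigs = {
            v: (colors[v], tuple(sorted((o, colors[u]) for u, o in adj[v])))
            for v in colors
        }
        palette = {s: i for i, s in enumerate(sorted(set(sigs.values())))}
        colors = {v: palette[sigs[v]] for v in sigs}
        if len(palette) == ncolors:
            return colors
        ncolors = len(palette)


def _canonical_form(graph: nx.Graph, attr_of):
    """Exact canonical form of a vertex-attributed, edge-ordered graph.

    Refinement first; on ties, individualize each vertex of the first
    non-singleton color class and take the lexicographically smallest leaf.
    Pendant twins (degree-1 vertices sharing the same neighbor, attributes
    and bond order -- typically the hydrogens of a methyl group) are
    provably automorphic, so only one branch is explored for them.
    """
    nodes = list(graph.nodes)
    adj = {
        v: tuple((u, graph.edges[v, u]["order"]) for u in graph.adj[v]) for v in nodes
    }
    attrs = {v: attr_of(v) for v in nodes}
    palette = {a: i for i, a in enumerate(sorted(set(attrs.values())))}
    init = {v: palette[attrs[v]] for v in nodes}
    best: list = [None]

    def leaf(colors):
        order = sorted(nodes, key=lambda v: colors[v])
        index = {v: i for i, v in enumerate(order)}
        node_sig = tuple(attrs[v] for v in order)
        edge_sig = tuple(
            sorted(
                (min(index[u], index[v]), max(index[u], index[v]), d["order"])
                for u, v, d in graph.edges(data=True)
            )
        )
        return node_sig, edge_sig

    def search(colors):
        colors = _refine(adj, colors)
        cells: dict[int, list] = {}
        for v, c in colors.items():
            cells.setdefault(c, []).append(v)
        target = None
        for c in sorted(cells):
            if len(cells[c]) > 1:
                target = cells[c]
                break
        if target is None:
            form = leaf(colors)
            if best[0] is None or form < best[0]:
                best[0] = form
            return
        target = sorted(target, key=lambda v: str(v))
        first = target[0]
        if all(len(adj[v]) == 1 for v in target):
            nbrs = {(adj[v][0][0], adj[v][0][1]) for v in target}
            if len(nbrs) == 1:  # pendant twins: automorphic, one branch suffices
                target = [first]
        for v in target:
            branched = {u: c * 2 for u, c in colors.items()}
            branched[v] -= 1
            search(branched)

    search(init)
    return best[0]


def _form_to_key(form) -> str:
    node_sig, edge_sig = form
    nodes = ",".join(format_label(el, ch) if extra == "" else
                     format_label(el, ch) + "@" + extra
                     for el, ch, extra in node_sig)
    edges = ",".join(f"{i}~{j}{o}" for i, j, o in edge_sig)
    return nodes + "/" + edges


# ---------------------------------------------------------------------------
# MolGraph and State
# ---------------------------------------------------------------------------

class MolGraph:
    """One molecule: a connected, simple graph of typed atoms and bonds.

    Instances are treated as immutable once constructed; canonical keys are
    cached.  Use :meth:`copy` before mutating the underlying graph.
    """

    def __init__(self, graph: nx.Graph):
        if graph.number_of_nodes() == 0:
            raise ChemGraphError("a molecule must have at least one atom")
        if not nx.is_connected(graph):
            raise ChemGraphError(
                "not a single molecule: graph is disconnected "
                "(use a state manifest for mixtures)"
            )
        for v, d in graph.nodes(data=True):
            el = d.get("element")
            if not el or not _ELEMENT_RE.match(el):
                raise ChemGraphError(f"atom {v}: invalid element {el!r}")
            ch = d.get("charge")
            if ch is None or not isinstance(ch, int) or abs(ch) > MAX_ABS_CHARGE:
                raise ChemGraphError(f"atom {v}: invalid charge {ch!r}")
            d.setdefault("residue", "")
            d.setdefault("role", "")
        for u, v, d in graph.edges(data=True):
            if u == v:
                raise ChemGraphError(f"self-loop on atom {u}")
            if d.get("order") not in BOND_ORDERS:
                raise ChemGraphError(f"bond {u}-{v}: invalid order {d.get('order')!r}")
        self.graph = graph
        self._key: str | None = None
        self._annotated_key: str | None = None
        self._order: list | None = None

    # -- factories ---------------------------------------------------------

    @classmethod
    def from_atoms(
        cls,
        atoms: Sequence[tuple],
        bonds: Sequence[tuple],
    ) -> "MolGraph":
        """Build from ``atoms = [(id, element, charge[, residue])]`` and
        ``bonds = [(u, v, order)]``."""
        g = nx.Graph()
        for atom in atoms:
            aid, element, charge = atom[0], atom[1], atom[2]
            residue = atom[3] if len(atom) > 3 else ""
            g.add_node(aid, element=element, charge=charge, residue=residue, role="")
        for u, v, order in bonds:
            g.add_edge(u, v, order=order)
        return cls(g)

    def copy(self) -> "MolGraph":
        return MolGraph(self.graph.copy())

    # -- basic queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    def total_charge(self) -> int:
        return sum(d["charge"] for _, d in self.graph.nodes(data=True))

    def composition(self) -> tuple[tuple[tuple[str, int], ...], int]:
        """Element multiset plus summed formal charge; serialization-stable."""
        counts = Counter(d["element"] for _, d in self.graph.nodes(data=True))
        return tuple(sorted(counts.items())), self.total_charge()

    def with_residue(self, residue: str) -> "MolGraph":
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d["residue"] = residue
        return MolGraph(g)

    # -- canonicalization --------------------------------------------------

    def _attr(self, include_residue: bool):
        if include_residue:
            return lambda v: (
                self.graph.nodes[v]["element"],
                self.graph.nodes[v]["charge"],
                self.graph.nodes[v]["residue"],
            )
        return lambda v: (
            self.graph.nodes[v]["element"],
            self.graph.nodes[v]["charge"],
            "",
        )

    def canonical_order(self) -> list:
        """Atom ids in canonical serialization order."""
        if self._order is None:
            form = _canonical_form(self.graph, self._attr(False))
            self._key = _form_to_key(form)
            order = self._search_order(form)
            if order is None:  # pragma: no cover - canonical search is exhaustive
                raise ChemGraphError("internal error: canonical order not found")
            self._order = order
        return self._order

    def _search_order(self, form):
        graph = self.graph
        nodes = list(graph.nodes)
        adj = {
            v: tuple((u, graph.edges[v, u]["order"]) for u in graph.adj[v])
            for v in nodes
        }
        attr = self._attr(False)
        attrs = {v: attr(v) for v in nodes}
        palette = {a: i for i, a in enumerate(sorted(set(attrs.values())))}
        init = {v: palette[attrs[v]] for v in nodes}
        found: list = [None]

        def leaf(colors):
            order = sorted(nodes, key=lambda v: colors[v])
            index = {v: i for i, v in enumerate(order)}
            node_sig = tuple(attrs[v] for v in order)
            edge_sig = tuple(
                sorted(
                    (min(index[u], index[v]), max(index[u], index[v]), d["order"])
                    for u, v, d in graph.edges(data=True)
                )
            )
            return (node_sig, edge_sig), order

        def search(colors):
            if found[0] is not None:
                return
            colors = _refine(adj, colors)
            cells: dict[int, list] = {}
            for v, c in colors.items():
                cells.setdefault(c, []).append(v)
            target = None
            for c in sorted(cells):
                if len(cells[c]) > 1:
                    target = cells[c]
                    break
            if target is None:
                f, order = leaf(colors)
                if f == form:
                    found[0] = order
                return
            target = sorted(target, key=lambda v: str(v))
            if all(len(adj[v]) == 1 for v in target):
                nbrs = {(adj[v][0][0], adj[v][0][1]) for v in target}
                if len(nbrs) == 1:
                    target = [target[0]]
            for v in target:
                branched = {u: c * 2 for u, c in colors.items()}
                branched[v] -= 1
                search(branched)
                if found[0] is not None:
                    return

        search(init)
        return found[0]

    @property
    def key(self) -> str:
        """Canonical key: equal iff graphs are isomorphic respecting element,
        charge and bond order.  Residue/role annotations are excluded."""
        if self._key is None:
            self._key = _form_to_key(_canonical_form(self.graph, self._attr(False)))
        return self._key

    def annotated_key(self) -> str:
        """Canonical key that additionally respects residue annotations."""
        if self._annotated_key is None:
            self._annotated_key = _form_to_key(
                _canonical_form(self.graph, self._attr(True))
            )
        return self._annotated_key

    def is_isomorphic(self, other: "MolGraph") -> bool:
        return self.key == other.key

    def __repr__(self) -> str:
        return f"<MolGraph {self.n_atoms} atoms, {self.n_bonds} bonds>"


class State:
    """A multiset of molecules; the context in which rules are applied.

    One graph is stored per molecule *instance* so that per-copy residue
    annotations survive; the canonical state key depends only on molecule
    keys and counts.
    """

    def __init__(self, molecules: Iterable[MolGraph] = ()):
        self._mols: dict[str, list[MolGraph]] = {}
        for m in molecules:
            self._mols.setdefault(m.key, []).append(m)
        self._key: str | None = None

    @property
    def key(self) -> str:
        if self._key is None:
            parts = [f"{len(v)}*{k}" for k, v in sorted(self._mols.items())]
            self._key = "&".join(parts)
        return self._key

    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self._mols.items()}

    def molecules(self) -> Iterator[MolGraph]:
        """All molecule instances, ordered by canonical key then insertion."""
        for k in sorted(self._mols):
            yield from self._mols[k]

    def instances(self) -> Iterator[tuple[str, int, MolGraph]]:
        for k in sorted(self._mols):
            for i, m in enumerate(self._mols[k]):
                yield k, i, m

    def instance(self, key: str, idx: int) -> MolGraph:
        return self._mols[key][idx]

    @property
    def n_molecules(self) -> int:
        return sum(len(v) for v in self._mols.values())

    @property
    def n_atoms(self) -> int:
        return sum(m.n_atoms for m in self.molecules())

    def composition(self) -> tuple[tuple[tuple[str, int], ...], int]:
        counts: Counter = Counter()
        charge = 0
        for m in self.molecules():
            c, q = m.composition()
            counts.update(dict(c))
            charge += q
        return tuple(sorted(counts.items())), charge

    def is_empty(self) -> bool:
        return not self._mols

    def __eq__(self, other) -> bool:
        return isinstance(other, State) and self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __repr__(self) -> str:
        return f"<State {self.n_molecules} molecules, {self.n_atoms} atoms>"


def state_union(states: Iterable[State]) -> State:
    """Disjoint union of states; counts add per molecule key.

    Commutative and associative; the empty state is the identity.
    """
    mols: list[MolGraph] = []
    for s in states:
        mols.extend(s.molecules())
    return State(mols)


def state_embeds(a: State, g: State) -> bool:
    """Whole-molecule multiset inclusion: every molecule of ``a`` occurs in
    ``g`` with at least the same count."""
    gc = g.counts()
    return all(n <= gc.get(k, 0) for k, n in a.counts().items())


def canonical_key(x: "MolGraph | State", *, include_residue: bool = False) -> str:
    """Canonical key of a molecule or state.

    Key equality is exactly isomorphism respecting element, charge and bond
    order; for states, equality of the molecule-key multiset.  With
    ``include_residue`` the key also distinguishes residue annotations.
    """
    if isinstance(x, MolGraph):
        return x.annotated_key() if include_residue else x.key
    if isinstance(x, State):
        if not include_residue:
            return x.key
        parts = sorted(f"{m.annotated_key()}" for m in x.molecules())
        counted = Counter(parts)
        return "&".join(f"{n}*{k}" for k, n in sorted(counted.items()))
    raise TypeError(f"cannot canonicalize {type(x).__name__}")


# ---------------------------------------------------------------------------
# Molecule / state I/O
# ---------------------------------------------------------------------------

def parse_molecule(text: str) -> MolGraph:
    """Parse a single connected molecule from GML-dialect text.

    Raises :class:`ParseError` with a line number on malformed syntax and
    :class:`ChemGraphError` if the graph is disconnected.
    """
    return MolGraph(parse_graph(text))


def write_molecule(m: MolGraph) -> str:
    """Serialize a molecule deterministically (canonical atom order).

    ``parse_molecule(write_molecule(m))`` is isomorphic to ``m``; isomorphic
    inputs serialize byte-identically (annotations excluded from ordering).
    """
    order = m.canonical_order()
    index = {v: i for i, v in enumerate(order)}
    lines = ["graph ["]
    for v in order:
        d = m.graph.nodes[v]
        label = format_label(d["element"], d["charge"])
        extra = ""
        if d.get("residue"):
            extra += f' residue "{d["residue"]}"'
        if d.get("role"):
            extra += f' role "{d["role"]}"'
        lines.append(f'  node [ id {index[v]} label "{label}"{extra} ]')
    edges = sorted(
        (min(index[u], index[v]), max(index[u], index[v]), d["order"])
        for u, v, d in m.graph.edges(data=True)
    )
    for i, j, o in edges:
        lines.append(f'  edge [ source {i} target {j} label "{o}" ]')
    lines.append("]")
    return "\n".join(lines) + "\n"


def write_graph(g: nx.Graph) -> str:
    """Serialize a possibly disconnected graph (ids kept as-is, sorted)."""
    lines = ["graph ["]
    for v in sorted(g.nodes, key=str):
        d = g.nodes[v]
        label = format_label(d["element"], d["charge"])
        extra = ""
        if d.get("residue"):
            extra += f' residue "{d["residue"]}"'
        lines.append(f'  node [ id {v} label "{label}"{extra} ]')
    for u, v, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(f'  edge [ source {u} target {v} label "{d["order"]}" ]')
    lines.append("]")
    return "\n".join(lines) + "\n"


def parse_state_manifest(text: str, base_dir: "str | Path | None" = None) -> State:
    """Read a state from a JSON manifest: a list of ``{"file": path,
    "count": n}`` or ``{"gml": inline-text, "count": n}`` entries."""
    try:
        items = json.loads(text)
    except json.JSONDecodeError as e:
        raise ChemGraphError(f"state manifest is not valid JSON: {e}") from e
    if not isinstance(items, list):
        raise ChemGraphError("state manifest must be a JSON list")
    mols: list[MolGraph] = []
    for item in items:
        if not isinstance(item, Mapping):
            raise ChemGraphError("manifest entries must be objects")
        count = item.get("count", 1)
        if not isinstance(count, int) or count < 1:
            raise ChemGraphError(f"invalid count {count!r}")
        if "gml" in item:
            m = parse_molecule(item["gml"])
        elif "file" in item:
            path = Path(item["file"])
            if base_dir is not None and not path.is_absolute():
                path = Path(base_dir) / path
            m = parse_molecule(path.read_text())
        else:
            raise ChemGraphError("manifest entry needs 'file' or 'gml'")
        if "residue" in item:
            m = m.with_residue(str(item["residue"]))
        for _ in range(count):
            mols.append(m.copy() if count > 1 else m)
    return State(mols)


def state_manifest(s: State) -> list[dict]:
    """Inverse of :func:`parse_state_manifest`, using inline GML."""
    out = []
    for k, n in sorted(s.counts().items()):
        rep = s.instance(k, 0)
        out.append({"gml": write_molecule(rep), "count": n})
    return out
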