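"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's canonicalization, VF2 matching and
BFS machinery: isomorphism is decided by permutation search, matching by
exhaustive assignment, spaces by a naive set-closure loop and paths by
plain recursive DFS.
"""

from __future__ import annotations

import itertools

from enzmech.chemgraph import MolGraph, State
from enzmech.dpo import Rule, derive_all


def brute_force_isomorphic(a: MolGraph, b: MolGraph) -> bool:
    """Exact isomorphism by backtracking permutation search (element,
    charge and bond order respected)."""
    ga, gb = a.graph, b.graph
    if ga.number_of_nodes() != gb.number_of_nodes():
        return False
    if ga.number_of_edges() != gb.number_of_edges():
        return False

    def attr(g, v):
        d = g.nodes[v]
        return (d["element"], d["charge"])

    if sorted(attr(ga, v) for v in ga) != sorted(attr(gb, v) for v in gb):
        return False
    nodes_a = sorted(ga.nodes, key=lambda v: (attr(ga, v), ga.degree(v)))
    nodes_b = list(gb.nodes)

    def extend(i: int, mapping: dict, used: set) -> bool:
        if i == len(nodes_a):
            return True
        u = nodes_a[i]
        for v in nodes_b:
            if v in used or attr(ga, u) != attr(gb, v):
                continue
            if ga.degree(u) != gb.degree(v):
                continue
            ok = True
            for w in ga.adj[u]:
                if w in mapping:
                    if not gb.has_edge(v, mapping[w]):
                        ok = False
                        break
                    if (
                        ga.edges[u, w]["order"]
                        != gb.edges[v, mapping[w]]["order"]
                    ):
                        ok = False
                        break
            if not ok:
                continue
            mapping[u] = v
            if extend(i + 1, mapping, used | {v}):
                return True
            del mapping[u]
        return False

    return extend(0, {}, set())


def count_monomorphisms(pattern, host) -> int:
    """Count injective label-respecting embeddings of ``pattern`` into
    ``host`` (both networkx graphs) by exhaustive assignment."""
    pn = list(pattern.nodes)
    hn = list(host.nodes)
    count = 0
    for image in itertools.permutations(hn, len(pn)):
        m = dict(zip(pn, image))
        ok = True
        for v in pn:
            pv, hv = pattern.nodes[v], host.nodes[m[v]]
            if pv["element"] != hv["element"]:
                ok = False
                break
            if pv["charge"] is not None and pv["charge"] != hv["charge"]:
                ok = False
                break
        if ok:
            for u, v, d in pattern.edges(data=True):
                if not host.has_edge(m[u], m[v]) or (
                    host.edges[m[u], m[v]]["order"] != d["order"]
                ):
                    ok = False
                    break
        if ok:
            count += 1
    return count


def naive_closure(rules: list[Rule], g0: State, depth: int):
    """Set-fixpoint realization of the k-step extension: repeatedly apply
    every rule at every match of every known state.

    Returns ``(states: dict key -> State, edges: dict (src, tgt) ->
    witness set)``.
    """
    states = {g0.key: g0}
    edges: dict[tuple[str, str], set] = {}
    frontier = [g0.key]
    for _ in range(depth):
        new = []
        for k in frontier:
            for tr in derive_all(rules, states[k]):
                edges.setdefault((tr.source, tr.target), set()).update(
                    tr.witnesses
                )
                if tr.target not in states:
                    states[tr.target] = tr.target_state
                    new.append(tr.target)
        frontier = new
    return states, edges


def dfs_paths(edges, src: str, dst: str, max_len: int) -> list[tuple[str, ...]]:
    """All simple src->dst paths of length <= max_len by recursive DFS over
    an edge dict/set of (u, v) pairs."""
    adj: dict[str, list[str]] = {}
    for (u, v) in edges:
        adj.setdefault(u, []).append(v)
    for u in adj:
        adj[u].sort()
    out: list[tuple[str, ...]] = []

    def walk(node: str, path: tuple[str, ...]):
        if node == dst and len(path) > 1:
            out.append(path)
            return
        if len(path) - 1 >= max_len:
            return
        for nxt in adj.get(node, ()):
            if nxt not in path:
                walk(nxt, path + (nxt,))

    walk(src, (src,))
    return sorted(out)
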