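"""Reachable state spaces: k-step expansion, bidirectional join, pruning.

The k-step extension of an initial state G0 is the breadth-first closure

    G_0 = {G0},   G_{k+1} = {H | exists G in G_k, rule p, match m: G => H} u G_k

deduplicated by canonical state key, so the space is a directed graph over
isomorphism classes of states.  To find paths from an initial state G_I to
a final state G_F without expanding to depth 2k, the space grown forward
from G_I is joined with the space grown from G_F under *inverted* rules
(edges flipped); the join contains every G_I -> G_F path of length <= 2k
provided neither half was truncated.  Pruning to nodes both reachable from
G_I and co-reachable to G_F yields the *relevant* state space: a flow with
a single source and a single drain.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .chemgraph import ChemGraphError, State
from .dpo import Rule, Transition, derive_all, invert_rule

__all__ = [
    "Limits",
    "StateSpace",
    "expand",
    "expand_backward",
    "join_spaces",
    "prune_relevant",
]


@dataclass(frozen=True)
class Limits:
    """Resource limits for a state-space construction.

    ``budget_s`` bounds wall-clock time for the whole invocation; on expiry
    the partial space is returned with its truncation flag set (mirroring
    an "unable to determine" outcome rather than an error).
    """

    max_states: int | None = None
    budget_s: float | None = 180.0


@dataclass
class StateSpace:
    """A directed graph over canonical states with witnessed transitions."""

    states: dict[str, State]
    edges: dict[tuple[str, str], tuple[tuple[str, str], ...]]
    roots: tuple[str, ...]
    depth: dict[str, int]
    k: int
    truncated: bool = False
    limits: Limits = field(default_factory=Limits)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        for (s, t), w in self.edges.items():
            g.add_edge(s, t, witnesses=w)
        return g

    def successors(self, key: str) -> list[str]:
        return sorted(t for (s, t) in self.edges if s == key)

    def to_json(self) -> dict:
        """JSON-serializable export (nodes with manifests, witnessed edges)."""
        from .chemgraph import state_manifest

        return {
            "roots": list(self.roots),
            "k": self.k,
            "truncated": self.truncated,
            "nodes": [
                {
                    "key": k,
                    "depth": self.depth.get(k),
                    "molecules": state_manifest(s),
                }
                for k, s in sorted(self.states.items())
            ],
            "edges": [
                {
                    "source": s,
                    "target": t,
                    "witnesses": [
                        {"rule": r, "match": d} for r, d in w
                    ],
                }
                for (s, t), w in sorted(self.edges.items())
            ],
        }

    def __repr__(self) -> str:
        flag = ", truncated" if self.truncated else ""
        return f"<StateSpace |V|={self.n_states} |E|={self.n_edges}{flag}>"


def expand(
    g0: State,
    rules: Sequence[Rule],
    k: int,
    limits: Limits | None = None,
) -> StateSpace:
    """Breadth-first k-step expansion from ``g0`` with state-key dedup.

    Deterministic for fixed inputs and limits.  ``k=0`` yields exactly the
    root.  Node sets are nested in ``k`` (monotone) and transitions are
    recorded between all discovered states, including cross edges.
    """
    if k < 0:
        raise ValueError("depth k must be >= 0")
    limits = limits or Limits()
    t0 = time.monotonic()
    states: dict[str, State] = {g0.key: g0}
    depth: dict[str, int] = {g0.key: 0}
    edges: dict[tuple[str, str], tuple[tuple[str, str], ...]] = {}
    frontier = [g0.key]
    truncated = False

    def over_budget() -> bool:
        return (
            limits.budget_s is not None
            and time.monotonic() - t0 > limits.budget_s
        )

    for level in range(k):
        if truncated or not frontier:
            break
        next_frontier: list[str] = []
        for key in frontier:
            if over_budget():
                truncated = True
                break
            for tr in derive_all(rules, states[key]):
                edges[(tr.source, tr.target)] = tuple(
                    sorted(set(edges.get((tr.source, tr.target), ())) | set(tr.witnesses))
                )
                if tr.target not in states:
                    if (
                        limits.max_states is not None
                        and len(states) >= limits.max_states
                    ):
                        truncated = True
                        continue
                    states[tr.target] = tr.target_state
                    depth[tr.target] = level + 1
                    next_frontier.append(tr.target)
        frontier = sorted(next_frontier)
    return StateSpace(
        states=states,
        edges=edges,
        roots=(g0.key,),
        depth=depth,
        k=k,
        truncated=truncated,
        limits=limits,
    )


def expand_backward(
    gF: State,
    rules: Sequence[Rule],
    k: int,
    limits: Limits | None = None,
) -> StateSpace:
    """Expand from the final state under inverted rules, then flip every
    edge so that edges point toward ``gF`` (predecessor semantics)."""
    inv = [invert_rule(p) for p in rules]
    sp = expand(gF, inv, k, limits)
    flipped = {(t, s): w for (s, t), w in sp.edges.items()}
    return StateSpace(
        states=sp.states,
        edges=flipped,
        roots=sp.roots,
        depth=sp.depth,
        k=sp.k,
        truncated=sp.truncated,
        limits=sp.limits,
    )


def join_spaces(fwd: StateSpace, bwd: StateSpace) -> StateSpace:
    """Union of the forward and backward spaces on shared canonical states.

    Contains every root-to-root path of length at most ``fwd.k + bwd.k``
    provided neither input was truncated.  Raises if the two root states
    have different atomic compositions (mass conservation forbids a path).
    """
    for r1 in fwd.roots:
        for r2 in bwd.roots:
            c1 = fwd.states[r1].composition()
            c2 = bwd.states[r2].composition()
            if c1 != c2:
                raise ChemGraphError(
                    "cannot join state spaces: root states differ in atomic "
                    f"composition ({c1} vs {c2})"
                )
    states = dict(fwd.states)
    for k_, s in bwd.states.items():
        states.setdefault(k_, s)
    edges = dict(fwd.edges)
    for e, w in bwd.edges.items():
        edges[e] = tuple(sorted(set(edges.get(e, ())) | set(w)))
    depth = dict(bwd.depth)
    depth.update(fwd.depth)  # forward discovery depth wins on shared states
    return StateSpace(
        states=states,
        edges=edges,
        roots=tuple(dict.fromkeys(fwd.roots + bwd.roots)),
        depth=depth,
        k=fwd.k + bwd.k,
        truncated=fwd.truncated or bwd.truncated,
        limits=fwd.limits,
    )


def prune_relevant(s: StateSpace, gI: str, gF: str) -> StateSpace:
    """Keep exactly the states reachable from ``gI`` and co-reachable to
    ``gF`` (with incident edges): the *relevant* state space.

    Every surviving node lies on some gI -> gF path and all such paths are
    preserved.  If either endpoint is missing the result is empty.
    """
    if gI not in s.states or gF not in s.states:
        return StateSpace(
            states={}, edges={}, roots=(), depth={}, k=s.k,
            truncated=s.truncated, limits=s.limits,
        )
    dg = s.to_digraph()
    fwd = {gI} | nx.descendants(dg, gI)
    bwd = {gF} | nx.ancestors(dg, gF)
    keep = fwd & bwd
    states = {k_: v for k_, v in s.states.items() if k_ in keep}
    edges = {
        (a, b): w for (a, b), w in s.edges.items() if a in keep and b in keep
    }
    return StateSpace(
        states=states,
        edges=edges,
        roots=tuple(r for r in (gI, gF)),
        depth={k_: d for k_, d in s.depth.items() if k_ in keep},
        k=s.k,
        truncated=s.truncated,
        limits=s.limits,
    )
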