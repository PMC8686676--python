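"""Catalytic mechanism search: traces, residue tracking and classification.

A *trace* is a chained sequence of transitions carving a path from an
initial state G_I to a final state G_F in a state space; it represents a
candidate mechanism.  For catalysis we require a catalyst multiset A to
embed intact in both endpoints: G_I = E (+) A and G_F = P (+) A, where (+)
is disjoint union.  Because canonical state keys deliberately forget atom
identity, each trace is *replayed* on concrete annotated states to recover
which residue atoms intersect each step's reaction-center image; a residue
is *active* in a trace if it does.  Mechanisms are then classified as
noncatalytic (no active residue), single-amino-acid (exactly one active
residue instance) or multi-amino-acid.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .chemgraph import ChemGraphError, State, state_embeds, state_union
from .dpo import Rule, apply_rule, find_matches
from .statespace import (
    Limits,
    StateSpace,
    expand,
    expand_backward,
    join_spaces,
    prune_relevant,
)

__all__ = [
    "Trace",
    "TraceStep",
    "MechanismQuery",
    "Classification",
    "SearchResult",
    "AnnotationError",
    "find_traces",
    "replay_trace",
    "active_amino_acids",
    "classify_trace",
    "search_mechanisms",
]


class AnnotationError(ChemGraphError):
    """Residue information required but unavailable."""


@dataclass(frozen=True)
class TraceStep:
    source: str
    target: str
    rule_id: str
    match_digest: str


@dataclass
class Trace:
    """One mechanism candidate: a chained sequence of witnessed transitions.

    ``center_residues`` (one set per step, filled by :func:`replay_trace`)
    holds the residue annotations of the atoms in each step's
    reaction-center image; empty annotations (substrate atoms) are dropped.
    """

    steps: tuple[TraceStep, ...]
    center_residues: tuple[frozenset[str], ...] | None = None

    def __post_init__(self):
        if not self.steps:
            raise ValueError("a trace must contain at least one transition")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.target != b.source:
                raise ValueError("trace transitions do not chain")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def source(self) -> str:
        return self.steps[0].source

    @property
    def target(self) -> str:
        return self.steps[-1].target

    @property
    def state_keys(self) -> tuple[str, ...]:
        return (self.steps[0].source,) + tuple(s.target for s in self.steps)

    @property
    def rules_used(self) -> tuple[str, ...]:
        return tuple(s.rule_id for s in self.steps)

    def to_json(self) -> dict:
        out = {
            "length": self.length,
            "states": list(self.state_keys),
            "steps": [
                {"rule": s.rule_id, "match": s.match_digest} for s in self.steps
            ],
        }
        if self.center_residues is not None:
            out["center_residues"] = [sorted(c) for c in self.center_residues]
        return out

    def describe(self) -> str:
        """Human-readable step listing."""
        lines = [f"trace of length {self.length}"]
        for i, s in enumerate(self.steps, 1):
            lines.append(f"  step {i}: apply {s.rule_id}")
            if self.center_residues is not None:
                res = sorted(self.center_residues[i - 1])
                lines.append(
                    "          center residues: " + (", ".join(res) or "(none)")
                )
        return "\n".join(lines)


def find_traces(
    s: StateSpace,
    gI: str,
    gF: str,
    max_len: int,
    mode: str = "minimal",
    witness_cap: int = 1000,
) -> list[Trace]:
    """Enumerate traces from ``gI`` to ``gF`` in a (pruned) state space.

    ``mode="minimal"`` returns all shortest paths (when the shortest length
    is within ``max_len``); ``mode="all"`` returns all simple paths of
    length at most ``max_len``.  Paths are ordered lexicographically by
    their state-key sequence; each path is expanded into one trace per
    combination of per-edge rule witnesses, up to ``witness_cap`` traces in
    total.
    """
    if gI == gF:
        raise ChemGraphError(
            "degenerate query: initial and final states coincide "
            "(a mechanism is a nonempty step sequence)"
        )
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if mode not in ("minimal", "all"):
        raise ValueError(f"unknown mode {mode!r}")
    if gI not in s.states or gF not in s.states:
        return []
    dg = s.to_digraph()
    if mode == "minimal":
        try:
            paths = [list(p) for p in nx.all_shortest_paths(dg, gI, gF)]
        except nx.NetworkXNoPath:
            return []
        paths = [p for p in paths if len(p) - 1 <= max_len]
    else:
        paths = [list(p) for p in nx.all_simple_paths(dg, gI, gF, cutoff=max_len)]
    paths.sort()

    traces: list[Trace] = []
    for path in paths:
        # one trace per rule-choice combination: witnesses that differ only
        # by an automorphic match collapse to one representative per rule
        edge_witnesses = []
        for a, b in zip(path, path[1:]):
            by_rule: dict[str, str] = {}
            for rule_id, digest in s.edges[(a, b)]:
                by_rule.setdefault(rule_id, digest)
            edge_witnesses.append(tuple(sorted(by_rule.items())))
        for combo in itertools.product(*edge_witnesses):
            steps = tuple(
                TraceStep(source=a, target=b, rule_id=r, match_digest=d)
                for (a, b), (r, d) in zip(zip(path, path[1:]), combo)
            )
            traces.append(Trace(steps=steps))
            if len(traces) >= witness_cap:
                return traces
    return traces


def replay_trace(
    trace: Trace, g0: State, rules: Sequence[Rule]
) -> Trace:
    """Re-execute a trace on a concrete annotated initial state.

    Canonical states forget which copy of a molecule is which; replay
    recovers atom identity by applying each step's witness rule to the
    concrete state (preferring the recorded match digest, falling back to
    any match that reaches the step's target key) and recording the residue
    annotations of the atoms in the reaction-center image.  Returns a copy
    of the trace with ``center_residues`` filled.
    """
    by_id: dict[str, Rule] = {}
    for p in rules:
        by_id.setdefault(p.rule_id, p)
    if g0.key != trace.source:
        raise ChemGraphError("replay initial state does not match trace source")
    cur = g0
    centers: list[frozenset[str]] = []
    for step in trace.steps:
        if step.rule_id not in by_id:
            raise ChemGraphError(f"unknown rule {step.rule_id!r} in trace")
        p = by_id[step.rule_id]
        matches = find_matches(p, cur)
        chosen = None
        nxt = None
        # prefer the witness digest; it may not be reproducible on the
        # replayed instance numbering, so fall back to target-key agreement
        for m in matches:
            if m.digest == step.match_digest:
                h = apply_rule(p, m, cur)
                if h.key == step.target:
                    chosen, nxt = m, h
                    break
        if chosen is None:
            for m in matches:
                h = apply_rule(p, m, cur)
                if h.key == step.target:
                    chosen, nxt = m, h
                    break
        if chosen is None:
            raise ChemGraphError(
                f"trace replay failed: rule {step.rule_id!r} cannot reach "
                "the recorded target state"
            )
        action_atoms = [chosen.mapping[v] for v in p.action_nodes()]
        residues = set()
        for key, idx, atom in action_atoms:
            residues.add(cur.instance(key, idx).graph.nodes[atom]["residue"])
        residues.discard("")
        centers.append(frozenset(residues))
        cur = nxt
    return Trace(steps=trace.steps, center_residues=tuple(centers))


def active_amino_acids(t: Trace, library=None) -> dict[str, int]:
    """Residues whose atoms intersect at least one step's reaction center.

    Returns a multiset ``{amino-acid label: number of active instances}``.
    Residue annotations are ``"Label#instance"`` strings; tautomer labels
    are normalized to their parent amino acid through ``library`` (an
    object with ``resolve(label)``, e.g.
    :class:`enzmech.fixtures.AminoAcidLibrary`).  Raises
    :class:`AnnotationError` when the trace carries no replay information.
    """
    if t.center_residues is None:
        raise AnnotationError(
            "catalyst atoms unannotated: replay the trace on an annotated "
            "initial state before classification"
        )
    instances: set[tuple[str, str]] = set()
    for center in t.center_residues:
        for rid in center:
            label, _, inst = rid.partition("#")
            if library is not None:
                label = library.resolve(label)
            instances.add((label, inst))
    out: dict[str, int] = {}
    for label, _ in instances:
        out[label] = out.get(label, 0) + 1
    return dict(sorted(out.items()))


@dataclass(frozen=True)
class Classification:
    """Catalytic classification of one trace."""

    kind: str  # "noncatalytic" | "sAA" | "multiAA"
    active: Mapping[str, int]
    catalyst_conserved: bool

    @property
    def label(self) -> str:
        if self.kind == "sAA":
            return f"sAA({next(iter(self.active))})"
        return self.kind


def classify_trace(t: Trace, library=None, *, catalyst_conserved: bool = True) -> Classification:
    """Classify a replayed trace by its active amino-acid usage.

    Empty active set: noncatalytic.  Exactly one active residue instance:
    an sAA mechanism.  Otherwise: multiAA.
    """
    active = active_amino_acids(t, library)
    n_instances = sum(active.values())
    if n_instances == 0:
        kind = "noncatalytic"
    elif n_instances == 1:
        kind = "sAA"
    else:
        kind = "multiAA"
    return Classification(kind=kind, active=active, catalyst_conserved=catalyst_conserved)


@dataclass
class MechanismQuery:
    """A catalytic mechanism search problem.

    The search looks for A-catalyzed traces of length at most ``max_len``
    (which must not exceed ``2 * k``) transforming G_I = educts (+)
    catalyst into G_F = products (+) catalyst.
    """

    educts: State
    products: State
    catalyst: State
    rules: Sequence[Rule]
    k: int = 3
    max_len: int = 6
    mode: str = "minimal"
    limits: Limits = field(default_factory=Limits)
    witness_cap: int = 1000
    library: object | None = None

    def initial_state(self) -> State:
        return state_union([self.educts, self.catalyst])

    def final_state(self) -> State:
        return state_union([self.products, self.catalyst])


@dataclass
class SearchResult:
    """Traces found plus statistics of the explored spaces."""

    traces: list[Trace]
    classifications: list[Classification]
    space: StateSpace
    relevant: StateSpace
    gI: str
    gF: str
    wall_time_s: float
    truncated: bool
    witness_cap_hit: bool

    def to_json(self) -> dict:
        return {
            "gI": self.gI,
            "gF": self.gF,
            "n_states_joined": self.space.n_states,
            "n_edges_joined": self.space.n_edges,
            "n_states_relevant": self.relevant.n_states,
            "n_edges_relevant": self.relevant.n_edges,
            "truncated": self.truncated,
            "witness_cap_hit": self.witness_cap_hit,
            "wall_time_s": self.wall_time_s,
            "traces": [t.to_json() for t in self.traces],
            "classifications": [
                {
                    "kind": c.kind,
                    "label": c.label,
                    "active": dict(c.active),
                    "catalyst_conserved": c.catalyst_conserved,
                }
                for c in self.classifications
            ],
        }


def search_mechanisms(q: MechanismQuery) -> SearchResult:
    """End-to-end catalytic mechanism search.

    Builds G_I = E (+) A and G_F = P (+) A, checks mass balance, expands
    forward from G_I and backward from G_F to depth ``k``, joins and prunes
    to the relevant space, enumerates traces up to ``max_len``, replays
    each on the annotated G_I and classifies it.
    """
    if q.max_len > 2 * q.k:
        raise ValueError(
            f"max_len={q.max_len} exceeds the bidirectional guarantee 2*k={2 * q.k}"
        )
    t0 = time.monotonic()
    gI = q.initial_state()
    gF = q.final_state()
    if gI.composition() != gF.composition():
        raise ChemGraphError(
            "overall reaction is not mass-balanced with this catalyst: "
            f"{gI.composition()} vs {gF.composition()}"
        )
    if gI.key == gF.key:
        raise ChemGraphError(
            "degenerate query: educt and product states coincide"
        )
    fwd = expand(gI, q.rules, q.k, q.limits)
    bwd = expand_backward(gF, q.rules, q.k, q.limits)
    joined = join_spaces(fwd, bwd)
    relevant = prune_relevant(joined, gI.key, gF.key)
    traces = (
        find_traces(
            relevant, gI.key, gF.key, q.max_len, q.mode, q.witness_cap
        )
        if relevant.n_states
        else []
    )
    cap_hit = len(traces) >= q.witness_cap
    replayed: list[Trace] = []
    classifications: list[Classification] = []
    conserved = state_embeds(q.catalyst, gI) and state_embeds(q.catalyst, gF)
    for t in traces:
        rt = replay_trace(t, gI, q.rules)
        replayed.append(rt)
        classifications.append(
            classify_trace(rt, q.library, catalyst_conserved=conserved)
        )
    return SearchResult(
        traces=replayed,
        classifications=classifications,
        space=joined,
        relevant=relevant,
        gI=gI.key,
        gF=gF.key,
        wall_time_s=time.monotonic() - t0,
        truncated=joined.truncated,
        witness_cap_hit=cap_hit,
    )
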