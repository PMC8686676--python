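# Methods

This note records the modeling assumptions, design choices and numerical
conventions behind `enzmech`, in the spirit of a model-documentation page:
what the machinery computes, which knobs matter, and what the shipped
fixtures do and do not demonstrate.

## Chemical graph model

Molecules are connected simple graphs; atoms carry an element symbol and
an integer formal charge, bonds carry one of four orders (`-`, `=`, `#`,
`:`). Hydrogens are always explicit: inputs are expected to come from a
preprocessing stage that adds them, and the package never infers valence.
Charges outside ±4 are rejected as likely encoding errors. Aromatic bonds
are an opaque fourth bond label — there is no kekulization or aromaticity
perception; two encodings of the same ring (alternating vs aromatic
labels) are different graphs, and inputs must be consistent about which
they use. Stereochemistry, isotopes and coordination bonds are out of
scope; metal and radical chemistry is excluded at the rule-extraction
filter precisely because the model cannot represent coordination bonds or
single-electron species.

Atoms may carry a *residue* annotation (`"Label#instance"`) and a role
tag. Annotations are bookkeeping: they ride through rewriting via the
atom map but never influence matching or canonical keys unless a key is
explicitly requested with residues included.

## Canonical keys

State spaces are graphs over isomorphism classes, so an exact canonical
form is load-bearing. The implementation uses iterative color refinement
(initial colors = element + charge, refined by multisets of
(bond-order, neighbor-color)) followed by individualization and
backtracking on refinement ties, taking the lexicographically smallest
leaf form. One shortcut is applied: when a tied cell consists of
degree-one vertices attached to a single common neighbor with equal
attributes and bond order (the hydrogens of a methyl or ammonium group),
the vertices are provably automorphic and only one branch is explored.
This keeps molecule canonicalization effectively linear for the
tree-like, hydrogen-heavy graphs that dominate chemistry while remaining
exact for symmetric cases (rings, twin substituents), which still branch
fully. Exactness is tested against a brute-force permutation-search
oracle on random molecules. A state's key is the sorted multiset of its
molecule keys with counts.

## Rules and rewriting

A rule stores one shared node set with left/right attributes and
left/right edge sets; the injections of the DPO span are identities after
this identification. Consequences of the atom-conserving restriction:

- elements never change, only charges and bonds;
- total formal charge must balance between the sides (electron
  bookkeeping);
- the dangling condition of general DPO rewriting reduces to a
  *parallel-bond check*: a match is rejected if forming a right-side bond
  would create a second bond between an already-bonded atom pair;
- a bond present on both sides with different order is represented as
  delete-plus-add, which makes the action computation uniform.

Matching enumerates injective monomorphisms of the left pattern into the
instance-expanded state (VF2 per connected pattern component, combined
with a cross-component injectivity filter), so patterns may span several
molecules, including distinct copies of the same species. Matches related
by an automorphism of *L* are kept at this level; deduplication happens
at the state level in `derive_all`, which emits one transition per
distinct product-state key with all (rule, match) witnesses aggregated.
Application rebuilds only the molecule instances touched by the match and
re-uses the cached canonical keys of untouched molecules.

## State spaces and the bidirectional guarantee

`expand` is a breadth-first realization of the k-step extension with
state-key deduplication; transitions are recorded from every state
expanded (depth < k). Backward expansion runs the same procedure under
inverted rules and flips the edges. Joining the two spaces on shared
canonical states yields every initial→final path of length ≤ 2k provided
neither half was truncated; the join refuses root states with different
atomic compositions since mass conservation then forbids any path.
"Shared parts" are whole states under isomorphism — partial sharing of
molecule subsets is not defined here. Pruning keeps exactly the states
reachable from the source and co-reachable to the drain, which preserves
every source→drain path and leaves a single source and single drain.

Limits are explicit: depth k (default 3), mechanism length ℓ (default 6,
must satisfy ℓ ≤ 2k), a wall-clock budget (default 180 s) and an optional
state cap. On expiry the truncation flag is set and partial results are
returned — a truncated search means "unable to determine", not an error.

## Traces, residue identity and classification

Minimal-mode search returns all shortest source→drain paths; `all` mode
returns all simple paths up to ℓ. Each path is expanded into one trace
per combination of per-edge *rule* choices (witnesses differing only by
an automorphic match collapse), capped at 1000 traces by default; the cap
is reported when hit. Both views of mechanism identity are thus
available: state sequences, and rule-labelled traces over them.

Canonical states deliberately forget which copy of a molecule is which,
so each trace is *replayed* on the concrete annotated initial state: the
witness rule of every step is re-matched (preferring the recorded match
digest, falling back to any match that reaches the step's recorded target
key) and the residue annotations in the reaction-center image are
recorded per step. A residue is active in a trace if it intersects at
least one step's center; tautomer labels normalize to their parent amino
acid through the library. Classification: no active residue instance →
noncatalytic; exactly one → sAA(x); otherwise multiAA. Catalyst
conservation (whole-molecule multiset embedding of A in both endpoints)
holds by construction of the query and is asserted, not searched for.
Whole-molecule embedding was chosen over subgraph embedding because the
catalyst is a set of molecules that must reappear *intact*, and multiset
inclusion over canonical keys is cheap and unambiguous.

## Rule abstraction

A step is a maximally refined rule; abstraction keeps the reaction center
(atoms with changed bonds or charges under the atom map) and adds context
by three guidelines, each independently switchable for ablation:

1. *local topology* — atoms directly bonded to the center on either side;
2. *functional patterns* — monomorphic matches of a configurable pattern
   library into the educt and the product graphs; a match intersecting
   the center contributes all its atoms (union over overlapping matches,
   either side suffices; provenance records which);
3. *whole side chains* — all atoms of any residue instance intersecting
   the center. The side-chain boundary is whatever the annotations say:
   backbone truncation is the annotator's responsibility.

Left/right attributes and edges are the induced subgraphs of the selected
atoms on each side. Molecules sharing no atom with the center are dropped
entirely. Every context atom is attributed to the guideline(s) that
pulled it in. The central correctness property — tested at every policy —
is the round trip: the extracted rule, applied to the originating educt
state, reproduces the originating product state. Context node sets nest
across the policy ladder action ⊆ topology ⊆ default ⊆ maximal. Match
*sets* are anti-monotone in context when compared on reaction-center
images; raw match counts are not a monotone quantity because added
context (e.g. methyl hydrogens) multiplies automorphic embeddings of the
same chemical event.

Admission filters: the metal filter is an organic-element *allowlist*
(H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I — configurable) rather than a
metal blocklist, the safer complement; radical steps are flagged in the
input metadata, not inferred. Atom tracking checks that consecutive steps
chain at whole-molecule granularity; molecules missing on exactly one
side of a junction are propagated as untouched spectators, while a
two-sided mismatch at a junction means the steps disagree about the same
matter (a molecule transformed without an accounting step) — spectator
addition would double-count atoms, so the mechanism is excluded. A step
whose own sides are not related by a bijective atom map is excluded
outright.

## Fixtures: what they emulate and what they do not

The shipped toys are deliberately small, fully balanced chemistries built
from the proton-transfer / addition / elimination step vocabulary that
dominates curated enzymatic mechanisms:

- *proton_transfer*: a water-relay acid-base system (2 rules);
- *glu_tautomerization*: glutamate-assisted keto-enol tautomerization —
  a two-step single-residue proton shuttle;
- *his_ser_acyl_transfer*: transesterification of methyl formate with
  ethanol through a covalent serine-formate intermediate, His/Ser
  jointly catalytic; the five-step two-part addition/elimination cycle
  restores the histidine mid-trace and reuses it, and a shorter
  His-only general-base route coexists;
- *fig1_step*: a single atom-mapped step (concerted serine activation
  and nucleophilic attack on a methyl ester) together with the rule
  abstracted from it at the default policy;
- *branching_ladder*: two polyol chains with 18 mutually distinguishable
  hydroxyl sites plus three ammonia bases. Its depth-3 forward space is
  analytically C(18,0)+C(18,1)+C(18,2)+C(18,3) = 988 states, sized a
  priori to exercise the pipeline at the ~10³-state scale at which most
  realistic single-reaction searches operate.

Amino-acid side chains are methyl-capped fragments (e.g. serine as
propan-1-ol, histidine as 4-methylimidazole in two neutral tautomers)
with exact formal charges; the library is small and user-extensible, as
is the ~20-entry functional-pattern set. Expected toy outcomes are
documented prose; the test suite recomputes all of them with independent
brute-force oracles (permutation isomorphism, exhaustive assignment
matching, naive set-closure, DFS path enumeration).

What passing these fixtures does *not* show: behavior on database-scale
inputs (hundreds of atoms per state, thousands of rules), robustness to
inconsistent aromatic encodings across sources, or chemical plausibility
ranking of the enumerated mechanisms — the search is purely structural
and reports everything reachable.

## Numerical and procedural conventions

- Determinism: all serializations are canonical-order; match lists,
  transition lists and trace lists are sorted; repeated runs are
  byte-stable. No randomness exists outside the explicitly seeded
  generators.
- Degenerate queries (educt state equal to product state, or a
  zero-length trace) are rejected: a mechanism is a nonempty step
  sequence.
- The replay fallback (target-key agreement when the recorded match
  digest does not reproduce) exists because instance numbering inside a
  canonical state is not stable across expansion and replay.
- Default operating point: k = 3, ℓ = 6, 180 s budget, 1000-trace cap.
  The length bound reflects that curated mechanisms are typically short
  (median ≈ 3 steps); all four numbers are plain parameters.

## Known limitations

- Negative application conditions (e.g. "no hydrogen on this nitrogen")
  are not expressible, so minimal-context rules can over-apply and
  generate chemically implausible states (a doubly protonated neutral
  ring nitrogen, say); context is the only brake, which is exactly why
  context policy matters.
- Canonicalization worst case is exponential for highly regular graphs;
  molecule-scale inputs with chemical attributes refine essentially
  immediately, but the package is not a general-purpose graph canonizer.
- The pattern library and residue library are illustrative defaults, not
  curated chemistry; users supply their own for serious work.
- Witness digests are positional and may shift between sessions if the
  state construction order changes; only canonical keys are stable
  identifiers for states.
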