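# enzmech

Rule-based exploration of enzymatic reaction mechanisms by double-pushout
(DPO) graph rewriting.

Enzymatic catalysis is rarely a single event: at a catalytic site, several
elementary steps — proton transfers, nucleophilic additions, eliminations —
chain into a cyclic network that converts substrates into products while
every protein component regains its initial chemical state.  `enzmech`
makes this kind of chemistry *executable*: it represents molecules as
typed graphs, elementary chemistry as graph-rewrite rules, and mechanism
drafting as a path search through a space of reachable "test tube" states.

## The model

A **molecule** is a connected undirected graph whose nodes are atoms
(element symbol + integer formal charge, hydrogens explicit) and whose
edges are bonds of order single/double/triple/aromatic.  A **state** *G*
is a multiset of molecules — a disconnected graph with invariant atomic
composition.

A **rule** is an atom-conserving DPO span *p* = (*L* ← *K* → *R*) over one
shared atom set: only bonds and charges may change between the left
pattern *L* and right pattern *R*.  The minimal rule — exactly the broken,
formed and re-ordered bonds plus charge changes — is the **action**
(the formalization of the reaction center); invariant atoms and bonds
around it are **context** *C*.  A rule applies to a state through a match
*m* ∈ *M*(*p*, *G*), an injective label-respecting embedding of *L*,
giving a **transition** (direct derivation) *G* ⇒<sub>*p,m*</sub> *H*.

Iterating over a rule set R yields the reachable state space
*S<sub>k</sub>* over

G<sub>0</sub> = {G<sub>0</sub>},  G<sub>k+1</sub> = { H | ∃ G ∈ G<sub>k</sub>, p ∈ R, m ∈ M(p, G) : G ⇒<sub>p,m</sub> H } ∪ G<sub>k</sub>

deduplicated by canonical graph keys.  A **trace** τ is a chained sequence
of transitions G<sub>I</sub> ⇒<sup>τ</sup> G<sub>F</sub>; it is
**A-catalyzed** (τ<sub>A</sub>) when a catalyst multiset *A* embeds intact
in both endpoints, G<sub>I</sub> = E ⊕ A and G<sub>F</sub> = P ⊕ A (⊕ the
disjoint union).  Because every rule is invertible by swapping *L* and
*R*, the space grown forward from G<sub>I</sub> to depth *k* joined with
the space grown from G<sub>F</sub> under inverted rules contains every
G<sub>I</sub> → G<sub>F</sub> path of length ≤ 2*k*; pruning to states
both reachable and co-reachable leaves the *relevant* state space, a flow
from a single source to a single drain in which mechanisms are enumerated
as (minimal) paths.

Rules are not written by hand but **abstracted** from atom-mapped
elementary steps: the reaction center is kept and context is added by
three guidelines — (1) the center's immediate neighborhood, (2) matched
functional patterns (carboxylate, imidazole, ester, …) that intersect the
center, (3) the whole side chain of any amino acid touching the center.
Steps relying on metal ions or radical single-electron chemistry are
filtered out, and mechanisms whose steps do not chain at whole-molecule
granularity are repaired by spectator propagation or excluded.  Traces are
classified by their **active** amino acids (residues whose atoms intersect
a step's reaction center): noncatalytic, single-amino-acid (sAA), or
multi-amino-acid mechanisms.

## Worked example

Glutamate-assisted keto-enol tautomerization: acetaldehyde is converted to
vinyl alcohol with a glutamate side chain as the catalyst.  The shipped
toy chemistry has two rules (base-mediated enolate formation; an O→O
proton transfer):

```python
from enzmech.fixtures import toy_chemistry
from enzmech.mechsearch import search_mechanisms

toy = toy_chemistry("glu_tautomerization")
result = search_mechanisms(toy.query())
print(f"relevant space: |V|={result.relevant.n_states} |E|={result.relevant.n_edges}")
for trace, cls in zip(result.traces, result.classifications):
    print(f"{cls.label}:")
    print(trace.describe())
```

prints

```
relevant space: |V|=3 |E|=3
sAA(Glu):
trace of length 2
  step 1: apply enolate_form
          center residues: Glu#1
  step 2: apply pt_o_to_o
          center residues: Glu#1
```

i.e. the relevant state space has three states (educts ⊕ catalyst, the
enolate intermediate, products ⊕ catalyst) and one minimal mechanism of
length 2: the glutamate carboxylate abstracts an α-proton, then the
protonated glutamate reprotonates the enolate oxygen.  Both reaction
centers intersect the glutamate (residue instance `Glu#1`), so the
mechanism is classified sAA(Glu) — catalyzed exclusively by a single
amino acid, which is restored in the final state.

The same machinery runs from the shell:

```sh
enzmech validate rules/*.gml
enzmech expand  --state educts.json --rules rules/ --depth 3 --out space.json
enzmech search  --educts educts.json --products products.json \
                --catalyst catalyst.json --rules rules/ \
                --depth 3 --max-len 6 --mode all --out result.json
enzmech extract --steps steps/ --patterns patterns/ --policy default --out rules/
```

## Layout

- `enzmech.chemgraph` — molecules, states, canonical keys, GML-dialect I/O
- `enzmech.dpo` — rules, validation, inversion, matching, application
- `enzmech.statespace` — k-step expansion, bidirectional join, pruning
- `enzmech.mechsearch` — trace enumeration, residue tracking, classification
- `enzmech.ruleextract` — reaction centers, context-guided rule abstraction,
  admission filters, atom tracking
- `enzmech.fixtures` — toy chemistries, amino-acid side-chain library,
  pattern set, random generators
- `enzmech.cli` — the `enzmech` command

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
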