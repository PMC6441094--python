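# Methods

## Graph model and score

Molecules are undirected labelled graphs. Atoms carry element, formal
charge and an aromaticity flag; bonds carry an order drawn from
{1 (single), 1.5 (aromatic), 2 (double), 3 (triple)} and a `protected`
flag. Hydrogens are made explicit for every mapping computation, because
bonds to hydrogen are edited (and therefore scored) like any other bond;
output emits heavy-atom map numbers by default and hydrogen maps behind a
flag. Stereochemistry is parsed and discarded — the mapping problem as
treated here is constitutional. Aromatic bonds are kept as a distinct
order rather than kekulized, so an aromatic system only pays when it is
actually disrupted.

A complete mapping is an element-preserving bijection between the two
sides' atoms. Its score is the sum of bond-order units removed or changed
on the reactant side — cutting an edge costs its order (a fully broken
double bond is a σ and a π bond, hence 2), re-ordering an edge costs the
absolute order difference, product-side bond formation is free — plus the
scores of any heuristic templates applied. Charges may change freely
(mapping is element-preserving, not charge-preserving). Scores live on a
0.5-unit grid; the aromatic order 1.5 is what puts half-units on it.

Counting a broken double bond as two units is deliberate: it makes the
metathesis arithmetic come out right (breaking two C=C edges costs 4,
visibly worse than the chemically wrong two-single-cut alternative at 2,
which is exactly the gap the +0.5 metathesis heuristic closes) while
leaving single/hydrogen cut costs at +1 and a double→single conversion at
+1.

## Environments and periphery matching

An atom's order-*k* environment is the subgraph induced by all atoms
within *k* bonds, canonically serialized so that two atoms get equal
descriptors exactly when their environments are isomorphic with roots
matched. Canonicalization is colour refinement plus individualization of
the smallest tied colour class, branching once per *twin* class (vertices
with identical neighbourhoods are automorphic, so only one representative
is branched — this keeps methyl and water hydrogens from exploding the
search). Element, charge and aromaticity all enter the initial colours;
both are switchable for experiments. Descriptor strings are an internal
format and never persisted.

Atoms of both reaction sides are bucket-sorted by descriptor at orders
4 → 3 → 2 → 1. A descriptor class left with exactly one free atom on each
side fixes that pair; the fixing is deliberately conservative (ambiguous
symmetric classes stay free for the matcher). Atoms near the reaction
center differ at low orders already and remain unlabelled, which localizes
the expensive search where the chemistry happens. If a seeded search finds
nothing, it is retried unseeded — a periphery fix is a strong bet, not a
proof.

## Search

Four quick tests exclude most candidate pairings before any matching:
equal component counts, matchable component sizes, matchable environment
multisets, pairwise component isomorphism (checked via whole-graph
canonical forms).

The matcher is a VF2 variant that extends a partial matching to *all*
unmatched immediate neighbours of a matched atom before moving on, and
backtracks when a block cannot be placed. Around the unlabelled region,
subsets of non-protected bonds incident to unlabelled atoms are cut
(singles, then pairs, … up to six bonds); the cut-set exploration is a DFS
whose admissible bound is `cut units + element-pair edge surplus`, since
every reactant edge in surplus of its element-pair count on the product
side must eventually be cut. Interchangeable leaf targets (the hydrogens
of one methyl group) are assigned canonically rather than permuted, so
reported tie lists are modulo hydrogen relabelling.

Search effort is metered in decision-tree vertices against a budget of
10⁶ per reaction (both branches share one counter — the budget is global
per reaction, not per component or candidate). Exceeding it returns the
best solution found so far flagged `truncated`, never a silent wrong
answer. Unbounded searches use iterative deepening on the edit score
(levels one unit apart), so cheap solutions are found without enumerating
deep cut combinations.

## Heuristics

Twenty reaction templates (ids a–u with `o` unused, to avoid digit
confusion) are shipped as YAML data: a SMARTS pattern whose atom-map
labels name the pattern atoms, an explicit bond-edit list (break / form /
order), a score, and an optional list of bonds to protect afterwards.
Free pattern valences accept any substituent unless the SMARTS says
otherwise. Applying a template at an embedded site rewrites a copy of the
reactant graph; applications that touch protected bonds, violate
valences, or leave the graph structurally unchanged are rejected. All
templates conserve atom count — condensation templates expel their water
as a separate component rather than deleting atoms, so composition is
invariant across rewriting.

Candidates are all single applications at all sites plus stacked
applications up to a configurable depth (default 2 — single applications
cover most named reactions, while cascades occasionally need two; deeper
stacking multiplies decoys faster than coverage), deduplicated by
canonical form of the rewritten graph (plus its protected-bond set), and
capped (default 500) to keep degenerate inputs bounded. User template
directories are accepted; loading them logs a warning because every extra
heuristic also mints new decoy solutions.

Scores: +0.5 by default; +1 for the Robinson annulation [i] (it edits ten
bonds, so +1 is still a large discount); 0 for the allylic hydrogen shift
[r] and −1.5 for keto–enol tautomerization [j], both of which relocate
notation rather than chemistry. No floor is applied, so a total score can
be negative (a pure tautomerization maps at −1.5). The identity of [j] is
the least certain transcription in the registry and is marked as such.

## Dual-branch orchestration and pruning

The plain (no-heuristics) branch and the heuristics branch run under an
interleaving contract: the plain branch's best score S is the initial
incumbent, any candidate whose total could not beat the incumbent is
rejected (`prune` is strict — ties are kept), and the incumbent tightens
as better heuristic solutions appear. Candidates are processed by a
global deepening ladder ordered by optimistic score (accrued template
cost plus the edge-surplus lower bound), so promising intermediates
resolve early and prune the rest cheaply. Pruning provably never changes
the selected score, only wall-clock; the suite checks this on fixtures.
On exact score ties the no-heuristics solution is preferred (fewer
mechanistic assumptions; configurable), and all ties are reported.

## Stoichiometry balancing

Reactions as chemists write them are usually unbalanced. Before mapping,
a fixed cascade runs, stopping at the first stage that zeroes the
per-element deficit:

1. **substrate copies** — the smallest multiset of copies (≤ 3 extra in
   total) that zeroes the deficit; a single copy may instead reduce it to
   a pure n·H₂O imbalance for the water stage to finish (wider
   copy-plus-water searches admit spurious no-op combinations and are not
   attempted);
2. **balancing templates** — hard-coded completions for popular reaction
   families (esterification, amide formation, ester hydrolysis ship as a
   representative, extensible YAML library), which also seed the template
   core atoms into the mapping;
3. **water** — n·H₂O added to one side when that is the entire remaining
   deficit;
4. **single atoms** — each missing atom as a one-atom molecule, refused
   above 7 missing atoms (a strict reading of "fewer than about eight"),
   beyond which the placement combinatorics are intractable.

Any balancing output either has a zero deficit or carries an explicit
`unbalanceable` status.

## Fixtures and what passing them shows

The fixture corpus holds ~20 hand-mapped named reactions spanning all five
heuristic groups and all four balancing paths, plus a generator that
grafts random alkyl substituents onto known-truth core transforms
(SN2, Williamson, E2, Diels–Alder) identically on both sides. Truth
comparison is automorphism-aware on heavy atoms: two mappings agree when
they differ only by a symmetry of the molecules — comparing naively would
miscount every symmetric molecule.

These fixtures are small (≤ ~25 atoms with hydrogens), constitutionally
clean, and decorated only with alkyl groups; passing them demonstrates the
scoring model, the decoy mechanism, and balancing, but not performance on
large natural-product substrates, condensed polycyclic aromatics, ionic
equations, or multi-step cascades — the Hantzsch dihydropyridine
synthesis is included as a balancing showcase precisely because its full
mapping exceeds the default search budget in this implementation.

## Numerical and degenerate-input choices

Determinism is absolute: atoms are visited in sorted id order, candidates
in sorted order, and ties broken by the lexicographically smallest mapping
pair list, so identical inputs give identical outputs. Scores are
half-integer floats and compared exactly. Empty partial mappings, empty
candidate lists, reactions with no heuristic matches, and single-atom
species are all legal inputs to every stage. A mapping search on sides
with unequal element counts reports `unmappable` rather than guessing.

## Known limitations

- Bounded search: optimality is only guaranteed within the vertex budget
  and the six-bond cut limit; `truncated` results are best-effort.
- Periphery fixing can, in principle, exclude the optimum; the unseeded
  fallback fires only when the seeded search finds nothing at all.
- Charge balancing of ionic equations and 3D/stereochemical information
  are out of scope.
- Large condensation cascades (> ~8 edited bond units) can exhaust the
  default budget; raising `--node-limit` helps at a wall-clock cost.
- Agents (the middle reaction-SMILES field) are never mapped; the
  metathesis template deliberately compensates for an absent catalyst
  rather than modelling it.
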