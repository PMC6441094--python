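# atommap

Heuristic-guided atom–atom mapping of organic reactions.

Atom mapping — deciding which substrate atom becomes which product atom — is
what makes reactions machine-readable: it underpins reaction classification,
substructure search over reaction databases, and the automatic extraction of
reaction rules for synthesis-planning programs. The problem contains
subgraph isomorphism and is NP-hard, and the popular *minimal chemical
distance* ansatz (assume the reaction cuts the fewest possible bonds) gives
chemically wrong answers for whole reaction families: pericyclic reactions,
1,2-rearrangements, and metathesis all cut **more** bonds than the cheapest
graph edit would.

`atommap` combines an exact graph-edit search with a small library of
mechanistic *reaction heuristics* that steer it toward chemically correct
answers, and a stoichiometry balancer that repairs the reactions chemists
actually write (missing substrate copies, condensation water, lost atoms).

## The model

A reaction is a pair of labelled molecular graphs with explicit hydrogens.
A complete mapping `m` (an element-preserving bijection from reactant atoms
to product atoms) is scored by the bond-order units it edits on the
reactant side:

- cutting a bond costs its order — 1 for a single bond (including X–H
  bonds), 1.5 aromatic, 2 for a fully broken double bond (σ + π), 3 triple;
- changing a bond's order costs the absolute order difference
  (e.g. C=C → C–C is +1);
- bonds formed on the product side are free;
- applying a reaction heuristic costs its template score — usually **+0.5**,
  much less than the bonds it actually reorganizes (+1 for the Robinson
  annulation template, −1.5 for keto–enol tautomerization, 0 for the
  allylic hydrogen shift).

The mapper returns the minimal-score complete mapping. The search labels
atoms by canonical *k*-th-order environments (the rooted subgraph within
*k* bonds, *k* = 4…1), bucket-sorts them into cross-reaction equivalence
classes, fixes unambiguous periphery atoms first, and resolves the
remaining reaction-center region with a VF2-style matcher that extends a
partial matching to all immediate neighbours of a matched atom at once,
plus enumeration of bond cut sets (up to six bonds) around the unlabelled
atoms. Two branches run under one decision-tree budget (10⁶ vertices by
default): a plain branch and a branch over heuristically rewritten
intermediates; the plain branch's best score S prunes any heuristic
candidate scoring above S, and the lower-scoring solution wins.

The 20 heuristics ship as reviewable YAML files
(`src/atommap/data/heuristics/`): pericyclic motifs (Diels–Alder,
[3,3]-sigmatropic, electrocyclic, [2+2]), symmetry disambiguators
(anhydride exchange, acyl-oxygen esterification), carbonyl chemistry
(hemiacetal addition, aldol condensation, Robinson annulation,
tautomerization), olefin metathesis (which compensates for the unwritten
catalyst), and non-pericyclic rearrangements (pinacol, allylic
transposition, Meinwald, Beckmann, Prins–pinacol, retro-Diels–Alder, …).

## Worked example

```bash
$ cat demo.smi
C=CCOC=C>>C=CCCC=O
CC=C.CC=C>>CC=CC.C=C
CC(=O)O.CCO>>CC(=O)OCC
$ atommap map demo.smi -o demo_out.smi --report demo.tsv
summary: mapped=3
$ cat demo_out.smi
[CH2:1]=[CH:2][CH2:3][O:4][CH:5]=[CH2:6]>>[CH2:1]([CH:2]=[CH2:3])[CH2:6][CH:5]=[O:4]
[CH3:1][CH:2]=[CH2:3].[CH3:4][CH:5]=[CH2:6]>>[CH3:1][CH:2]=[CH:5][CH3:4].[CH2:3]=[CH2:6]
[CH3:1][C:2](=[O:3])[OH:4].[CH3:5][CH2:6][OH:7]>>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5].[OH2:4]
$ cut -f1,4,5,6,10 demo.tsv
index  status  score  heuristics  additions
1      mapped  0.5    b
2      mapped  0.5    k
3      mapped  0.5    f           O(products,template)
```

Line 1 is a Claisen rearrangement: the sigmatropic template [b] yields the
correct mapping (allylic oxygen becomes the carbonyl oxygen, score 0.5)
even though a wrong mapping exists that cuts fewer bonds. Line 2 is a
cross-metathesis: without heuristics the cheapest solution wrongly cuts the
two allylic single bonds (score 2.0); template [k] reorganizes the two
double bonds for 0.5 and restores the chemically correct alkylidene
exchange. Line 3 is an esterification written without its water product:
the balancer completes it from a hard-coded template (the `O(products,
template)` addition), and the acyl-oxygen template [f] routes the ester
bridge oxygen to the alcohol, as isotope labelling says it should.

The same functionality is available as a library:

```python
>>> from atommap import map_reaction_smiles
>>> res = map_reaction_smiles("CC=C.CC=C>>CC=CC.C=C")
>>> res.score, [h.template_id for h in res.best.heuristic_applications]
(0.5, ['k'])
```

`atommap validate mapped.smi reference.smi` compares two mapped files with
automorphism-aware equality (mappings that differ only by a molecular
symmetry count as identical).

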