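"""Built-in toy reactions with known ground-truth mappings.

Every fixture carries an unmapped reaction, a hand-mapped truth (heavy-atom
map numbers), the score the mapper is expected to reach, and the heuristics
expected in the winning solution.  Fixtures span all five heuristic groups
and all four balancing paths, so they double as demonstration inputs and as
the regression corpus for the test suite.

Ground-truth comparison is automorphism-aware: two mappings are equivalent
when they are related by a symmetry of the reaction graphs (relabelling
identical molecules or symmetry-equivalent atoms is not a chemical
difference).  Naive pairwise comparison would miscount symmetric molecules.

``random_decorated_reaction`` grows known-truth fixtures by grafting random
alkyl substituents onto a core transform, identically on both sides, so the
constructed mapping remains correct by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from .chemgraph import AtomMapping, MolGraph, ReactionRecord, parse_reaction
from .isomorphism import neighbor_extend_match


@dataclass
class Fixture:
    name: str
    reaction: str  # unmapped reaction SMILES
    truth: Optional[str]  # mapped reaction SMILES (heavy atoms)
    expected_score: Optional[float] = None
    expected_heuristics: list[str] = field(default_factory=list)
    notes: str = ""


_BUILTIN: list[Fixture] = [
    Fixture(
        "identity_ethane",
        "CC>>CC",
        "[CH3:1][CH3:2]>>[CH3:1][CH3:2]",
        0.0,
        [],
    ),
    Fixture(
        "claisen_rearrangement",
        "C=CCOC=C>>C=CCCC=O",
        "[CH2:1]=[CH:2][CH2:3][O:4][CH:5]=[CH2:6]"
        ">>[CH2:3]=[CH:2][CH2:1][CH2:6][CH:5]=[O:4]",
        0.5,
        ["b"],
        "correct mapping cuts more bonds than the minimal-cut decoy",
    ),
    Fixture(
        "diels_alder",
        "C=CC=C.C=C>>C1=CCCCC1",
        "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
        ">>[CH:2]1=[CH:3][CH2:4][CH2:5][CH2:6][CH2:1]1",
        0.5,
        ["a"],
    ),
    Fixture(
        "electrocyclic_closure",
        "C=CC=CC=C>>C1=CC=CCC1",
        "[CH2:1]=[CH:2][CH:3]=[CH:4][CH:5]=[CH2:6]"
        ">>[CH:2]1=[CH:3][CH:4]=[CH:5][CH2:6][CH2:1]1",
        0.5,
        ["c"],
    ),
    Fixture(
        "ketene_cycloaddition",
        "C=C=O.C=C>>O=C1CCC1",
        "[CH2:1]=[C:2]=[O:3].[CH2:4]=[CH2:5]"
        ">>[O:3]=[C:2]1[CH2:1][CH2:4][CH2:5]1",
        0.5,
        ["d"],
    ),
    Fixture(
        "anhydride_acid_exchange",
        "CC(=O)OC(C)=O.CCC(=O)O>>CC(=O)O.CCC(=O)OC(C)=O",
        "[CH3:1][C:2](=[O:3])[O:4][C:5](=[O:6])[CH3:7].[CH3:8][CH2:9][C:10](=[O:11])[O:12][H]"
        ">>[CH3:1][C:2](=[O:3])[O:4][H].[CH3:8][CH2:9][C:10](=[O:11])[O:12][C:5](=[O:6])[CH3:7]",
        0.5,
        ["e"],
        "central oxygen of the new anhydride comes from the acid",
    ),
    Fixture(
        "esterification",
        "CC(=O)O.CCO>>CC(=O)OCC",
        "[CH3:1][C:2](=[O:3])[O:4][H].[CH3:5][CH2:6][O:7][H]"
        ">>[CH3:1][C:2](=[O:3])[O:7][CH2:6][CH3:5].[OH2:4]",
        0.5,
        ["f"],
        "water product restored by balancing; ester oxygen from the alcohol",
    ),
    Fixture(
        "hemiacetal_formation",
        "CC=O.CO>>COC(C)O",
        "[CH3:1][CH:2]=[O:3].[CH3:4][O:5][H]"
        ">>[CH3:4][O:5][CH:2]([CH3:1])[O:3][H]",
        0.5,
        ["g"],
    ),
    Fixture(
        "aldol_condensation",
        "CC(C)=O.C=O>>CC(=O)C=C.O",
        "[CH3:1][C:2](=[O:3])[CH3:4].[CH2:5]=[O:6]"
        ">>[CH3:1][C:2](=[O:3])[CH:4]=[CH2:5].[OH2:6]",
        0.5,
        ["h"],
    ),
    Fixture(
        "robinson_annulation",
        "C=CC(C)=O.CC(C)=O>>O=C1C=C(C)CCC1.O",
        "[CH2:1]=[CH:2][C:3]([CH3:4])=[O:5].[CH3:6][C:7]([CH3:8])=[O:9]"
        ">>[O:5]=[C:3]1[CH:4]=[C:7]([CH3:8])[CH2:6][CH2:1][CH2:2]1.[OH2:9]",
        1.0,
        ["i"],
    ),
    Fixture(
        "keto_enol_tautomer",
        "CC(C)=O>>CC(O)=C",
        "[CH3:1][C:2]([CH3:3])=[O:4]>>[CH3:1][C:2]([O:4][H])=[CH2:3]",
        -1.5,
        ["j"],
        "negative template score; total may drop below zero",
    ),
    Fixture(
        "cross_metathesis",
        "CC=C.CC=C>>CC=CC.C=C",
        "[CH3:1][CH:2]=[CH2:3].[CH3:4][CH:5]=[CH2:6]"
        ">>[CH3:1][CH:2]=[CH:5][CH3:4].[CH2:3]=[CH2:6]",
        0.5,
        ["k"],
        "the cheaper two-single-bond solution is chemically wrong",
    ),
    Fixture(
        "pinacol_rearrangement",
        "CC(C)(O)C(C)(C)O>>CC(C)(C)C(C)=O",
        "[CH3:1][C:2]([CH3:3])([O:4][H])[C:5]([CH3:6])([CH3:7])[O:8][H]"
        ">>[C:5]([CH3:6])([CH3:7])([CH3:1])[C:2]([CH3:3])=[O:4].[OH2:8]",
        0.5,
        ["l"],
        "water product restored by balancing",
    ),
    Fixture(
        "allylic_transposition",
        "CC=CCCl>>CC(Cl)C=C",
        "[CH3:1][CH:2]=[CH:3][CH2:4][Cl:5]"
        ">>[CH3:1][CH:2]([Cl:5])[CH:3]=[CH2:4]",
        0.5,
        ["n"],
    ),
    Fixture(
        "meinwald_rearrangement",
        "CC1CO1>>CC(C)=O",
        "[CH3:1][CH:2]1[CH2:3][O:4]1>>[CH3:1][C:2]([CH3:3])=[O:4]",
        0.5,
        ["p"],
    ),
    Fixture(
        "beckmann_rearrangement",
        "CC(C)=NO>>CC(=O)NC",
        "[CH3:1][C:2]([CH3:3])=[N:4][O:5]"
        ">>[CH3:3][C:2](=[O:5])[NH:4][CH3:1]",
        0.5,
        ["q"],
    ),
    Fixture(
        "retro_diels_alder",
        "C1=CCCCC1>>C=CC=C.C=C",
        "[CH:1]1=[CH:2][CH2:3][CH2:4][CH2:5][CH2:6]1"
        ">>[CH2:6]=[CH:1][CH:2]=[CH2:3].[CH2:4]=[CH2:5]",
        0.5,
        ["u"],
    ),
    Fixture(
        "prins_cyclization",
        "C=CCCO.C=O>>OC1CCOCC1",
        "[CH2:1]=[CH:2][CH2:3][CH2:4][O:5][H].[CH2:6]=[O:7]"
        ">>[O:7]([H])[CH:2]1[CH2:3][CH2:4][O:5][CH2:6][CH2:1]1",
        2.5,
        ["d"],
        "two oxygen sources; the minimal-cut solution assigns them wrongly",
    ),
    Fixture(
        "prins_pinacol_cascade",
        "O=CCCCC(C)(O)C=C>>CC1CCCCC(=O)CO1",
        "[O:1]=[CH:2][CH2:3][CH2:4][CH2:5][C:6]([CH3:7])([O:8][H])[CH:9]=[CH2:10]"
        ">>[CH3:10][CH:2]1[CH2:3][CH2:4][CH2:5][CH2:9][C:6](=[O:8])[CH2:7][O:1]1",
        3.5,
        ["s"],
        "worked example: wrong-site application of [s] scores 4.5",
    ),
    Fixture(
        "sn2_amination",
        "CCBr.N>>CCN.[BrH]",
        "[CH3:1][CH2:2][Br:3].[NH3:4]>>[CH3:1][CH2:2][NH2:4].[Br:3][H]",
        2.0,
        [],
    ),
    Fixture(
        "alcohol_oxidation",
        "CC(C)O>>CC(C)=O",
        "[CH3:1][CH:2]([CH3:3])[O:4][H]>>[CH3:1][C:2]([CH3:3])=[O:4].[H].[H]",
        3.0,
        [],
        "two missing hydrogens restored as one-atom molecules",
    ),
    Fixture(
        "amide_hydrolysis",
        "CC(=O)NC>>CC(=O)O.NC",
        "[CH3:1][C:2](=[O:3])[NH:4][CH3:5].[OH2:6]"
        ">>[CH3:1][C:2](=[O:3])[O:6][H].[NH2:4][CH3:5]",
        2.0,
        [],
        "missing water restored on the reactant side",
    ),
    Fixture(
        "hantzsch_dihydropyridine",
        "CC(=O)CC(=O)OC.C=O.N>>COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1",
        None,
        None,
        [],
        "balancing showcase: one ketoester copy plus three waters; the full "
        "mapping exceeds the default search budget",
    ),
]


def builtin_fixtures() -> list[Fixture]:
    """The shipped fixture corpus (>= 12 reactions, all heuristic groups)."""
    return list(_BUILTIN)


# -- automorphism-aware mapping comparison ---------------------------------


def _heavy_graph(g: MolGraph) -> MolGraph:
    return g.subgraph(g.heavy_ids())


def truth_mapping(truth: str) -> tuple[ReactionRecord, AtomMapping]:
    """Parse a mapped reaction SMILES into a record plus its mapping."""
    rec = parse_reaction(truth)
    m = rec.reference_mapping()
    if m is None:
        raise ValueError("truth carries no atom-map numbers")
    return rec, m


def mappings_agree(
    rec_a: ReactionRecord,
    map_a: AtomMapping,
    rec_b: ReactionRecord,
    map_b: AtomMapping,
) -> bool:
    """Automorphism-aware equality of two heavy-atom mappings.

    The mappings agree when reactant- and product-side isomorphisms
    sigma_R, sigma_P exist with ``map_b o sigma_R == sigma_P o map_a`` —
    i.e. the assignments differ only by a relabelling symmetry of the
    molecules, as with the two equivalent mappings of a symmetric product.
    """
    ra, pa = _heavy_graph(rec_a.reactant_graph()), _heavy_graph(rec_a.product_graph())
    rb, pb = _heavy_graph(rec_b.reactant_graph()), _heavy_graph(rec_b.product_graph())
    a = {i: j for i, j in map_a.pairs.items() if i in ra.atoms}
    b = {i: j for i, j in map_b.pairs.items() if i in rb.atoms}
    if len(a) != len(b):
        return False
    sigmas, _ = neighbor_extend_match(ra, rb)
    for sigma_r, _changes, _cost in sigmas:
        # tau must be the product-side isomorphism induced by sigma_r
        tau = {}
        ok = True
        for i, j in a.items():
            i2 = sigma_r[i]
            if i2 not in b:
                ok = False
                break
            tau[j] = b[i2]
        if not ok or len(set(tau.values())) != len(tau):
            continue
        if _is_isomorphism(pa, pb, tau):
            return True
    return False


def _is_isomorphism(g1: MolGraph, g2: MolGraph, m: dict[int, int]) -> bool:
    if set(m) != set(g1.atoms) or set(m.values()) != set(g2.atoms):
        return False
    for i, j in m.items():
        if g1.atoms[i].element != g2.atoms[j].element:
            return False
    if len(g1.bonds) != len(g2.bonds):
        return False
    for (i, j), bond in g1.bonds.items():
        other = g2.get_bond(m[i], m[j])
        if other is None or other.order != bond.order:
            return False
    return True


# -- random decorated fixtures ---------------------------------------------

_CORES: list[tuple[str, str, float, list[str]]] = [
    (
        "sn2_core",
        "[CH3:1][CH2:2][Br:3].[NH3:4]>>[CH3:1][CH2:2][NH2:4].[Br:3][H]",
        2.0,
        [],
    ),
    (
        "williamson_core",
        "[CH3:1][O:2][H].[Cl:3][CH2:4][CH3:5]"
        ">>[CH3:1][O:2][CH2:4][CH3:5].[Cl:3][H]",
        2.0,
        [],
    ),
    (
        "elimination_core",
        "[CH3:1][CH2:2][CH:3]([Br:4])[CH3:5]"
        ">>[CH3:1][CH:2]=[CH:3][CH3:5].[Br:4][H]",
        3.0,
        [],
    ),
    (
        "diels_alder_core",
        "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
        ">>[CH:2]1=[CH:3][CH2:4][CH2:5][CH2:6][CH2:1]1",
        0.5,
        ["a"],
    ),
]


def _decorate_side(mol: Chem.Mol, target_map: int, chain: list[int]) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    target = next(
        a for a in rw.GetAtoms() if a.GetAtomMapNum() == target_map
    )
    if target.GetNumExplicitHs() > 0:
        target.SetNumExplicitHs(target.GetNumExplicitHs() - 1)
    prev = target.GetIdx()
    for map_num in chain:
        at = Chem.Atom("C")
        at.SetAtomMapNum(map_num)
        idx = rw.AddAtom(at)
        rw.AddBond(prev, idx, Chem.BondType.SINGLE)
        prev = idx
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def random_decorated_reaction(
    seed: int, size: tuple[int, int] = (6, 12)
) -> Fixture:
    """A core transform with random alkyl decorations on both sides.

    Deterministic per seed; the truth mapping is correct by construction
    because each substituent is grafted onto the same mapped atom on both
    sides.  ``size`` bounds the heavy-atom count of the reactant side.
    """
    rng = random.Random(seed)
    name, truth, score, heur = rng.choice(_CORES)
    rside, aside, pside = truth.split(">")
    rmol = Chem.MolFromSmiles(rside)
    pmol = Chem.MolFromSmiles(pside)
    next_map = max(a.GetAtomMapNum() for a in rmol.GetAtoms()) + 1
    lo, hi = size
    target_heavy = rng.randint(max(lo, rmol.GetNumAtoms()), max(hi, rmol.GetNumAtoms()))
    guard = 0
    while rmol.GetNumAtoms() < target_heavy and guard < 20:
        guard += 1
        candidates = [
            a.GetAtomMapNum()
            for a in rmol.GetAtoms()
            if a.GetAtomMapNum() and a.GetNumExplicitHs() > 0 and a.GetSymbol() == "C"
        ]
        pmaps = {
            a.GetAtomMapNum()
            for a in pmol.GetAtoms()
            if a.GetAtomMapNum() and a.GetNumExplicitHs() > 0
        }
        candidates = [m for m in candidates if m in pmaps]
        if not candidates:
            break
        target_map = rng.choice(candidates)
        chain_len = rng.randint(1, min(3, target_heavy - rmol.GetNumAtoms()))
        chain = list(range(next_map, next_map + chain_len))
        next_map += chain_len
        rmol = _decorate_side(rmol, target_map, chain)
        pmol = _decorate_side(pmol, target_map, chain)
    truth_out = f"{Chem.MolToSmiles(rmol)}>{aside}>{Chem.MolToSmiles(pmol)}"
    plain_r = Chem.MolToSmiles(_strip_maps(rmol))
    plain_p = Chem.MolToSmiles(_strip_maps(pmol))
    return Fixture(
        name=f"{name}_seed{seed}",
        reaction=f"{plain_r}>{aside}>{plain_p}",
        truth=truth_out,
        expected_score=score,
        expected_heuristics=heur,
    )


def _strip_maps(mol: Chem.Mol) -> Chem.Mol:
    out = Chem.Mol(mol)
    for a in out.GetAtoms():
        a.SetAtomMapNum(0)
    return out
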