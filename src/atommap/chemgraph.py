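"""Molecular / reaction graph data model and reaction I/O.

Molecules are labelled graphs: atoms (with element, charge, aromaticity) and
bonds (with order single/aromatic/double/triple).  Hydrogens are made explicit
for all mapping computations because the mapping score counts bonds to
hydrogen like any other bond; output emits heavy-atom maps by default.

RDKit does the heavy lifting for SMILES / RXN parsing, valence checking and
SMILES output; the in-memory model used by the matcher is the plain
:class:`MolGraph` below, which supports arbitrary (non-contiguous) atom ids so
that species extracted from a reaction side keep their side-global ids.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import AllChem

from .errors import ChemistryError, InputError, OutputError, ParseError

RDLogger.DisableLog("rdApp.*")

# Bond orders are kept numeric so that edit costs (order units) fall out
# naturally: cutting a double bond removes two order units (sigma + pi).
ORDER_SINGLE = 1.0
ORDER_AROMATIC = 1.5
ORDER_DOUBLE = 2.0
ORDER_TRIPLE = 3.0

_RD_TO_ORDER = {
    Chem.BondType.SINGLE: ORDER_SINGLE,
    Chem.BondType.AROMATIC: ORDER_AROMATIC,
    Chem.BondType.DOUBLE: ORDER_DOUBLE,
    Chem.BondType.TRIPLE: ORDER_TRIPLE,
}
_ORDER_TO_RD = {v: k for k, v in _RD_TO_ORDER.items()}


@dataclass
class Atom:
    """One atom node.

    ``index`` is unique within its graph (and within its reaction side for
    species extracted from a reaction).  ``map_number`` carries an atom-map
    annotation read from input; the mapper itself ignores it.
    """

    index: int
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    is_explicit_hydrogen: bool = False
    map_number: Optional[int] = None


@dataclass
class Bond:
    """Undirected bond between two atom ids.

    ``protected`` marks bonds that heuristic rewriting forbids from appearing
    in any subsequent cut set.
    """

    i: int
    j: int
    order: float = ORDER_SINGLE
    protected: bool = False

    @property
    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


def bond_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


class MolGraph:
    """A molecular graph (one species or a whole multi-component side)."""

    def __init__(self, atoms: Iterable[Atom] = (), bonds: Iterable[Bond] = ()):
        self.atoms: dict[int, Atom] = {}
        self.bonds: dict[tuple[int, int], Bond] = {}
        self._adj: dict[int, dict[int, Bond]] = {}
        for a in atoms:
            self.add_atom(a)
        for b in bonds:
            self.add_bond(b)

    # -- construction -----------------------------------------------------

    def add_atom(self, atom: Atom) -> None:
        if atom.index in self.atoms:
            raise ValueError(f"duplicate atom index {atom.index}")
        self.atoms[atom.index] = atom
        self._adj[atom.index] = {}

    def add_bond(self, bond: Bond) -> None:
        if bond.i == bond.j:
            raise ValueError("self-bond")
        if bond.i not in self.atoms or bond.j not in self.atoms:
            raise ValueError("bond endpoint missing from graph")
        key = bond.key
        if key in self.bonds:
            raise ValueError(f"duplicate bond {key}")
        self.bonds[key] = bond
        self._adj[bond.i][bond.j] = bond
        self._adj[bond.j][bond.i] = bond

    def remove_bond(self, i: int, j: int) -> Bond:
        bond = self.bonds.pop(bond_key(i, j))
        del self._adj[i][j]
        del self._adj[j][i]
        return bond

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def atom_ids(self) -> list[int]:
        return sorted(self.atoms)

    def neighbors(self, i: int) -> dict[int, Bond]:
        return self._adj[i]

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def get_bond(self, i: int, j: int) -> Optional[Bond]:
        return self.bonds.get(bond_key(i, j))

    def element_counts(self) -> Counter:
        return Counter(a.element for a in self.atoms.values())

    def heavy_ids(self) -> list[int]:
        return sorted(i for i, a in self.atoms.items() if a.element != "H")

    def copy(self) -> "MolGraph":
        return MolGraph(
            (replace(a) for a in self.atoms.values()),
            (replace(b) for b in self.bonds.values()),
        )

    def subgraph(self, ids: Iterable[int]) -> "MolGraph":
        """Induced subgraph; atom ids are preserved."""
        keep = set(ids)
        g = MolGraph()
        for i in sorted(keep):
            g.add_atom(replace(self.atoms[i]))
        for (i, j), b in self.bonds.items():
            if i in keep and j in keep:
                g.add_bond(replace(b))
        return g

    def component_ids(self) -> list[set[int]]:
        """Connected components as sets of atom ids (deterministic order)."""
        seen: set[int] = set()
        out: list[set[int]] = []
        for start in self.atom_ids():
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                u = stack.pop()
                for v in self._adj[u]:
                    if v not in comp:
                        comp.add(v)
                        stack.append(v)
            seen |= comp
            out.append(comp)
        return out


# -- RDKit bridge ----------------------------------------------------------


def mol_from_rdkit(rdmol: Chem.Mol, index_offset: int = 0) -> MolGraph:
    g = MolGraph()
    for at in rdmol.GetAtoms():
        g.add_atom(
            Atom(
                index=at.GetIdx() + index_offset,
                element=at.GetSymbol(),
                formal_charge=at.GetFormalCharge(),
                aromatic=at.GetIsAromatic(),
                is_explicit_hydrogen=(at.GetSymbol() == "H"),
                map_number=at.GetAtomMapNum() or None,
            )
        )
    for bd in rdmol.GetBonds():
        order = _RD_TO_ORDER.get(bd.GetBondType())
        if order is None:
            raise ParseError(f"unsupported bond type {bd.GetBondType()}")
        g.add_bond(
            Bond(
                bd.GetBeginAtomIdx() + index_offset,
                bd.GetEndAtomIdx() + index_offset,
                order=order,
            )
        )
    return g


def mol_to_rdkit(
    mol: MolGraph, sanitize: bool = True, keep_map_numbers: bool = False
) -> tuple[Chem.Mol, dict[int, int]]:
    """Build an RDKit mol; returns (mol, atommap-id -> rdkit-idx)."""
    rw = Chem.RWMol()
    id_to_idx: dict[int, int] = {}
    for i in mol.atom_ids():
        a = mol.atoms[i]
        rdat = Chem.Atom(a.element)
        rdat.SetFormalCharge(a.formal_charge)
        rdat.SetIsAromatic(a.aromatic)
        rdat.SetNoImplicit(True)
        if keep_map_numbers and a.map_number:
            rdat.SetAtomMapNum(a.map_number)
        id_to_idx[i] = rw.AddAtom(rdat)
    for (i, j), b in mol.bonds.items():
        rw.AddBond(id_to_idx[i], id_to_idx[j], _ORDER_TO_RD[b.order])
        if b.order == ORDER_AROMATIC:
            rw.GetBondBetweenAtoms(id_to_idx[i], id_to_idx[j]).SetIsAromatic(True)
    out = rw.GetMol()
    if sanitize:
        try:
            Chem.SanitizeMol(out)
        except Exception:
            # Fall back to a partial sanitization: enough for substructure
            # matching (ring info, valence bookkeeping) without kekulization.
            out = rw.GetMol()
            Chem.SanitizeMol(
                out,
                Chem.SanitizeFlags.SANITIZE_FINDRADICALS
                | Chem.SanitizeFlags.SANITIZE_SETCONJUGATION
                | Chem.SanitizeFlags.SANITIZE_SETHYBRIDIZATION
                | Chem.SanitizeFlags.SANITIZE_SYMMRINGS,
                catchErrors=True,
            )
    return out, id_to_idx


def check_valences(mol: MolGraph) -> bool:
    """True iff RDKit accepts the explicit-valence picture of every atom."""
    try:
        rd, _ = mol_to_rdkit(mol, sanitize=False)
        Chem.SanitizeMol(rd)
        return True
    except Exception:
        return False


# -- reaction record -------------------------------------------------------


@dataclass
class Addition:
    """One species added during stoichiometry balancing."""

    species_smiles: str
    side: str  # "reactants" | "products"
    reason: str  # "copy" | "template" | "water" | "single_atom"


@dataclass
class ReactionRecord:
    """Reactants, products and agents of one reaction.

    Species within a side share one id space (side-global ids), so a side can
    be combined into a single :class:`MolGraph` without re-indexing.
    """

    reactants: list[MolGraph] = field(default_factory=list)
    products: list[MolGraph] = field(default_factory=list)
    agents: list[MolGraph] = field(default_factory=list)
    additions: list[Addition] = field(default_factory=list)

    @property
    def balance_deficit(self) -> dict[str, int]:
        """Per-element signed count: reactant count minus product count."""
        d: Counter = Counter()
        for m in self.reactants:
            for e, c in m.element_counts().items():
                d[e] += c
        for m in self.products:
            for e, c in m.element_counts().items():
                d[e] -= c  # plain arithmetic: Counter.__sub__ drops negatives
        return {e: c for e, c in sorted(d.items()) if c != 0}

    @property
    def is_balanced(self) -> bool:
        return not self.balance_deficit

    def reactant_graph(self) -> MolGraph:
        return combine(self.reactants)

    def product_graph(self) -> MolGraph:
        return combine(self.products)

    def copy(self) -> "ReactionRecord":
        return ReactionRecord(
            [m.copy() for m in self.reactants],
            [m.copy() for m in self.products],
            [m.copy() for m in self.agents],
            list(self.additions),
        )

    def reference_mapping(self) -> Optional["AtomMapping"]:
        """Mapping implied by input atom-map numbers, if both sides carry them."""
        rnums = {
            a.map_number: a.index
            for m in self.reactants
            for a in m.atoms.values()
            if a.map_number
        }
        pnums = {
            a.map_number: a.index
            for m in self.products
            for a in m.atoms.values()
            if a.map_number
        }
        common = set(rnums) & set(pnums)
        if not common:
            return None
        return AtomMapping({rnums[n]: pnums[n] for n in common})


def combine(mols: Iterable[MolGraph]) -> MolGraph:
    """Union of species graphs (ids must already be disjoint)."""
    g = MolGraph()
    for m in mols:
        for i in m.atom_ids():
            g.add_atom(replace(m.atoms[i]))
        for b in m.bonds.values():
            g.add_bond(replace(b))
    return g


class AtomMapping:
    """Injective association reactant-atom-id -> product-atom-id."""

    def __init__(self, pairs: Optional[dict[int, int]] = None):
        self.pairs: dict[int, int] = dict(pairs or {})
        if len(set(self.pairs.values())) != len(self.pairs):
            raise ValueError("mapping is not injective")

    def __len__(self) -> int:
        return len(self.pairs)

    def __getitem__(self, i: int) -> int:
        return self.pairs[i]

    def __contains__(self, i: int) -> bool:
        return i in self.pairs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AtomMapping) and self.pairs == other.pairs

    def inverse(self) -> dict[int, int]:
        return {v: k for k, v in self.pairs.items()}

    def items(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs.items()))

    def is_element_preserving(self, r: MolGraph, p: MolGraph) -> bool:
        return all(
            r.atoms[i].element == p.atoms[j].element for i, j in self.pairs.items()
        )


# -- parsing ---------------------------------------------------------------


def _parse_side(text: str, explicit_h: bool) -> list[MolGraph]:
    """Parse one '.'-joined side into species graphs sharing one id space."""
    if not text:
        return []
    rd = Chem.MolFromSmiles(text, sanitize=True)
    if rd is None:
        raise ParseError(f"unparsable SMILES: {text!r}")
    if explicit_h:
        rd = Chem.AddHs(rd)
    frag_idx_lists = Chem.GetMolFrags(rd, asMols=False)
    whole = mol_from_rdkit(rd)
    return [whole.subgraph(ids) for ids in frag_idx_lists]


def parse_reaction(text: str, explicit_h: bool = True) -> ReactionRecord:
    """Parse a reaction SMILES ``reactants>agents>products``.

    Atom-map numbers present in the input are retained on the atoms (for use
    as reference mappings) but are otherwise ignored by the mapper.
    """
    text = text.strip()
    parts = text.split(">")
    if len(parts) == 2:  # tolerate ">>" written as "a>>b" -> ['a','','b'] is 3
        parts = [parts[0], "", parts[1]]
    if len(parts) != 3:
        raise ParseError(
            f"expected 'reactants>agents>products' with two '>' separators: {text!r}"
        )
    rtxt, atxt, ptxt = (p.strip() for p in parts)
    if not rtxt or not ptxt:
        raise InputError("reaction must have a non-empty reactant and product side")
    reactants = _parse_side(rtxt, explicit_h)
    products = _parse_side(ptxt, explicit_h)
    agents = _parse_side(atxt, explicit_h) if atxt else []
    return ReactionRecord(reactants, products, agents)


def parse_rxn_block(text: str, explicit_h: bool = True) -> ReactionRecord:
    """Parse an MDL RXN V2000 block."""
    try:
        rxn = AllChem.ReactionFromRxnBlock(text)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise ParseError(f"unparsable RXN block: {exc}") from None
    if rxn is None:
        raise ParseError("unparsable RXN block")
    smi_r = ".".join(Chem.MolToSmiles(m) for m in rxn.GetReactants())
    smi_p = ".".join(Chem.MolToSmiles(m) for m in rxn.GetProducts())
    if not smi_r or not smi_p:
        raise InputError("RXN block must contain reactants and products")
    return parse_reaction(f"{smi_r}>>{smi_p}", explicit_h=explicit_h)


# -- operations ------------------------------------------------------------


def explicitize_hydrogens(mol: MolGraph) -> MolGraph:
    """Return a copy with every implicit hydrogen as an explicit atom.

    The heavy-atom subgraph is unchanged.  Raises :class:`ChemistryError` for
    unresolvable valences.
    """
    try:
        rd, _ = mol_to_rdkit(mol, sanitize=False)
        for at in rd.GetAtoms():
            at.SetNoImplicit(False)
        Chem.SanitizeMol(rd)
        rd = Chem.AddHs(rd)
    except ChemistryError:
        raise
    except Exception as exc:
        raise ChemistryError(f"unresolvable valence: {exc}") from None
    return mol_from_rdkit(rd)


def connected_components(mols: list[MolGraph]) -> list[MolGraph]:
    """Split a list of graphs into maximal connected subgraphs (ids preserved)."""
    out: list[MolGraph] = []
    for m in mols:
        for comp in m.component_ids():
            out.append(m.subgraph(comp))
    return out


def species_smiles(mol: MolGraph, heavy_only_h: bool = True) -> str:
    """Canonical SMILES of one species (implicit-H convention)."""
    rd, _ = mol_to_rdkit(mol, sanitize=True)
    try:
        rd = Chem.RemoveHs(rd)
    except Exception:
        pass
    return Chem.MolToSmiles(rd)


def write_mapped_reaction(
    rxn: ReactionRecord,
    mapping: AtomMapping,
    emit_h_maps: bool = False,
    strict: bool = True,
) -> str:
    """Serialize a mapped reaction as reaction SMILES with ``:n`` annotations.

    Reactant atom *i* and product atom ``mapping[i]`` carry the same map
    number.  Heavy atoms only by default; ``emit_h_maps`` includes hydrogens.
    """
    rside = rxn.reactant_graph()
    pside = rxn.product_graph()
    heavy = set(rside.heavy_ids())
    missing = heavy - set(mapping.pairs)
    if missing and strict:
        raise OutputError(
            f"mapping incomplete over heavy atoms (missing reactant ids {sorted(missing)})"
        )
    numbers: dict[int, int] = {}
    n = 0
    for i in sorted(mapping.pairs):
        if rside.atoms[i].element == "H" and not emit_h_maps:
            continue
        n += 1
        numbers[i] = n

    def _side_smiles(side_mols: list[MolGraph], is_product: bool) -> str:
        pieces = []
        inv = mapping.inverse()
        for m in side_mols:
            mm = m.copy()
            for a in mm.atoms.values():
                if is_product:
                    src = inv.get(a.index)
                    a.map_number = numbers.get(src) if src is not None else None
                else:
                    a.map_number = numbers.get(a.index)
            rd, _ = mol_to_rdkit(mm, sanitize=True, keep_map_numbers=True)
            try:
                rd = Chem.RemoveHs(rd)  # keeps hydrogens that carry map numbers
            except Exception:
                pass
            pieces.append(Chem.MolToSmiles(rd))
        return ".".join(pieces)

    left = _side_smiles(rxn.reactants, is_product=False)
    right = _side_smiles(rxn.products, is_product=True)
    middle = ".".join(species_smiles(m) for m in rxn.agents) if rxn.agents else ""
    return f"{left}>{middle}>{right}"
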