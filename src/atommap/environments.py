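"""Canonical k-th-order atom environments and cross-reaction bucket sorting.

An atom's *k-th-order environment* is the subgraph induced by all atoms
within ``k`` bonds of it.  Atoms are labelled by a canonical serialization of
that rooted subgraph — an exact structural descriptor, not a scalar
extended-connectivity code — so two atoms receive the same descriptor exactly
when their radius-``k`` neighbourhoods are isomorphic with the roots
corresponding.

Canonicalization uses colour refinement (Weisfeiler-Lehman style) followed by
individualization of the first non-singleton colour class, taking the
lexicographically smallest serialization over all branches.  This is exact
for arbitrary graphs; molecular neighbourhood subgraphs are small enough that
the worst-case branching never matters in practice.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional

from .chemgraph import MolGraph

MAX_ORDER = 4


@dataclass(frozen=True)
class AtomEnvironment:
    """Canonical descriptor of the radius-``order`` subgraph around an atom."""

    root_atom: int
    order: int
    descriptor: str


@dataclass
class BucketPartition:
    """Atoms of both reaction sides grouped by identical environments.

    ``classes`` maps descriptor -> (reactant atom ids, product atom ids).
    """

    order: int
    classes: dict[str, tuple[list[int], list[int]]]


# -- canonical labelling ----------------------------------------------------


def _atom_color(g: MolGraph, i: int, include_charge: bool, include_aromatic: bool) -> str:
    a = g.atoms[i]
    parts = [a.element]
    if include_charge:
        parts.append(str(a.formal_charge))
    if include_aromatic:
        parts.append("a" if a.aromatic else "-")
    return "|".join(parts)


def _refine(g: MolGraph, ids: list[int], colors: dict[int, int]) -> dict[int, int]:
    """Iterated colour refinement until the partition is stable."""
    while True:
        sigs = {}
        for v in ids:
            nbr = sorted(
                (g.neighbors(v)[u].order, colors[u])
                for u in g.neighbors(v)
                if u in colors
            )
            sigs[v] = (colors[v], tuple(nbr))
        order = sorted(set(sigs.values()))
        rank = {s: r for r, s in enumerate(order)}
        new = {v: rank[sigs[v]] for v in ids}
        if new == colors:
            return new
        colors = new


def _serialize(g: MolGraph, ids: list[int], colors: dict[int, int], init: dict[int, str]) -> str:
    """Serialization under the (discrete) colour order."""
    order = sorted(ids, key=lambda v: colors[v])
    pos = {v: p for p, v in enumerate(order)}
    atoms = ";".join(init[v] for v in order)
    edges = []
    for (i, j), b in g.bonds.items():
        if i in pos and j in pos:
            pi, pj = sorted((pos[i], pos[j]))
            edges.append((pi, pj, b.order))
    edges.sort()
    etxt = ";".join(f"{i},{j},{o:g}" for i, j, o in edges)
    return atoms + "//" + etxt


def _canonical(g: MolGraph, ids: list[int], colors: dict[int, int], init: dict[int, str]) -> str:
    colors = _refine(g, ids, colors)
    by_color: dict[int, list[int]] = defaultdict(list)
    for v in ids:
        by_color[colors[v]].append(v)
    target = None
    for c in sorted(by_color):
        if len(by_color[c]) > 1 and (target is None or len(by_color[c]) < len(target)):
            target = by_color[c]
    if target is None:
        return _serialize(g, ids, colors, init)
    # Individualize one representative per twin class of the smallest tied
    # colour class; true twins (identical neighbourhoods) are automorphic, so
    # branching on more than one of them cannot change the minimum.
    twins: dict[tuple, int] = {}
    for v in sorted(target):
        sig = tuple(sorted((u, g.neighbors(v)[u].order) for u in g.neighbors(v) if u in colors))
        twins.setdefault(sig, v)
    best: Optional[str] = None
    n = len(ids)
    for v in sorted(twins.values()):
        branched = dict(colors)
        branched[v] = n + 1  # fresh colour
        s = _canonical(g, ids, branched, init)
        if best is None or s < best:
            best = s
    return best  # type: ignore[return-value]


def canonical_form(
    mol: MolGraph,
    ids: Optional[list[int]] = None,
    root: Optional[int] = None,
    include_charge: bool = True,
    include_aromatic: bool = True,
) -> str:
    """Canonical serialization of (a vertex subset of) a molecular graph.

    With ``root`` given, the serialization is canonical for *root-preserving*
    isomorphism: equal strings iff the graphs are isomorphic by a map sending
    root to root.
    """
    if ids is None:
        ids = mol.atom_ids()
    init = {
        v: _atom_color(mol, v, include_charge, include_aromatic)
        + ("!R" if v == root else "")
        for v in ids
    }
    order = sorted(set(init.values()))
    rank = {s: r for r, s in enumerate(order)}
    colors = {v: rank[init[v]] for v in ids}
    return _canonical(mol, ids, colors, init)


# -- environments -----------------------------------------------------------


def _ball(mol: MolGraph, root: int, k: int) -> list[int]:
    """Atom ids within k bonds of root."""
    dist = {root: 0}
    frontier = [root]
    for d in range(1, k + 1):
        nxt = []
        for u in frontier:
            for v in mol.neighbors(u):
                if v not in dist:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return sorted(dist)


def environment(
    mol: MolGraph,
    atom: int,
    k: int,
    include_charge: bool = True,
    include_aromatic: bool = True,
) -> AtomEnvironment:
    """Canonical descriptor of the order-``k`` environment of ``atom``."""
    if not 1 <= k <= MAX_ORDER:
        raise ValueError(f"environment order must be in 1..{MAX_ORDER}, got {k}")
    if atom not in mol.atoms:
        raise KeyError(f"atom {atom} not in graph")
    ids = _ball(mol, atom, k)
    desc = canonical_form(
        mol, ids, root=atom,
        include_charge=include_charge, include_aromatic=include_aromatic,
    )
    return AtomEnvironment(root_atom=atom, order=k, descriptor=f"k{k}:" + desc)


def all_environments(mol: MolGraph, k: int, **kw) -> dict[int, str]:
    """Descriptor for every atom of ``mol`` at order ``k``."""
    return {i: environment(mol, i, k, **kw).descriptor for i in mol.atom_ids()}


def bucket_partition(
    reactants: list[MolGraph] | MolGraph,
    products: list[MolGraph] | MolGraph,
    k: int,
    **kw,
) -> BucketPartition:
    """Bucket-sort all atoms of both sides by their order-``k`` environments."""
    from .chemgraph import combine  # late import to avoid cycle at module load

    rg = reactants if isinstance(reactants, MolGraph) else combine(reactants)
    pg = products if isinstance(products, MolGraph) else combine(products)
    classes: dict[str, tuple[list[int], list[int]]] = {}
    for i, d in all_environments(rg, k, **kw).items():
        classes.setdefault(d, ([], []))[0].append(i)
    for i, d in all_environments(pg, k, **kw).items():
        classes.setdefault(d, ([], []))[1].append(i)
    return BucketPartition(order=k, classes=classes)


def environment_multiset(mol: MolGraph, ids: list[int] | None, k: int) -> Counter:
    """Multiset of order-``k`` descriptors over ``ids`` (used by Test 3)."""
    if ids is None:
        ids = mol.atom_ids()
    return Counter(environment(mol, i, k).descriptor for i in ids)
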