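"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's search machinery: plain enumeration
over atom bijections and permutations, with hydrogen placement handled by
counting (hydrogens attached to a heavy atom are interchangeable, so for a
fixed heavy-atom bijection the optimal hydrogen extension keeps
min(h_r, h_p) hydrogens per atom and cuts the excess).
"""

from __future__ import annotations

import math
from collections import defaultdict

from atommap.chemgraph import MolGraph


def _heavy_by_element(g: MolGraph) -> dict[str, list[int]]:
    out: dict[str, list[int]] = defaultdict(list)
    for i in g.heavy_ids():
        out[g.atoms[i].element].append(i)
    return out


def _h_count(g: MolGraph, i: int) -> int:
    return sum(1 for n in g.neighbors(i) if g.atoms[n].element == "H")


def brute_force_min_cost(rg: MolGraph, pg: MolGraph) -> float:
    """Minimal edit cost over all element-preserving bijections.

    Cost: a reactant bond whose image is absent costs its order; whose image
    has a different order costs the absolute difference; product-only bonds
    are free.  Assumes equal element counts and no H-H bonds.
    """
    for g in (rg, pg):
        for (i, j) in g.bonds:
            assert not (
                g.atoms[i].element == "H" and g.atoms[j].element == "H"
            ), "oracle does not handle H-H bonds"
    r_el, p_el = _heavy_by_element(rg), _heavy_by_element(pg)
    assert sorted(r_el) == sorted(p_el)
    order: list[int] = [i for el in sorted(r_el) for i in r_el[el]]
    pools = {el: list(p_el[el]) for el in p_el}
    best = [math.inf]

    def h_cost(i: int, j: int) -> float:
        return float(max(0, _h_count(rg, i) - _h_count(pg, j)))

    def rec(k: int, assign: dict[int, int], used: set[int], cost: float) -> None:
        if cost >= best[0]:
            return
        if k == len(order):
            best[0] = cost
            return
        i = order[k]
        for j in pools[rg.atoms[i].element]:
            if j in used:
                continue
            delta = h_cost(i, j)
            for w, b in rg.neighbors(i).items():
                if w in assign:
                    pb = pg.get_bond(j, assign[w])
                    delta += b.order if pb is None else abs(pb.order - b.order)
            if cost + delta < best[0]:
                assign[i] = j
                used.add(j)
                rec(k + 1, assign, used, cost + delta)
                del assign[i]
                used.remove(j)

    rec(0, {}, set(), 0.0)
    return best[0]


def _atom_eq(a, b) -> bool:
    return (
        a.element == b.element
        and a.formal_charge == b.formal_charge
        and a.aromatic == b.aromatic
    )


def _all_isomorphisms(
    g1: MolGraph,
    g2: MolGraph,
    fixed: dict[int, int],
    first_only: bool = False,
) -> list[dict[int, int]]:
    """Exhaustive backtracking over atom assignments in id order.

    Independent of the package's matcher: no environments, no neighbour
    blocks — plain depth-first assignment with edge-consistency checks.
    """
    ids1 = g1.atom_ids()
    out: list[dict[int, int]] = []

    def rec(k: int, m: dict[int, int], used: set[int]) -> bool:
        if k == len(ids1):
            out.append(dict(m))
            return first_only
        i = ids1[k]
        if i in fixed:
            targets = [fixed[i]]
        else:
            targets = [j for j in g2.atom_ids() if j not in used]
        for j in targets:
            if j in used or not _atom_eq(g1.atoms[i], g2.atoms[j]):
                continue
            if g1.degree(i) != g2.degree(j):
                continue
            ok = True
            for w, b in g1.neighbors(i).items():
                if w in m:
                    pb = g2.get_bond(j, m[w])
                    if pb is None or pb.order != b.order:
                        ok = False
                        break
            if not ok:
                continue
            m[i] = j
            used.add(j)
            if rec(k + 1, m, used):
                return True
            del m[i]
            used.remove(j)
        return False

    if len(ids1) == len(g2) and len(g1.bonds) == len(g2.bonds):
        rec(0, {}, set())
    return out


def brute_force_isomorphisms(g1: MolGraph, g2: MolGraph) -> list[dict[int, int]]:
    """All exact isomorphisms of g1 onto g2 (element, charge, order equal)."""
    return _all_isomorphisms(g1, g2, fixed={})


def rooted_isomorphic(g1: MolGraph, r1: int, g2: MolGraph, r2: int) -> bool:
    """Root-preserving isomorphism test by exhaustive backtracking."""
    if not _atom_eq(g1.atoms[r1], g2.atoms[r2]):
        return False
    return bool(_all_isomorphisms(g1, g2, fixed={r1: r2}, first_only=True))


def union_find_components(n_atoms: list[int], edges: list[tuple[int, int]]) -> int:
    """Component count by union-find (oracle for connected_components)."""
    parent = {i: i for i in n_atoms}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return len({find(i) for i in n_atoms})
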