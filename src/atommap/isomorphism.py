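"""Isomorphic mapping search: combinatorial tests, matcher, cut sets, scoring.

The mapping score counts bond-order units edited on the reactant side:
cutting a bond costs its order (single 1, aromatic 1.5, double 2, triple 3 —
a fully broken double bond is a sigma and a pi bond), changing a bond's order
costs the absolute order difference, and bonds formed on the product side are
free.  Heuristic applications contribute their template scores.  The search
strives to find complete mappings of minimal score.

The matcher is a VF2 variant that, rather than adding one node at a time,
extends a partial matching to *all* unmatched immediate neighbours of a
matched atom before moving on, back-tracking when a block cannot be placed.
Search effort is metered as decision-tree vertices against a budget
(default one million vertices per reaction).
"""

from __future__ import annotations

import itertools
import math
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from .chemgraph import (
    AtomMapping,
    Bond,
    MolGraph,
    ReactionRecord,
    bond_key,
    connected_components,
)
from .environments import MAX_ORDER, bucket_partition, canonical_form, environment_multiset
from .errors import BudgetExceeded


@dataclass
class SearchBudget:
    """Limits on the mapping search."""

    max_tree_vertices: int = 1_000_000
    max_cut_set_size: int = 6
    time_limit_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_tree_vertices <= 0 or self.max_cut_set_size <= 0:
            raise ValueError("budget limits must be positive")

    def counter(self) -> "BudgetCounter":
        return BudgetCounter(self)


class BudgetCounter:
    """Mutable decision-tree vertex counter shared across one reaction."""

    def __init__(self, budget: SearchBudget):
        self.budget = budget
        self.vertices = 0
        self._deadline = (
            time.monotonic() + budget.time_limit_s if budget.time_limit_s else None
        )

    def tick(self) -> None:
        self.vertices += 1
        if self.vertices > self.budget.max_tree_vertices:
            raise BudgetExceeded("decision tree exceeded vertex budget")
        if self._deadline is not None and self.vertices % 1024 == 0:
            if time.monotonic() > self._deadline:
                raise BudgetExceeded("time limit exceeded")


@dataclass
class HeuristicApplication:
    """Provenance of one heuristic template application."""

    template_id: str
    site: tuple[tuple[int, int], ...]  # sorted (pattern label, atom id) pairs
    score: float
    bonds_edited: int = 0


@dataclass
class MappingSolution:
    """A complete atom assignment with its edit script and score."""

    mapping: AtomMapping
    cut_bonds: list[Bond] = field(default_factory=list)
    formed_bonds: list[Bond] = field(default_factory=list)
    order_changed_bonds: list[tuple[tuple[int, int], float, float]] = field(
        default_factory=list
    )
    heuristic_applications: list[HeuristicApplication] = field(default_factory=list)
    score: float = 0.0

    @property
    def broken_bond_units(self) -> float:
        """Bond-order units removed: full cuts plus order reductions."""
        units = sum(b.order for b in self.cut_bonds)
        units += sum(max(0.0, old - new) for _, old, new in self.order_changed_bonds)
        return units

    def sort_key(self) -> tuple:
        return (self.score, tuple(sorted(self.mapping.pairs.items())))


def score(sol: MappingSolution) -> float:
    """Recompute the score of a solution from its edit script."""
    s = sum(b.order for b in sol.cut_bonds)
    s += sum(abs(new - old) for _, old, new in sol.order_changed_bonds)
    s += sum(h.score for h in sol.heuristic_applications)
    return s


def mapping_edit_cost(r: MolGraph, p: MolGraph, mapping: AtomMapping) -> float:
    """Edit cost of an arbitrary complete mapping (no heuristic terms)."""
    cost = 0.0
    for (i, j), b in r.bonds.items():
        if i not in mapping or j not in mapping:
            raise ValueError("mapping incomplete")
        pb = p.get_bond(mapping[i], mapping[j])
        cost += b.order if pb is None else abs(pb.order - b.order)
    return cost


def solution_from_mapping(
    r: MolGraph,
    p: MolGraph,
    mapping: AtomMapping,
    heuristic_applications: Optional[list[HeuristicApplication]] = None,
) -> MappingSolution:
    """Build the canonical edit script of a complete mapping.

    A reactant bond whose image atoms are bonded in the product is an order
    change (possibly trivial); one whose image atoms are not bonded is a cut.
    Product bonds that are no bond's image are formed.
    """
    cuts: list[Bond] = []
    changes: list[tuple[tuple[int, int], float, float]] = []
    covered: set[tuple[int, int]] = set()
    for (i, j), b in sorted(r.bonds.items()):
        pi, pj = mapping[i], mapping[j]
        pb = p.get_bond(pi, pj)
        if pb is None:
            cuts.append(b)
        else:
            covered.add(pb.key)
            if pb.order != b.order:
                changes.append(((i, j), b.order, pb.order))
    formed = [b for k, b in sorted(p.bonds.items()) if k not in covered]
    apps = list(heuristic_applications or [])
    sol = MappingSolution(
        mapping=mapping,
        cut_bonds=cuts,
        formed_bonds=formed,
        order_changed_bonds=changes,
        heuristic_applications=apps,
    )
    sol.score = score(sol)
    return sol


def is_valid_solution(r: MolGraph, p: MolGraph, sol: MappingSolution) -> bool:
    """Machine-check: applying the edit script to the reactant graph yields a
    graph identical (under the mapping) to the product graph."""
    m = sol.mapping
    if set(m.pairs) != set(r.atoms) or set(m.pairs.values()) != set(p.atoms):
        return False
    if not m.is_element_preserving(r, p):
        return False
    cut = {b.key for b in sol.cut_bonds}
    changed = {bond_key(i, j): (old, new) for (i, j), old, new in sol.order_changed_bonds}
    image_edges = {}
    for (i, j), b in r.bonds.items():
        if (i, j) in cut:
            continue
        order = changed[(i, j)][1] if (i, j) in changed else b.order
        image_edges[bond_key(m[i], m[j])] = order
    for b in sol.formed_bonds:
        if b.key in image_edges:
            return False
        image_edges[b.key] = b.order
    p_edges = {k: b.order for k, b in p.bonds.items()}
    return image_edges == p_edges


# -- the four combinatorial tests ------------------------------------------


def test1_component_count(r: ReactionRecord) -> bool:
    """Test 1: equal numbers of connected components on the two sides."""
    return len(connected_components(r.reactants)) == len(
        connected_components(r.products)
    )


def test2_component_sizes(r: ReactionRecord) -> bool:
    """Test 2: components can be matched by atom count."""
    rs = sorted(len(c) for c in connected_components(r.reactants))
    ps = sorted(len(c) for c in connected_components(r.products))
    return rs == ps


def test3_node_multisets(r: ReactionRecord, k: int = MAX_ORDER) -> bool:
    """Test 3: components can be matched by multisets of node environments."""
    def keys(mols):
        out = Counter()
        for c in connected_components(mols):
            ms = environment_multiset(c, None, k)
            out[frozenset(ms.items())] += 1
        return out

    return keys(r.reactants) == keys(r.products)


def test4_pairwise_isomorphism(r: ReactionRecord) -> bool:
    """Test 4: components can be matched pairwise-isomorphically."""
    def keys(mols):
        return Counter(canonical_form(c) for c in connected_components(mols))

    return keys(r.reactants) == keys(r.products)


def component_pairing(r: ReactionRecord) -> Optional[dict[str, tuple[list, list]]]:
    """Candidate component pairing classes when all four tests pass."""
    if not (
        test1_component_count(r)
        and test2_component_sizes(r)
        and test3_node_multisets(r)
        and test4_pairwise_isomorphism(r)
    ):
        return None
    classes: dict[str, tuple[list, list]] = {}
    for c in connected_components(r.reactants):
        classes.setdefault(canonical_form(c), ([], []))[0].append(c)
    for c in connected_components(r.products):
        classes.setdefault(canonical_form(c), ([], []))[1].append(c)
    return classes


# -- neighbour-extension matcher -------------------------------------------


def neighbor_extend_match(
    g1: MolGraph,
    g2: MolGraph,
    seed: Optional[AtomMapping] = None,
    budget: Optional[SearchBudget] = None,
    *,
    allow_order_changes: bool = False,
    cost_bound: float = math.inf,
    collapse_equivalent_leaves: bool = False,
    counter: Optional[BudgetCounter] = None,
) -> tuple[list[tuple[AtomMapping, list, float]], bool]:
    """Complete matchings of ``g1`` into ``g2`` extending ``seed``.

    Every ``g1`` bond must map onto a ``g2`` bond; with
    ``allow_order_changes`` an order mismatch is admitted at cost
    ``|order difference|`` and recorded.  Returns ``(solutions, truncated)``
    where each solution is ``(mapping, order_changes, cost)``; only
    minimal-cost solutions (within ``cost_bound``) are kept.  With
    ``collapse_equivalent_leaves`` interchangeable leaf targets (e.g. the
    hydrogens of a methyl group) are assigned canonically instead of
    permuted.
    """
    if counter is None:
        counter = (budget or SearchBudget()).counter()
    if not allow_order_changes and len(g1) == len(g2) and len(g1.bonds) != len(
        g2.bonds
    ):
        # exact mode on equal-sized graphs is an isomorphism test: a strict
        # monomorphism (g2 with extra bonds) is not a matching
        return [], False
    seed_pairs = dict(seed.pairs) if seed else {}
    for i, j in seed_pairs.items():
        if g1.atoms[i].element != g2.atoms[j].element:
            return [], False
    mapping = dict(seed_pairs)
    used = set(mapping.values())
    order1 = g1.atom_ids()
    best: list[float] = [cost_bound]
    sols: list[tuple[AtomMapping, list, float]] = []
    truncated = [False]

    # cost of seed-adjacent edges is accounted lazily when atoms join; edges
    # internal to the seed are the caller's responsibility (forced edits).
    def pair_cost(n: int, c: int, current: dict[int, int]) -> Optional[list]:
        """Edge-consistency of assigning n->c; returns order changes or None."""
        changes = []
        for w, b in g1.neighbors(n).items():
            if w not in current:
                continue
            pb = g2.get_bond(c, current[w])
            if pb is None:
                return None
            if pb.order != b.order:
                if not allow_order_changes:
                    return None
                changes.append((bond_key(n, w), b.order, pb.order))
        return changes

    def candidates_for(n: int, current: dict[int, int]) -> list[int]:
        el = g1.atoms[n].element
        matched_nbrs = [w for w in g1.neighbors(n) if w in current]
        if matched_nbrs:
            pool = [
                c
                for c in g2.neighbors(current[matched_nbrs[0]])
                if c not in used and g2.atoms[c].element == el
            ]
        else:
            pool = [c for c in g2.atom_ids() if c not in used and g2.atoms[c].element == el]
        pool = [c for c in pool if g2.degree(c) >= g1.degree(n)]
        pool.sort()
        if collapse_equivalent_leaves and g1.degree(n) == 1 and matched_nbrs:
            seen_sig = set()
            kept = []
            for c in pool:
                if g2.degree(c) == 1:
                    bc = g2.neighbors(c)[current[matched_nbrs[0]]]
                    sig = (g2.atoms[c].formal_charge, g2.atoms[c].aromatic, bc.order)
                    if sig in seen_sig:
                        continue
                    seen_sig.add(sig)
                kept.append(c)
            pool = kept
        return pool

    def record_solution(cost: float, changes: list) -> None:
        if cost < best[0]:
            best[0] = cost
            sols.clear()
        if cost <= best[0]:
            m = AtomMapping(dict(mapping))
            if all(s[0].pairs != m.pairs for s in sols):
                sols.append((m, list(changes), cost))

    def next_block() -> Optional[list[int]]:
        # all unmatched immediate neighbours of the lowest matched atom that
        # has any; otherwise the most-constrained unmatched atom alone.
        for u in sorted(mapping):
            block = sorted(w for w in g1.neighbors(u) if w not in mapping)
            if block:
                return block
        rest = [v for v in order1 if v not in mapping]
        if not rest:
            return None
        rest.sort(key=lambda v: (len(candidates_for(v, mapping)), v))
        return [rest[0]]

    def place(block: list[int], bi: int, cost: float, changes: list) -> None:
        counter.tick()
        if cost > best[0]:
            return
        if bi == len(block):
            nb = next_block()
            if nb is None:
                record_solution(cost, changes)
                return
            place(nb, 0, cost, changes)
            return
        n = block[bi]
        for c in candidates_for(n, mapping):
            delta = pair_cost(n, c, mapping)
            if delta is None:
                continue
            dcost = sum(abs(new - old) for _, old, new in delta)
            if cost + dcost > best[0]:
                continue
            mapping[n] = c
            used.add(c)
            changes.extend(delta)
            place(block, bi + 1, cost + dcost, changes)
            del mapping[n]
            used.remove(c)
            del changes[len(changes) - len(delta):]

    try:
        nb = next_block()
        if nb is None:
            record_solution(0.0, [])
        else:
            place(nb, 0, 0.0, [])
    except BudgetExceeded:
        truncated[0] = True
    return sols, truncated[0]


# -- periphery-to-centre matching ------------------------------------------


def periphery_to_center_match(
    r: ReactionRecord | tuple[MolGraph, MolGraph],
    budget: Optional[SearchBudget] = None,
    orders: Sequence[int] = (4, 3, 2, 1),
) -> AtomMapping:
    """Fix atoms whose environments agree unambiguously, periphery first.

    Environments are compared at order 4 down to 1; a descriptor class left
    with exactly one free atom on each side fixes that pair.  Atoms near the
    reaction centre, where neighbourhoods differ, remain free.
    """
    if isinstance(r, ReactionRecord):
        rg, pg = r.reactant_graph(), r.product_graph()
    else:
        rg, pg = r
    fixed: dict[int, int] = {}
    used_p: set[int] = set()
    for k in orders:
        part = bucket_partition(rg, pg, k)
        for desc in sorted(part.classes):
            ra, pa = part.classes[desc]
            ra_free = [i for i in ra if i not in fixed]
            pa_free = [j for j in pa if j not in used_p]
            if len(ra_free) == 1 and len(pa_free) == 1:
                fixed[ra_free[0]] = pa_free[0]
                used_p.add(pa_free[0])
    return AtomMapping(fixed)


# -- bond-cut enumeration ---------------------------------------------------


def enumerate_bond_cut_sets(
    region: MolGraph | Iterable[Bond], max_size: int = 6
) -> Iterator[tuple[Bond, ...]]:
    """All subsets of eligible bonds, by increasing cardinality then lex order.

    Protected bonds never appear in any set.
    """
    if isinstance(region, MolGraph):
        bonds = [b for _, b in sorted(region.bonds.items())]
    else:
        bonds = sorted(region, key=lambda b: b.key)
    bonds = [b for b in bonds if not b.protected]
    for size in range(1, min(max_size, len(bonds)) + 1):
        yield from itertools.combinations(bonds, size)


# -- minimal-edit search ----------------------------------------------------


def _edge_pair_counter(g: MolGraph) -> Counter:
    return Counter(
        frozenset((g.atoms[i].element, g.atoms[j].element)) for (i, j) in g.bonds
    )


def edit_lower_bound(rg: MolGraph, pg: MolGraph) -> float:
    """Cheap lower bound on the edit cost between two graphs.

    Every reactant edge in surplus of its element-pair count on the product
    side must be cut, at >= 1 order unit apiece.
    """
    pc = _edge_pair_counter(pg)
    return float(
        sum(max(0, c - pc[k]) for k, c in _edge_pair_counter(rg).items())
    )


def minimum_edit_mappings(
    rg: MolGraph,
    pg: MolGraph,
    seed: Optional[AtomMapping] = None,
    budget: Optional[SearchBudget] = None,
    counter: Optional[BudgetCounter] = None,
    cost_bound: float = math.inf,
    seed_hint: Optional[AtomMapping] = None,
) -> tuple[list[MappingSolution], str]:
    """All minimal-edit complete mappings of one reactant graph onto one
    product graph, found by periphery matching plus bond-cut enumeration.

    Returns ``(solutions, status)`` with status in ``{"mapped", "truncated",
    "unmappable"}``.  Only solutions with score <= ``cost_bound`` are kept.
    ``seed`` replaces periphery matching entirely; ``seed_hint`` (e.g.
    template-core assignments from balancing) is merged over the periphery
    map, winning any conflicts.
    """
    budget = budget or SearchBudget()
    if counter is None:
        counter = budget.counter()
    if rg.element_counts() != pg.element_counts():
        return [], "unmappable"
    if edit_lower_bound(rg, pg) > cost_bound:
        return [], "unmappable"

    def run(
        seed_map: AtomMapping, cost_bound: float
    ) -> tuple[list[MappingSolution], bool]:
        # forced edits among edges internal to the seed
        seed_pairs = dict(seed_map.pairs)
        while True:
            conflict = None
            for (i, j), b in sorted(rg.bonds.items()):
                if b.protected and i in seed_pairs and j in seed_pairs:
                    if pg.get_bond(seed_pairs[i], seed_pairs[j]) is None:
                        conflict = max(i, j)
                        break
            if conflict is None:
                break
            del seed_pairs[conflict]
        forced_cuts: list[Bond] = []
        base = 0.0
        for (i, j), b in sorted(rg.bonds.items()):
            if i in seed_pairs and j in seed_pairs:
                pb = pg.get_bond(seed_pairs[i], seed_pairs[j])
                if pb is None:
                    forced_cuts.append(b)
                    base += b.order
                elif pb.order != b.order:
                    base += abs(pb.order - b.order)
        labelled = set(seed_pairs)
        eligible = [
            b
            for (i, j), b in sorted(rg.bonds.items())
            if not b.protected
            and b not in forced_cuts
            and (i not in labelled or j not in labelled)
        ]
        p_pairs = _edge_pair_counter(pg)
        state = {
            "best": cost_bound,
            "found": {},  # mapping key -> MappingSolution
            "truncated": False,
        }
        work = rg.copy()
        for b in forced_cuts:
            work.remove_bond(b.i, b.j)
        # incremental element-pair surplus: every surplus reactant edge must
        # be cut at >= 1 unit, and (cut units + surplus) never decreases along
        # a cut-set extension, so it is an admissible subtree bound.
        w_pairs = _edge_pair_counter(work)
        excess = sum(max(0, c - p_pairs[k]) for k, c in w_pairs.items())
        seed_for_match = AtomMapping(seed_pairs)

        def pair_key(b: Bond) -> frozenset:
            return frozenset((rg.atoms[b.i].element, rg.atoms[b.j].element))

        def attempt(cut_units: float) -> None:
            res, trunc = neighbor_extend_match(
                work,
                pg,
                seed_for_match,
                allow_order_changes=True,
                cost_bound=state["best"] - cut_units,
                collapse_equivalent_leaves=True,
                counter=counter,
            )
            state["truncated"] = state["truncated"] or trunc
            for m, _changes, _c in res:
                sol = solution_from_mapping(rg, pg, m)
                if sol.score > state["best"]:
                    continue
                if sol.score < state["best"]:
                    state["best"] = sol.score
                    state["found"] = {
                        k: v
                        for k, v in state["found"].items()
                        if v.score <= sol.score
                    }
                state["found"].setdefault(tuple(sorted(m.pairs.items())), sol)

        def dfs(start: int, cut_units: float, size: int) -> None:
            nonlocal excess
            counter.tick()
            if cut_units + excess > state["best"]:
                return
            if excess == 0:
                attempt(cut_units)
            if size == budget.max_cut_set_size:
                return
            for k in range(start, len(eligible)):
                b = eligible[k]
                pk = pair_key(b)
                was_surplus = w_pairs[pk] > p_pairs[pk]
                work.remove_bond(b.i, b.j)
                w_pairs[pk] -= 1
                if was_surplus:
                    excess -= 1
                dfs(k + 1, cut_units + b.order, size + 1)
                work.add_bond(b)
                w_pairs[pk] += 1
                if was_surplus:
                    excess += 1

        try:
            dfs(0, base, 0)
        except BudgetExceeded:
            state["truncated"] = True
        sols = sorted(
            (s for s in state["found"].values() if s.score <= state["best"]),
            key=lambda s: s.sort_key(),
        )
        return sols, state["truncated"]

    if seed is not None:
        seed_map = seed
    else:
        seed_map = periphery_to_center_match((rg, pg))
        if seed_hint is not None and len(seed_hint) > 0:
            merged = {
                i: j
                for i, j in seed_map.pairs.items()
                if i not in seed_hint.pairs
                and j not in set(seed_hint.pairs.values())
            }
            merged.update(seed_hint.pairs)
            seed_map = AtomMapping(merged)

    def search(seed_map: AtomMapping) -> tuple[list[MappingSolution], bool]:
        if math.isfinite(cost_bound):
            return run(seed_map, cost_bound)
        # Unbounded call: iterative deepening on the edit score.  Each level
        # explores only cut sets within the level's unit budget, so cheap
        # solutions are found without enumerating deep cut combinations.
        ceiling = sum(b.order for b in rg.bonds.values()) + sum(
            b.order for b in pg.bonds.values()
        )
        level = 0.0
        while level <= ceiling:
            sols, truncated = run(seed_map, level)
            if sols or truncated:
                return sols, truncated
            level += 1.0
        return [], False

    sols, truncated = search(seed_map)
    if not sols and not truncated and len(seed_map) > 0:
        # conservative fallback: a periphery fix may have been inconsistent
        sols, truncated = search(AtomMapping({}))
    if truncated:
        return sols, "truncated"
    return sols, ("mapped" if sols else "unmappable")


def find_best_isomorphism(
    r: ReactionRecord,
    budget: Optional[SearchBudget] = None,
    use_heuristic_candidates: bool = False,
    counter: Optional[BudgetCounter] = None,
    cost_bound: float = math.inf,
) -> tuple[list[MappingSolution], str]:
    """Minimal-score complete mappings of a reaction record.

    With ``use_heuristic_candidates`` the full dual-branch search of the
    orchestrator is used; otherwise only direct (no-heuristics) mapping.
    """
    if use_heuristic_candidates:
        from .search import MapperConfig, map_reaction

        cfg = MapperConfig(budget=budget or SearchBudget(), heuristics_on=True)
        result = map_reaction(r, cfg)
        sols = ([result.best] if result.best else []) + result.alternates
        return sols, result.status
    return minimum_edit_mappings(
        r.reactant_graph(),
        r.product_graph(),
        budget=budget,
        counter=counter,
        cost_bound=cost_bound,
    )
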