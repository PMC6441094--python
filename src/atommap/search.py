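"""Dual-branch mapping orchestration.

A reaction is balanced, then mapped along two branches: a plain
minimal-edit search (no heuristics) and a search over heuristically
rewritten intermediate candidates.  The best no-heuristics score S is used
to reject any with-heuristics candidate whose score exceeds S — the
heuristics branch can only improve on or tie the plain branch, never lose
to it.  The lower-scoring solution wins; on exact ties the no-heuristics
solution is preferred (fewer mechanistic assumptions; configurable).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Optional

from .chemgraph import ReactionRecord
from .errors import BudgetExceeded
from .heuristics import CandidateIntermediate, generate_candidates, registry
from .isomorphism import (
    BudgetCounter,
    MappingSolution,
    SearchBudget,
    edit_lower_bound,
    minimum_edit_mappings,
    score as score_of,
)
from .stoichiometry import DEFAULT_MISSING_ATOM_LIMIT, balance


@dataclass
class MapperConfig:
    """User-facing knobs; defaults mirror the algorithm's stated constants."""

    budget: SearchBudget = field(default_factory=SearchBudget)
    heuristics_on: bool = True
    max_heuristic_applications: int = 2
    balance_on: bool = True
    missing_atom_limit: int = DEFAULT_MISSING_ATOM_LIMIT
    emit_hydrogen_maps: bool = False
    report_ties: bool = True
    prefer_no_heuristics: bool = True
    pruning_on: bool = True
    max_candidates: int = 500


@dataclass
class SearchState:
    """Cross-branch bookkeeping during one reaction's search."""

    best_no_heuristics_score: float = math.inf
    best_solutions: list[MappingSolution] = field(default_factory=list)
    pruned_count: int = 0
    truncated: bool = False


def prune(state: SearchState, candidate_score: float) -> bool:
    """True iff a with-heuristics candidate should be rejected (score > S)."""
    return candidate_score > state.best_no_heuristics_score


@dataclass
class MappingResult:
    best: Optional[MappingSolution]
    alternates: list[MappingSolution]
    status: str  # mapped | truncated | unbalanceable | unmappable
    state: SearchState
    record: ReactionRecord
    elapsed_s: float = 0.0

    @property
    def score(self) -> Optional[float]:
        return self.best.score if self.best else None


def map_candidate(
    cand: CandidateIntermediate,
    record: ReactionRecord,
    budget: SearchBudget,
    counter: Optional[BudgetCounter] = None,
    cost_bound: float = math.inf,
) -> tuple[list[MappingSolution], str]:
    """Map one heuristic intermediate onto the products.

    Edit scores are computed against the *rewritten* reactant graph; the
    returned solutions carry the heuristic provenance and total score
    (accrued template scores plus edit cost).
    """
    sols, status = minimum_edit_mappings(
        cand.rewritten,
        record.product_graph(),
        budget=budget,
        counter=counter,
        cost_bound=cost_bound - cand.accrued_score
        if cost_bound is not math.inf
        else math.inf,
    )
    out = []
    for s in sols:
        s.heuristic_applications = list(cand.provenance)
        s.score = score_of(s)
        out.append(s)
    return out, status


def map_reaction(r: ReactionRecord, cfg: Optional[MapperConfig] = None) -> MappingResult:
    """Map a reaction: balance, run both branches, select the minimum."""
    cfg = cfg or MapperConfig()
    t0 = time.monotonic()
    record = r.copy()
    state = SearchState()
    template_seed = None
    if cfg.balance_on:
        record, bstatus, template_seed = balance(
            record, missing_atom_limit=cfg.missing_atom_limit
        )
        if bstatus == "unbalanceable":
            return MappingResult(None, [], "unbalanceable", state, record,
                                 time.monotonic() - t0)
    counter = cfg.budget.counter()
    pg = record.product_graph()

    # right branch: no heuristics
    plain, plain_status = minimum_edit_mappings(
        record.reactant_graph(), pg, budget=cfg.budget, counter=counter,
        seed_hint=template_seed,
    )
    if plain_status == "truncated":
        state.truncated = True
    if plain:
        state.best_no_heuristics_score = plain[0].score
    all_solutions: list[tuple[int, MappingSolution]] = [(0, s) for s in plain]

    # left branch: heuristic intermediates, pruned against S
    if cfg.heuristics_on:
        try:
            candidates = generate_candidates(
                record,
                max_applications=cfg.max_heuristic_applications,
                templates=registry(),
                max_candidates=cfg.max_candidates,
            )
        except BudgetExceeded:
            candidates = []
            state.truncated = True
        # Incumbent across both branches: S from the plain branch, improved
        # as cheaper heuristic solutions are found.  Any candidate whose
        # accrued template score alone exceeds the incumbent cannot win.
        #
        # Candidates are processed by iterative deepening: each round allows
        # every unresolved candidate a total-score bound of (its optimistic
        # score + round level), so promising intermediates resolve early and
        # the tightened incumbent prunes the rest cheaply.
        incumbent = state.best_no_heuristics_score
        ordered = sorted(
            (c for c in candidates[1:]),  # candidates[0] is unmodified
            key=lambda c: (
                c.accrued_score + edit_lower_bound(c.rewritten, pg),
                c.accrued_score,
            ),
        )
        optimistic = [
            c.accrued_score + edit_lower_bound(c.rewritten, pg) for c in ordered
        ]
        unresolved = set(range(len(ordered)))
        level = 0.0
        while unresolved:
            progressed = False
            for idx in sorted(unresolved):
                cand = ordered[idx]
                if cfg.pruning_on and (
                    prune(state, cand.accrued_score)
                    or cand.accrued_score > incumbent
                    or optimistic[idx] > incumbent
                ):
                    state.pruned_count += 1
                    unresolved.discard(idx)
                    continue
                ceiling = (
                    cand.accrued_score
                    + sum(b.order for b in cand.rewritten.bonds.values())
                    + sum(b.order for b in pg.bonds.values())
                )
                cap = min(incumbent, ceiling) if cfg.pruning_on else ceiling
                target = optimistic[idx] + level
                final_round = target >= cap
                target = min(target, cap)
                sols, status = map_candidate(
                    cand, record, cfg.budget, counter=counter, cost_bound=target
                )
                if status == "truncated":
                    state.truncated = True
                    unresolved.discard(idx)
                    continue
                if sols:
                    unresolved.discard(idx)
                    for s in sols:
                        if cfg.pruning_on and prune(state, s.score):
                            state.pruned_count += 1
                            continue
                        incumbent = min(incumbent, s.score)
                        all_solutions.append((1, s))
                elif final_round:
                    unresolved.discard(idx)  # proven not better than incumbent
                else:
                    progressed = True  # revisit with a looser bound
            if not progressed:
                break
            level += 1.0

    if not all_solutions:
        status = "truncated" if state.truncated else "unmappable"
        return MappingResult(None, [], status, state, record,
                             time.monotonic() - t0)

    best_score = min(s.score for _, s in all_solutions)
    tied = [(branch, s) for branch, s in all_solutions if s.score == best_score]
    tied.sort(key=lambda bs: (bs[0] if cfg.prefer_no_heuristics else -bs[0],)
              + bs[1].sort_key())
    # deduplicate identical mappings (a heuristic route can rediscover the
    # plain mapping with equal score)
    seen = set()
    uniq = []
    for branch, s in tied:
        key = tuple(sorted(s.mapping.pairs.items()))
        if key not in seen:
            seen.add(key)
            uniq.append(s)
    best, alternates = uniq[0], (uniq[1:] if cfg.report_ties else [])
    state.best_solutions = uniq
    status = "truncated" if state.truncated else "mapped"
    return MappingResult(best, alternates, status, state, record,
                         time.monotonic() - t0)


def rewritten_reactant_graph(record: ReactionRecord, sol: MappingSolution):
    """Replay a solution's heuristic provenance on the reactant graph.

    Returns the intermediate graph that the solution's edit script (cuts,
    order changes, formed bonds) applies to — the reactant graph itself when
    no heuristics were used.
    """
    from .heuristics import apply as apply_template, registry

    by_id = {t.id: t for t in registry()}
    g = record.reactant_graph()
    cand = None
    for app in sol.heuristic_applications:
        t = by_id[app.template_id]
        cand = apply_template(t, dict(app.site), cand if cand is not None else [g])
        if cand is None:
            raise ValueError("stored heuristic provenance does not replay")
    return cand.rewritten if cand is not None else g


def map_reaction_smiles(text: str, cfg: Optional[MapperConfig] = None) -> MappingResult:
    """Convenience wrapper: parse a reaction SMILES and map it."""
    from .chemgraph import parse_reaction

    return map_reaction(parse_reaction(text), cfg)
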