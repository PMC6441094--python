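"""Pre-mapping stoichiometry correction.

Chemists rarely write reactions with full stoichiometry: duplicate
substrates, condensation water, and counterion/byproduct atoms are omitted.
Before mapping, the reaction is balanced in a fixed stage order —
substrate copies, then hard-coded balancing templates, then water, then
single missing atoms — stopping at the first stage that zeroes the
per-element deficit.  Single-atom addition is refused above a configurable
limit (default 7) beyond which the mapping combinatorics become intractable.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from rdkit import Chem

from .chemgraph import (
    Addition,
    AtomMapping,
    MolGraph,
    ReactionRecord,
    combine,
    mol_from_rdkit,
    mol_to_rdkit,
)

DEFAULT_MISSING_ATOM_LIMIT = 7
MAX_EXTRA_COPIES = 3

WATER = Counter({"O": 1, "H": 2})


def check_balance(r: ReactionRecord) -> dict[str, int]:
    """Per-element deficit: positive means excess on the reactant side."""
    return r.balance_deficit


def _add_species(r: ReactionRecord, smiles: str, side: str, reason: str) -> None:
    rd = Chem.MolFromSmiles(smiles)
    rd = Chem.AddHs(rd)
    mols = r.reactants if side == "reactants" else r.products
    offset = max((max(m.atoms) for m in (r.reactants + r.products + r.agents) if m.atoms), default=-1) + 1
    mols.append(mol_from_rdkit(rd, index_offset=offset))
    r.additions.append(Addition(species_smiles=smiles, side=side, reason=reason))


def _species_formula(m: MolGraph) -> Counter:
    return m.element_counts()


def balance_by_copies(r: ReactionRecord) -> ReactionRecord:
    """Add copies of existing substrates (and, symmetrically, products).

    The smallest multiset of copies (at most three in total) is chosen that
    either zeroes the deficit or reduces it to a pure water imbalance that
    the water stage can finish.  Returns the (possibly modified) record.
    """
    deficit = Counter(r.balance_deficit)
    if not deficit:
        return r
    from .chemgraph import species_smiles

    # candidate species: copies of reactants offset the product side's excess
    # and vice versa; search all small multisets over both sides.
    options: list[tuple[str, str, Counter]] = []
    for m in r.reactants:
        options.append((species_smiles(m), "reactants", _species_formula(m)))
    for m in r.products:
        options.append((species_smiles(m), "products", _species_formula(m)))

    def residual(combo) -> Counter:
        d = Counter(deficit)
        for smiles, side, formula in combo:
            sign = 1 if side == "reactants" else -1
            for e, c in formula.items():
                d[e] += sign * c
        return Counter({e: c for e, c in d.items() if c})

    def water_only(d: Counter) -> bool:
        if not d:
            return True
        elems = set(d)
        if elems - {"H", "O"}:
            return False
        sgn = 1 if d.get("O", 0) > 0 else -1
        return d.get("H", 0) == 2 * d.get("O", 0) and sgn * d.get("O", 0) > 0

    # A water-only residual is accepted only for a single copy: wider
    # copy-plus-water searches admit spurious no-op combinations (one copy of
    # everything on both sides leaves any condensation deficit "water-only").
    best: Optional[tuple] = None
    for n in range(1, MAX_EXTRA_COPIES + 1):
        for combo in itertools.combinations_with_replacement(options, n):
            res = residual(combo)
            exact = not res
            if exact or (n == 1 and water_only(res)):
                rank = (0 if exact else 1, n)
                if best is None or rank < best[0]:
                    best = (rank, combo)
        if best is not None and best[0][0] == 0:
            break  # smallest exact solution found
    if best is None:
        return r
    for smiles, side, _formula in best[1]:
        _add_species(r, smiles, side, "copy")
    return r


def balance_by_water(r: ReactionRecord) -> ReactionRecord:
    """Add the minimal number of water molecules to one side, when the whole
    remaining deficit is n * H2O."""
    deficit = Counter(r.balance_deficit)
    if not deficit or set(deficit) - {"H", "O"}:
        return r
    n_o, n_h = deficit.get("O", 0), deficit.get("H", 0)
    if n_o == 0 or n_h != 2 * n_o:
        return r
    side = "products" if n_o > 0 else "reactants"
    for _ in range(abs(n_o)):
        _add_species(r, "O", side, "water")
    return r


def add_missing_atoms(
    r: ReactionRecord, limit: int = DEFAULT_MISSING_ATOM_LIMIT
) -> tuple[ReactionRecord, str]:
    """Add each missing atom as a one-atom molecule on the deficient side.

    Returns ``(record, status)`` with status ``"balanced"`` or
    ``"unbalanceable"`` (deficit above the limit; record left unchanged).
    """
    deficit = Counter(r.balance_deficit)
    if not deficit:
        return r, "balanced"
    total = sum(abs(c) for c in deficit.values())
    if total > limit:
        return r, "unbalanceable"
    for e, c in sorted(deficit.items()):
        side = "products" if c > 0 else "reactants"
        token = f"[{e}H0]" if e != "H" else "[H]"
        for _ in range(abs(c)):
            _add_species(r, token, side, "single_atom")
    return r, "balanced"


# -- balancing templates ----------------------------------------------------


@dataclass
class BalancingTemplate:
    """A hard-coded completion for one popular reaction family.

    ``reactant_smarts`` / ``product_smarts`` are lists of queries that must
    all embed (injectively) into the respective side.  Pattern labels shared
    between the two sides seed the atom mapping.  ``completion`` names the
    species to add and the side to add them to; the completion must zero the
    deficit or the template is rejected for that reaction.
    """

    name: str
    reactant_smarts: list[str]
    product_smarts: list[str]
    completion_side: str
    completion_smiles: list[str] = field(default_factory=list)

    def _match_side(self, mols: list[MolGraph]) -> Optional[dict[int, int]]:
        g = combine(mols)
        rd, id_to_idx = mol_to_rdkit(g, sanitize=True)
        idx_to_id = {v: k for k, v in id_to_idx.items()}
        assignment: dict[int, int] = {}
        used: set[int] = set()

        def backtrack(qi: int) -> bool:
            if qi == len(self.reactant_smarts if mols is None else queries):
                return True
            q = Chem.MolFromSmarts(queries[qi])
            label_of = {
                a.GetIdx(): a.GetAtomMapNum()
                for a in q.GetAtoms()
                if a.GetAtomMapNum()
            }
            for match in rd.GetSubstructMatches(q, uniquify=False, maxMatches=2000):
                atoms = {idx_to_id[i] for i in match}
                if atoms & used:
                    continue
                for qidx, label in label_of.items():
                    assignment[label] = idx_to_id[match[qidx]]
                used.update(atoms)
                if backtrack(qi + 1):
                    return True
                used.difference_update(atoms)
                for label in label_of.values():
                    assignment.pop(label, None)
            return False

        queries = self._current_queries
        return assignment if backtrack(0) else None

    def try_apply(
        self, r: ReactionRecord
    ) -> Optional[tuple[ReactionRecord, AtomMapping]]:
        self._current_queries = self.reactant_smarts
        r_assign = self._match_side(r.reactants)
        if r_assign is None:
            return None
        self._current_queries = self.product_smarts
        p_assign = self._match_side(r.products)
        if p_assign is None:
            return None
        trial = r.copy()
        for smiles in self.completion_smiles:
            _add_species(trial, smiles, self.completion_side, "template")
        if not trial.is_balanced:
            return None
        shared = sorted(set(r_assign) & set(p_assign))
        seed = AtomMapping({r_assign[k]: p_assign[k] for k in shared})
        return trial, seed


def _parse_balancing(data: dict) -> BalancingTemplate:
    return BalancingTemplate(
        name=str(data["name"]),
        reactant_smarts=[str(s) for s in data["reactant_smarts"]],
        product_smarts=[str(s) for s in data["product_smarts"]],
        completion_side=str(data["completion"]["side"]),
        completion_smiles=[str(s) for s in data["completion"]["species"]],
    )


@lru_cache(maxsize=1)
def balancing_templates() -> tuple[BalancingTemplate, ...]:
    """The shipped, representative balancing-template library."""
    root = resources.files("atommap").joinpath("data", "balancing")
    out = []
    for f in sorted(root.iterdir(), key=lambda p: p.name):
        if f.name.endswith(".yaml"):
            out.append(_parse_balancing(yaml.safe_load(f.read_text())))
    return tuple(out)


def load_balancing_templates(directory: Path) -> list[BalancingTemplate]:
    out = []
    for f in sorted(Path(directory).glob("*.yaml")):
        with open(f) as fh:
            out.append(_parse_balancing(yaml.safe_load(fh)))
    return out


def apply_balancing_templates(
    r: ReactionRecord, templates: Optional[list[BalancingTemplate]] = None
) -> tuple[ReactionRecord, AtomMapping]:
    """First matching template completes the reaction and seeds core atoms."""
    templates = list(templates) if templates is not None else list(balancing_templates())
    for t in templates:
        res = t.try_apply(r)
        if res is not None:
            return res
    return r, AtomMapping({})


def balance(
    r: ReactionRecord,
    missing_atom_limit: int = DEFAULT_MISSING_ATOM_LIMIT,
    templates: Optional[list[BalancingTemplate]] = None,
) -> tuple[ReactionRecord, str, AtomMapping]:
    """Run the balancing cascade: copies, templates, water, single atoms.

    Returns ``(record, status, seed)`` with status in ``{"balanced",
    "unbalanceable"}``.  The record is modified in place.
    """
    seed = AtomMapping({})
    if r.is_balanced:
        return r, "balanced", seed
    balance_by_copies(r)
    if r.is_balanced:
        return r, "balanced", seed
    r2, seed2 = apply_balancing_templates(r, templates)
    if r2.is_balanced:
        return r2, "balanced", seed2
    balance_by_water(r)
    if r.is_balanced:
        return r, "balanced", seed
    r, status = add_missing_atoms(r, limit=missing_atom_limit)
    return r, ("balanced" if status == "balanced" else "unbalanceable"), seed
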