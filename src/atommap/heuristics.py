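"""Registry and application engine for the 20 reaction heuristics.

Each heuristic is a mechanistic motif — a substructure pattern plus a bond
rewrite — that transforms substrates into a plausible intermediate at a
discounted score (+0.5 by default; exceptions: [i] +1, [j] -1.5, [r] 0).
Applying a heuristic where it mechanistically belongs yields an intermediate
close to the product (few further cuts); applying it at a wrong site yields
a decoy whose completion is expensive, so minimal-score selection discards
it.

Templates are data, not code: one YAML file per heuristic under
``data/heuristics``, with a SMARTS pattern (atom-map labels name the pattern
atoms) and an explicit bond-edit list (SMARTS alone cannot express the
protected-bond flag).  Bonds a template marks ``protect`` may never be
broken by any subsequent operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml
from rdkit import Chem

from .chemgraph import Bond, MolGraph, ReactionRecord, combine, mol_to_rdkit
from .errors import ChemistryError
from .isomorphism import HeuristicApplication

log = logging.getLogger(__name__)

GROUPS = {
    "pericyclic",
    "symmetry-disambiguation",
    "carbonyl",
    "missing-information",
    "rearrangement",
}
ALLOWED_SCORES = {-1.5, 0.0, 0.5, 1.0}


@dataclass(frozen=True)
class BondEdit:
    kind: str  # "break" | "form" | "order"
    a: int  # pattern labels
    b: int
    order: Optional[float] = None


@dataclass
class HeuristicTemplate:
    """One reaction heuristic: pattern, rewrite, score, protected bonds."""

    id: str
    name: str
    group: str
    score: float
    pattern: str
    edits: list[BondEdit]
    protect: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"template {self.id}: unknown group {self.group!r}")
        if self.score not in ALLOWED_SCORES:
            raise ValueError(f"template {self.id}: score {self.score} not allowed")
        self._query = Chem.MolFromSmarts(self.pattern)
        if self._query is None:
            raise ValueError(f"template {self.id}: bad SMARTS {self.pattern!r}")
        labels = {
            a.GetAtomMapNum() for a in self._query.GetAtoms() if a.GetAtomMapNum()
        }
        for e in self.edits:
            if e.a not in labels or e.b not in labels:
                raise ValueError(f"template {self.id}: edit references unknown label")

    def inverse_edits(self) -> list[BondEdit]:
        """Edit list that undoes this template's rewrite.

        For order edits the original order is resolved at application time;
        here breaks and forms swap and order edits are returned as-is for the
        caller to re-target (used by the registry round-trip self-test).
        """
        inv = []
        for e in reversed(self.edits):
            if e.kind == "break":
                inv.append(BondEdit("form", e.a, e.b, e.order))
            elif e.kind == "form":
                inv.append(BondEdit("break", e.a, e.b, None))
            else:
                inv.append(e)
        return inv


@dataclass
class CandidateIntermediate:
    """A heuristically rewritten reactant set awaiting isomorphic mapping."""

    rewritten: MolGraph
    provenance: list[HeuristicApplication] = field(default_factory=list)
    accrued_score: float = 0.0

    @property
    def partial_map(self) -> dict[int, int]:
        """Original-reactant-atom -> intermediate-atom correspondence.

        Rewriting edits bonds only, so the correspondence is the identity on
        atom ids.
        """
        return {i: i for i in self.rewritten.atom_ids()}


def _parse_template(data: dict) -> HeuristicTemplate:
    edits = []
    for row in data.get("edits", []):
        kind, a, b = row[0], int(row[1]), int(row[2])
        order = float(row[3]) if len(row) > 3 else None
        if kind not in ("break", "form", "order"):
            raise ValueError(f"unknown edit kind {kind!r}")
        if kind in ("form", "order") and order is None:
            raise ValueError(f"{kind} edit requires an order")
        edits.append(BondEdit(kind, a, b, order))
    protect = [tuple(int(x) for x in pair) for pair in data.get("protect", [])]
    return HeuristicTemplate(
        id=str(data["id"]),
        name=str(data["name"]),
        group=str(data["group"]),
        score=float(data["score"]),
        pattern=str(data["pattern"]),
        edits=edits,
        protect=protect,  # type: ignore[arg-type]
    )


def load_templates(directory: Path) -> list[HeuristicTemplate]:
    """Load templates from a directory of YAML files (sorted by id)."""
    out = []
    for f in sorted(Path(directory).glob("*.yaml")):
        with open(f) as fh:
            out.append(_parse_template(yaml.safe_load(fh)))
    return sorted(out, key=lambda t: t.id)


@lru_cache(maxsize=1)
def registry() -> tuple[HeuristicTemplate, ...]:
    """The 20 built-in reaction heuristics."""
    root = resources.files("atommap").joinpath("data", "heuristics")
    out = []
    for f in sorted(root.iterdir(), key=lambda p: p.name):
        if f.name.endswith(".yaml"):
            out.append(_parse_template(yaml.safe_load(f.read_text())))
    return tuple(sorted(out, key=lambda t: t.id))


def extended_registry(extra_dirs: Iterable[Path] = ()) -> list[HeuristicTemplate]:
    """Built-in templates plus user-supplied ones.

    Extra heuristics widen coverage but create more decoy solutions, so their
    use is logged as a warning.
    """
    out = list(registry())
    for d in extra_dirs:
        extra = load_templates(d)
        if extra:
            log.warning(
                "loaded %d user heuristic templates from %s; extra heuristics "
                "can create additional decoy solutions",
                len(extra),
                d,
            )
        out.extend(extra)
    return out


# -- matching and application ----------------------------------------------


def graph_key(g: MolGraph) -> str:
    """Canonical structural key of a graph (RDKit canonical SMILES)."""
    rd, _ = mol_to_rdkit(g, sanitize=True)
    return Chem.MolToSmiles(rd, allHsExplicit=True)


def intermediate_key(g: MolGraph) -> str:
    """Canonical dedup key for a rewritten intermediate.

    The structural key plus the protected-bond set (not expressible in
    SMILES), so that equal graphs with different protection are kept apart.
    """
    prot = sorted(k for k, b in g.bonds.items() if b.protected)
    return graph_key(g) + "|" + ",".join(f"{i}-{j}" for i, j in prot)


def match_sites(
    t: HeuristicTemplate, reactants: list[MolGraph] | MolGraph
) -> list[dict[int, int]]:
    """All embeddings of a template pattern into the reactant graph.

    Each embedding maps pattern label -> atom id.  Matching is exhaustive
    (all symmetry-equivalent placements included); downstream deduplication
    collapses embeddings that lead to identical intermediates.
    """
    g = reactants if isinstance(reactants, MolGraph) else combine(reactants)
    rd, id_to_idx = mol_to_rdkit(g, sanitize=True)
    idx_to_id = {v: k for k, v in id_to_idx.items()}
    label_of = {
        a.GetIdx(): a.GetAtomMapNum()
        for a in t._query.GetAtoms()
        if a.GetAtomMapNum()
    }
    out = []
    for match in rd.GetSubstructMatches(t._query, uniquify=False, maxMatches=20000):
        emb = {
            label: idx_to_id[match[qidx]] for qidx, label in label_of.items()
        }
        out.append(emb)
    return out


def apply(
    t: HeuristicTemplate,
    embedding: dict[int, int],
    reactants: list[MolGraph] | MolGraph | CandidateIntermediate,
) -> Optional[CandidateIntermediate]:
    """Execute a template rewrite at one site.

    Returns ``None`` when the application is rejected: the rewrite touches a
    protected bond, is structurally inconsistent with the site, leaves the
    graph unchanged (degenerate embedding), or produces an invalid valence
    picture.
    """
    if isinstance(reactants, CandidateIntermediate):
        base, provenance, accrued = (
            reactants.rewritten,
            reactants.provenance,
            reactants.accrued_score,
        )
    else:
        base = reactants if isinstance(reactants, MolGraph) else combine(reactants)
        provenance, accrued = [], 0.0
    g = base.copy()
    for e in t.edits:
        i, j = embedding[e.a], embedding[e.b]
        bond = g.get_bond(i, j)
        if e.kind == "break":
            if bond is None or bond.protected:
                return None
            g.remove_bond(i, j)
        elif e.kind == "form":
            if bond is not None:
                return None
            g.add_bond(Bond(i, j, order=e.order))
        else:  # order
            if bond is None or bond.protected or bond.order == e.order:
                return None
            bond.order = e.order
    for a, b in t.protect:
        bond = g.get_bond(embedding[a], embedding[b])
        if bond is None:
            raise ChemistryError(
                f"template {t.id}: protected bond {a}-{b} absent after rewrite"
            )
        bond.protected = True
    from .chemgraph import check_valences

    if not check_valences(g):
        return None
    if graph_key(g) == graph_key(base):
        return None  # degenerate: structurally unchanged
    site = tuple(sorted(embedding.items()))
    app = HeuristicApplication(
        template_id=t.id, site=site, score=t.score, bonds_edited=len(t.edits)
    )
    return CandidateIntermediate(
        rewritten=g,
        provenance=provenance + [app],
        accrued_score=accrued + t.score,
    )


def generate_candidates(
    r: ReactionRecord | list[MolGraph],
    max_applications: int = 2,
    templates: Optional[Iterable[HeuristicTemplate]] = None,
    max_candidates: int = 500,
) -> list[CandidateIntermediate]:
    """All heuristic rewrites of the reactants, up to ``max_applications``
    stacked applications, deduplicated by intermediate canonical form.

    The unmodified reactant graph is always the first candidate.
    """
    if max_applications < 1:
        raise ValueError("max_applications must be >= 1")
    mols = r.reactants if isinstance(r, ReactionRecord) else r
    base = combine(mols)
    templates = list(templates) if templates is not None else list(registry())
    start = CandidateIntermediate(rewritten=base)
    out = [start]
    seen = {intermediate_key(base)}
    frontier = [start]
    for _depth in range(max_applications):
        nxt = []
        for cand in frontier:
            for t in templates:
                for emb in match_sites(t, cand.rewritten):
                    new = apply(t, emb, cand)
                    if new is None:
                        continue
                    key = intermediate_key(new.rewritten)
                    if key in seen:
                        continue
                    seen.add(key)
                    nxt.append(new)
                    out.append(new)
                    if len(out) >= max_candidates:
                        log.warning(
                            "candidate generation capped at %d intermediates",
                            max_candidates,
                        )
                        return out
        frontier = nxt
    return out
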