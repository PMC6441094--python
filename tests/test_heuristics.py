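"""The heuristic template registry and application engine."""

import itertools

import pytest

from atommap.chemgraph import combine, parse_reaction
from atommap.heuristics import (
    BondEdit,
    HeuristicTemplate,
    apply,
    generate_candidates,
    intermediate_key,
    match_sites,
    registry,
)


EXPECTED_IDS = list("abcdefghijklmn") + list("pqrstu")  # no 'o'
SCORE_EXCEPTIONS = {"i": 1.0, "j": -1.5, "r": 0.0}


class TestRegistry:
    def test_twenty_templates(self):
        assert len(registry()) == 20

    def test_ids(self):
        assert [t.id for t in registry()] == EXPECTED_IDS

    def test_scores(self):
        for t in registry():
            assert t.score == SCORE_EXCEPTIONS.get(t.id, 0.5)

    def test_groups_cover_all_five(self):
        groups = {t.group for t in registry()}
        assert groups == {
            "pericyclic",
            "symmetry-disambiguation",
            "carbonyl",
            "missing-information",
            "rearrangement",
        }

    @pytest.mark.parametrize(
        "tid,example",
        [
            ("a", "C=CC=C.C=C"),
            ("b", "C=CCOC=C"),
            ("c", "C=CC=CC=C"),
            ("d", "C=C=O.C=C"),
            ("e", "CC(=O)OC(C)=O.CCC(=O)O"),
            ("f", "CC(=O)O.CCO"),
            ("g", "CC=O.CO"),
            ("h", "CC(C)=O.C=O"),
            ("i", "C=CC(C)=O.CC(C)=O"),
            ("j", "CC(C)=O"),
            ("k", "CC=C.CC=C"),
            ("l", "CC(C)(O)C(C)(C)O"),
            ("m", "CC(O)C(C)(C)O"),
            ("n", "CC=CCCl"),
            ("p", "CC1CO1"),
            ("q", "CC(C)=NO"),
            ("r", "C=CCC"),
            ("s", "O=CCCCC(C)(O)C=C"),
            ("t", "O=CCCCC(O)C=C"),
            ("u", "C1=CCCCC1"),
        ],
    )
    def test_rewrite_then_revert_restores_substrate(self, tid, example):
        """Applying a template and undoing its edits restores the graph."""
        t = next(x for x in registry() if x.id == tid)
        reactants = parse_reaction(f"{example}>>C").reactants
        base = combine(reactants)
        sites = match_sites(t, reactants)
        assert sites, f"template {tid} finds no site on its own example"
        cand = None
        emb = None
        for e in sites:
            cand = apply(t, e, reactants)
            if cand is not None:
                emb = e
                break
        assert cand is not None
        # build the inverse edit list with original orders
        inverse = []
        for e in reversed(t.edits):
            i, j = emb[e.a], emb[e.b]
            if e.kind == "break":
                inverse.append(("form", i, j, base.get_bond(i, j).order))
            elif e.kind == "form":
                inverse.append(("break", i, j, None))
            else:
                inverse.append(("order", i, j, base.get_bond(i, j).order))
        g = cand.rewritten.copy()
        from atommap.chemgraph import Bond

        for kind, i, j, order in inverse:
            if kind == "break":
                g.remove_bond(i, j)
            elif kind == "form":
                g.add_bond(Bond(i, j, order=order))
            else:
                g.get_bond(i, j).order = order
        for b in g.bonds.values():
            b.protected = False
        assert intermediate_key(g) == intermediate_key(base)


class TestMatchSites:
    def test_no_alkene_no_metathesis(self):
        k = next(t for t in registry() if t.id == "k")
        assert match_sites(k, parse_reaction("CCO.CCC>>C").reactants) == []

    def test_prins_pinacol_has_correct_and_decoy_site(self):
        s = next(t for t in registry() if t.id == "s")
        sites = match_sites(s, parse_reaction("O=CCCCC(C)(O)C=C>>C").reactants)
        migrating = {emb[1] for emb in sites}
        assert len(migrating) == 2  # ring-chain carbon vs methyl carbon

    def test_embedding_count_matches_brute_force(self):
        """Metathesis pattern embeddings = ordered pairs of distinct C=C
        times the 2x2 orientation choices."""
        k = next(t for t in registry() if t.id == "k")
        reactants = parse_reaction("CC=C.CC=C.C=C>>C").reactants
        g = combine(reactants)
        doubles = [kk for kk, b in g.bonds.items() if b.order == 2.0]
        expected = 0
        for b1, b2 in itertools.permutations(doubles, 2):
            expected += 4  # two orientations per bond
        assert len(match_sites(k, reactants)) == expected


class TestApply:
    def test_metathesis_costs_half(self):
        k = next(t for t in registry() if t.id == "k")
        reactants = parse_reaction("CC=C.CC=C>>C").reactants
        for emb in match_sites(k, reactants):
            cand = apply(k, emb, reactants)
            if cand is not None:
                assert cand.accrued_score == 0.5
                break
        else:
            pytest.fail("no valid metathesis application")

    def test_protected_bonds_marked(self):
        k = next(t for t in registry() if t.id == "k")
        reactants = parse_reaction("CC=C.CC=C>>C").reactants
        cand = next(
            c
            for emb in match_sites(k, reactants)
            if (c := apply(k, emb, reactants)) is not None
        )
        assert sum(b.protected for b in cand.rewritten.bonds.values()) == 2

    def test_degenerate_application_discarded(self):
        # metathesis pairing that reconstructs the same two propenes
        k = next(t for t in registry() if t.id == "k")
        reactants = parse_reaction("CC=C.CC=C>>C").reactants
        results = [apply(k, emb, reactants) for emb in match_sites(k, reactants)]
        assert any(c is None for c in results)  # degenerate orientations

    def test_valence_violation_rejected(self):
        bad = HeuristicTemplate(
            id="z",
            name="bad",
            group="rearrangement",
            score=0.5,
            pattern="[C:1][C:2]",
            edits=[BondEdit("form", 1, 2, 2.0)],  # would need a parallel bond
        )
        reactants = parse_reaction("CC>>C").reactants
        for emb in match_sites(bad, reactants):
            assert apply(bad, emb, reactants) is None

    def test_composition_conserved(self):
        h = next(t for t in registry() if t.id == "h")
        reactants = parse_reaction("CC(C)=O.C=O>>C").reactants
        base = combine(reactants)
        for emb in match_sites(h, reactants):
            cand = apply(h, emb, reactants)
            if cand is not None:
                assert cand.rewritten.element_counts() == base.element_counts()


class TestGenerateCandidates:
    def test_inert_reaction_only_unmodified(self):
        cands = generate_candidates(parse_reaction("CC.C>>CC.C"))
        assert len(cands) == 1
        assert cands[0].accrued_score == 0.0

    def test_candidate_count_bounded_by_embeddings(self):
        r = parse_reaction("CC=C.CC=C>>CC=CC.C=C")
        total_embeddings = sum(
            len(match_sites(t, r.reactants)) for t in registry()
        )
        cands = generate_candidates(r, max_applications=1)
        assert len(cands) - 1 <= total_embeddings

    def test_all_candidates_conserve_composition(self):
        r = parse_reaction("CC(C)=O.C=O>>CC(=O)C=C.O")
        base = combine(r.reactants)
        for cand in generate_candidates(r, max_applications=2):
            assert cand.rewritten.element_counts() == base.element_counts()

    def test_provenance_depth_bounded(self):
        r = parse_reaction("C=CC=C.C=C>>C1=CCCCC1")
        for cand in generate_candidates(r, max_applications=2):
            assert len(cand.provenance) <= 2
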