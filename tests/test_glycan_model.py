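"""Grammar, canonicalization and motif-matching behaviour."""

import numpy as np
import pytest

from glycotraits.glycan_model import (
    GlycanStructure,
    GlycanSyntaxError,
    GlycanVocabularyError,
    Residue,
    count_motif,
    isomorphic,
    iter_residues,
    parse_glycan,
    parse_motif,
    serialize_glycan,
)

from conftest import random_tree

SLEX = "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc"


# ---------------------------------------------------------------------------
# independent oracle: exhaustive anchored subtree matching
# ---------------------------------------------------------------------------


def oracle_count(g, m):
    """Brute-force anchored-subtree matcher, independent of the library path."""

    def residue_ok(t, node):
        r = node.residue
        checks = [
            (t.monosaccharide, None if t.monosaccharide is None else r.monosaccharide),
            (t.anomericity, r.anomericity),
            (t.anomeric_carbon, r.anomeric_carbon),
            (t.linkage_position, r.linkage_position),
        ]
        if t.monosaccharide is not None and r.monosaccharide not in t.monosaccharide:
            return False
        for tv, gv in checks[1:]:
            if tv is not None and gv != tv:
                return False
        return t.substituents <= r.substituents

    def embeds(t, node):
        if not residue_ok(t, node):
            return False
        for forb in t.forbidden_children:
            if any(residue_ok(forb, c) for c in node.children):
                return False
        kids = node.children
        from itertools import permutations

        if len(t.children) > len(kids):
            return False
        if not t.children:
            return True
        return any(
            all(embeds(tc, gc) for tc, gc in zip(t.children, perm))
            for perm in permutations(kids, len(t.children))
        )

    return sum(1 for node in iter_residues(g) if embeds(m.root, node))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_two_residue_chain():
    g = parse_glycan("Gal(b1-4)GlcNAc", "N")
    assert g.residue.monosaccharide == "GlcNAc"
    assert g.residue.linkage_position == "?"  # root has no parent linkage
    (child,) = g.children
    assert child.residue.monosaccharide == "Gal"
    assert child.residue.anomericity == "b"
    assert child.residue.linkage_position == "4"


def test_parse_branched_slex():
    g = parse_glycan(SLEX)
    assert g.residue.monosaccharide == "GlcNAc"
    assert len(g.children) == 2
    monos = sorted(c.residue.monosaccharide for c in g.children)
    assert monos == ["Fuc", "Gal"]
    gal = next(c for c in g.children if c.residue.monosaccharide == "Gal")
    assert gal.children[0].residue.monosaccharide == "Neu5Ac"
    assert gal.children[0].residue.anomeric_carbon == "2"


def test_unknown_monosaccharide_rejected():
    with pytest.raises(GlycanVocabularyError, match="Xyz"):
        parse_glycan("Xyz(b1-4)GlcNAc")


@pytest.mark.parametrize(
    "text",
    ["Gal(b1-4)[Fuc(a1-3GlcNAc", "Gal(b1-4)]GlcNAc", "[Fuc(a1-3)]", ""],
)
def test_malformed_text_raises_syntax_error_with_offset(text):
    with pytest.raises((GlycanSyntaxError, GlycanVocabularyError)):
        parse_glycan(text)


def test_substituent_parsing():
    g = parse_glycan("GlcNAc6S")
    assert ("6", "sulfate") in g.residue.substituents


# ---------------------------------------------------------------------------
# serialization / canonicalization
# ---------------------------------------------------------------------------


def test_serialize_round_trip_simple():
    assert serialize_glycan(parse_glycan("Gal(b1-4)GlcNAc")) == "Gal(b1-4)GlcNAc"


def test_branch_order_insensitive_canonical_form():
    a = parse_glycan("Gal(b1-4)[Fuc(a1-3)]GlcNAc")
    b = parse_glycan("Fuc(a1-3)[Gal(b1-4)]GlcNAc")
    assert serialize_glycan(a) == serialize_glycan(b)
    assert isomorphic(a, b)


def test_round_trip_random_trees():
    rng = np.random.default_rng(42)
    for _ in range(50):
        tree = random_tree(rng)
        text = serialize_glycan(tree)
        again = parse_glycan(text)
        assert isomorphic(tree, again), text
        assert serialize_glycan(again) == text


# ---------------------------------------------------------------------------
# motif counting
# ---------------------------------------------------------------------------


def test_slex_single_match():
    m = parse_motif(SLEX, "sLex")
    assert count_motif(parse_glycan(SLEX), m) == 1
    assert count_motif(parse_glycan("Gal(b1-4)GlcNAc"), m) == 0


def test_biantennary_counts_two_anchors():
    m = parse_motif(SLEX, "sLex")
    bi = parse_glycan(
        "Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-3)"
        "[Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc(b1-2)Man(a1-6)]"
        "Man(b1-4)GlcNAc(b1-4)GlcNAc",
        "N",
    )
    expected = oracle_count(bi, m)
    assert expected == 2
    assert count_motif(bi, m) == expected


def test_ambiguous_linkage_matches_only_wildcards():
    amb = parse_glycan("Neu5Ac(a2-?)Gal(b1-4)GlcNAc")
    concrete = parse_motif("Neu5Ac(a2-3)", "a2,3")
    wild = parse_motif("Neu5Ac(a2-?)", "any-sialyl")
    assert count_motif(amb, concrete) == 0
    assert count_motif(amb, wild) == 1


def test_forbidden_children_exclude_matches():
    lex = parse_motif(
        "Gal(b1-4)[Fuc(a1-3)]GlcNAc",
        "Lex",
        forbidden=[{"at": "Gal", "child": "Neu5Ac|Neu5Gc"}],
    )
    assert count_motif(parse_glycan("Gal(b1-4)[Fuc(a1-3)]GlcNAc"), lex) == 1
    assert count_motif(parse_glycan(SLEX), lex) == 0


def test_all_wildcard_pattern_matches_every_residue():
    m = parse_motif("*(??-?)", "any")
    g = parse_glycan(SLEX)
    assert count_motif(g, m) == len(g) == 4


def test_count_monotone_under_grafting():
    """Adding a disjoint subtree never decreases an existing motif count."""
    m = parse_motif(SLEX, "sLex")
    base = parse_glycan(SLEX)
    before = count_motif(base, m)
    grafted = parse_glycan(SLEX)
    grafted.children.append(GlycanStructure(residue=Residue("Gal", "b", "1", "6")))
    assert count_motif(grafted, m) >= before


def test_matches_exhaustive_oracle_on_small_structures():
    structures = [
        SLEX,
        "Gal(b1-4)GlcNAc",
        "Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-3)Gal(b1-4)Glc",
        "Neu5Ac(a2-8)Neu5Ac(a2-3)Gal(b1-3)GalNAc",
        "GlcNAc(b1-6)[Gal(b1-3)]GalNAc",
        "Fuc(a1-2)Gal(b1-3)[Neu5Ac(a2-6)]GalNAc",
    ]
    motifs = [
        parse_motif(SLEX, "sLex"),
        parse_motif("Gal(b1-4)GlcNAc", "LacNAc"),
        parse_motif("Neu5Ac|Neu5Gc(a2-3)", "a2,3"),
        parse_motif("Neu5Ac|Neu5Gc(a2-6)", "a2,6"),
        parse_motif("Fuc(a1-2)Gal", "H"),
        parse_motif("*(??-?)", "any"),
    ]
    for text in structures:
        g = parse_glycan(text)
        assert len(g) <= 8
        for m in motifs:
            assert count_motif(g, m) == oracle_count(g, m), (text, m.name)
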