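"""Glycan structures, a condensed-IUPAC grammar, and epitope motif matching.

Glycans are rooted trees of monosaccharide residues.  The reducing-end
residue is the root; every other residue records the anomericity and the
position on its parent through which it is attached (e.g. ``Gal(b1-4)GlcNAc``
is a two-residue tree with root GlcNAc and a Gal child attached b1-4).

The text dialect is condensed IUPAC read leaf-to-root: residues are written
``Name(<anomer><carbon>-<position>)`` and side branches are enclosed in
square brackets immediately before their parent residue, as in
``Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc``.  Ambiguous anomericity or
linkage positions are written ``?`` (``x`` is accepted as a synonym).
Substituents such as sulfate are appended to the residue name as
``<position><suffix>`` (``GlcNAc6S`` = GlcNAc carrying a 6-O-sulfate).

Epitope motifs (sialyl Lewis x/a, H antigen, sialylation linkages, ...) are
expressed as pattern trees over the same residue alphabet in which any field
may be a wildcard; :func:`count_motif` counts residue-anchored matches, which
is the multiplicity used by the derived-trait engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_VOCABULARY",
    "SIALIC_ACIDS",
    "UNKNOWN",
    "GlycanSyntaxError",
    "GlycanVocabularyError",
    "Residue",
    "GlycanStructure",
    "MotifPattern",
    "ResidueTemplate",
    "parse_glycan",
    "parse_motif",
    "serialize_glycan",
    "count_motif",
    "iter_residues",
    "isomorphic",
]

#: Marker for an unknown / unspecified anomericity or linkage position.
UNKNOWN = "?"

#: Closed monosaccharide vocabulary.  Sorted by length at tokenization time so
#: that e.g. ``GlcNAc`` is preferred over ``Glc``.
DEFAULT_VOCABULARY = frozenset(
    {
        "Glc",
        "Gal",
        "Man",
        "GlcNAc",
        "GalNAc",
        "ManNAc",
        "Fuc",
        "Xyl",
        "Neu5Ac",
        "Neu5Gc",
        "KDN",
        "GlcA",
        "IdoA",
    }
)

SIALIC_ACIDS = frozenset({"Neu5Ac", "Neu5Gc", "KDN"})

#: Substituent suffix codes: ``Gal3S`` -> sulfate at position 3.
DEFAULT_SUBSTITUENT_SUFFIXES = {"S": "sulfate", "P": "phosphate"}


class GlycanSyntaxError(ValueError):
    """Malformed glycan text; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class GlycanVocabularyError(ValueError):
    """Monosaccharide token outside the configured vocabulary."""

    def __init__(self, token: str, offset: int | None = None):
        self.token = token
        self.offset = offset
        msg = f"unknown monosaccharide token {token!r}"
        if offset is not None:
            msg = f"{msg} (at character {offset})"
        super().__init__(msg)


@dataclass
class Residue:
    """One monosaccharide in a glycan tree.

    ``linkage_position`` is the carbon on the *parent* residue through which
    this residue is attached; the root carries :data:`UNKNOWN`.
    ``anomeric_carbon`` is the residue's own anomeric carbon as written in the
    linkage (1 for most hexoses, 2 for sialic acids).
    """

    monosaccharide: str
    anomericity: str = UNKNOWN  # 'a' | 'b' | '?'
    anomeric_carbon: str = UNKNOWN  # '1' | '2' | '?'
    linkage_position: str = UNKNOWN  # '1'..'9' | '?'
    substituents: frozenset[tuple[str, str]] = frozenset()  # (position, name)


@dataclass
class GlycanStructure:
    """A rooted, ordered glycan tree with provenance."""

    residue: Residue
    children: list["GlycanStructure"] = field(default_factory=list)
    glycan_class: str | None = None  # 'N' | 'O' | 'GSL'
    source_text: str | None = None
    glytoucan_id: str | None = None

    def __len__(self) -> int:
        return 1 + sum(len(c) for c in self.children)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return serialize_glycan(self)


def iter_residues(g: GlycanStructure):
    """Yield every node of ``g`` (pre-order)."""
    yield g
    for child in g.children:
        yield from iter_residues(child)


# ---------------------------------------------------------------------------
# Tokenizer / parser
# ---------------------------------------------------------------------------


def _tokenize_residue(
    text: str,
    start: int,
    vocabulary: frozenset[str],
    suffixes: dict[str, str],
):
    """Read one residue name (longest vocabulary match) plus substituents."""
    candidates = [m for m in vocabulary if text.startswith(m, start)]
    if not candidates:
        # Pull out the offending word for the error message.
        end = start
        while end < len(text) and (text[end].isalnum() or text[end] == "'"):
            end += 1
        token = text[start:end] or text[start : start + 1]
        raise GlycanVocabularyError(token, offset=start)
    name = max(candidates, key=len)
    pos = start + len(name)
    subs: set[tuple[str, str]] = set()
    # Substituents: one or more "<digit><suffix>" groups, e.g. "6S" or "3S6S".
    while pos < len(text) and text[pos].isdigit():
        digit = text[pos]
        matched = None
        for code in sorted(suffixes, key=len, reverse=True):
            if text.startswith(code, pos + 1):
                matched = code
                break
        if matched is None:
            break
        subs.add((digit, suffixes[matched]))
        pos += 1 + len(matched)
    return name, frozenset(subs), pos


def _parse_linkage(text: str, start: int):
    """Parse ``(a2-3)`` / ``(b1-?)`` returning (anomer, carbon, position, end)."""
    if start >= len(text) or text[start] != "(":
        return None
    close = text.find(")", start)
    if close == -1:
        raise GlycanSyntaxError("unclosed linkage parenthesis", offset=start)
    body = text[start + 1 : close]
    if "-" not in body:
        raise GlycanSyntaxError(f"malformed linkage {body!r}", offset=start)
    left, _, right = body.partition("-")
    if not left:
        raise GlycanSyntaxError(f"malformed linkage {body!r}", offset=start)
    anomer = left[0]
    if anomer in ("x", "X"):
        anomer = UNKNOWN
    if anomer not in ("a", "b", UNKNOWN):
        raise GlycanSyntaxError(f"bad anomericity {left[0]!r}", offset=start)
    carbon = left[1:] or UNKNOWN
    if carbon in ("x", "X"):
        carbon = UNKNOWN
    if not (carbon == UNKNOWN or carbon.isdigit()):
        raise GlycanSyntaxError(f"bad anomeric carbon {carbon!r}", offset=start)
    position = right.strip() or UNKNOWN
    if position in ("x", "X"):
        position = UNKNOWN
    if not (position == UNKNOWN or position.isdigit()):
        raise GlycanSyntaxError(f"bad linkage position {position!r}", offset=start)
    return anomer, carbon, position, close + 1


def _parse_chain(
    text: str,
    start: int,
    end: int,
    vocabulary: frozenset[str],
    suffixes: dict[str, str],
    wildcard_mono: bool,
) -> GlycanStructure:
    """Parse ``text[start:end]`` as a chain; the rightmost residue is its root."""
    main: GlycanStructure | None = None
    pending: list[GlycanStructure] = []
    pos = start
    while pos < end:
        ch = text[pos]
        if ch == "[":
            depth = 1
            scan = pos + 1
            while scan < end and depth:
                if text[scan] == "[":
                    depth += 1
                elif text[scan] == "]":
                    depth -= 1
                scan += 1
            if depth:
                raise GlycanSyntaxError("unbalanced '[' bracket", offset=pos)
            branch = _parse_chain(
                text, pos + 1, scan - 1, vocabulary, suffixes, wildcard_mono
            )
            if branch.residue.linkage_position == UNKNOWN and branch.residue.anomericity == UNKNOWN:
                # Branch roots normally carry their linkage; tolerate its absence.
                pass
            pending.append(branch)
            pos = scan
        elif ch == "]":
            raise GlycanSyntaxError("unbalanced ']' bracket", offset=pos)
        else:
            if wildcard_mono and ch == "*":
                name, subs = UNKNOWN, frozenset()
                pos += 1
                # optional substituent requirement on a wildcard: *6S
                while pos < end and text[pos].isdigit():
                    digit = text[pos]
                    matched = None
                    for code in sorted(suffixes, key=len, reverse=True):
                        if text.startswith(code, pos + 1):
                            matched = code
                            break
                    if matched is None:
                        break
                    subs = subs | {(digit, suffixes[matched])}
                    pos += 1 + len(matched)
            elif wildcard_mono and _looks_like_alternation(text, pos, end):
                name, pos = _read_alternation(text, pos, end, vocabulary)
                subs = frozenset()
            else:
                name, subs, pos = _tokenize_residue(text, pos, vocabulary, suffixes)
            linkage = _parse_linkage(text, pos)
            if linkage is None:
                residue = Residue(name, UNKNOWN, UNKNOWN, UNKNOWN, subs)
            else:
                anomer, carbon, position, pos = linkage
                residue = Residue(name, anomer, carbon, position, subs)
            node = GlycanStructure(residue=residue)
            if main is not None:
                node.children.append(main)
            node.children.extend(pending)
            pending = []
            main = node
    if main is None:
        raise GlycanSyntaxError("empty glycan chain", offset=start)
    if pending:
        raise GlycanSyntaxError(
            "dangling branch with no parent residue", offset=end
        )
    return main


def _looks_like_alternation(text: str, pos: int, end: int) -> bool:
    scan = pos
    while scan < end and (text[scan].isalnum() or text[scan] == "|"):
        scan += 1
    return "|" in text[pos:scan]


def _read_alternation(text: str, pos: int, end: int, vocabulary: frozenset[str]):
    scan = pos
    while scan < end and (text[scan].isalnum() or text[scan] == "|"):
        nxt = text[scan]
        if nxt == "(":
            break
        scan += 1
    # back off trailing linkage digits consumed by isalnum: names never end
    # in '(' so find the last position where the remainder parses as names.
    chunk = text[pos:scan]
    if "(" in chunk:
        chunk = chunk[: chunk.index("(")]
    names = chunk.split("|")
    for n in names:
        if n not in vocabulary:
            raise GlycanVocabularyError(n, offset=pos)
    return "|".join(sorted(names)), pos + len(chunk)


def parse_glycan(
    text: str,
    glycan_class: str | None = None,
    *,
    vocabulary: frozenset[str] = DEFAULT_VOCABULARY,
    substituent_suffixes: dict[str, str] | None = None,
    glytoucan_id: str | None = None,
) -> GlycanStructure:
    """Parse a condensed-IUPAC glycan string into a canonical tree.

    The root is the reducing-end residue; branch order is normalised by a
    deterministic canonical sort (linkage position ascending, then the
    serialized subtree lexicographically).  Raises
    :class:`GlycanVocabularyError` for unknown monosaccharides and
    :class:`GlycanSyntaxError` (with character offset) for malformed text.
    """
    suffixes = substituent_suffixes or DEFAULT_SUBSTITUENT_SUFFIXES
    stripped = text.strip()
    if not stripped:
        raise GlycanSyntaxError("empty glycan string", offset=0)
    tree = _parse_chain(stripped, 0, len(stripped), vocabulary, suffixes, False)
    root = tree.residue
    if root.linkage_position != UNKNOWN or root.anomericity != UNKNOWN:
        # A linkage on the overall root has nothing to attach to; normalise it
        # away (GSL tables often write e.g. "Glc(b1-1)" toward the ceramide).
        tree.residue = Residue(
            root.monosaccharide, UNKNOWN, UNKNOWN, UNKNOWN, root.substituents
        )
    _canonicalize(tree)
    tree.glycan_class = glycan_class
    tree.source_text = text
    tree.glytoucan_id = glytoucan_id
    return tree


def _sort_key(node: GlycanStructure):
    # Full subtree text including the node's own linkage, so same-position
    # children with different anomers still order deterministically.
    pos = node.residue.linkage_position
    return (
        pos == UNKNOWN,
        int(pos) if pos != UNKNOWN else 0,
        _serialize(node, is_root=False),
    )


def _canonicalize(node: GlycanStructure) -> None:
    for child in node.children:
        _canonicalize(child)
    node.children.sort(key=_sort_key)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _residue_text(r: Residue, *, with_linkage: bool) -> str:
    subs = "".join(
        f"{pos}{_suffix_for(name)}" for pos, name in sorted(r.substituents)
    )
    base = f"{r.monosaccharide}{subs}"
    if not with_linkage:
        return base
    return f"{base}({r.anomericity}{r.anomeric_carbon}-{r.linkage_position})"


def _suffix_for(substituent: str) -> str:
    for code, name in DEFAULT_SUBSTITUENT_SUFFIXES.items():
        if name == substituent:
            return code
    return substituent


def serialize_glycan(g: GlycanStructure) -> str:
    """Canonical condensed-IUPAC string; ``parse(serialize(g))`` ≅ ``g``.

    Children are emitted in canonical order with the last (highest linkage
    position) child on the main chain and the rest bracketed, matching the
    conventional appearance of e.g. ``Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc``.
    """
    return _serialize(g, is_root=True)


def _serialize(node: GlycanStructure, *, is_root: bool) -> str:
    children = sorted(node.children, key=_sort_key)
    prefix = ""
    if children:
        *bracketed, main = children
        prefix = _serialize(main, is_root=False)
        prefix += "".join(f"[{_serialize(b, is_root=False)}]" for b in bracketed)
    return prefix + _residue_text(node.residue, with_linkage=not is_root)


def isomorphic(a: GlycanStructure, b: GlycanStructure) -> bool:
    """Tree isomorphism irrespective of child order (canonical-form equality)."""
    ra, rb = a.residue, b.residue
    if (
        ra.monosaccharide != rb.monosaccharide
        or ra.anomericity != rb.anomericity
        or ra.anomeric_carbon != rb.anomeric_carbon
        or ra.linkage_position != rb.linkage_position
        or ra.substituents != rb.substituents
    ):
        return False
    if len(a.children) != len(b.children):
        return False
    ca = sorted(a.children, key=_sort_key)
    cb = sorted(b.children, key=_sort_key)
    return all(isomorphic(x, y) for x, y in zip(ca, cb))


# ---------------------------------------------------------------------------
# Motif patterns and matching
# ---------------------------------------------------------------------------


@dataclass
class ResidueTemplate:
    """One node of a motif pattern; ``None`` fields are wildcards.

    ``monosaccharide`` may be a set of alternatives (e.g. the sialic acids).
    ``substituents`` is a *required subset* of the matched residue's
    substituents.  ``children`` must all be embeddable into distinct children
    of the matched residue; extra glycan children are allowed unless they
    match one of ``forbidden_children``.
    """

    monosaccharide: frozenset[str] | None = None
    anomericity: str | None = None
    anomeric_carbon: str | None = None
    linkage_position: str | None = None
    substituents: frozenset[tuple[str, str]] = frozenset()
    children: list["ResidueTemplate"] = field(default_factory=list)
    forbidden_children: list["ResidueTemplate"] = field(default_factory=list)


@dataclass
class MotifPattern:
    """A named epitope pattern anchored at its root template."""

    name: str
    root: ResidueTemplate


def _field_matches(pattern_value: str | None, glycan_value: str) -> bool:
    # Ambiguous glycan fields ('?') satisfy only wildcard pattern fields:
    # an uncertain linkage must never be counted toward a concrete trait
    # (e.g. '?' sialylation is neither a2,3 nor a2,6).
    if pattern_value is None:
        return True
    return glycan_value == pattern_value


def _residue_matches(t: ResidueTemplate, node: GlycanStructure) -> bool:
    r = node.residue
    if t.monosaccharide is not None and r.monosaccharide not in t.monosaccharide:
        return False
    if not _field_matches(t.anomericity, r.anomericity):
        return False
    if not _field_matches(t.anomeric_carbon, r.anomeric_carbon):
        return False
    if not _field_matches(t.linkage_position, r.linkage_position):
        return False
    if not t.substituents <= r.substituents:
        return False
    return True


def _matches_at(t: ResidueTemplate, node: GlycanStructure) -> bool:
    """Does the pattern rooted at ``t`` embed at ``node``?

    A pattern root written without a linkage has wildcard linkage fields and
    can anchor anywhere; writing one (``Neu5Ac(a2-3)``) constrains how the
    anchor hangs off its own parent.
    """
    if not _residue_matches(t, node):
        return False
    for forbidden in t.forbidden_children:
        if any(_residue_matches(forbidden, c) for c in node.children):
            return False
    if not t.children:
        return True
    if len(t.children) > len(node.children):
        return False
    # Injective assignment of template children onto distinct glycan children.
    for assignment in itertools.permutations(node.children, len(t.children)):
        if all(_matches_at(tc, gc) for tc, gc in zip(t.children, assignment)):
            return True
    return False


def count_motif(g: GlycanStructure, m: MotifPattern) -> int:
    """Number of distinct residue-anchored matches of ``m`` in ``g``.

    Each residue of ``g`` is tried as the anchor for the pattern root;
    anchors are counted independently, so a biantennary glycan carrying the
    sialyl Lewis x unit on both antennae counts 2.
    """
    return sum(1 for node in iter_residues(g) if _matches_at(m.root, node))


def parse_motif(
    pattern_text: str,
    name: str = "",
    *,
    forbidden: list[dict] | None = None,
    vocabulary: frozenset[str] = DEFAULT_VOCABULARY,
    substituent_suffixes: dict[str, str] | None = None,
) -> MotifPattern:
    """Build a :class:`MotifPattern` from condensed-IUPAC pattern text.

    The grammar is the structure grammar plus two wildcard forms: ``*`` for
    "any monosaccharide" and ``A|B`` alternation (``Neu5Ac|Neu5Gc``); a ``?``
    in a linkage makes that field a wildcard.  ``forbidden`` entries are
    ``{"at": <mono name in pattern>, "child": <template text>}`` and forbid
    the named pattern node from having a matching glycan child (e.g. a Lewis
    x galactose that must not be further sialylated).
    """
    suffixes = substituent_suffixes or DEFAULT_SUBSTITUENT_SUFFIXES
    stripped = pattern_text.strip()
    tree = _parse_chain(stripped, 0, len(stripped), vocabulary, suffixes, True)
    root = _to_template(tree)
    for rule in forbidden or []:
        target = _find_template_node(root, rule["at"])
        if target is None:
            raise ValueError(
                f"forbidden-child anchor {rule['at']!r} not found in pattern {name!r}"
            )
        target.forbidden_children.append(_child_template(rule["child"], vocabulary, suffixes))
    return MotifPattern(name=name, root=root)


def _wild(value: str) -> str | None:
    return None if value == UNKNOWN else value


def _to_template(node: GlycanStructure) -> ResidueTemplate:
    r = node.residue
    mono = None if r.monosaccharide == UNKNOWN else frozenset(r.monosaccharide.split("|"))
    t = ResidueTemplate(
        monosaccharide=mono,
        anomericity=_wild(r.anomericity),
        anomeric_carbon=_wild(r.anomeric_carbon),
        linkage_position=_wild(r.linkage_position),
        substituents=r.substituents,
        children=[_to_template(c) for c in node.children],
    )
    return t


def _child_template(text: str, vocabulary, suffixes) -> ResidueTemplate:
    tree = _parse_chain(text.strip(), 0, len(text.strip()), vocabulary, suffixes, True)
    return _to_template(tree)


def _find_template_node(t: ResidueTemplate, mono_name: str) -> ResidueTemplate | None:
    if t.monosaccharide is not None and mono_name in t.monosaccharide:
        return t
    for c in t.children:
        found = _find_template_node(c, mono_name)
        if found is not None:
            return found
    return None
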