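"""Derived glycan traits: from per-glycan relative abundances to trait matrices.

A derived trait (e.g. "a2,3-sialylation", "(s)Lex/a", "H antigen") summarises
a glycomics panel per sample: the trait value is the sum of the relative
abundances of all glycans carrying the trait's epitope, each multiplied by
the number of times the epitope occurs on that glycan.  Traits are computed
per glycan class (N, O, GSL) and can then be integrated across classes by
summing the class-wise values trait by trait.

Trait rules come in three modes:

``motif_count``
    one or more :class:`~glycotraits.glycan_model.MotifPattern` objects; the
    per-glycan count is the summed anchored-match count (``presence`` mode
    clips it to 0/1, used for the ganglioside trait where any sialic acid
    makes a GSL a ganglioside).
``annotation_column``
    the count is taken from a pre-annotated column of the input table, for
    species reported as compositions whose structures cannot be parsed.
``numeric_property``
    a per-structure numeric function, used for N-glycan antennarity (number
    of antennae on the trimannosyl core).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .glycan_model import (
    GlycanStructure,
    MotifPattern,
    count_motif,
    iter_residues,
    parse_glycan,
    parse_motif,
)

__all__ = [
    "GLYCAN_CLASSES",
    "TraitRule",
    "GlycanRecord",
    "GlycomicsPanel",
    "TraitMatrix",
    "default_rules",
    "annotate_panel",
    "compute_trait_matrix",
    "integrate_traits",
    "antenna_count",
]

logger = logging.getLogger(__name__)

GLYCAN_CLASSES = ("N", "O", "GSL")

#: Tolerated deviation of per-sample abundance totals from 100 before a
#: renormalization warning is emitted (in percent of the total).
RENORMALIZE_WARN_FRACTION = 0.01


# ---------------------------------------------------------------------------
# Numeric property functions
# ---------------------------------------------------------------------------


def antenna_count(g: GlycanStructure) -> int:
    """Antennae on the N-glycan trimannosyl core.

    Counted as GlcNAc residues whose parent is a mannose that is itself
    attached to a mannose (i.e. GlcNAc on the α-arms).  The chitobiose core
    GlcNAcs and a bisecting GlcNAc (attached to the β-mannose, whose parent
    is a GlcNAc) are thereby excluded.
    """
    n = 0
    for node in iter_residues(g):
        if node.residue.monosaccharide != "Man":
            continue
        for child in node.children:
            if child.residue.monosaccharide == "Man":
                for grand in child.children:
                    if grand.residue.monosaccharide == "GlcNAc":
                        n += 1
    return n


NUMERIC_PROPERTIES = {"antenna_count": antenna_count}


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass
class TraitRule:
    """One derived-trait definition."""

    trait_name: str
    applicable_classes: frozenset[str] = frozenset(GLYCAN_CLASSES)
    mode: str = "motif_count"  # motif_count | annotation_column | numeric_property
    motifs: list[MotifPattern] = field(default_factory=list)
    count_mode: str = "multiplicity"  # multiplicity | presence
    property_name: str | None = None  # for numeric_property
    annotation_column: str | None = None  # for annotation_column

    def __post_init__(self):
        self.applicable_classes = frozenset(self.applicable_classes)
        modes = {"motif_count", "annotation_column", "numeric_property"}
        if self.mode not in modes:
            raise ValueError(f"unknown trait rule mode {self.mode!r}")
        if self.mode == "motif_count" and not self.motifs:
            raise ValueError(f"trait {self.trait_name!r}: motif_count rule needs motifs")
        if self.mode == "numeric_property" and self.property_name not in NUMERIC_PROPERTIES:
            raise ValueError(
                f"trait {self.trait_name!r}: unknown numeric property {self.property_name!r}"
            )
        if self.mode == "annotation_column" and not self.annotation_column:
            self.annotation_column = self.trait_name

    def count(self, glycan: GlycanStructure) -> float:
        if self.mode == "motif_count":
            total = sum(count_motif(glycan, m) for m in self.motifs)
            return min(total, 1) if self.count_mode == "presence" else total
        if self.mode == "numeric_property":
            return NUMERIC_PROPERTIES[self.property_name](glycan)
        raise ValueError("annotation_column rules are counted from the table")


_SIA = "Neu5Ac|Neu5Gc"


def _lewis_motifs() -> dict[str, MotifPattern]:
    """The four Lewis-family epitopes; the plain forms exclude sialylated
    galactoses so that the combined family never double-counts an anchor."""
    return {
        "sLex": parse_motif("Neu5Ac(a2-3)Gal(b1-4)[Fuc(a1-3)]GlcNAc", "sLex"),
        "sLea": parse_motif("Neu5Ac(a2-3)Gal(b1-3)[Fuc(a1-4)]GlcNAc", "sLea"),
        "Lex": parse_motif(
            "Gal(b1-4)[Fuc(a1-3)]GlcNAc",
            "Lex",
            forbidden=[{"at": "Gal", "child": _SIA}],
        ),
        "Lea": parse_motif(
            "Gal(b1-3)[Fuc(a1-4)]GlcNAc",
            "Lea",
            forbidden=[{"at": "Gal", "child": _SIA}],
        ),
    }


def default_rules() -> list[TraitRule]:
    """The built-in derived-trait vocabulary.

    Covers the shared traits (sialylation linkages, Lewis family, H antigen,
    LacNAc) plus the class-specific ones: N-glycan antennarity, O-glycan
    T antigen / core 2 / sulfation, and GSL gangliosides / Neu5Gc.
    """
    lewis = _lewis_motifs()
    all_classes = frozenset(GLYCAN_CLASSES)
    rules = [
        TraitRule("(s)Lex/a", all_classes, motifs=list(lewis.values())),
        TraitRule("sLex", all_classes, motifs=[lewis["sLex"]]),
        TraitRule("sLea", all_classes, motifs=[lewis["sLea"]]),
        TraitRule("Lex", all_classes, motifs=[lewis["Lex"]]),
        TraitRule("Lea", all_classes, motifs=[lewis["Lea"]]),
        TraitRule(
            "H antigen",
            all_classes,
            motifs=[parse_motif("Fuc(a1-2)Gal", "H antigen")],
        ),
        TraitRule(
            "a2,3-sialylation",
            all_classes,
            motifs=[parse_motif(f"{_SIA}(a2-3)", "a2,3-sialylation")],
        ),
        TraitRule(
            "a2,6-sialylation",
            all_classes,
            motifs=[parse_motif(f"{_SIA}(a2-6)", "a2,6-sialylation")],
        ),
        TraitRule(
            "a2,8-sialylation",
            all_classes,
            motifs=[parse_motif(f"{_SIA}(a2-8)", "a2,8-sialylation")],
        ),
        TraitRule(
            "LacNAc",
            all_classes,
            motifs=[parse_motif("Gal(b1-4)GlcNAc", "LacNAc")],
        ),
        TraitRule("antennarity", {"N"}, mode="numeric_property", property_name="antenna_count"),
        TraitRule(
            "T antigen",
            {"O"},
            motifs=[
                parse_motif(
                    "Gal(b1-3)GalNAc",
                    "T antigen",
                    forbidden=[
                        {"at": "Gal", "child": "*"},
                        {"at": "GalNAc", "child": "*(??-6)"},
                    ],
                )
            ],
        ),
        TraitRule(
            "core 2",
            {"O"},
            motifs=[parse_motif("GlcNAc(b1-6)[Gal(b1-3)]GalNAc", "core 2")],
        ),
        TraitRule(
            "sulfation",
            {"O"},
            motifs=[
                parse_motif("*1S", "sulfation"),
                parse_motif("*2S", "sulfation"),
                parse_motif("*3S", "sulfation"),
                parse_motif("*4S", "sulfation"),
                parse_motif("*6S", "sulfation"),
            ],
        ),
        TraitRule(
            "Neu5Gc",
            {"GSL"},
            motifs=[parse_motif("Neu5Gc(??-?)", "Neu5Gc")],
        ),
        TraitRule(
            "gangliosides",
            {"GSL"},
            motifs=[parse_motif(f"{_SIA}(??-?)", "gangliosides")],
            count_mode="presence",
        ),
    ]
    return rules


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


@dataclass
class GlycanRecord:
    """One glycan species of a panel."""

    glycan_id: str
    structure_text: str | None = None
    glytoucan_id: str | None = None
    annotations: dict[str, float] = field(default_factory=dict)
    structure: GlycanStructure | None = None

    def parsed(self, glycan_class: str) -> GlycanStructure | None:
        if self.structure is None and self.structure_text:
            self.structure = parse_glycan(
                self.structure_text, glycan_class, glytoucan_id=self.glytoucan_id
            )
        return self.structure


@dataclass
class GlycomicsPanel:
    """Per-class glycomics table: glycans × samples relative abundances.

    ``abundances`` is indexed by glycan_id with one column per sample.  On
    construction every sample is renormalised so that the panel is
    compositional (totals of 100); inputs off by more than 1% are reported.
    """

    glycan_class: str
    glycans: list[GlycanRecord]
    abundances: pd.DataFrame
    fab_labels: pd.Series | None = None

    def __post_init__(self):
        if self.glycan_class not in GLYCAN_CLASSES:
            raise ValueError(f"unknown glycan class {self.glycan_class!r}")
        ids = [g.glycan_id for g in self.glycans]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate glycan_id(s): {dupes}")
        if list(self.abundances.index) != ids:
            self.abundances = self.abundances.loc[ids]
        if (self.abundances.to_numpy() < 0).any():
            bad = self.abundances[self.abundances < 0].stack().index[0]
            raise ValueError(f"negative abundance at glycan {bad[0]!r}, sample {bad[1]!r}")
        totals = self.abundances.sum(axis=0)
        if (totals <= 0).any():
            empty = totals.index[totals <= 0].tolist()
            raise ValueError(f"sample(s) with zero total abundance: {empty}")
        off = (totals - 100.0).abs() / 100.0
        if (off > RENORMALIZE_WARN_FRACTION).any():
            worst = totals[off.idxmax()]
            logger.warning(
                "%s-glycan panel: per-sample totals deviate from 100 "
                "(worst %s = %.3f); renormalizing",
                self.glycan_class,
                off.idxmax(),
                worst,
            )
        self.abundances = self.abundances.div(totals, axis=1) * 100.0

    @property
    def samples(self) -> list[str]:
        return list(self.abundances.columns)

    def record(self, glycan_id: str) -> GlycanRecord:
        for g in self.glycans:
            if g.glycan_id == glycan_id:
                return g
        raise KeyError(glycan_id)


@dataclass
class TraitMatrix:
    """Samples × traits matrix of derived-trait values (relative-abundance units)."""

    values: pd.DataFrame
    glycan_class: str  # 'N' | 'O' | 'GSL' | 'integrated'
    provenance: str = "default"

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _applicable(rules: list[TraitRule], glycan_class: str) -> list[TraitRule]:
    return [r for r in rules if glycan_class in r.applicable_classes]


def annotate_panel(panel: GlycomicsPanel, rules: list[TraitRule]) -> pd.DataFrame:
    """Per-glycan trait counts (glycans × traits) for the applicable rules.

    Motif and numeric rules require a parsable structure; annotation rules
    read the pre-annotated count from the record.  A glycan that supports
    neither path for a rule raises an error naming the glycan and the trait.
    """
    applicable = _applicable(rules, panel.glycan_class)
    counts = pd.DataFrame(
        0.0,
        index=[g.glycan_id for g in panel.glycans],
        columns=[r.trait_name for r in applicable],
    )
    for g in panel.glycans:
        structure = g.parsed(panel.glycan_class) if g.structure_text else None
        for rule in applicable:
            if rule.mode == "annotation_column":
                if rule.annotation_column in g.annotations:
                    counts.at[g.glycan_id, rule.trait_name] = g.annotations[
                        rule.annotation_column
                    ]
                    continue
                raise ValueError(
                    f"glycan {g.glycan_id!r} has no annotation for trait "
                    f"{rule.trait_name!r} (column {rule.annotation_column!r})"
                )
            if structure is not None:
                counts.at[g.glycan_id, rule.trait_name] = rule.count(structure)
            elif rule.trait_name in g.annotations:
                # Structure-free fallback path for composition-only species.
                counts.at[g.glycan_id, rule.trait_name] = g.annotations[rule.trait_name]
            else:
                raise ValueError(
                    f"glycan {g.glycan_id!r} has neither a structure nor an "
                    f"annotation for trait {rule.trait_name!r}"
                )
    return counts


def compute_trait_matrix(
    panel: GlycomicsPanel,
    rules: list[TraitRule],
    provenance: str = "default",
) -> TraitMatrix:
    """Derived-trait values per sample.

    value(sample, trait) = Σ_glycan abundance(glycan, sample) × count(glycan, trait),
    i.e. relative abundances weighted by epitope multiplicity.
    """
    counts = annotate_panel(panel, rules)
    values = panel.abundances.T.to_numpy() @ counts.to_numpy()
    df = pd.DataFrame(values, index=panel.samples, columns=counts.columns)
    return TraitMatrix(values=df, glycan_class=panel.glycan_class, provenance=provenance)


def integrate_traits(per_class: list[TraitMatrix], provenance: str | None = None) -> TraitMatrix:
    """Sum trait values across glycan classes.

    Trait names are aligned case-insensitively (exact match after lowering);
    a trait absent from a class contributes 0 there.  All matrices must
    cover the same samples.
    """
    if not per_class:
        raise ValueError("no trait matrices to integrate")
    base_samples = set(per_class[0].samples)
    for tm in per_class[1:]:
        if set(tm.samples) != base_samples:
            missing = base_samples.symmetric_difference(tm.samples)
            raise ValueError(
                f"sample sets differ between class matrices: {sorted(missing)}"
            )
    sample_order = per_class[0].samples
    # Canonical (first-seen) spelling per lower-cased trait name.
    canonical: dict[str, str] = {}
    for tm in per_class:
        for trait in tm.traits:
            canonical.setdefault(trait.lower(), trait)
    columns = list(canonical.values())
    total = pd.DataFrame(0.0, index=sample_order, columns=columns)
    for tm in per_class:
        for trait in tm.traits:
            total[canonical[trait.lower()]] += tm.values[trait].reindex(sample_order)
    prov = provenance or "+".join(tm.glycan_class for tm in per_class)
    return TraitMatrix(values=total, glycan_class="integrated", provenance=prov)
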