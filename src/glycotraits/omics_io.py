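"""Tabular I/O: glycomics tables, expression matrices, probe maps, panels.

All tables travel as TSV/CSV (delimiter inferred from the file suffix,
``.tsv`` → tab, otherwise comma).  Glycomics tables have the layout::

    glycan_id, structure, glytoucan_id, [annotation columns...], <sample>...

where ``structure`` and ``glytoucan_id`` may be empty and any column named
``annot:<trait>`` provides a pre-annotated epitope count for species whose
structures are ambiguous.  Expression matrices are genes × samples with the
gene symbol in the first column.  Gene panels and trait-rule libraries are
YAML (or JSON, which YAML subsumes).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .trait_engine import (
    GlycanRecord,
    GlycomicsPanel,
    TraitMatrix,
    TraitRule,
    default_rules,
)
from .glycan_model import parse_motif

__all__ = [
    "GenePanel",
    "ExpressionMatrix",
    "read_glycomics_table",
    "write_glycomics_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "collapse_probes",
    "read_gene_panels",
    "read_trait_rules",
    "read_trait_table",
    "write_trait_matrix",
    "read_fab_labels",
    "write_manifest",
]

logger = logging.getLogger(__name__)

ANNOTATION_PREFIX = "annot:"
RESERVED_COLUMNS = ("glycan_id", "structure", "glytoucan_id", "class")

#: Rows with more than this fraction of missing expression values are dropped.
MAX_MISSING_FRACTION = 0.2


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


# ---------------------------------------------------------------------------
# Gene panels and expression
# ---------------------------------------------------------------------------


@dataclass
class GenePanel:
    """A named, ordered gene list (e.g. the GST or TF panel)."""

    name: str
    genes: list[str]

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"gene panel {self.name!r} has duplicate symbols: {dupes}")


@dataclass
class ExpressionMatrix:
    """Genes × samples normalized expression with panel tags and FAB labels."""

    values: pd.DataFrame  # genes × samples
    panel_tags: pd.Series = None  # gene -> panel name or 'other'
    fab_labels: pd.Series | None = None  # sample -> FAB class

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dupes = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene symbols: {dupes}")
        if self.panel_tags is None:
            self.panel_tags = pd.Series("other", index=self.values.index)
        all_missing = self.values.isna().all(axis=1)
        if all_missing.any():
            raise ValueError(
                f"all-missing gene rows: {sorted(self.values.index[all_missing])}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, genes: list[str]) -> pd.DataFrame:
        present = [g for g in genes if g in self.values.index]
        return self.values.loc[present]


def attach_panels(values: pd.DataFrame, panels: list[GenePanel]) -> pd.Series:
    tags = pd.Series("other", index=values.index, dtype=object)
    for panel in panels:
        for gene in panel.genes:
            if gene in tags.index:
                tags.loc[gene] = panel.name
    return tags


def read_expression_matrix(
    path: str | Path,
    panels: list[GenePanel] | None = None,
    fab_labels: pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a genes × samples table (first column = gene symbol).

    Values must be numeric (missing cells allowed); a non-numeric cell is
    reported with its coordinates.  Rows missing in more than 20% of samples
    are dropped with a warning.
    """
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        raw[col] = converted
    missing_frac = raw.isna().mean(axis=1)
    drop = missing_frac > MAX_MISSING_FRACTION
    if drop.any():
        logger.warning(
            "dropping %d gene row(s) with >%.0f%% missing values: %s",
            int(drop.sum()),
            MAX_MISSING_FRACTION * 100,
            sorted(raw.index[drop]),
        )
        raw = raw[~drop]
    tags = attach_panels(raw, panels or [])
    return ExpressionMatrix(values=raw, panel_tags=tags, fab_labels=fab_labels)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene")


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: dict[str, str],
    panels: list[GenePanel] | None = None,
) -> ExpressionMatrix:
    """Collapse microarray probe rows to one row per gene.

    For every gene, the probe with the highest mean expression across samples
    is retained; ties break toward the lexicographically smallest probe id.
    Probes absent from the map are dropped (counted in the log).  This is a
    deterministic stand-in for manual probe curation.
    """
    unmapped = [p for p in probe_matrix.index if p not in probe_map]
    if unmapped:
        logger.warning("dropping %d unmapped probe(s): %s", len(unmapped), sorted(unmapped))
    kept = probe_matrix.loc[[p for p in probe_matrix.index if p in probe_map]]
    means = kept.mean(axis=1, skipna=True)
    chosen: dict[str, str] = {}
    for probe in sorted(kept.index):  # sorted => lexicographic tie-break
        gene = probe_map[probe]
        if gene not in chosen or means[probe] > means[chosen[gene]]:
            chosen[gene] = probe
    rows = pd.DataFrame(
        {gene: kept.loc[probe] for gene, probe in sorted(chosen.items())}
    ).T
    rows.index.name = "gene"
    for gene, probe in sorted(chosen.items()):
        logger.info("probe collapse: %s <- %s (mean %.4g)", gene, probe, means[probe])
    tags = attach_panels(rows, panels or [])
    return ExpressionMatrix(values=rows, panel_tags=tags)


# ---------------------------------------------------------------------------
# Glycomics tables
# ---------------------------------------------------------------------------


def read_glycomics_table(
    path: str | Path,
    glycan_class: str,
    fab_labels: pd.Series | None = None,
) -> GlycomicsPanel:
    """Read a per-class glycomics table into a validated panel."""
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, dtype={"glycan_id": str})
    if "glycan_id" not in raw.columns:
        raise ValueError(f"{path}: missing required column 'glycan_id'")
    annot_cols = [c for c in raw.columns if c.startswith(ANNOTATION_PREFIX)]
    sample_cols = [
        c for c in raw.columns if c not in RESERVED_COLUMNS and c not in annot_cols
    ]
    if not sample_cols:
        raise ValueError(f"{path}: no sample columns found")
    records = []
    for _, row in raw.iterrows():
        structure = row.get("structure")
        if pd.isna(structure) or not str(structure).strip():
            structure = None
        gtc = row.get("glytoucan_id")
        if pd.isna(gtc) or not str(gtc).strip():
            gtc = None
        annotations = {
            c[len(ANNOTATION_PREFIX) :]: float(row[c])
            for c in annot_cols
            if not pd.isna(row[c])
        }
        records.append(
            GlycanRecord(
                glycan_id=str(row["glycan_id"]),
                structure_text=structure,
                glytoucan_id=gtc,
                annotations=annotations,
            )
        )
    abundances = raw.set_index("glycan_id")[sample_cols].astype(float)
    return GlycomicsPanel(
        glycan_class=glycan_class,
        glycans=records,
        abundances=abundances,
        fab_labels=fab_labels,
    )


def write_glycomics_table(panel: GlycomicsPanel, path: str | Path) -> None:
    """Write a panel back to disk in the documented layout."""
    rows = []
    for g in panel.glycans:
        row = {
            "glycan_id": g.glycan_id,
            "structure": g.structure_text or "",
            "glytoucan_id": g.glytoucan_id or "",
        }
        for trait, value in sorted(g.annotations.items()):
            row[f"{ANNOTATION_PREFIX}{trait}"] = value
        for sample in panel.samples:
            row[sample] = panel.abundances.at[g.glycan_id, sample]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Config: panels, trait rules, labels
# ---------------------------------------------------------------------------


def read_gene_panels(path: str | Path) -> list[GenePanel]:
    """YAML/JSON mapping of panel name -> gene list."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [GenePanel(name=name, genes=list(genes)) for name, genes in data.items()]


def read_trait_rules(path: str | Path) -> list[TraitRule]:
    """Load a trait-rule library from YAML/JSON.

    Each entry: ``name``, ``classes`` (subset of N/O/GSL), ``mode``
    (default ``motif_count``), and mode-specific fields — ``motifs`` (list of
    ``{pattern, forbidden?}``), ``property`` or ``column``.  An entry that is
    just a name pulls the built-in rule of that name.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    builtin = {r.trait_name.lower(): r for r in default_rules()}
    rules = []
    for entry in entries:
        if isinstance(entry, str):
            try:
                rules.append(builtin[entry.lower()])
            except KeyError:
                raise ValueError(f"unknown built-in trait rule {entry!r}") from None
            continue
        name = entry["name"]
        classes = frozenset(entry.get("classes", ("N", "O", "GSL")))
        mode = entry.get("mode", "motif_count")
        if mode == "motif_count":
            motifs = [
                parse_motif(m["pattern"], name, forbidden=m.get("forbidden"))
                for m in entry["motifs"]
            ]
            rules.append(
                TraitRule(
                    name,
                    classes,
                    motifs=motifs,
                    count_mode=entry.get("count_mode", "multiplicity"),
                )
            )
        elif mode == "numeric_property":
            rules.append(
                TraitRule(name, classes, mode=mode, property_name=entry["property"])
            )
        else:
            rules.append(
                TraitRule(name, classes, mode=mode, annotation_column=entry.get("column"))
            )
    return rules


def read_fab_labels(path: str | Path) -> pd.Series:
    """Two-column table sample_id, fab."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id, fab")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str), name="fab")


# ---------------------------------------------------------------------------
# Trait matrices and results
# ---------------------------------------------------------------------------


def write_trait_matrix(tm: TraitMatrix, path: str | Path) -> None:
    tm.values.to_csv(path, sep=_sep_for(path), index_label="sample")


def read_trait_table(path: str | Path, glycan_class: str = "integrated") -> TraitMatrix:
    """Read a samples × traits table of derived-trait values.

    This is the entry point for externally quantified trait tables (one row
    per sample, named trait columns), e.g. published per-cell-line values.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return TraitMatrix(values=df.astype(float), glycan_class=glycan_class, provenance=str(path))


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Deterministic JSON run manifest (sorted keys, no timestamps)."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
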