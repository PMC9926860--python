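"""FAB-class comparisons: one-way ANOVA with Tukey HSD post-hoc tiers.

Gene expression is compared across FAB classes (M0–M7) with a classical
one-way ANOVA followed by Tukey's honestly-significant-difference test
(Tukey–Kramer for unequal group sizes).  Pairwise adjusted p-values are
tiered at p ≤ 0.05 / 0.01 / 0.001 / 0.0001 (* to ****).  Groups below the
minimum size (default 3) are excluded before testing — small rare classes
carry too little information for the post-hoc comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .omics_io import ExpressionMatrix, GenePanel

__all__ = [
    "TIER_THRESHOLDS",
    "AnovaResult",
    "anova_oneway",
    "tukey_hsd",
    "fab_screen",
]

logger = logging.getLogger(__name__)

#: Adjusted-p tiers for the post-hoc pairs.
TIER_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))

DEFAULT_MIN_GROUP_SIZE = 3


def tier(p: float) -> str:
    if np.isnan(p):
        return ""
    for cutoff, marker in TIER_THRESHOLDS:
        if p <= cutoff:
            return marker
    return ""


def _split_groups(values, group_labels, min_group_size: int):
    """Group values by label, dropping undersized groups with a warning."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    groups: dict[str, np.ndarray] = {}
    for name in sorted(pd.unique(labels).tolist()):
        member = values[labels == name]
        if member.size < min_group_size:
            logger.warning(
                "excluding group %r with %d member(s) (< %d)",
                name,
                member.size,
                min_group_size,
            )
            continue
        groups[name] = member
    if len(groups) < 2:
        raise ValueError(
            f"fewer than 2 groups of size ≥ {min_group_size} remain; cannot test"
        )
    return groups


@dataclass
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int
    groups_used: list[str]
    groups_excluded: list[str] = field(default_factory=list)


def anova_oneway(
    values,
    group_labels,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> AnovaResult:
    """Classical one-way ANOVA across the labelled groups."""
    all_names = sorted(pd.unique(np.asarray(group_labels)).tolist())
    groups = _split_groups(values, group_labels, min_group_size)
    F, p = stats.f_oneway(*groups.values())
    n_total = sum(v.size for v in groups.values())
    return AnovaResult(
        F=float(F),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        groups_used=list(groups),
        groups_excluded=[g for g in all_names if g not in groups],
    )


def tukey_hsd(
    values,
    group_labels,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """All-pairs Tukey HSD table: group_a, group_b, difference, p_adj, tier.

    Uses the studentized-range distribution (Tukey–Kramer for unequal n).
    The difference reported is mean(group_b) − mean(group_a).
    """
    groups = _split_groups(values, group_labels, min_group_size)
    names = list(groups)
    res = stats.tukey_hsd(*groups.values())
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            p_adj = float(res.pvalue[i, j])
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "difference": float(groups[b].mean() - groups[a].mean()),
                    "p_adj": p_adj,
                    "tier": tier(p_adj),
                }
            )
    return pd.DataFrame(rows)


def fab_screen(
    expr: ExpressionMatrix,
    genes: GenePanel,
    min_group_size: int = DEFAULT_MIN_GROUP_SIZE,
) -> dict:
    """Per-gene ANOVA + Tukey report across FAB classes.

    Returns ``{"pairs": tidy DataFrame, "anova": DataFrame, "not_found":
    [genes], "excluded_groups": [labels]}``.  Genes absent from the matrix
    are reported, not fatal.
    """
    if expr.fab_labels is None:
        raise ValueError("expression matrix has no FAB labels")
    labels = expr.fab_labels.reindex(expr.samples)
    keep = labels.notna()
    # Cohort-level exclusion of undersized groups (logged once, not per gene);
    # per-gene missing values can still trigger further exclusions below.
    sizes = labels[keep].value_counts()
    small = sorted(sizes.index[sizes < min_group_size].tolist())
    if small:
        logger.warning(
            "fab_screen: excluding group(s) below %d samples: %s",
            min_group_size,
            {g: int(sizes[g]) for g in small},
        )
        keep &= ~labels.isin(small)
    if keep.sum() < 2 * min_group_size:
        raise ValueError("too few FAB-labelled samples for a group comparison")
    not_found = [g for g in genes.genes if g not in expr.values.index]
    if not_found:
        logger.warning("fab_screen: gene(s) not in matrix: %s", not_found)
    pair_rows = []
    anova_rows = []
    excluded: set[str] = set(small)
    for gene in genes.genes:
        if gene in not_found:
            continue
        vals = expr.values.loc[gene, keep[keep].index].to_numpy(dtype=float)
        labs = labels[keep].to_numpy()
        a = anova_oneway(vals, labs, min_group_size)
        excluded.update(a.groups_excluded)
        anova_rows.append(
            {
                "gene": gene,
                "F": a.F,
                "p": a.p,
                "df_between": a.df_between,
                "df_within": a.df_within,
            }
        )
        table = tukey_hsd(vals, labs, min_group_size)
        table.insert(0, "gene", gene)
        pair_rows.append(table)
    pairs = (
        pd.concat(pair_rows, ignore_index=True)
        if pair_rows
        else pd.DataFrame(columns=["gene", "group_a", "group_b", "difference", "p_adj", "tier"])
    )
    return {
        "pairs": pairs,
        "anova": pd.DataFrame(anova_rows),
        "not_found": not_found,
        "excluded_groups": sorted(excluded),
    }
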