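"""Spearman correlation of traits and genes, and the RV2 matrix correlation.

Pairwise associations between derived glycan traits and gene expression (and
between gene panels) use Spearman's rank correlation with midrank tie
handling; p-values come from the t-approximation by default, with an exact
permutation option for small n.  Significance is tiered at the conventional
p ≤ 0.05 / 0.01 / 0.001 cut-offs on the raw p-values; Benjamini–Hochberg
adjusted values are reported alongside.

Whole-matrix similarity between two cohorts (e.g. the gene–gene correlation
structure of cell lines versus primary blasts over a shared gene set) is
measured with the modified RV coefficient (RV2): configuration matrices
AAᵀ and BBᵀ are formed from column-centred data, their diagonals deleted,
and the coefficient is their normalised Frobenius inner product.  Unlike the
classical RV coefficient, RV2 is not inflated toward 1 in high dimensions;
it lies in [−1, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "STAR_THRESHOLDS",
    "CorrelationResult",
    "RV2Result",
    "spearman",
    "correlate_blocks",
    "stars",
    "rv2",
    "rv2_permutation_test",
    "cross_class_trait_correlations",
]

logger = logging.getLogger(__name__)

#: Raw-p significance tiers and their markers.
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

MIN_SAMPLES = 4


def stars(p: float, thresholds=STAR_THRESHOLDS) -> str:
    """Significance marker for a raw p-value ('' when not significant)."""
    if np.isnan(p):
        return ""
    for cutoff, marker in thresholds:
        if p <= cutoff:
            return marker
    return ""


def spearman(
    x,
    y,
    *,
    method: str = "t",
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rho and p for two paired vectors.

    Pairs with a missing value on either side are removed; at least 4
    complete pairs are required.  Ties are midranked.  ``method='t'`` uses
    the t-approximation; ``method='permutation'`` permutes one vector
    ``n_perm`` times for an exact-style p.  A constant vector has no defined
    rank correlation and yields ``(nan, nan)`` with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    if method == "t":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        rho = float(stats.spearmanr(x, y).statistic)
        count = 0
        for _ in range(n_perm):
            perm_rho = float(stats.spearmanr(x, rng.permutation(y)).statistic)
            if abs(perm_rho) >= abs(rho) - 1e-12:
                count += 1
        return rho, (count + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class CorrelationResult:
    """Pairwise Spearman results between a row block and a column block."""

    rho: pd.DataFrame  # rows × cols
    p: pd.DataFrame
    n_used: pd.DataFrame
    p_adjusted: pd.DataFrame  # Benjamini–Hochberg across all finite pairs

    @property
    def star_table(self) -> pd.DataFrame:
        return self.p.map(stars)

    def to_long(self) -> pd.DataFrame:
        """Tidy long format: row, column, rho, p, p_bh, n, stars."""
        rows = []
        for r in self.rho.index:
            for c in self.rho.columns:
                pv = self.p.at[r, c]
                rows.append(
                    {
                        "row": r,
                        "column": c,
                        "rho": self.rho.at[r, c],
                        "p": pv,
                        "p_bh": self.p_adjusted.at[r, c],
                        "n": int(self.n_used.at[r, c]),
                        "stars": stars(pv),
                    }
                )
        return pd.DataFrame(rows)


def _block_frame(block) -> pd.DataFrame:
    """Coerce a TraitMatrix / ExpressionMatrix / DataFrame to samples × features."""
    # Local imports avoid a cycle at module load.
    from .trait_engine import TraitMatrix
    from .omics_io import ExpressionMatrix

    if isinstance(block, TraitMatrix):
        return block.values
    if isinstance(block, ExpressionMatrix):
        return block.values.T
    if isinstance(block, pd.DataFrame):
        return block
    raise TypeError(f"cannot interpret {type(block).__name__} as a feature block")


def correlate_blocks(rows, cols, *, method: str = "t") -> CorrelationResult:
    """Full Spearman rho/p matrices between two feature blocks.

    ``rows`` and ``cols`` may be TraitMatrix (samples × traits),
    ExpressionMatrix (genes × samples) or plain samples × features frames;
    they are aligned on their shared samples (≥ 4 required).  Missing values
    are removed pairwise.
    """
    rf = _block_frame(rows)
    cf = _block_frame(cols)
    shared = [s for s in rf.index if s in set(cf.index)]
    if len(shared) < MIN_SAMPLES:
        raise ValueError(
            f"only {len(shared)} shared samples between blocks; need ≥ {MIN_SAMPLES}"
        )
    rf = rf.loc[shared]
    cf = cf.loc[shared]
    rho = pd.DataFrame(np.nan, index=rf.columns, columns=cf.columns)
    pval = pd.DataFrame(np.nan, index=rf.columns, columns=cf.columns)
    n_used = pd.DataFrame(0, index=rf.columns, columns=cf.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-vector warnings summarised below
        for rname in rf.columns:
            xv = rf[rname].to_numpy(dtype=float)
            for cname in cf.columns:
                yv = cf[cname].to_numpy(dtype=float)
                ok = np.isfinite(xv) & np.isfinite(yv)
                n_used.at[rname, cname] = int(ok.sum())
                if ok.sum() < MIN_SAMPLES:
                    continue
                r, p = spearman(xv[ok], yv[ok], method=method)
                rho.at[rname, cname] = r
                pval.at[rname, cname] = p
    n_constant = int(pval.isna().to_numpy().sum())
    if n_constant:
        logger.warning("correlate_blocks: %d pair(s) undefined (constant vectors)", n_constant)
    flat = pval.to_numpy().ravel()
    adj = np.full_like(flat, np.nan)
    finite = np.isfinite(flat)
    if finite.any():
        adj[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    p_adj = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    return CorrelationResult(rho=rho, p=pval, n_used=n_used, p_adjusted=p_adj)


def cross_class_trait_correlations(
    matrices: dict[str, "pd.DataFrame | object"],
    pairs: list[tuple[str, str, str]],
    *,
    method: str = "t",
) -> pd.DataFrame:
    """Spearman correlation of the same trait between two glycan classes.

    ``matrices`` maps class name -> TraitMatrix/DataFrame (samples × traits);
    ``pairs`` lists (trait, class_a, class_b).  Returns a tidy frame with
    rho and p per requested pair.
    """
    rows = []
    for trait, cls_a, cls_b in pairs:
        a = _block_frame(matrices[cls_a])
        b = _block_frame(matrices[cls_b])
        shared = [s for s in a.index if s in set(b.index)]
        r, p = spearman(a.loc[shared, trait], b.loc[shared, trait], method=method)
        rows.append(
            {
                "trait": trait,
                "class_a": cls_a,
                "class_b": cls_b,
                "rho": r,
                "p": p,
                "n": len(shared),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RV2
# ---------------------------------------------------------------------------


@dataclass
class RV2Result:
    coefficient: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


def _tilde_configuration(M: np.ndarray) -> np.ndarray:
    """Column-centred cross-product matrix with the diagonal deleted."""
    centred = M - M.mean(axis=0, keepdims=True)
    S = centred @ centred.T
    np.fill_diagonal(S, 0.0)
    return S


def rv2(A, B) -> RV2Result:
    """Modified RV (RV2) coefficient between two row-matched matrices.

    Rows are the shared entities (e.g. genes); columns may differ in number
    and meaning.  Columns are mean-centred, configuration matrices AAᵀ/BBᵀ
    formed, diagonals set to zero, and the coefficient computed as their
    Frobenius inner product over the product of Frobenius norms.
    """
    A = np.asarray(_rows(A), dtype=float)
    B = np.asarray(_rows(B), dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"row mismatch: {A.shape[0]} vs {B.shape[0]}")
    if A.shape[0] < 3:
        raise ValueError("RV2 needs at least 3 rows (diagonal-deleted configuration)")
    Sa = _tilde_configuration(A)
    Sb = _tilde_configuration(B)
    denom = np.linalg.norm(Sa) * np.linalg.norm(Sb)
    if denom == 0:
        raise ValueError("degenerate configuration (zero off-diagonal structure)")
    return RV2Result(coefficient=float(np.sum(Sa * Sb) / denom))


def _rows(M) -> np.ndarray:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float)
    return np.asarray(M, dtype=float)


def align_by_rows(A: pd.DataFrame, B: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-align two labelled matrices on their sorted shared row names."""
    shared = sorted(set(A.index) & set(B.index))
    if not shared:
        raise ValueError("no shared row labels")
    return A.loc[shared], B.loc[shared]


def rv2_permutation_test(A, B, n_perm: int = 999, seed: int | None = None) -> RV2Result:
    """RV2 with a row-permutation p-value.

    The observed coefficient is compared with the coefficients obtained after
    permuting the row order of B; p = (1 + #{permuted ≥ observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    A = _rows(A)
    B = _rows(B)
    observed = rv2(A, B).coefficient
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(B.shape[0])
        if rv2(A, B[perm]).coefficient >= observed - 1e-12:
            count += 1
    return RV2Result(
        coefficient=observed,
        p_value=(count + 1) / (n_perm + 1),
        n_permutations=n_perm,
        seed=seed,
    )
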