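"""Unit-variance PCA over combined glycan-feature blocks, z-scores, radar data.

The per-class derived-trait matrices are combined into one feature table.
To keep any one glycan class from dominating the decomposition, blocks are
balanced to approximately equal feature counts (by default each block keeps
its top-variance features down to the size of the smallest block).  Features
are then centred and scaled to unit variance before the eigendecomposition,
so every trait enters on the same footing regardless of its raw scale.

Group (radar) profiles are mean z-scores per FAB class, with the
z-transformation computed over all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trait_engine import TraitMatrix

__all__ = [
    "PCAResult",
    "balance_features",
    "pca_unit_variance",
    "z_transform",
    "group_profile",
]

logger = logging.getLogger(__name__)


def balance_features(
    blocks: list[TraitMatrix],
    policy: str = "min_block",
) -> pd.DataFrame:
    """Combine per-class trait matrices into one samples × features table.

    ``min_block`` keeps, per block, the k highest-variance features where k
    is the smallest block's feature count; ``all`` keeps everything.
    Column names are prefixed with the block's glycan class so the block
    membership of every feature stays visible.
    """
    if not blocks:
        raise ValueError("no feature blocks")
    for b in blocks:
        if not b.traits:
            raise ValueError(f"empty feature block for class {b.glycan_class!r}")
    base = blocks[0].samples
    for b in blocks[1:]:
        if set(b.samples) != set(base):
            raise ValueError("blocks cover different sample sets")
    if policy == "min_block":
        k = min(len(b.traits) for b in blocks)
    elif policy == "all":
        k = None
    else:
        raise ValueError(f"unknown balancing policy {policy!r}")
    pieces = []
    for b in blocks:
        values = b.values.loc[base]
        if k is not None and len(values.columns) > k:
            variances = values.var(axis=0, ddof=1)
            keep = variances.sort_values(ascending=False, kind="stable").index[:k]
            keep = [c for c in values.columns if c in set(keep)]  # original order
            logger.info(
                "balance_features: class %s keeps %d/%d features: %s",
                b.glycan_class,
                k,
                len(values.columns),
                list(keep),
            )
            values = values[keep]
        values = values.rename(columns=lambda c: f"{b.glycan_class}:{c}")
        pieces.append(values)
    return pd.concat(pieces, axis=1)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # features × components (unit-norm eigenvectors)
    explained_variance_ratio: np.ndarray
    dropped_features: list[str]

    @property
    def components(self) -> list[str]:
        return list(self.scores.columns)


def pca_unit_variance(X: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of autoscaled data (centred, unit variance, ddof=1).

    Constant features cannot be scaled and are dropped with a warning.  The
    decomposition is by SVD of the scaled matrix; each component's sign is
    fixed so that its largest-magnitude loading is positive.  Requesting more
    components than the rank truncates with a warning.
    """
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 samples")
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    dropped = list(X.columns[constant])
    if dropped:
        logger.warning("pca_unit_variance: dropping constant feature(s): %s", dropped)
        X = X.loc[:, ~constant]
        sd = sd[~constant]
    Z = (X - X.mean(axis=0)) / sd
    n, p = Z.shape
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    tol = S.max(initial=0.0) * max(n, p) * np.finfo(float).eps
    rank = int((S > tol).sum())
    k = rank if n_components is None else min(n_components, rank)
    if n_components is not None and n_components > rank:
        logger.warning(
            "pca_unit_variance: requested %d components but rank is %d; truncating",
            n_components,
            rank,
        )
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(k):
        idx = np.argmax(np.abs(Vt[j]))
        if Vt[j, idx] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = (S[:k] ** 2) / total_var
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=X.columns, columns=comp_names),
        explained_variance_ratio=evr,
        dropped_features=dropped,
    )


def z_transform(X: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scores over all samples (sample sd, ddof=1).

    A zero-variance feature is emitted as all-zero with a warning rather
    than NaN, so downstream group profiles stay defined.
    """
    if X.shape[0] < 2:
        raise ValueError("z-transform needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "z_transform: zero-variance feature(s) set to 0: %s",
            list(X.columns[zero]),
        )
        sd = sd.replace(0, 1.0)
    return (X - mean) / sd


def group_profile(
    Z: pd.DataFrame,
    group_labels: pd.Series,
    groups_of_interest: list[str] | None = None,
) -> pd.DataFrame:
    """Mean z-score per (group, feature) — the radar-plot data.

    ``group_labels`` maps sample -> group (e.g. FAB class).  Each requested
    group needs at least 2 samples.  Returns groups × features.
    """
    labels = group_labels.reindex(Z.index)
    known = sorted(labels.dropna().unique().tolist())
    groups = groups_of_interest or known
    unknown = [g for g in groups if g not in known]
    if unknown:
        raise ValueError(f"unknown group label(s) {unknown}; known: {known}")
    rows = {}
    for g in groups:
        members = Z.loc[labels == g]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has {len(members)} sample(s); need ≥ 2")
        rows[g] = members.mean(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out
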