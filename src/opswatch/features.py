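"""Descriptor reduction and importance ranking.

The reduction has two stages.  First, every descriptor column with at
least one missing value or with zero variance is dropped: missing values
arise when the descriptor software fails to recognise a structure, and a
column that cannot be computed for every molecule (or never varies) cannot
serve as a model feature.  Second, redundant descriptors are pruned by
Pearson correlation: columns are scanned in descending-variance order and
a descriptor is retained only if its absolute correlation with every
previously retained descriptor stays below the threshold, keeping one
representative (the most spread one) per correlated block.

Importance ranking fits a seeded random forest and reports each retained
descriptor's mean-impurity-decrease share, plus its min-max "relative
importance" rescaling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .data import DescriptorMatrix

__all__ = [
    "drop_unusable_descriptors",
    "pearson_prune",
    "importance_rank",
    "relative_importance",
]

logger = logging.getLogger(__name__)


def drop_unusable_descriptors(
    X: DescriptorMatrix,
) -> tuple[DescriptorMatrix, list[str]]:
    """Remove descriptor columns with any missing value or zero variance.

    Molecule rows are untouched.  Returns the cleaned matrix and the list
    of removed descriptor names (also logged).

    Raises
    ------
    ValueError
        If no usable descriptor remains.
    """
    frame = X.frame
    has_missing = frame.isna().any(axis=0)
    # a column is zero-variance when all its (non-missing) values coincide
    constant = frame.nunique(dropna=True) <= 1
    drop = has_missing | constant
    removed = list(frame.columns[drop])
    kept = frame.loc[:, ~drop]
    if kept.shape[1] == 0:
        raise ValueError("no usable descriptors remain after cleanup")
    if removed:
        logger.info(
            "dropped %d unusable descriptors (%d with missing values, %d constant)",
            len(removed), int(has_missing.sum()), int((constant & ~has_missing).sum()),
        )
    return DescriptorMatrix(kept.copy()), removed


def pearson_prune(X: DescriptorMatrix, threshold: float = 0.95) -> list[str]:
    """Greedy Pearson redundancy pruning; returns retained names in scan order.

    Columns are scanned by descending variance (ties by name ascending); a
    descriptor is retained iff its absolute Pearson correlation with every
    previously retained descriptor is strictly below ``threshold``.

    The matrix must be complete (run :func:`drop_unusable_descriptors`
    first) and have at least two molecules.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    frame = X.frame
    if frame.isna().any().any():
        raise ValueError("matrix contains missing values; clean it first")
    if frame.shape[0] < 2:
        raise ValueError("correlation undefined with fewer than 2 molecules")
    variances = frame.var(axis=0, ddof=1)
    if (variances == 0).any():
        raise ValueError("zero-variance columns present; clean the matrix first")

    order = sorted(frame.columns, key=lambda c: (-variances[c], c))
    values = frame.to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(frame.columns)}
    # standardize once; |r| between standardized columns is |x.y| / (n-1)
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=1)
    n = values.shape[0]

    retained: list[str] = []
    retained_z: list[np.ndarray] = []
    for name in order:
        zj = z[:, col_idx[name]]
        if retained_z:
            corr = np.abs(np.array(retained_z) @ zj) / (n - 1)
            if (corr >= threshold - 1e-12).any():
                continue
        retained.append(name)
        retained_z.append(zj)
    return retained


def importance_rank(
    X: DescriptorMatrix,
    y: pd.Series,
    seed: int = 0,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Random-forest impurity-decrease importance shares, sorted descending.

    Returns a DataFrame with columns ``descriptor`` and ``importance``
    (shares summing to 1), sorted by importance descending with ties
    broken by descriptor name ascending.
    """
    frame = X.frame
    if frame.isna().any().any():
        raise ValueError("matrix contains missing values; clean it first")
    y = y.loc[frame.index]
    if y.nunique() < 2:
        raise ValueError("importance ranking needs at least 2 classes")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(frame.to_numpy(), y.to_numpy())
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    tbl = pd.DataFrame({"descriptor": frame.columns, "importance": imp})
    return (
        tbl.sort_values(["importance", "descriptor"], ascending=[False, True])
        .reset_index(drop=True)
    )


def relative_importance(tbl: pd.DataFrame) -> pd.DataFrame:
    """Append a min-max rescaled ``relative_importance`` column.

    ``relative = (importance - min) / (max - min)``, so the largest
    importance maps to 1 and the smallest to 0.  Requires at least two
    rows and a nondegenerate range.
    """
    if len(tbl) < 2:
        raise ValueError("relative importance needs at least 2 rows")
    imp = tbl["importance"].to_numpy(dtype=float)
    lo, hi = imp.min(), imp.max()
    if hi == lo:
        raise ValueError("degenerate importance range (max equals min)")
    out = tbl.copy()
    out["relative_importance"] = (imp - lo) / (hi - lo)
    return out
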