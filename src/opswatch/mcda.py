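"""Entropy-weight + TOPSIS composite toxicity engine.

The composite score for an entity (a pesticide or a transformation
product) is built in four steps:

1. **Orientation normalization** — every indicator column is min-max
   scaled to [0, 1] so that larger always means more toxic: benefit-type
   indicators (probabilities, BCF) map through ``(x - min)/(max - min)``,
   cost-type concentrations (IGC50, LC50DM, LC50FM) through
   ``(max - x)/(max - min)``.
2. **Entropy weighting** — with ``p_ij = r_ij / sum_i r_ij`` (and
   ``0 ln 0 := 0``), the Shannon entropy of indicator *j* is
   ``e_j = -(1/ln n) sum_i p_ij ln p_ij``; weights are
   ``w_j = (1 - e_j) / sum_k (1 - e_k)``.  Indicators whose values are
   spread over few entities have low entropy and high weight; a constant
   indicator has entropy 1 and weight 0.
3. **TOPSIS** — on the weighted matrix ``v_ij = w_j r_ij``, the positive
   ideal is the column-wise maximum and the negative ideal the column-wise
   minimum; the closeness ``C_i = D-_i / (D+_i + D-_i)`` of each entity to
   the ideal uses Euclidean distances and lies in [0, 1].
4. **Parent/product aggregation** — a parent's combined indicator vector
   is a convex mix (default half/half) of its own vector and the mean of
   its products' vectors, and the watch-list score is the TOPSIS closeness
   of the combined matrix.

Min-max (not vector) normalization feeds TOPSIS, shared with the
orientation step, so an entity that attains every column maximum scores
exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    PROBABILITY_INDICATORS,
    ToxicityMatrix,
    TransformationMap,
)

__all__ = [
    "NormalizedMatrix",
    "EntropyWeights",
    "MCDAResult",
    "orient_normalize",
    "entropy_weights",
    "topsis_scores",
    "adjusted_product_scores",
    "aggregate_parent_products",
    "composite_toxicity_scores",
]


@dataclass
class NormalizedMatrix:
    """Orientation-aligned values in [0, 1]; higher always = more toxic."""

    frame: pd.DataFrame

    @property
    def entity_names(self) -> list[str]:
        return list(self.frame.index)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class EntropyWeights:
    """Per-indicator Shannon entropy ``e_j`` and weight ``w_j`` (sum 1)."""

    entropy: pd.Series
    weights: pd.Series


@dataclass
class MCDAResult:
    """Per-entity distances to the ideal solutions and closeness score."""

    frame: pd.DataFrame  # columns: d_plus, d_minus, closeness

    @property
    def closeness(self) -> pd.Series:
        return self.frame["closeness"]

    def ranking(self) -> pd.DataFrame:
        return self.frame.sort_values(
            "closeness", ascending=False, kind="mergesort"
        )


def orient_normalize(T: ToxicityMatrix) -> NormalizedMatrix:
    """Min-max normalize every indicator so that larger = more toxic.

    Constant columns are mapped to all-0.5 with a warning (they carry no
    ranking information and receive entropy weight 0 anyway).  Negative
    values in probability-type indicators raise.
    """
    frame = T.frame
    if frame.isna().any().any():
        raise ValueError("toxicity matrix contains missing values")
    for col in frame.columns:
        if col in PROBABILITY_INDICATORS and (frame[col] < 0).any():
            raise ValueError(f"negative probability indicator {col!r}")
    out = {}
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(
                f"indicator {col!r} is constant; normalized to 0.5",
                stacklevel=2,
            )
            out[col] = np.full_like(x, 0.5)
        elif T.orientation[col] == "cost":
            out[col] = (hi - x) / (hi - lo)
        else:
            out[col] = (x - lo) / (hi - lo)
    return NormalizedMatrix(pd.DataFrame(out, index=frame.index))


def entropy_weights(R: NormalizedMatrix) -> EntropyWeights:
    """Objective indicator weights from Shannon entropy of value shares.

    Raises ``ValueError`` when every indicator is constant (degenerate:
    all entropies are 1 so no weight can be assigned).
    """
    frame = R.frame
    if (frame.to_numpy() < 0).any():
        raise ValueError("normalized values must be nonnegative")
    n = len(frame)
    if n < 2:
        raise ValueError("entropy weighting needs at least 2 entities")
    values = frame.to_numpy(dtype=float)
    col_sums = values.sum(axis=0)
    e = np.ones(values.shape[1])
    nz = col_sums > 0
    p = np.zeros_like(values)
    p[:, nz] = values[:, nz] / col_sums[nz]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e[nz] = -plogp[:, nz].sum(axis=0) / np.log(n)
    # clip tiny negative drift from floating point
    e = np.clip(e, 0.0, 1.0)
    d = 1.0 - e
    if d.sum() <= 0:
        raise ValueError("entropy degenerate: all indicators constant")
    w = d / d.sum()
    return EntropyWeights(
        entropy=pd.Series(e, index=frame.columns, name="entropy"),
        weights=pd.Series(w, index=frame.columns, name="weight"),
    )


def topsis_scores(R: NormalizedMatrix, w: EntropyWeights) -> MCDAResult:
    """Closeness of every entity to the ideal-toxic solution.

    The weighted matrix is ``v_ij = w_j r_ij``; the positive ideal takes
    the column-wise maxima (most toxic) and the negative ideal the minima;
    ``C_i = D-_i / (D+_i + D-_i)``.
    """
    frame = R.frame
    if len(frame) < 2:
        raise ValueError("TOPSIS needs at least 2 entities")
    weights = w.weights.loc[frame.columns].to_numpy(dtype=float)
    v = frame.to_numpy(dtype=float) * weights
    ideal_pos = v.max(axis=0)
    ideal_neg = v.min(axis=0)
    d_plus = np.sqrt(((v - ideal_pos) ** 2).sum(axis=1))
    d_minus = np.sqrt(((v - ideal_neg) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).any():
        raise ValueError("no discrimination: entities identical under weights")
    closeness = d_minus / denom
    return MCDAResult(
        pd.DataFrame(
            {"d_plus": d_plus, "d_minus": d_minus, "closeness": closeness},
            index=frame.index,
        )
    )


def adjusted_product_scores(
    T_products: ToxicityMatrix, res: MCDAResult
) -> pd.Series:
    """Per-product adjusted score: mean normalized indicator level x closeness.

    ``res`` must hold the TOPSIS result computed on the oriented-normalized
    product matrix; the adjustment multiplies each product's mean
    oriented-normalized indicator value by its closeness score, so a
    product must be both broadly and distinctively toxic to rank high.
    """
    if set(T_products.entity_names) != set(res.frame.index):
        raise ValueError("entity names differ between matrix and MCDA result")
    normalized = orient_normalize(T_products).frame
    means = normalized.mean(axis=1)
    adjusted = means * res.closeness.loc[means.index]
    adjusted.name = "adjusted_score"
    return adjusted


def aggregate_parent_products(
    parents: ToxicityMatrix,
    products: ToxicityMatrix,
    m: TransformationMap,
    parent_weight: float = 0.5,
) -> ToxicityMatrix:
    """Combine each parent's indicators with its products' averages.

    The combined vector is ``parent_weight * parent + (1 - parent_weight)
    * mean(products)``; a parent with zero products keeps its own vector.
    The output has one row per parent, in parent order.
    """
    if not 0.0 <= parent_weight <= 1.0:
        raise ValueError("parent_weight must lie in [0, 1]")
    missing_parents = [p for p in m if p not in parents.frame.index]
    if missing_parents:
        raise ValueError(f"parents missing from matrix: {missing_parents}")
    rows = {}
    for parent in parents.entity_names:
        pvec = parents.frame.loc[parent]
        prods = m.products.get(parent, [])
        absent = [q for q in prods if q not in products.frame.index]
        if absent:
            raise ValueError(f"products missing from matrix: {absent}")
        if prods:
            pmean = products.frame.loc[prods].mean(axis=0)
            rows[parent] = parent_weight * pvec + (1.0 - parent_weight) * pmean
        else:
            rows[parent] = pvec
    combined = pd.DataFrame.from_dict(rows, orient="index")
    combined = combined.loc[parents.entity_names, parents.frame.columns]
    combined.index.name = parents.frame.index.name
    return ToxicityMatrix(combined, dict(parents.orientation))


def composite_toxicity_scores(
    parents: ToxicityMatrix,
    products: ToxicityMatrix,
    m: TransformationMap,
    parent_weight: float = 0.5,
) -> tuple[pd.Series, EntropyWeights]:
    """End-to-end composite toxicity: aggregate, normalize, weight, TOPSIS.

    Returns the per-parent closeness scores (the watch-list input) and the
    entropy weights used.
    """
    combined = aggregate_parent_products(parents, products, m, parent_weight)
    normalized = orient_normalize(combined)
    weights = entropy_weights(normalized)
    result = topsis_scores(normalized, weights)
    scores = result.closeness.copy()
    scores.name = "composite_toxicity"
    return scores, weights
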