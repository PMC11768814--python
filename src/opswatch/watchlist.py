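"""Standard-deviation attention binning and end-to-end orchestration.

Composite toxicity scores are turned into a four-level "special attention"
list by mean-centred standard-deviation intervals: with ``d = C - mean``
and ``delta`` the population standard deviation of the scores,

* special   : d in (1.85 delta, 3.7 delta]
* focus     : d in (0, 1.85 delta]
* general   : d in (-1.85 delta, 0]
* secondary : d in (-3.7 delta, -1.85 delta]

Scores beyond +-3.7 delta clamp to the nearest extreme level with a
warning.  Higher score always means equal-or-higher attention priority,
and the assignment is invariant to positive affine transformations of the
score vector.

``reproduce_paper`` re-derives every fixture-encoded published figure
(management-list class counts, the 75/6/89 application tally, delta =
0.0459, the 54/54 attention-level agreement, and the min-max relative
importances) and reports pass/fail per check.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import (
    AttentionLevel,
    PRINTED_TO_LEVEL,
    ToxicityMatrix,
    TransformationMap,
    WatchList,
)
from .fixtures import load_paper_fixtures
from .mcda import composite_toxicity_scores

__all__ = [
    "compute_delta",
    "assign_levels",
    "build_watchlist",
    "reproduce_paper",
]

#: Interval half-width in population-SD units.
SD_INTERVAL = 1.85


def compute_delta(scores: pd.Series | np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of the scores."""
    values = np.asarray(scores, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 scores")
    return float(values.mean()), float(values.std(ddof=0))


def _level_for(d: float, delta: float) -> tuple[AttentionLevel, bool]:
    """Bin a mean deviation; returns (level, clamped?)."""
    if d > 3.7 * delta:
        return AttentionLevel.SPECIAL, True
    if d > SD_INTERVAL * delta:
        return AttentionLevel.SPECIAL, False
    if d > 0:
        return AttentionLevel.FOCUS, False
    if d > -SD_INTERVAL * delta:
        return AttentionLevel.GENERAL, False
    if d > -3.7 * delta:
        return AttentionLevel.SECONDARY, False
    return AttentionLevel.SECONDARY, True


def assign_levels(
    scores: pd.Series,
    mean: float | None = None,
    delta: float | None = None,
) -> WatchList:
    """Bin composite toxicity scores into the four attention levels.

    ``mean``/``delta`` default to the statistics of ``scores`` itself;
    pass them explicitly to bin against a reference population.  Bins are
    left-open/right-closed, so a score exactly at the mean falls in
    "general".  The result is sorted by score descending, ties by name
    ascending.
    """
    if mean is None or delta is None:
        mean, delta = compute_delta(scores)
    if delta <= 0:
        raise ValueError("no dispersion; levels undefined (delta = 0)")
    levels = []
    for name, score in scores.items():
        level, clamped = _level_for(float(score) - mean, delta)
        if clamped:
            warnings.warn(
                f"{name}: deviation beyond +-3.7 delta; clamped to "
                f"{level.value}",
                stacklevel=2,
            )
        levels.append(level)
    frame = pd.DataFrame(
        {
            "composite_toxicity": scores.to_numpy(dtype=float),
            "deviation": scores.to_numpy(dtype=float) - mean,
            "level": levels,
        },
        index=scores.index.copy(),
    )
    # sort by score descending, ties by name ascending
    order = np.lexsort(
        (frame.index.to_numpy(), -frame["composite_toxicity"].to_numpy())
    )
    frame = frame.iloc[order]
    return WatchList(frame=frame, mean=float(mean), delta=float(delta))


def build_watchlist(
    parents: ToxicityMatrix,
    products: ToxicityMatrix,
    tmap: TransformationMap,
    parent_weight: float = 0.5,
) -> WatchList:
    """End-to-end: aggregate toxicity, score by entropy-TOPSIS, bin levels."""
    scores, _ = composite_toxicity_scores(parents, products, tmap, parent_weight)
    return assign_levels(scores)


# ---------------------------------------------------------------------------
# fixture-based reproduction report
# ---------------------------------------------------------------------------


def _check(value, expected, ok) -> dict:
    return {"value": value, "expected": expected, "passed": bool(ok)}


def reproduce_paper() -> dict:
    """Recompute every fixture-encoded published figure; report pass/fail.

    Returns a JSON-serializable report with one entry per check and an
    overall ``passed`` flag.  Raises if a fixture is missing or malformed
    (no partial report).
    """
    fx = load_paper_fixtures()
    checks: dict[str, dict] = {}

    counts = fx.china_counts()
    expected_counts = {"banned": 17, "restricted": 8, "unrestricted": 54}
    checks["china_list_counts"] = _check(
        counts, expected_counts, counts == expected_counts
    )

    tally = fx.application_predictions["y1"].value_counts()
    got = (
        int(tally.get("banned", 0)),
        int(tally.get("restricted", 0)),
        int(tally.get("unrestricted", 0)),
    )
    checks["application_tally"] = _check(list(got), [75, 6, 89], got == (75, 6, 89))

    scores = fx.composite_toxicity["composite_toxicity"]
    mean, delta = compute_delta(scores)
    checks["delta"] = _check(round(delta, 4), 0.0459, abs(delta - 0.0459) <= 0.0005)

    wl = assign_levels(scores, mean, delta)
    printed = fx.composite_toxicity["printed_level"].map(PRINTED_TO_LEVEL)
    agree = int((wl.frame["level"].loc[printed.index] == printed).sum())
    checks["watchlist_agreement"] = _check(agree, len(printed), agree == len(printed))

    imp = fx.importance_table
    vals = imp["importance"].to_numpy(dtype=float)
    recomputed = (vals - vals.min()) / (vals.max() - vals.min())
    err = float(np.abs(recomputed - imp["relative_importance"].to_numpy()).max())
    checks["relative_importance_max_err"] = _check(
        round(err, 6), "<= 0.005", err <= 0.005
    )

    return {"checks": checks, "passed": all(c["passed"] for c in checks.values())}
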