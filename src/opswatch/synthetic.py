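"""Synthetic test-bed generator for the prioritization pipeline.

Real inputs to the pipeline are a PaDEL-style descriptor table, regulatory
labels, an ADMET-style toxicity-indicator table, and a biotransformation
parent->product map.  None of those can be bundled, so this module plants
their *statistical* structure instead:

* descriptors are class-conditional Gaussians with correlated redundant
  blocks and injected missing columns — controllable signal and redundancy,
  not molecular realism;
* the 20 probability-type toxicity indicators are Beta draws (one (a, b)
  pair per indicator), the four continuous eco-endpoints are log-normal,
  with the three lethal/inhibition concentrations recorded as cost-oriented;
* each parent gets a truncated-Poisson number of transformation products
  whose indicator profiles are a convex mix of the parent profile and a
  fresh draw, reproducing the observation that products carry toxicity
  similar to their parents.

Everything is deterministic given ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    COST_INDICATORS,
    INDICATOR_NAMES,
    PROBABILITY_INDICATORS,
    DescriptorMatrix,
    ToxicityMatrix,
    TransformationMap,
)

__all__ = [
    "SyntheticConfig",
    "DEFAULT_INDICATOR_PARAMS",
    "generate_descriptors",
    "generate_toxicity",
    "generate_products",
]

#: Per-indicator distribution parameters.  Probability-type indicators take
#: Beta(a, b); the four continuous eco-endpoints take log-normal
#: (mu, sigma) on the log scale.  The mix emulates ADMET output for this
#: compound family: several endpoints (genotoxicity, hepatotoxicity,
#: respiratory toxicity) sit near probability 1 for almost every molecule,
#: most others are moderate, and ototoxicity is rare but wildly variable
#: across molecules — by design the most dispersed indicator, so that
#: entropy weighting has a planted "most informative" column.
DEFAULT_INDICATOR_PARAMS: dict[str, tuple[float, float]] = {
    "hERG blockers": (2.0, 5.0),
    "hERG blockers (10 um)": (1.5, 6.0),
    "DILI": (8.0, 3.0),
    "AMES toxicity": (5.0, 4.0),
    "rat oral acute toxicity": (6.0, 3.0),
    "FDAMDD": (4.0, 4.0),
    "skin sensitization": (10.0, 2.0),
    "carcinogenicity": (3.0, 4.0),
    "eye corrosion": (2.0, 6.0),
    "eye irritation": (12.0, 2.0),
    "respiratory toxicity": (25.0, 2.0),
    "human hepatotoxicity": (30.0, 2.0),
    "drug-induced nephrotoxicity": (15.0, 2.0),
    "drug-induced neurotoxicity": (12.0, 2.0),
    "ototoxicity": (0.2, 0.8),
    "nematotoxicity": (2.0, 3.0),
    "genotoxicity": (60.0, 1.0),
    "RPMI-8226 immunotoxicity": (2.0, 4.0),
    "A549 cytotoxicity": (3.0, 3.0),
    "Hek293 cytotoxicity": (3.0, 3.0),
    # log-normal (mu, sigma): BCF in L/kg-ish magnitudes, concentrations in
    # mg/L-ish magnitudes; sigmas kept moderate so no eco-endpoint out-skews
    # the planted high-dispersion probability indicator.
    "BCF": (1.0, 0.6),
    "IGC50": (2.0, 0.7),
    "LC50DM": (1.5, 0.7),
    "LC50FM": (1.8, 0.7),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror the published analysis: 79 molecules in class
    proportions 17:8:54, strongly redundant descriptor blocks
    (within-block correlation 0.97), 5% of descriptor columns carrying
    missing cells, 0-8 transformation products per parent with a 0.6
    parent weight in product toxicity.
    """

    n_molecules: int = 79
    class_proportions: tuple[float, float, float] = (17 / 79, 8 / 79, 54 / 79)
    n_descriptors: int = 200
    n_informative: int = 20
    effect_size: float = 1.5
    block_size: int = 5
    block_rho: float = 0.97
    missing_rate: float = 0.05
    indicator_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_PARAMS)
    )
    n_products_mean: float = 4.0
    parent_mix: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must lie in [0, 1)")
        if not 0.0 <= self.parent_mix <= 1.0:
            raise ValueError("parent_mix must lie in [0, 1]")
        if self.n_informative * self.block_size > self.n_descriptors:
            raise ValueError(
                "n_informative * block_size exceeds n_descriptors: "
                f"{self.n_informative} * {self.block_size} > {self.n_descriptors}"
            )
        for name, (a, b) in self.indicator_params.items():
            if name in PROBABILITY_INDICATORS and (a <= 0 or b <= 0):
                raise ValueError(f"nonpositive Beta parameters for {name!r}")
            if name not in PROBABILITY_INDICATORS and b <= 0:
                raise ValueError(f"nonpositive log-sd for {name!r}")


_CLASS_LABELS = ("banned", "restricted", "unrestricted")


def _class_counts(cfg: SyntheticConfig) -> list[int]:
    """Largest-remainder apportionment of n_molecules to the three classes."""
    raw = [p * cfg.n_molecules for p in cfg.class_proportions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = cfg.n_molecules - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def generate_descriptors(
    cfg: SyntheticConfig,
) -> tuple[DescriptorMatrix, pd.Series]:
    """Generate a descriptor matrix with planted class signal and redundancy.

    The first ``n_informative * block_size`` columns form ``n_informative``
    redundant blocks: an informative anchor whose class-conditional means
    are separated by ``effect_size`` (in within-class SD units between
    adjacent classes), plus ``block_size - 1`` noisy copies correlated with
    the anchor at about ``block_rho``.  Remaining columns are pure noise.
    ``missing_rate`` of all columns then receive a few missing cells.

    Returns the matrix and a y1-style label Series indexed by molecule.
    """
    rng = np.random.default_rng(cfg.seed)
    n, p = cfg.n_molecules, cfg.n_descriptors
    counts = _class_counts(cfg)
    codes = np.repeat(np.arange(3), counts)
    rng.shuffle(codes)
    names = [f"MOL{i + 1:03d}" for i in range(n)]
    labels = pd.Series(
        [_CLASS_LABELS[c] for c in codes], index=pd.Index(names, name="name"),
        name="y1",
    )

    X = np.empty((n, p))
    # class offsets on the anchors: adjacent classes effect_size apart
    centered = np.array([-1.0, 0.0, 1.0])
    col = 0
    for j in range(cfg.n_informative):
        # deterministic alternating signs keep the class-conditional
        # distribution identical across seeds (seeds vary the sample only)
        sign = 1.0 if j % 2 == 0 else -1.0
        mu = cfg.effect_size * sign * centered[codes]
        anchor = rng.standard_normal(n)
        X[:, col] = anchor + mu
        for _ in range(cfg.block_size - 1):
            col += 1
            noise = rng.standard_normal(n)
            X[:, col] = (
                cfg.block_rho * anchor
                + np.sqrt(1.0 - cfg.block_rho**2) * noise
                + mu
            )
        col += 1
    X[:, col:] = rng.standard_normal((n, p - col))

    frame = pd.DataFrame(
        X,
        index=pd.Index(names, name="name"),
        columns=[f"D{j + 1:04d}" for j in range(p)],
    )

    n_missing_cols = int(round(cfg.missing_rate * p))
    if n_missing_cols:
        cols = rng.choice(p, size=n_missing_cols, replace=False)
        for c in cols:
            k = int(rng.integers(1, 4))
            rows = rng.choice(n, size=k, replace=False)
            frame.iloc[rows, c] = np.nan
    return DescriptorMatrix(frame), labels


def _draw_indicator(
    rng: np.random.Generator, name: str, params: tuple[float, float], size: int
) -> np.ndarray:
    a, b = params
    if name in PROBABILITY_INDICATORS:
        return rng.beta(a, b, size=size)
    return np.exp(rng.normal(a, b, size=size))


def _draw_shifted(
    rng: np.random.Generator, name: str, params: tuple[float, float], size: int
) -> np.ndarray:
    """Draw from the most-toxic decile of an indicator's distribution."""
    a, b = params
    u = rng.uniform(0.9, 1.0, size=size)
    if name in PROBABILITY_INDICATORS:
        return stats.beta.ppf(u, a, b)
    if name in COST_INDICATORS:  # lower concentration = more toxic
        return np.exp(stats.norm.ppf(1.0 - u, a, b))
    return np.exp(stats.norm.ppf(u, a, b))


def generate_toxicity(
    cfg: SyntheticConfig,
    names: Sequence[str],
    shifted: Sequence[str] = (),
) -> ToxicityMatrix:
    """Generate a 24-indicator toxicity matrix for the given entities.

    Entities listed in ``shifted`` are drawn from the most-toxic decile of
    every indicator's distribution (upper tail for benefit-oriented
    indicators, lower tail for the cost-oriented concentrations) — a
    planted high-risk profile used to check end-to-end recovery.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 7)))
    unknown = set(shifted) - set(names)
    if unknown:
        raise ValueError(f"shifted entities not in names: {sorted(unknown)}")
    n = len(names)
    cols = {}
    for name in INDICATOR_NAMES:
        params = cfg.indicator_params[name]
        cols[name] = _draw_indicator(rng, name, params, n)
    frame = pd.DataFrame(cols, index=pd.Index(names, name="name"))
    if shifted:
        mask = frame.index.isin(shifted)
        for name in INDICATOR_NAMES:
            params = cfg.indicator_params[name]
            frame.loc[mask, name] = _draw_shifted(
                rng, name, params, int(mask.sum())
            )
    return ToxicityMatrix(frame)


def generate_products(
    cfg: SyntheticConfig, parents: ToxicityMatrix
) -> tuple[TransformationMap, ToxicityMatrix]:
    """Generate transformation products with parent-correlated toxicity.

    Each parent receives ``k ~ min(Poisson(n_products_mean), 8)`` products;
    a product's indicator vector is ``parent_mix * parent +
    (1 - parent_mix) * fresh`` where ``fresh`` is an independent draw from
    the indicator distributions, clipped to valid ranges.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 13)))
    lam = cfg.parent_mix
    mapping: dict[str, list[str]] = {}
    rows: list[np.ndarray] = []
    row_names: list[str] = []
    indicator_names = parents.indicator_names
    for parent in parents.entity_names:
        k = int(min(rng.poisson(cfg.n_products_mean), 8))
        prods = []
        pvec = parents.frame.loc[parent].to_numpy()
        for i in range(k):
            fresh = np.array(
                [
                    _draw_indicator(rng, nm, cfg.indicator_params[nm], 1)[0]
                    for nm in indicator_names
                ]
            )
            mix = lam * pvec + (1.0 - lam) * fresh
            for j, nm in enumerate(indicator_names):
                if nm in PROBABILITY_INDICATORS:
                    mix[j] = float(np.clip(mix[j], 0.0, 1.0))
                else:
                    mix[j] = max(mix[j], 0.0)
            name = f"{parent}::TP{i + 1}"
            prods.append(name)
            rows.append(mix)
            row_names.append(name)
        mapping[parent] = prods
    frame = pd.DataFrame(
        rows if rows else np.empty((0, len(indicator_names))),
        index=pd.Index(row_names, name="name"),
        columns=indicator_names,
    )
    return TransformationMap(mapping), ToxicityMatrix(frame, dict(parents.orientation))


def with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Convenience: a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
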