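"""Core domain types and CSV readers/writers.

The pipeline moves four kinds of tables around:

* a descriptor matrix (molecules x numeric molecular descriptors, missing
  values permitted) — the classification feature space;
* regulatory label tables for the three label sets (``y1`` China
  banned/restricted/unrestricted, ``y2`` EPA yes/no, ``y3`` EU
  yes/no/not-listed);
* a toxicity matrix (entities x 24 named indicators: 20 probability-type
  endpoints in [0, 1] plus four continuous eco-endpoints) with a
  per-indicator orientation saying whether a *larger* raw value means more
  toxicity (benefit-type) or less (cost-type, for the three median-effect
  concentrations);
* a parent -> transformation-product map.

All tables are UTF-8, comma-delimited CSV with "." decimals.  Missing cells
may be written as empty strings or as ``NA``; both are canonicalized to NaN
on read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegulatoryStatus",
    "EpaStatus",
    "EuStatus",
    "AttentionLevel",
    "MoleculeRecord",
    "DescriptorMatrix",
    "ToxicityMatrix",
    "TransformationMap",
    "WatchList",
    "INDICATOR_NAMES",
    "COST_INDICATORS",
    "DEFAULT_ORIENTATION",
    "read_descriptor_table",
    "write_descriptor_table",
    "read_toxicity_table",
    "write_toxicity_table",
    "read_label_table",
    "write_watchlist",
    "read_watchlist",
]

#: Missing-value spellings accepted in input CSVs (PaDEL-style exports use
#: both empty cells and "NA").
_NA_STRINGS = frozenset({"", "NA", "NaN", "nan"})

#: The 24 toxicity indicators, in roster order: 20 probability-type
#: endpoints followed by the four continuous eco-endpoints.
INDICATOR_NAMES: tuple[str, ...] = (
    "hERG blockers",
    "hERG blockers (10 um)",
    "DILI",
    "AMES toxicity",
    "rat oral acute toxicity",
    "FDAMDD",
    "skin sensitization",
    "carcinogenicity",
    "eye corrosion",
    "eye irritation",
    "respiratory toxicity",
    "human hepatotoxicity",
    "drug-induced nephrotoxicity",
    "drug-induced neurotoxicity",
    "ototoxicity",
    "nematotoxicity",
    "genotoxicity",
    "RPMI-8226 immunotoxicity",
    "A549 cytotoxicity",
    "Hek293 cytotoxicity",
    "BCF",
    "IGC50",
    "LC50DM",
    "LC50FM",
)

#: Indicators where a *smaller* raw value means more toxicity (median
#: growth-inhibition / lethal concentrations).  BCF is benefit-oriented:
#: higher bioconcentration means more toxicity.
COST_INDICATORS: frozenset[str] = frozenset({"IGC50", "LC50DM", "LC50FM"})

DEFAULT_ORIENTATION: dict[str, str] = {
    name: ("cost" if name in COST_INDICATORS else "benefit")
    for name in INDICATOR_NAMES
}

#: Names of the probability-type indicators (values constrained to [0, 1]).
PROBABILITY_INDICATORS: tuple[str, ...] = INDICATOR_NAMES[:20]


class RegulatoryStatus(str, enum.Enum):
    """China management status (label set y1)."""

    BANNED = "banned"
    RESTRICTED = "restricted"
    UNRESTRICTED = "unrestricted"


class EpaStatus(str, enum.Enum):
    """EPA registration status (label set y2)."""

    YES = "yes"
    NO = "no"


class EuStatus(str, enum.Enum):
    """EU registration status (label set y3)."""

    YES = "yes"
    NO = "no"
    NOT_LISTED = "not_listed"


class AttentionLevel(str, enum.Enum):
    """Watch-list attention level, highest toxicity first."""

    SPECIAL = "special"
    FOCUS = "focus"
    GENERAL = "general"
    SECONDARY = "secondary"

    @property
    def printed(self) -> str:
        return _PRINTED_LEVEL[self]

    #: priority rank for monotonicity checks (0 = highest attention)
    @property
    def priority(self) -> int:
        return _LEVEL_PRIORITY[self]


_PRINTED_LEVEL = {
    AttentionLevel.SPECIAL: "Special Focus",
    AttentionLevel.FOCUS: "Focus",
    AttentionLevel.GENERAL: "General Focus",
    AttentionLevel.SECONDARY: "Secondary Focus",
}
_LEVEL_PRIORITY = {
    AttentionLevel.SPECIAL: 0,
    AttentionLevel.FOCUS: 1,
    AttentionLevel.GENERAL: 2,
    AttentionLevel.SECONDARY: 3,
}

PRINTED_TO_LEVEL = {v: k for k, v in _PRINTED_LEVEL.items()}


@dataclass(frozen=True)
class MoleculeRecord:
    """A named compound with optional SMILES and up-to-three labels."""

    name: str
    smiles: str | None = None
    y1: RegulatoryStatus | None = None
    y2: EpaStatus | None = None
    y3: EuStatus | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("molecule name must be nonempty")


def _check_unique(names: Iterable[str], axis: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ValueError(f"duplicate {axis} name: {n!r}")
        seen.add(n)


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors numeric table; NaN marks missing cells."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "molecule")
        _check_unique(self.frame.columns, "descriptor")
        self.frame = self.frame.astype(float)

    @property
    def molecule_names(self) -> list[str]:
        return list(self.frame.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_missing(self) -> int:
        return int(self.frame.isna().sum().sum())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        r, c = self.frame.shape
        return f"DescriptorMatrix({r} molecules x {c} descriptors, {self.n_missing} missing)"


@dataclass
class ToxicityMatrix:
    """Entities x toxicity indicators with a per-indicator orientation.

    ``orientation[j]`` is ``"benefit"`` when a larger raw value of indicator
    *j* means more toxicity and ``"cost"`` when a smaller value does.
    """

    frame: pd.DataFrame
    orientation: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "entity")
        _check_unique(self.frame.columns, "indicator")
        self.frame = self.frame.astype(float)
        orientation = dict(self.orientation) if self.orientation else {}
        for col in self.frame.columns:
            orientation.setdefault(col, DEFAULT_ORIENTATION.get(col, "benefit"))
        bad = {k: v for k, v in orientation.items() if v not in ("benefit", "cost")}
        if bad:
            raise ValueError(f"invalid orientation values: {bad}")
        self.orientation = orientation
        # probability-type indicators must live in [0, 1]
        for col in self.frame.columns:
            if col in PROBABILITY_INDICATORS:
                vals = self.frame[col].dropna()
                if ((vals < 0) | (vals > 1)).any():
                    raise ValueError(
                        f"probability indicator {col!r} has values outside [0, 1]"
                    )

    @property
    def entity_names(self) -> list[str]:
        return list(self.frame.index)

    @property
    def indicator_names(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class TransformationMap:
    """Parent name -> ordered list of transformation-product names."""

    products: dict[str, list[str]]

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for parent, prods in self.products.items():
            for p in prods:
                if p in owner:
                    raise ValueError(
                        f"product {p!r} assigned to both {owner[p]!r} and {parent!r}"
                    )
                owner[p] = parent

    def __getitem__(self, parent: str) -> list[str]:
        return self.products[parent]

    def __iter__(self):
        return iter(self.products)

    def items(self):
        return self.products.items()

    @property
    def all_products(self) -> list[str]:
        return [p for prods in self.products.values() for p in prods]


@dataclass
class WatchList:
    """Per-molecule composite toxicity, deviation from the mean, and level.

    ``frame`` has columns ``composite_toxicity``, ``deviation`` and
    ``level`` (an :class:`AttentionLevel`), indexed by molecule name and
    sorted by composite toxicity descending (ties by name ascending).
    ``delta`` is the population standard deviation of the score vector and
    ``mean`` its arithmetic mean.
    """

    frame: pd.DataFrame
    mean: float
    delta: float

    def level_counts(self) -> dict[AttentionLevel, int]:
        counts = {lvl: 0 for lvl in AttentionLevel}
        for lvl in self.frame["level"]:
            counts[lvl] += 1
        return counts

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path: str | Path, index_label: str) -> pd.DataFrame:
    """Read a name-indexed numeric CSV, reporting bad cells by coordinate."""
    # check the raw header first: pandas silently renames duplicates
    import csv as _csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(_csv.reader(fh), [])
    _check_unique(header[1:], "column")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 1:
        raise ValueError(f"{path}: no columns found")
    name_col = raw.columns[0]
    _check_unique(raw[name_col], index_label)
    _check_unique(raw.columns[1:], "column")
    data = {}
    for col in raw.columns[1:]:
        cleaned = raw[col].str.strip().where(~raw[col].str.strip().isin(_NA_STRINGS))
        numeric = pd.to_numeric(cleaned, errors="coerce")
        bad = cleaned.notna() & numeric.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {raw[col].iloc[i]!r} in column "
                f"{col!r}, row {raw[name_col].iloc[i]!r}"
            )
        data[col] = numeric
    out = pd.DataFrame(data)
    out.index = pd.Index(raw[name_col].astype(str), name=name_col)
    return out


def read_descriptor_table(path: str | Path) -> DescriptorMatrix:
    """Read a molecules x descriptors CSV (first column = molecule name).

    Empty cells and ``NA`` are canonicalized to missing (NaN), never to
    zero.  Column order is preserved.  Duplicate molecule or descriptor
    names and non-numeric cells raise ``ValueError`` with coordinates.
    """
    return DescriptorMatrix(_read_numeric_table(path, "molecule"))


def write_descriptor_table(path: str | Path, X: DescriptorMatrix) -> None:
    """Write a descriptor matrix; missing cells become empty strings."""
    X.frame.to_csv(path, index_label="name", na_rep="")


def read_toxicity_table(
    path: str | Path, orientation: Mapping[str, str] | None = None
) -> ToxicityMatrix:
    """Read an entities x indicators CSV; orientation defaults to the roster."""
    frame = _read_numeric_table(path, "entity")
    return ToxicityMatrix(frame, orientation or {})


def write_toxicity_table(path: str | Path, T: ToxicityMatrix) -> None:
    T.frame.to_csv(path, index_label="name", na_rep="")


def read_label_table(path: str | Path, column: str | None = None) -> pd.Series:
    """Read a two-column (name, label) CSV into a name-indexed Series."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    name_col = raw.columns[0]
    label_col = column or raw.columns[1]
    _check_unique(raw[name_col], "molecule")
    return pd.Series(
        raw[label_col].to_numpy(), index=pd.Index(raw[name_col], name=name_col),
        name=label_col,
    )


def write_watchlist(path: str | Path, wl: WatchList) -> None:
    """Write a watch list as CSV: name, composite_toxicity, deviation, level.

    Rows are sorted by composite toxicity descending, ties broken by name
    ascending (the frame is kept in that order by construction).
    """
    out = wl.frame.copy()
    out["level"] = [lvl.value for lvl in out["level"]]
    out.to_csv(path, index_label="name")


def read_watchlist(path: str | Path) -> WatchList:
    """Read back a watch list written by :func:`write_watchlist`."""
    frame = pd.read_csv(path, index_col=0)
    frame["level"] = [AttentionLevel(v) for v in frame["level"]]
    scores = frame["composite_toxicity"].to_numpy(dtype=float)
    if len(scores) == 0:
        return WatchList(frame, mean=float("nan"), delta=float("nan"))
    return WatchList(frame, mean=float(scores.mean()), delta=float(scores.std()))
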