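"""Packaged reference tables for the published pesticide analysis.

Four small CSVs ship with the package so every downstream stage can be
exercised without any downloads:

* ``china_management_list.csv`` — the 79 organophosphorus pesticides on
  China's management list (17 banned, 8 restricted, 54 unrestricted);
* ``importance_ranking.csv`` — the 78 retained molecular descriptors with
  their random-forest importance share and min-max relative importance;
* ``application_predictions.csv`` — predicted China-status labels for 170
  EU-unregistered molecules;
* ``composite_toxicity.csv`` — the 54 unrestricted molecules with their
  composite (parent + transformation product) toxicity score and printed
  attention level.

The tables are data, reproduced verbatim, including their oddities: the
management list contains "Phosphoric acid" among the banned entries and
lists "Mecarbam" twice in the unrestricted block.  The loader keeps those
rows as printed rather than repairing them; consumers that need unique
names must deduplicate explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from ..data import MoleculeRecord, RegulatoryStatus

__all__ = ["PaperFixtures", "FixtureError", "load_paper_fixtures"]

_STATUS = {
    "Banned": RegulatoryStatus.BANNED,
    "Restricted": RegulatoryStatus.RESTRICTED,
    "Unrestricted": RegulatoryStatus.UNRESTRICTED,
}

_EXPECTED = {
    "china_rows": 79,
    "china_counts": {"banned": 17, "restricted": 8, "unrestricted": 54},
    "importance_rows": 78,
    "application_rows": 170,
    "composite_rows": 54,
}


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its shape/content checks."""


@dataclass
class PaperFixtures:
    """The four reference tables, validated on load."""

    china_list: list[MoleculeRecord]
    importance_table: pd.DataFrame
    application_predictions: pd.DataFrame
    composite_toxicity: pd.DataFrame

    def china_counts(self) -> dict[str, int]:
        counts = {s.value: 0 for s in RegulatoryStatus}
        for rec in self.china_list:
            counts[rec.y1.value] += 1
        return counts


def _fixture_path(name: str):
    return resources.files("opswatch.fixtures").joinpath(name)


def _read(name: str, **kwargs) -> pd.DataFrame:
    path = _fixture_path(name)
    try:
        with resources.as_file(path) as p:
            return pd.read_csv(p, **kwargs)
    except FileNotFoundError as exc:  # pragma: no cover - packaging defect
        raise FixtureError(f"missing packaged fixture {name!r}") from exc


def load_paper_fixtures() -> PaperFixtures:
    """Load and validate the packaged reference tables.

    Raises
    ------
    FixtureError
        If any table's row counts or value ranges do not match the
        published figures (fixtures are bit-exact data, not code).
    """
    china = _read("china_management_list.csv", dtype=str)
    if len(china) != _EXPECTED["china_rows"]:
        raise FixtureError(f"management list has {len(china)} rows, expected 79")
    records = [
        MoleculeRecord(name=row["name"], y1=_STATUS[row["level"]])
        for _, row in china.iterrows()
    ]
    counts = {s.value: 0 for s in RegulatoryStatus}
    for rec in records:
        counts[rec.y1.value] += 1
    if counts != _EXPECTED["china_counts"]:
        raise FixtureError(f"management-list class counts {counts} mismatch")

    imp = _read("importance_ranking.csv")
    if len(imp) != _EXPECTED["importance_rows"]:
        raise FixtureError(f"importance table has {len(imp)} rows, expected 78")
    if imp["descriptor"].duplicated().any():
        raise FixtureError("duplicate descriptor in importance table")
    if (imp["importance"] < 0).any():
        raise FixtureError("negative importance in fixture")

    app = _read("application_predictions.csv", dtype=str)
    if len(app) != _EXPECTED["application_rows"]:
        raise FixtureError(f"application table has {len(app)} rows, expected 170")
    if not set(app["prediction"]) <= set(_STATUS):
        raise FixtureError("unknown prediction label in application table")
    app = app.assign(y1=[_STATUS[p] for p in app["prediction"]])

    comp = _read("composite_toxicity.csv")
    if len(comp) != _EXPECTED["composite_rows"]:
        raise FixtureError(f"composite table has {len(comp)} rows, expected 54")
    scores = comp["composite_toxicity"]
    if not ((scores > 0) & (scores < 1)).all():
        raise FixtureError("composite toxicity scores must lie in (0, 1)")

    return PaperFixtures(
        china_list=records,
        importance_table=imp,
        application_predictions=app,
        composite_toxicity=comp.set_index("name"),
    )
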