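"""Containers and I/O for factorial biochar-trial indicator tables.

The experiment behind this package is a two-year field trial crossing
biochar pyrolysis temperature (300/500/700 °C) with application rate
(10/20/30 t ha⁻¹) plus an untreated control (CK).  Each year yields a
treatment × indicator matrix of measured or derived values; downstream
weighting and fuzzy evaluation consume exactly that matrix.

Indicator ids follow the evaluation hierarchy's leaf codes:

========  ===============================  ===========  =================
id        name                             orientation  units
========  ===============================  ===========  =================
Z11       tuber yield                      positive     t ha-1
Z12       net income                       positive     CNY ha-1
Z21       starch content                   positive     %
Z22       vitamin C content                positive     mg/(100 g FW)
Z23       reducing sugar content           negative     %
Z31       water use efficiency (WUE)       positive     kg m-3
Z32       partial factor productivity      positive     kg kg-1
Z41       soil nitrate-N residue           negative     kg ha-1
Z42       soil available P residue         negative     kg ha-1
Z43       soil available K residue         negative     kg ha-1
========  ===============================  ===========  =================

Soil-residue indicators Z41–Z43 are figure-only in the source trial and
therefore absent from the packaged fixtures; the evaluator accepts any
subset of indicators and renormalizes weights over it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import DataError, StructureError

__all__ = [
    "TreatmentDesign",
    "IndicatorMeta",
    "TrialTable",
    "PAPER_INDICATORS",
    "factorial_design",
    "read_trial_table",
    "write_trial_table",
    "average_years",
    "load_fixture_frame",
    "load_fixture_table",
    "FIXTURE_YEARS",
]

FIXTURE_YEARS = ("2023", "2024")


@dataclass(frozen=True)
class TreatmentDesign:
    """One treatment: a (pyrolysis temperature, application rate) pair.

    The control carries ``pyrolysis_temperature=None`` and rate 0 — it has
    no biochar, hence no meaningful temperature coordinate.
    """

    treatment_id: str
    pyrolysis_temperature: float | None  # °C; None for the control
    application_rate: float  # t ha-1; 0 for the control

    def __post_init__(self) -> None:
        if self.application_rate < 0:
            raise DataError(
                f"treatment {self.treatment_id!r}: application_rate must be >= 0"
            )
        has_temp = self.pyrolysis_temperature is not None
        if has_temp != (self.application_rate > 0):
            raise DataError(
                f"treatment {self.treatment_id!r}: pyrolysis temperature must be "
                "present exactly when the application rate is positive"
            )

    @property
    def is_control(self) -> bool:
        return self.application_rate == 0


@dataclass(frozen=True)
class IndicatorMeta:
    indicator_id: str
    name: str
    orientation: str  # "positive" (larger better) or "negative" (smaller better)
    units: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("positive", "negative"):
            raise DataError(
                f"indicator {self.indicator_id!r}: orientation must be "
                f"'positive' or 'negative', got {self.orientation!r}"
            )


PAPER_INDICATORS: dict[str, IndicatorMeta] = {
    m.indicator_id: m
    for m in (
        IndicatorMeta("Z11", "tuber yield", "positive", "t ha-1"),
        IndicatorMeta("Z12", "net income", "positive", "CNY ha-1"),
        IndicatorMeta("Z21", "starch content", "positive", "%"),
        IndicatorMeta("Z22", "vitamin C content", "positive", "mg/(100 g FW)"),
        IndicatorMeta("Z23", "reducing sugar content", "negative", "%"),
        IndicatorMeta("Z31", "water use efficiency", "positive", "kg m-3"),
        IndicatorMeta("Z32", "partial factor productivity", "positive", "kg kg-1"),
        IndicatorMeta("Z41", "soil nitrate-N residue", "negative", "kg ha-1"),
        IndicatorMeta("Z42", "soil available P residue", "negative", "kg ha-1"),
        IndicatorMeta("Z43", "soil available K residue", "negative", "kg ha-1"),
    )
}


def factorial_design(
    temperature_levels: Iterable[float] = (300.0, 500.0, 700.0),
    rate_levels: Iterable[float] = (10.0, 20.0, 30.0),
    include_control: bool = True,
) -> dict[str, TreatmentDesign]:
    """The trial's 3×3 factorial (+ optional control) treatment design.

    Ids are ``T{i}C{j}`` with i indexing temperature and j indexing rate,
    e.g. ``T2C2`` = 500 °C × 20 t ha⁻¹; the control is ``CK``.
    """
    design: dict[str, TreatmentDesign] = {}
    if include_control:
        design["CK"] = TreatmentDesign("CK", None, 0.0)
    for i, temp in enumerate(temperature_levels, start=1):
        for j, rate in enumerate(rate_levels, start=1):
            tid = f"T{i}C{j}"
            design[tid] = TreatmentDesign(tid, float(temp), float(rate))
    return design


@dataclass
class TrialTable:
    """A validated treatment × indicator value matrix for one year (or an
    average of years)."""

    year: str
    values: pd.DataFrame  # index: treatment ids, columns: indicator ids
    design: dict[str, TreatmentDesign]
    meta: dict[str, IndicatorMeta]

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise DataError(f"duplicate treatment rows: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise DataError(f"duplicate indicator columns: {dups}")
        unknown = [c for c in df.columns if c not in self.meta]
        if unknown:
            raise DataError(f"unknown indicator columns: {unknown}")
        missing_design = [t for t in df.index if t not in self.design]
        if missing_design:
            raise DataError(f"treatments missing from design: {missing_design}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            r, c = np.argwhere(~np.isfinite(arr))[0]
            raise DataError(
                f"non-finite or missing cell at treatment {df.index[r]!r}, "
                f"indicator {df.columns[c]!r}"
            )
        self.values = df.astype(float)

    @property
    def treatments(self) -> list[str]:
        return list(self.values.index)

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    def orientation(self, indicator_id: str) -> str:
        return self.meta[indicator_id].orientation

    def column(self, indicator_id: str) -> pd.Series:
        return self.values[indicator_id]


def read_trial_table(
    path: str | Path | io.TextIOBase,
    meta: Mapping[str, IndicatorMeta],
    design: Mapping[str, TreatmentDesign] | None = None,
    year: str = "",
) -> TrialTable:
    """Read a treatment × indicator CSV (header = indicator ids, first
    column = treatment id) into a validated :class:`TrialTable`.

    If ``design`` is omitted, treatment coordinates are inferred from the
    standard ``CK`` / ``T{i}C{j}`` id convention.
    """
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty trial-table file: {path!r}") from exc
    if df.shape[1] == 0:
        raise DataError(f"trial-table file {path!r} has no indicator columns")
    for col in df.columns:
        if col not in meta:
            raise DataError(f"unknown indicator column {col!r} in {path!r}")
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise DataError(
                f"cell at treatment {bad[0]!r}, indicator {col!r} in {path!r} "
                "is missing or not numeric"
            )
        df[col] = parsed
    if design is None:
        design = _design_from_ids(df.index)
    return TrialTable(year=year, values=df, design=dict(design), meta=dict(meta))


def _design_from_ids(ids: Iterable[str]) -> dict[str, TreatmentDesign]:
    temp_levels = {1: 300.0, 2: 500.0, 3: 700.0}
    rate_levels = {1: 10.0, 2: 20.0, 3: 30.0}
    design: dict[str, TreatmentDesign] = {}
    for tid in ids:
        if tid == "CK":
            design[tid] = TreatmentDesign(tid, None, 0.0)
            continue
        try:
            t_idx, c_idx = int(tid[1]), int(tid[3])
            design[tid] = TreatmentDesign(tid, temp_levels[t_idx], rate_levels[c_idx])
        except (IndexError, ValueError, KeyError) as exc:
            raise DataError(
                f"cannot infer design coordinates from treatment id {tid!r}; "
                "supply an explicit design"
            ) from exc
    return design


def write_trial_table(table: TrialTable, path: str | Path) -> None:
    """Write a table to CSV with full float precision so that
    read → write → read round-trips exactly."""
    df = table.values.copy()
    df.index.name = "treatment"
    # pandas' default float formatting emits the shortest repr, which
    # round-trips float64 exactly
    df.to_csv(path)


def average_years(tables: list[TrialTable]) -> TrialTable:
    """Cell-wise arithmetic mean across years sharing one design and
    indicator set; the result's year label joins the inputs with '+'."""
    if not tables:
        raise StructureError("average_years requires at least one table")
    first = tables[0]
    for t in tables[1:]:
        if list(t.values.index) != list(first.values.index) or list(
            t.values.columns
        ) != list(first.values.columns):
            raise StructureError(
                "cannot average tables with mismatched treatments/indicators"
            )
        if t.meta != first.meta:
            raise StructureError("cannot average tables with mismatched metadata")
    stacked = sum(t.values.to_numpy(dtype=float) for t in tables) / len(tables)
    values = pd.DataFrame(stacked, index=first.values.index, columns=first.values.columns)
    return TrialTable(
        year="+".join(t.year for t in tables),
        values=values,
        design=dict(first.design),
        meta=dict(first.meta),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures (transcribed treatment-mean tables of the source trial).
# Significance-letter columns ('*_sig') are annotations and never parsed
# as data.
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "economics": "economics.csv",
    "growth": "growth.csv",
    "quality": "quality.csv",
    "efficiency": "efficiency.csv",
}

_FIXTURE_COLUMN_MAP = {
    # fixture name -> {csv column: indicator id}
    "growth": {"yield": "Z11"},
    "economics": {"net_income": "Z12"},
    "quality": {"starch": "Z21", "vitamin_c": "Z22", "reducing_sugar": "Z23"},
    "efficiency": {"wue": "Z31", "pfp": "Z32"},
}


def load_fixture_frame(name: str) -> pd.DataFrame:
    """Load one transcribed fixture ('economics', 'growth', 'quality',
    'efficiency') as a raw DataFrame including annotation columns."""
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError as exc:
        raise DataError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}"
        ) from exc
    ref = resources.files("pfce.data").joinpath(fname)
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"year": str})


def load_fixture_table(year: str) -> TrialTable:
    """Assemble the seven tabled evaluation indicators (Z11, Z12, Z21–Z23,
    Z31, Z32) for one trial year into a :class:`TrialTable`.

    Soil-residue indicators Z41–Z43 are unavailable in tabular form and are
    intentionally absent; weights are renormalized downstream.
    """
    year = str(year)
    if year not in FIXTURE_YEARS:
        raise DataError(f"fixture year must be one of {FIXTURE_YEARS}, got {year!r}")
    pieces = {}
    for name, colmap in _FIXTURE_COLUMN_MAP.items():
        df = load_fixture_frame(name)
        df = df[df["year"] == year].set_index("treatment")
        for src, zid in colmap.items():
            pieces[zid] = df[src].astype(float)
    values = pd.DataFrame(pieces)[sorted(pieces)]
    return TrialTable(
        year=year,
        values=values,
        design=factorial_design(),
        meta={k: PAPER_INDICATORS[k] for k in values.columns},
    )
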