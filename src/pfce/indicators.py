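"""Derived agronomic indicators and percent-contrast comparisons.

Implements the trial's bookkeeping quantities: leaf area index, crop
evapotranspiration from a simplified water balance, water use efficiency
(WUE, kg m⁻³), total fertilizer input and partial factor productivity
(PFP, kg kg⁻¹), net income, soil nutrient accumulation per profile layer,
and the percent-contrast ranges used to compare the best treatment with
all others.

Unit conventions: yield in kg ha⁻¹ where WUE/PFP are computed, water terms
in mm, fertilizer in kg ha⁻¹, money in CNY ha⁻¹.  WUE = Y / (10·ET) so
that kg ha⁻¹ over mm lands on kg m⁻³.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .exceptions import DataError
from .trial_data import TrialTable

__all__ = [
    "FertilizerSchedule",
    "RainfallPolicy",
    "WaterBalance",
    "EconomicInputs",
    "PAPER_FERTILIZER",
    "leaf_area_index",
    "effective_rainfall",
    "crop_et",
    "water_use_efficiency",
    "fertilizer_total",
    "partial_factor_productivity",
    "net_income",
    "nutrient_accumulation",
    "contrast_range",
]


@dataclass(frozen=True)
class FertilizerSchedule:
    """Fertilizer products applied to every plot, as (rate, nutrient mass
    fraction) pairs: urea (N), calcium superphosphate (P2O5), potassium
    sulfate (K2O)."""

    urea_rate: float  # kg ha-1
    urea_n_frac: float
    superphosphate_rate: float  # kg ha-1
    p2o5_frac: float
    potassium_sulfate_rate: float  # kg ha-1
    k2o_frac: float

    def __post_init__(self) -> None:
        for label, rate in (
            ("urea_rate", self.urea_rate),
            ("superphosphate_rate", self.superphosphate_rate),
            ("potassium_sulfate_rate", self.potassium_sulfate_rate),
        ):
            if rate < 0:
                raise DataError(f"{label} must be >= 0")
        for label, frac in (
            ("urea_n_frac", self.urea_n_frac),
            ("p2o5_frac", self.p2o5_frac),
            ("k2o_frac", self.k2o_frac),
        ):
            if not 0 < frac <= 1:
                raise DataError(f"{label} must lie in (0, 1]")


#: The trial's uniform schedule: urea 652.2 kg ha-1 at 46% N, calcium
#: superphosphate 391.3 kg ha-1 at 46% P2O5, potassium sulfate 666.6 kg ha-1
#: at 45% K2O  ->  FT = 780.0 kg ha-1.
PAPER_FERTILIZER = FertilizerSchedule(652.2, 0.46, 391.3, 0.46, 666.6, 0.45)


@dataclass(frozen=True)
class RainfallPolicy:
    """Effective-rainfall coefficients by event-size band.

    Events under 5 mm contribute nothing; for 5–50 mm the coefficient must
    lie in [0.8, 1.0]; above 50 mm in [0.70, 0.80].  The literature gives
    bands, not point values, so the coefficient within each band is an
    explicit configuration choice.
    """

    mid_coefficient: float = 0.9  # for 5 mm <= P <= 50 mm
    high_coefficient: float = 0.75  # for P > 50 mm

    def __post_init__(self) -> None:
        if not 0.8 <= self.mid_coefficient <= 1.0:
            raise DataError(
                "mid_coefficient must lie in [0.8, 1.0] "
                f"(got {self.mid_coefficient})"
            )
        if not 0.70 <= self.high_coefficient <= 0.80:
            raise DataError(
                "high_coefficient must lie in [0.70, 0.80] "
                f"(got {self.high_coefficient})"
            )


@dataclass(frozen=True)
class WaterBalance:
    """Season water balance. Groundwater recharge and surface runoff are
    taken as negligible (deep water table, flat terrain), leaving
    ET = P0 + I − ΔW − D."""

    rainfall_events: tuple[float, ...]  # individual event depths, mm
    irrigation: float  # mm
    soil_moisture_change: float  # ΔW, mm (end minus start)
    deep_percolation: float = 0.0  # D, mm

    def __post_init__(self) -> None:
        if self.irrigation < 0:
            raise DataError("irrigation must be >= 0")
        if any(p < 0 for p in self.rainfall_events):
            raise DataError("rainfall events must be >= 0")


@dataclass(frozen=True)
class EconomicInputs:
    gross_income: float  # CNY ha-1
    water_fee: float
    fertilizer_input: float  # includes biochar cost
    other_input: float

    def __post_init__(self) -> None:
        for label, cost in (
            ("water_fee", self.water_fee),
            ("fertilizer_input", self.fertilizer_input),
            ("other_input", self.other_input),
        ):
            if cost < 0:
                raise DataError(f"{label} must be >= 0")


def leaf_area_index(total_leaf_area: float, ground_area: float) -> float:
    """LAI = total leaf area / occupied ground area (both m²)."""
    if ground_area <= 0:
        raise DataError("ground_area must be > 0")
    if total_leaf_area < 0:
        raise DataError("total_leaf_area must be >= 0")
    return total_leaf_area / ground_area


def effective_rainfall(p: float, policy: RainfallPolicy = RainfallPolicy()) -> float:
    """Effective depth a·P of a single rainfall event (band boundaries 5 and
    50 mm belong to the middle band)."""
    if p < 0:
        raise DataError("rainfall must be >= 0")
    if p < 5:
        return 0.0
    if p <= 50:
        return policy.mid_coefficient * p
    return policy.high_coefficient * p


def crop_et(balance: WaterBalance, policy: RainfallPolicy = RainfallPolicy()) -> float:
    """Seasonal crop evapotranspiration, mm: effective rainfall plus
    irrigation minus soil-moisture gain and deep percolation."""
    p0 = sum(effective_rainfall(p, policy) for p in balance.rainfall_events)
    et = p0 + balance.irrigation - balance.soil_moisture_change - balance.deep_percolation
    if et <= 0:
        raise DataError(
            f"computed ET = {et:.3f} mm is not positive; water balance inconsistent"
        )
    return et


def water_use_efficiency(yield_kg_ha: float, et_mm: float) -> float:
    """WUE = Y / (10·ET), kg m⁻³."""
    if et_mm <= 0:
        raise DataError("ET must be > 0")
    if yield_kg_ha < 0:
        raise DataError("yield must be >= 0")
    return yield_kg_ha / (10.0 * et_mm)


def fertilizer_total(schedule: FertilizerSchedule) -> float:
    """FT: total applied N + P2O5 + K2O, kg ha⁻¹."""
    return (
        schedule.urea_rate * schedule.urea_n_frac
        + schedule.superphosphate_rate * schedule.p2o5_frac
        + schedule.potassium_sulfate_rate * schedule.k2o_frac
    )


def partial_factor_productivity(yield_kg_ha: float, ft_kg_ha: float) -> float:
    """PFP = Y / FT, kg tuber per kg applied nutrient."""
    if ft_kg_ha <= 0:
        raise DataError("total fertilizer input must be > 0")
    return yield_kg_ha / ft_kg_ha


def net_income(econ: EconomicInputs) -> float:
    """Gross income minus water, fertilizer (incl. biochar) and other
    inputs; may be negative."""
    return (
        econ.gross_income - econ.water_fee - econ.fertilizer_input - econ.other_input
    )


def nutrient_accumulation(
    layers: Sequence[tuple[float, float, float]] | tuple[float, float, float]
) -> float:
    """Soil nutrient stock, kg ha⁻¹, from (content mg kg⁻¹, layer thickness
    cm, bulk density g cm⁻³) triples; profile totals sum over layers:
    C = Σ M·H·ρ/10."""
    if isinstance(layers, tuple) and layers and not isinstance(layers[0], tuple):
        layers = [layers]  # single layer convenience
    total = 0.0
    for m, h, bd in layers:
        if m < 0 or h < 0 or bd < 0:
            raise DataError("content, thickness and bulk density must be >= 0")
        total += m * h * bd / 10.0
    return total


def contrast_range(
    table: TrialTable,
    indicator: str,
    focal_treatment: str,
    direction: Literal["increase", "decrease"],
    comparators: Iterable[str] | None = None,
) -> tuple[float, float]:
    """(min %, max %) contrast of a focal treatment against comparators.

    For ``direction='increase'`` each contrast is 100·(focal/other − 1);
    for ``'decrease'`` it is 100·(1 − focal/other).  The focal treatment is
    excluded from the comparator set.  Intended for tables already averaged
    across years (ratios of year-means, not year-mean ratios).
    """
    col = table.column(indicator)
    if focal_treatment not in col.index:
        raise DataError(f"focal treatment {focal_treatment!r} not in table")
    if comparators is None:
        comparators = [t for t in col.index if t != focal_treatment]
    else:
        comparators = [t for t in comparators if t != focal_treatment]
    if not comparators:
        raise DataError("no comparator treatments")
    focal = float(col[focal_treatment])
    contrasts = []
    for t in comparators:
        other = float(col[t])
        if other <= 0:
            raise DataError(
                f"comparator {t!r} has non-positive value {other}; "
                "percent contrast undefined"
            )
        ratio = focal / other
        contrasts.append(100.0 * (ratio - 1.0) if direction == "increase" else 100.0 * (1.0 - ratio))
    return (min(contrasts), max(contrasts))
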