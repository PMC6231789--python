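"""Valuation of resource use: unit prices, friction-cost rules, perspectives.

Four cost categories are distinguished, following the societal perspective of
the Dutch costing guidance:

* intervention costs — platform share per account, optionally plus the
  participant's own time (opportunity costs);
* health-care costs — care contacts priced at standardized unit prices, and
  medication priced per day of use by indication category;
* patient-and-family costs — (special) home care and informal care, the
  latter valued by the proxy-good method at the wage of domestic help;
* productivity losses — absenteeism valued under the friction-cost approach
  (losses count only up to the friction period, 85 days by default) and
  presenteeism valued as lost efficiency x wage on affected days.

All prices are indexed to a reference year (2016 by default).  No discounting
is applied by default: a rate parameter exists for API completeness but the
short trial horizon does not call for it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .trial_data import (
    CARE_ITEMS,
    DRUG_ITEMS,
    VISIT_ITEMS,
    ParticipantRecord,
    ResourceUse,
)


class UnpricedItemError(KeyError):
    """A resource-use item has no entry in the unit-price table."""


@dataclass(frozen=True)
class UnitPrice:
    price_eur: float
    unit: str
    price_year: int


@dataclass
class UnitPriceTable:
    """Unit prices per resource item plus year-indexing factors.

    ``index_factors`` maps a price year to the multiplier that converts it to
    the reference year; missing years default to 1.0 (no indexing).
    """

    prices: dict[str, UnitPrice]
    index_factors: dict[int, float] = field(default_factory=dict)

    def indexed_price(self, item: str, ref_year: int = 2016) -> float:
        if item not in self.prices:
            raise UnpricedItemError(f"no unit price for item: {item}")
        p = self.prices[item]
        if p.price_eur < 0:
            raise ValueError(f"negative unit price for {item}")
        factor = 1.0 if p.price_year == ref_year else self.index_factors.get(
            p.price_year, 1.0
        )
        return p.price_eur * factor


def read_price_csv(path) -> UnitPriceTable:
    df = pd.read_csv(path)
    required = {"item", "unit", "price_eur", "price_year"}
    if not required.issubset(df.columns):
        raise ValueError(f"price table must have columns {sorted(required)}")
    prices = {
        str(r.item): UnitPrice(float(r.price_eur), str(r.unit), int(r.price_year))
        for r in df.itertuples()
    }
    return UnitPriceTable(prices=prices)


def default_price_table() -> UnitPriceTable:
    """The packaged price fixture (plausible Dutch-guideline-style defaults)."""
    with resources.as_file(
        resources.files("trialcea.data").joinpath("unit_prices.csv")
    ) as p:
        return read_price_csv(p)


@dataclass
class FrictionParams:
    """Friction-cost valuation parameters.

    The friction period (85 calendar days by default, per Dutch guidance) is
    converted to workdays via ``workdays_per_week`` and rounded down; absent
    days beyond the cap carry no cost.  ``daily_wage`` is a single average
    gross wage per workday.
    """

    friction_period_days: float = 85.0
    workdays_per_week: float = 5.0
    daily_wage: float = 230.0

    def __post_init__(self) -> None:
        if self.friction_period_days <= 0:
            raise ValueError("friction_period_days must be positive")

    @property
    def cap_workdays(self) -> int:
        return math.floor(self.friction_period_days * self.workdays_per_week / 7.0)


@dataclass
class CostBreakdown:
    """Per-participant, per-wave costs in the four categories (EUR)."""

    participant_id: str
    wave: int
    employment: str = "paid"
    intervention: float = 0.0
    healthcare: dict[str, float] = field(default_factory=dict)
    patient_family: dict[str, float] = field(default_factory=dict)
    productivity: dict[str, float] = field(default_factory=dict)

    @property
    def healthcare_subtotal(self) -> float:
        return float(sum(self.healthcare.values()))

    @property
    def patient_family_subtotal(self) -> float:
        return float(sum(self.patient_family.values()))

    @property
    def productivity_subtotal(self) -> float:
        return float(sum(self.productivity.values()))

    def total(self, perspective: str = "societal") -> float:
        if perspective == "societal":
            return (
                self.intervention
                + self.healthcare_subtotal
                + self.patient_family_subtotal
                + self.productivity_subtotal
            )
        if perspective == "healthcare":
            return self.intervention + self.healthcare_subtotal
        if perspective == "employer":
            return self.intervention + self.productivity_subtotal
        raise ValueError(f"unknown perspective: {perspective}")


def drug_costs(
    days: Mapping[str, float], price_per_day: Mapping[str, float]
) -> float:
    """Medication cost: days of use x average per-day price per category."""
    total = 0.0
    for cat, d in days.items():
        if d < 0:
            raise ValueError(f"negative drug days for {cat}")
        if cat not in price_per_day:
            raise UnpricedItemError(f"no per-day price for drug category: {cat}")
        total += d * price_per_day[cat]
    return total


def absenteeism_cost(days_absent: float, p: FrictionParams) -> float:
    """Friction-cost value of absent workdays: capped at the friction period."""
    if days_absent < 0:
        raise ValueError("days_absent must be non-negative")
    return min(days_absent, p.cap_workdays) * p.daily_wage


def presenteeism_cost(days: float, efficiency: float, daily_wage: float) -> float:
    """Value of reduced productivity: affected days x lost fraction x wage."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    if days < 0:
        raise ValueError("days must be non-negative")
    return days * (1.0 - efficiency) * daily_wage


def informal_care_cost(hours: float, domestic_help_wage: float) -> float:
    """Proxy-good valuation of informal-care hours."""
    if hours < 0:
        raise ValueError("hours must be non-negative")
    return hours * domestic_help_wage


def intervention_cost(
    annual_platform_cost: float,
    annual_accounts: int,
    include_opportunity: bool = False,
    participant_hours: float = 0.0,
    wage: float = 0.0,
) -> float:
    """Per-participant intervention cost.

    The platform share is the annual hosting/support cost divided by the
    yearly number of accounts; the opportunity-cost variant adds the value of
    the participant's own time spent on the intervention.
    """
    if annual_accounts <= 0:
        raise ValueError("annual_accounts must be positive")
    cost = annual_platform_cost / annual_accounts
    if include_opportunity:
        cost += participant_hours * wage
    return cost


def price_resources(
    use: ResourceUse,
    prices: UnitPriceTable,
    ref_year: int = 2016,
) -> tuple[dict[str, float], dict[str, float]]:
    """Price the health-care and patient-and-family lines of one wave.

    Returns ``(healthcare_lines, patient_family_lines)``: visit items and
    medication in the first, home care / special home care / informal care in
    the second.  Each line is quantity x indexed unit price.
    """
    use.validate()
    healthcare: dict[str, float] = {}
    for item in VISIT_ITEMS:
        healthcare[item] = getattr(use, item) * prices.indexed_price(item, ref_year)
    healthcare["medication"] = drug_costs(
        {item: getattr(use, item) for item in DRUG_ITEMS},
        {item: prices.indexed_price(item, ref_year) for item in DRUG_ITEMS},
    )
    patient_family = {
        item: getattr(use, item) * prices.indexed_price(item, ref_year)
        for item in CARE_ITEMS
    }
    return healthcare, patient_family


def build_cost_breakdown(
    record: ParticipantRecord,
    wave: int,
    prices: UnitPriceTable,
    friction: FrictionParams | None = None,
    ref_year: int = 2016,
    intervention_eur: float = 0.0,
) -> CostBreakdown | None:
    """Full cost breakdown for one participant-wave; ``None`` if the wave was missed."""
    use = record.resource_use.get(wave)
    if use is None:
        return None
    friction = friction or FrictionParams()
    healthcare, patient_family = price_resources(use, prices, ref_year)
    productivity = {
        "absenteeism": absenteeism_cost(use.absenteeism_days, friction),
        "presenteeism": presenteeism_cost(
            use.presenteeism_days, use.presenteeism_efficiency, friction.daily_wage
        ),
    }
    return CostBreakdown(
        participant_id=record.participant_id,
        wave=wave,
        employment=record.employment,
        intervention=intervention_eur,
        healthcare=healthcare,
        patient_family=patient_family,
        productivity=productivity,
    )


def aggregate(
    breakdowns: Iterable[CostBreakdown],
    perspective: str = "societal",
) -> pd.DataFrame:
    """Per-participant category subtotals and perspective total.

    Societal sums all four categories; healthcare keeps intervention +
    health-care costs; employer keeps intervention + productivity losses and
    is restricted to participants in paid employment.
    """
    if perspective not in ("societal", "healthcare", "employer"):
        raise ValueError(f"unknown perspective: {perspective}")
    rows = []
    for b in breakdowns:
        if perspective == "employer" and b.employment != "paid":
            continue
        rows.append(
            {
                "participant_id": b.participant_id,
                "intervention": b.intervention,
                "healthcare": b.healthcare_subtotal,
                "patient_family": b.patient_family_subtotal,
                "productivity": b.productivity_subtotal,
                "total": b.total(perspective),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "intervention",
                "healthcare",
                "patient_family",
                "productivity",
                "total",
            ]
        )
    df = pd.DataFrame(rows).groupby("participant_id").sum()
    return df


__all__ = [
    "UnitPrice",
    "UnitPriceTable",
    "UnpricedItemError",
    "FrictionParams",
    "CostBreakdown",
    "read_price_csv",
    "default_price_table",
    "price_resources",
    "drug_costs",
    "absenteeism_cost",
    "presenteeism_cost",
    "informal_care_cost",
    "intervention_cost",
    "build_cost_breakdown",
    "aggregate",
]
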