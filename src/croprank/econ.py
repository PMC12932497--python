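"""Direct economic benefit ledger.

Net benefit of a season is grain revenue minus the five itemized costs:
EB = Y x UP - irrigation - fertilizer - seed - machinery - land rent,
all in CNY ha^-1.  Annual results sum the wheat and the maize season of one
rotation year; land rent declared annual is charged half to each season, so
the annual sum counts it exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import CostSchedule

__all__ = ["EconResult", "economic_benefit", "annual_econ", "econ_frame"]


@dataclass(frozen=True)
class EconResult:
    treatment_id: str
    year_label: str
    revenue: float      # CNY ha^-1
    total_cost: float   # CNY ha^-1
    net_benefit: float  # CNY ha^-1

    def __post_init__(self) -> None:
        if abs(self.net_benefit - (self.revenue - self.total_cost)) > 1e-9 * max(
            1.0, abs(self.revenue), abs(self.total_cost)
        ):
            raise ValueError("ledger does not close: net != revenue - cost")


def economic_benefit(
    grain_yield: float,
    price: float,
    costs: CostSchedule,
    treatment_id: str = "",
    year_label: str = "",
) -> EconResult:
    """Per-season economic ledger; net benefit may be negative."""
    if price <= 0:
        raise ValueError(f"grain price must be > 0, got {price}")
    if grain_yield < 0:
        raise ValueError("yield must be >= 0")
    revenue = grain_yield * price
    total = costs.total
    return EconResult(treatment_id, year_label, revenue, total, revenue - total)


def annual_econ(wheat: EconResult, maize: EconResult) -> EconResult:
    """Component-wise sum of the two seasons of one rotation year."""
    if wheat.treatment_id != maize.treatment_id or wheat.year_label != maize.year_label:
        raise ValueError(
            f"cannot sum seasons of different treatment/year: "
            f"({wheat.treatment_id!r}, {wheat.year_label!r}) vs "
            f"({maize.treatment_id!r}, {maize.year_label!r})"
        )
    revenue = wheat.revenue + maize.revenue
    cost = wheat.total_cost + maize.total_cost
    return EconResult(wheat.treatment_id, wheat.year_label, revenue, cost,
                      revenue - cost)


def econ_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.treatment_id, r.year_label, r.revenue, r.total_cost, r.net_benefit)
         for r in results],
        columns=["treatment_id", "year", "revenue", "cost", "net_benefit"],
    )
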