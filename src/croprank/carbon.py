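"""Cropland carbon ledger: crop sequestration vs management emissions.

Sequestration side: photosynthesis stoichiometry — producing 162 kg of dry
matter fixes 264 kg of CO2, i.e. 1.63 kg CO2 per kg dry matter, and 1 kg
CO2 contains 0.27 kg C, so each kg of above-ground dry matter sequesters
about 0.44 kg C (always computed as 1.63 x 0.27, never as the rounded
0.44).

Emission side: the coefficient method C = sum(N_i x K_i) restricted to the
two sources that differ between water-nitrogen treatments — fertilizer
manufacture (0.8956 kg C per kg N) and irrigation electricity (pumping
hours x pump power x 0.6410 kg C per kWh).  Pesticides, film, diesel and
tillage are outside the accounting boundary.  The carbon benefit is the
unitless ratio of sequestration to total emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .config import CarbonParams

__all__ = [
    "CarbonResult",
    "co2_fixed",
    "carbon_sequestered",
    "fertilizer_emission",
    "irrigation_emission",
    "total_emission",
    "carbon_benefit",
    "carbon_ledger",
    "carbon_frame",
]


@dataclass(frozen=True)
class CarbonResult:
    treatment_id: str
    year_label: str
    co2_fixed: float            # kg CO2 ha^-1
    c_sequestered: float        # kg C ha^-1
    fert_emission: float        # kg C ha^-1
    irrigation_emission: float  # kg C ha^-1
    total_emission: float       # kg C ha^-1
    carbon_benefit: float       # unitless ratio

    def __post_init__(self) -> None:
        if abs(self.total_emission - (self.fert_emission + self.irrigation_emission)
               ) > 1e-9 * max(1.0, self.total_emission):
            raise ValueError("emission ledger does not close")


def co2_fixed(dry_matter: float, params: CarbonParams = CarbonParams()) -> float:
    """CO2 fixed by the crop, kg ha^-1: dry matter x 1.63 at defaults."""
    if dry_matter < 0:
        raise ValueError("dry matter must be >= 0")
    return dry_matter * params.co2_per_dm


def carbon_sequestered(dry_matter: float, params: CarbonParams = CarbonParams()) -> float:
    """Carbon sequestered, kg C ha^-1: dry matter x (1.63 x 0.27) at defaults."""
    return co2_fixed(dry_matter, params) * params.c_per_co2


def fertilizer_emission(fertilizer_input: float,
                        params: CarbonParams = CarbonParams()) -> float:
    """Fertilizer-manufacture emission, kg C ha^-1.

    Applied to the nitrogen input mass by default (the base that reproduces
    the trial's printed emission magnitudes); callers accounting total
    N+P+K mass simply pass that mass instead.
    """
    if fertilizer_input < 0:
        raise ValueError("fertilizer input must be >= 0")
    return fertilizer_input * params.fert_coef


def irrigation_emission(volume: float, params: CarbonParams = CarbonParams()) -> float:
    """Irrigation-electricity emission, kg C ha^-1.

    Pumping hours (volume / pump flow) times pump power times the grid
    emission factor.
    """
    if volume < 0:
        raise ValueError("irrigation volume must be >= 0")
    if params.pump_flow <= 0:
        raise ValueError("pump flow must be > 0")
    hours = volume / params.pump_flow
    return hours * params.pump_power * params.elec_coef


def total_emission(components: Iterable[float]) -> float:
    """Total emission over any set of per-source emissions, kg C ha^-1."""
    comps = list(components)
    if any(c < 0 for c in comps):
        raise ValueError("emission components must be >= 0")
    return float(sum(comps))


def carbon_benefit(sequestered: float, emitted: float) -> float:
    """Sequestration-to-emission ratio, unitless."""
    if emitted <= 0:
        raise ValueError(f"total emission must be > 0 for the ratio, got {emitted}")
    if sequestered < 0:
        raise ValueError("sequestration must be >= 0")
    return sequestered / emitted


def carbon_ledger(
    dry_matter: float,
    fertilizer_input: float,
    irrigation_volume: float,
    params: CarbonParams = CarbonParams(),
    treatment_id: str = "",
    year_label: str = "",
) -> CarbonResult:
    """Full per-treatment annual carbon account from physical inputs."""
    fixed = co2_fixed(dry_matter, params)
    seq = fixed * params.c_per_co2
    fert = fertilizer_emission(fertilizer_input, params)
    irr = irrigation_emission(irrigation_volume, params)
    tot = total_emission([fert, irr])
    return CarbonResult(
        treatment_id=treatment_id, year_label=year_label,
        co2_fixed=fixed, c_sequestered=seq,
        fert_emission=fert, irrigation_emission=irr, total_emission=tot,
        carbon_benefit=carbon_benefit(seq, tot),
    )


def carbon_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.treatment_id, r.year_label, r.c_sequestered, r.fert_emission,
          r.irrigation_emission, r.total_emission, r.carbon_benefit)
         for r in results],
        columns=["treatment_id", "year", "c_sequestered", "fert_emission",
                 "irr_emission", "total_emission", "carbon_benefit"],
    )
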