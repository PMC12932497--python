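"""End-to-end orchestration: simulate -> indicators -> ledgers -> ranking.

One :func:`run_pipeline` call evaluates every configured irrigation-system
panel and rotation year: it simulates (or accepts) plot records, computes
replicate-mean efficiency indicators, builds the economic and carbon
ledgers, assembles the 11-indicator decision matrix and ranks the
treatments by entropy-weighted TOPSIS.  Everything is deterministic for a
fixed configuration seed, and each run records its provenance (config
hash, seed, package version).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from ._version import __version__
from .carbon import CarbonResult, carbon_frame, carbon_ledger
from .config import ConfigurationError, RunConfig, config_hash, resolve_cost_schedule
from .econ import EconResult, annual_econ, econ_frame, economic_benefit
from .indicators import (
    EfficiencyRecord,
    aggregate_by_treatment,
    annual_yield,
    efficiency_frame,
)
from .mcda import EntropyWeights, IndicatorMatrix, TopsisResult, evaluate
from .trial import records_to_frame, simulate_trial

__all__ = ["INDICATOR_NAMES", "INDICATOR_ORIENTATION", "RunReport",
           "assemble_indicator_matrix", "run_pipeline"]

logger = logging.getLogger(__name__)

#: The 11 evaluation indicators, in canonical column order: output (3),
#: economic (2), resource-use efficiency (4), environmental (2).
INDICATOR_NAMES = (
    "wheat_yield", "maize_yield", "annual_yield",
    "net_income", "production_costs",
    "wheat_wue", "maize_wue", "wheat_nue", "maize_nue",
    "carbon_sequestration", "carbon_emissions",
)

#: Orientation of each indicator: production costs and carbon emissions are
#: cost-type (smaller is better); everything else is benefit-type.
INDICATOR_ORIENTATION = {
    name: ("cost" if name in ("production_costs", "carbon_emissions") else "benefit")
    for name in INDICATOR_NAMES
}


@dataclass
class RunReport:
    """All tables produced by one pipeline run, keyed by (system, year)."""

    seed: int
    config_digest: str
    plot_records: dict[str, pd.DataFrame]                     # per system
    efficiency: dict[str, pd.DataFrame]                       # per system
    econ: dict[tuple[str, str], pd.DataFrame]                 # per (system, year)
    carbon: dict[tuple[str, str], pd.DataFrame]
    matrices: dict[tuple[str, str], IndicatorMatrix]
    weights: dict[tuple[str, str], EntropyWeights]
    rankings: dict[tuple[str, str], TopsisResult]
    warnings: list[str] = field(default_factory=list)

    def ranking_frame(self, system: str, year: str) -> pd.DataFrame:
        return self.rankings[(system, year)].to_frame()

    def summary(self) -> str:
        lines = [
            "# Water-nitrogen strategy evaluation",
            f"seed: {self.seed}",
            f"config: {self.config_digest}",
            f"croprank version: {__version__}",
            "",
        ]
        for (system, year), res in sorted(self.rankings.items()):
            lines.append(f"## {system} irrigation, {year}")
            lines.append(res.to_frame().round(4).to_string())
            w = self.weights[(system, year)].as_series().round(4)
            lines.append("entropy weights: "
                         + ", ".join(f"{k}={v}" for k, v in w.items()))
            lines.append("")
        if self.warnings:
            lines.append("## Warnings")
            lines.extend(f"- {w}" for w in self.warnings)
            lines.append("")
        return "\n".join(lines)

    def write(self, outdir) -> None:
        """Write every table as CSV plus a human-readable markdown summary."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for system, df in self.plot_records.items():
            df.to_csv(out / f"plots_{system}.csv", index=False)
        for system, df in self.efficiency.items():
            df.to_csv(out / f"efficiency_{system}.csv", index=False)
        for (system, year), df in self.econ.items():
            df.to_csv(out / f"econ_{system}_{year}.csv", index=False)
        for (system, year), df in self.carbon.items():
            df.to_csv(out / f"carbon_{system}_{year}.csv", index=False)
        for (system, year), m in self.matrices.items():
            m.to_frame().to_csv(out / f"matrix_{system}_{year}.csv")
        for (system, year), w in self.weights.items():
            w.as_series().to_csv(out / f"weights_{system}_{year}.csv")
        for (system, year), r in self.rankings.items():
            r.to_frame().to_csv(out / f"topsis_{system}_{year}.csv")
        (out / "summary.md").write_text(self.summary())


def _display_id(treatment_key: str) -> str:
    """Panel treatment keys may be system-qualified ('T4@drip') -> 'T4'."""
    return treatment_key.split("@")[0]


def assemble_indicator_matrix(
    efficiency: Sequence[EfficiencyRecord],
    econ: Sequence[EconResult],
    carbon: Sequence[CarbonResult],
    wheat_season: str,
    maize_season: str,
    treatment_order: Sequence[str],
    warnings: list[str] | None = None,
) -> IndicatorMatrix:
    """Build the 11-indicator decision matrix for one system-year panel.

    Undefined NUE (zero-N controls) is imputed as 0 — the worst benefit
    value — with a logged warning, so control rows stay in the panel.
    Raises ConfigurationError when any table misses a treatment.
    """
    eff = {(r.treatment_id, r.season_id): r for r in efficiency}
    eco = {r.treatment_id: r for r in econ}
    car = {r.treatment_id: r for r in carbon}

    rows = []
    for tid in treatment_order:
        try:
            ew = eff[(tid, wheat_season)]
            em = eff[(tid, maize_season)]
        except KeyError as exc:
            raise ConfigurationError(
                f"efficiency table misses treatment {tid!r} in season {exc.args[0]!r}"
            ) from None
        if tid not in eco:
            raise ConfigurationError(f"economic table misses treatment {tid!r}")
        if tid not in car:
            raise ConfigurationError(f"carbon table misses treatment {tid!r}")

        def impute_nue(rec: EfficiencyRecord) -> float:
            if rec.nue is None:
                msg = (f"treatment {rec.treatment_id!r}: undefined NUE "
                       f"(zero-N control) imputed as 0 in season {rec.season_id!r}")
                logger.warning(msg)
                if warnings is not None:
                    warnings.append(msg)
                return 0.0
            return rec.nue

        rows.append([
            ew.mean_yield, em.mean_yield,
            annual_yield(ew.mean_yield, em.mean_yield),
            eco[tid].net_benefit, eco[tid].total_cost,
            ew.wue, em.wue, impute_nue(ew), impute_nue(em),
            car[tid].c_sequestered, car[tid].total_emission,
        ])
    return IndicatorMatrix(
        alternative_ids=tuple(_display_id(t) for t in treatment_order),
        indicator_names=INDICATOR_NAMES,
        values=rows,
        orientation=INDICATOR_ORIENTATION,
    )


def run_pipeline(config: RunConfig, outdir=None) -> RunReport:
    """Run the full evaluation for every configured panel and year.

    Validates the configuration (every fertilized treatment must resolve a
    zero-N control, every cell a mean yield) before any simulation or
    output, simulates each system panel on its own deterministic stream,
    and evaluates each (system, year) 9 x 11 matrix separately — panels
    are never pooled across irrigation systems or years.
    """
    config.validate()
    digest = config_hash(config)
    report = RunReport(
        seed=config.seed, config_digest=digest,
        plot_records={}, efficiency={}, econ={}, carbon={},
        matrices={}, weights={}, rankings={},
    )

    for system, tids in config.systems.items():
        treatments = [config.treatments[t] for t in tids]
        seasons = list(config.seasons.values())
        records = simulate_trial(treatments, seasons, config.generator)
        report.plot_records[system] = records_to_frame(records)
        logger.info("system %s: %d plot records simulated", system, len(records))

        eff = aggregate_by_treatment(records, treatments, seasons,
                                     control_map=config.control_map)
        report.efficiency[system] = efficiency_frame(eff)
        eff_by_cell = {(r.treatment_id, r.season_id): r for r in eff}

        for year, (wheat_sid, maize_sid) in config.rotation_years.items():
            wheat = config.seasons[wheat_sid]
            maize = config.seasons[maize_sid]
            econ_rows, carbon_rows = [], []
            for t in treatments:
                ew = eff_by_cell[(t.id, wheat_sid)]
                em = eff_by_cell[(t.id, maize_sid)]
                e_wheat = economic_benefit(
                    ew.mean_yield, wheat.grain_price,
                    resolve_cost_schedule(wheat, t), t.id, year)
                e_maize = economic_benefit(
                    em.mean_yield, maize.grain_price,
                    resolve_cost_schedule(maize, t), t.id, year)
                econ_rows.append(annual_econ(e_wheat, e_maize))

                dm = ew.mean_dry_matter + em.mean_dry_matter
                n_input = 2 * t.n_rate  # both seasons fertilized at the same rate
                volume = (wheat.irrigation_volume(t.irrigation_method)
                          + maize.irrigation_volume(t.irrigation_method))
                carbon_rows.append(carbon_ledger(
                    dm, n_input, volume, config.carbon, t.id, year))

            report.econ[(system, year)] = econ_frame(econ_rows)
            report.carbon[(system, year)] = carbon_frame(carbon_rows)

            matrix = assemble_indicator_matrix(
                eff, econ_rows, carbon_rows, wheat_sid, maize_sid,
                treatment_order=tids, warnings=report.warnings,
            )
            result, weights = evaluate(matrix)
            report.matrices[(system, year)] = matrix
            report.weights[(system, year)] = weights
            report.rankings[(system, year)] = result
            logger.info("panel (%s, %s): best = %s", system, year,
                        result.alternative_ids[int(result.rank.argmin())])

    if outdir is not None:
        report.write(outdir)
    return report
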