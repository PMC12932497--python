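"""Synthetic plot-level data for a split-plot wheat-maize rotation trial.

Field measurements (grain moisture correction, oven-dried biomass, Kjeldahl
nitrogen) are emulated statistically, not mechanistically: each
(treatment, season) cell has a configured mean grain yield with Gaussian
plot noise, above-ground dry matter is grain divided by a noisy
grain-to-biomass ratio, and plant nitrogen uptake follows a saturating
(Mitscherlich-type) tissue-concentration response to the nitrogen rate.
Each cell draws from its own deterministic RNG substream, so adding or
removing a treatment never perturbs the records of another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import ConfigurationError, GeneratorModel, SeasonSpec, TreatmentSpec

__all__ = [
    "PlotRecord",
    "tissue_n_concentration",
    "simulate_trial",
    "records_to_frame",
    "frame_to_records",
    "write_trial",
    "read_trial",
    "TrialParseError",
]

#: CSV column order of the plot-record interchange format.
CSV_COLUMNS = [
    "treatment_id", "season_id", "replicate",
    "grain_yield_kg_ha", "dry_matter_kg_ha", "n_uptake_kg_ha",
]


class TrialParseError(ValueError):
    """A plot-record file row could not be parsed."""


@dataclass(frozen=True)
class PlotRecord:
    """One replicate plot observation in one season.

    grain_yield is standardized to storage moisture (13% wheat, 14% maize),
    dry_matter is above-ground biomass and n_uptake the nitrogen in it, all
    per hectare.
    """

    treatment_id: str
    season_id: str
    replicate: int
    grain_yield: float   # kg ha^-1
    dry_matter: float    # kg ha^-1
    n_uptake: float      # kg N ha^-1

    def __post_init__(self) -> None:
        if min(self.grain_yield, self.dry_matter, self.n_uptake) < 0:
            raise ValueError("plot quantities must be >= 0")


def tissue_n_concentration(n_rate: float, base: float, maximum: float, k: float) -> float:
    """Saturating above-ground tissue N concentration (kg N per kg dry matter).

    ``base`` at zero N, approaching ``maximum`` as the rate grows, with
    curvature ``k`` (per kg N ha^-1):  base + (max - base)(1 - exp(-k N)).
    Non-decreasing in the rate, which keeps the difference-method nitrogen
    use efficiency non-negative under zero noise.
    """
    return base + (maximum - base) * (1.0 - math.exp(-k * n_rate))


def _cell_rng(seed: int, treatment_id: str, season_id: str) -> np.random.Generator:
    # deterministic substream per cell; crc32 keeps entropy words < 2^32
    key = (seed & 0xFFFFFFFF,
           zlib.crc32(treatment_id.encode()),
           zlib.crc32(season_id.encode()))
    return np.random.default_rng(np.random.SeedSequence(key))


def simulate_trial(
    treatments: Sequence[TreatmentSpec],
    seasons: Sequence[SeasonSpec],
    model: GeneratorModel,
) -> list[PlotRecord]:
    """Draw ``model.n_replicates`` plot records per (treatment, season).

    Grain yield ~ Normal(cell mean, cell sd) truncated at 0; the
    grain-to-biomass ratio ~ Normal(harvest_index_mean, harvest_index_sd)
    truncated to (0.2, 0.8); N uptake is dry matter times the saturating
    tissue concentration times a (1 + Gaussian) multiplicative noise.
    Identical model (including seed) gives bit-identical output.

    Raises
    ------
    ConfigurationError
        If any (treatment, season) cell lacks a configured mean yield.
    """
    # validate the full grid up front so the error names the missing cell
    for t in treatments:
        for s in seasons:
            model.cell_mean(t.id, s.season_id)

    records: list[PlotRecord] = []
    for t in treatments:
        for s in seasons:
            mean = model.cell_mean(t.id, s.season_id)
            sd = model.cell_sd(t.id, s.season_id)
            rng = _cell_rng(model.seed, t.id, s.season_id)
            conc = tissue_n_concentration(
                t.n_rate, model.n_conc_base, model.n_conc_max, model.n_response_k
            )
            for rep in range(1, model.n_replicates + 1):
                grain = max(0.0, rng.normal(mean, sd)) if sd > 0 else mean
                h = rng.normal(model.harvest_index_mean, model.harvest_index_sd) \
                    if model.harvest_index_sd > 0 else model.harvest_index_mean
                h = min(max(h, 0.2), 0.8)
                dm = grain / h
                noise = rng.normal(0.0, model.n_noise_sd) if model.n_noise_sd > 0 else 0.0
                uptake = max(0.0, dm * conc * (1.0 + noise))
                records.append(PlotRecord(t.id, s.season_id, rep, grain, dm, uptake))
    return records


# ---------------------------------------------------------------------------
# interchange format


def records_to_frame(records: Iterable[PlotRecord]) -> pd.DataFrame:
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=["treatment_id", "season_id", "replicate",
                                     "grain_yield", "dry_matter", "n_uptake"])
    df.columns = CSV_COLUMNS
    return df


def frame_to_records(df: pd.DataFrame) -> list[PlotRecord]:
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise TrialParseError(f"plot-record table missing columns: {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            out.append(PlotRecord(
                treatment_id=str(row.treatment_id),
                season_id=str(row.season_id),
                replicate=int(row.replicate),
                grain_yield=float(row.grain_yield_kg_ha),
                dry_matter=float(row.dry_matter_kg_ha),
                n_uptake=float(row.n_uptake_kg_ha),
            ))
        except (TypeError, ValueError) as exc:
            raise TrialParseError(f"malformed plot record at line {i}: {exc}") from exc
    return out


def write_trial(records: Iterable[PlotRecord], path) -> None:
    """Write plot records as CSV with a header row (full float precision:
    pandas writes shortest round-trip representations)."""
    records_to_frame(records).to_csv(path, index=False)


def read_trial(path) -> list[PlotRecord]:
    """Read plot records back; inverse of :func:`write_trial` field-for-field."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrialParseError(f"cannot parse plot-record file {path}: {exc}") from exc
    return frame_to_records(df)
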