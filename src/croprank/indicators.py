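"""Resource-use-efficiency indicators for the rotation trial.

Irrigation water-use efficiency (WUE) is grain yield per unit irrigation
water, kg m^-3 — irrigation-water productivity, not an
evapotranspiration-based measure.  Nitrogen-use efficiency (NUE) follows
the difference method: the extra above-ground N uptake of a fertilized
plot over its zero-N control, as a percentage of the N applied.  Zero-N
controls have no defined NUE; that is represented by ``None``, never by 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import ConfigurationError, SeasonSpec, TreatmentSpec
from .trial import PlotRecord

__all__ = [
    "EfficiencyRecord",
    "compute_wue",
    "compute_nue",
    "annual_yield",
    "percent_change",
    "default_control_map",
    "aggregate_by_treatment",
    "efficiency_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EfficiencyRecord:
    """Per-treatment, per-season indicator summary (means over replicates)."""

    treatment_id: str
    season_id: str
    mean_yield: float           # kg ha^-1
    mean_dry_matter: float      # kg ha^-1
    mean_n_uptake: float        # kg N ha^-1
    wue: float                  # kg m^-3
    nue: float | None           # percent; None for zero-N controls


def compute_wue(grain_yield: float, irrigation_volume: float) -> float:
    """Irrigation water-use efficiency Y/I, kg m^-3.

    Raises a domain error for non-positive volume: a rain-fed or unmetered
    plot must be configured explicitly, never divided silently.
    """
    if irrigation_volume <= 0:
        raise ValueError(
            f"irrigation volume must be > 0 for WUE, got {irrigation_volume}"
        )
    if grain_yield < 0:
        raise ValueError("yield must be >= 0")
    return grain_yield / irrigation_volume


def compute_nue(
    uptake_fertilized: float, uptake_control: float, n_rate: float
) -> float | None:
    """Difference-method nitrogen use efficiency, percent.

    100 x (T_n - C_n) / N, where T_n / C_n are above-ground N uptake in the
    fertilized and control plots.  Returns ``None`` (undefined) when the N
    rate is zero; a negative value (control outperforming) is returned
    as-is and logged, not clipped.
    """
    if n_rate == 0:
        return None
    if n_rate < 0 or min(uptake_fertilized, uptake_control) < 0:
        raise ValueError("uptakes must be >= 0 and n_rate > 0")
    nue = 100.0 * (uptake_fertilized - uptake_control) / n_rate
    if nue < 0:
        logger.warning(
            "negative NUE %.2f%% (control uptake %.1f exceeds fertilized %.1f)",
            nue, uptake_control, uptake_fertilized,
        )
    return nue


def annual_yield(wheat_yield: float, maize_yield: float) -> float:
    """Annual system yield of one rotation year: wheat + maize, kg ha^-1."""
    if wheat_yield < 0 or maize_yield < 0:
        raise ValueError("yields must be >= 0")
    return wheat_yield + maize_yield


def percent_change(value: float, reference: float) -> float:
    """Relative difference 100 x (value - reference) / reference, percent."""
    if reference <= 0:
        raise ValueError(f"reference must be > 0, got {reference}")
    return 100.0 * (value - reference) / reference


def default_control_map(
    treatments: Sequence[TreatmentSpec],
    override: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Map each fertilized treatment to the zero-N control of its own
    irrigation system (flood plots to the flood control, drip/sprinkler
    plots to the optimized-system control).

    Raises
    ------
    ConfigurationError
        Naming the first fertilized treatment without a matching control.
    """
    by_id = {t.id: t for t in treatments}
    controls = [t for t in treatments if t.is_zero_n]
    mapping: dict[str, str] = {}
    for t in treatments:
        if t.is_zero_n:
            continue
        if override and t.id in override:
            cid = override[t.id]
            if cid not in by_id or not by_id[cid].is_zero_n:
                raise ConfigurationError(
                    f"control override for {t.id!r} points at {cid!r}, which is "
                    "not a zero-N treatment in the panel"
                )
            mapping[t.id] = cid
            continue
        same_method = [c for c in controls
                       if c.irrigation_method == t.irrigation_method]
        if not same_method:
            raise ConfigurationError(
                f"fertilized treatment {t.id!r} ({t.irrigation_method}) has no "
                "zero-N control under the same irrigation method"
            )
        mapping[t.id] = same_method[0].id
    return mapping


def aggregate_by_treatment(
    records: Iterable[PlotRecord],
    treatments: Sequence[TreatmentSpec],
    seasons: Sequence[SeasonSpec],
    control_map: Mapping[str, str] | None = None,
) -> list[EfficiencyRecord]:
    """Replicate means and efficiency indicators per (treatment, season).

    WUE uses the irrigation volume of the season under the treatment's own
    irrigation method; NUE uses the mapped zero-N control's mean uptake in
    the same season.  The control map defaults to same-irrigation-system
    pairing (see :func:`default_control_map`).
    """
    t_by_id = {t.id: t for t in treatments}
    s_by_id = {s.season_id: s for s in seasons}
    mapping = default_control_map(treatments, override=control_map)

    df = pd.DataFrame(
        [(r.treatment_id, r.season_id, r.grain_yield, r.dry_matter, r.n_uptake)
         for r in records],
        columns=["treatment_id", "season_id", "grain_yield", "dry_matter", "n_uptake"],
    )
    # sort so replicate-mean summation order (hence the floats) is identical
    # for any permutation of the input records
    df = df.sort_values(["treatment_id", "season_id", "grain_yield",
                         "dry_matter", "n_uptake"], kind="stable")
    means = df.groupby(["treatment_id", "season_id"], sort=False).mean(numeric_only=True)

    out: list[EfficiencyRecord] = []
    for (tid, sid), row in means.iterrows():
        if tid not in t_by_id or sid not in s_by_id:
            raise ConfigurationError(
                f"plot records mention ({tid!r}, {sid!r}) absent from the design"
            )
        t, s = t_by_id[tid], s_by_id[sid]
        volume = s.irrigation_volume(t.irrigation_method)
        wue = compute_wue(row["grain_yield"], volume)
        if t.is_zero_n:
            nue = None
        else:
            control = mapping[tid]
            try:
                control_uptake = means.loc[(control, sid), "n_uptake"]
            except KeyError:
                raise ConfigurationError(
                    f"control {control!r} has no records in season {sid!r}"
                ) from None
            nue = compute_nue(row["n_uptake"], float(control_uptake), t.n_rate)
        out.append(EfficiencyRecord(
            treatment_id=tid, season_id=sid,
            mean_yield=float(row["grain_yield"]),
            mean_dry_matter=float(row["dry_matter"]),
            mean_n_uptake=float(row["n_uptake"]),
            wue=wue, nue=nue,
        ))
    return out


def efficiency_frame(records: Sequence[EfficiencyRecord]) -> pd.DataFrame:
    """Tabular view (NUE of controls is NaN in the table, None in the records)."""
    return pd.DataFrame(
        [(r.treatment_id, r.season_id, r.mean_yield, r.mean_dry_matter,
          r.mean_n_uptake, r.wue, r.nue) for r in records],
        columns=["treatment_id", "season_id", "mean_yield", "mean_dry_matter",
                 "mean_n_uptake", "wue", "nue"],
    )
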