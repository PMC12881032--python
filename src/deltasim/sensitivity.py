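"""Ensemble execution, driver sensitivity ranges and poverty attribution.

The one-at-a-time (OAT) analysis compares, for each driver, the change
of each indicator in the 2041-2050 decade (vs the 2005-2014 baseline)
across that driver's settings: the parent world plus its OAT overrides.
The range (max - min change) per driver is normalised by the largest
range across drivers for that indicator and world, and classified as
low (<= 25% change), moderate (25-50%) or high (>= 50%).

Poverty attribution splits each household group's decadal poverty change
into a climatic share (climate, sea-level rise, cyclones) and a
non-climatic share (1 minus the climatic share).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CLIMATIC_DRIVERS, OAT_DRIVERS, RunSpec
from .indicators import ANALYSIS_DECADE_2050, BASELINE_DECADE, decadal_baseline_change, decadal_mean
from .scenario import parent_run_id
from .simulate import HOUSEHOLD_GROUPS6, SimulationSettings, run_simulation

logger = logging.getLogger(__name__)

INDICATORS = (
    "inundated_area_km2",
    "mean_soil_salinity_dS_m",
    "total_rice_t",
    "poverty_rate_pct",
    "gini",
    "gdp_per_capita",
)


@dataclass(frozen=True)
class SensitivityResult:
    driver: str
    indicator: str
    world: str
    raw_range: float
    normalised: float
    category: str


@dataclass(frozen=True)
class AttributionResult:
    household_group: str
    world: str
    decade: tuple[int, int]
    climatic_share: float
    nonclimatic_share: float
    extreme_year_climatic_share: Optional[float]


def run_ensemble(
    runspecs: Sequence[RunSpec],
    region,
    archetypes,
    settings: Optional[SimulationSettings] = None,
) -> dict[str, pd.DataFrame]:
    """Run every spec; returns run_id -> annual indicator table.

    Runs are independent and deterministic per (spec, settings); a failed
    run raises with its run_id while earlier results are preserved on the
    returned mapping via the exception's ``partial`` attribute.
    """
    tables: dict[str, pd.DataFrame] = {}
    for spec in runspecs:
        try:
            import time

            t0 = time.perf_counter()
            tables[spec.run_id] = run_simulation(spec, region, archetypes, settings)
            logger.info("run %s finished in %.1fs", spec.run_id, time.perf_counter() - t0)
        except Exception as exc:  # pragma: no cover - defensive
            exc.partial = tables  # type: ignore[attr-defined]
            raise RuntimeError(f"run {spec.run_id!r} failed: {exc}") from exc
    return tables


def categorise(pct_change: float) -> str:
    """Sensitivity class from an absolute percent change."""
    if not np.isfinite(pct_change):
        raise ValueError("percent change must be finite")
    mag = abs(pct_change)
    if mag <= 25.0:
        return "low"
    if mag >= 50.0:
        return "high"
    return "moderate"


def _driver_settings(
    runs: Sequence[RunSpec], driver: str, world: str
) -> list[str]:
    """Run ids forming a driver's settings: parent world + its OAT runs."""
    ids = [parent_run_id(world)]
    ids += [
        r.run_id
        for r in runs
        if r.parent_world == world and r.overridden_driver == driver
    ]
    return ids


def _decadal_change(
    table: pd.DataFrame,
    indicator: str,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
) -> tuple[float, Optional[float]]:
    return decadal_baseline_change(table[indicator], decade=decade)


def driver_sensitivity(
    tables: dict[str, pd.DataFrame],
    runs: Sequence[RunSpec],
    driver: str,
    indicator: str,
    world: str,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
) -> float:
    """Raw sensitivity range: max - min decadal percent change across the
    driver's settings (absolute change when the baseline is zero)."""
    ids = _driver_settings(runs, driver, world)
    if len(ids) < 2:
        raise ValueError(f"driver {driver!r} has fewer than two settings for {world}")
    changes = []
    for rid in ids:
        absolute, pct = _decadal_change(tables[rid], indicator, decade)
        changes.append(pct if pct is not None else absolute)
    return float(max(changes) - min(changes))


def sensitivity_table(
    tables: dict[str, pd.DataFrame],
    runs: Sequence[RunSpec],
    worlds: Sequence[str] = ("positive", "negative"),
    indicators: Sequence[str] = INDICATORS,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
) -> pd.DataFrame:
    """Per driver x indicator x world: raw range, normalised range, category.

    Normalisation is per (indicator, world): each driver's range divided
    by the largest range across drivers, so exactly one driver scores 1
    (unless all ranges are zero).
    """
    rows = []
    for world in worlds:
        for indicator in indicators:
            raw = {}
            for driver in OAT_DRIVERS:
                raw[driver] = driver_sensitivity(
                    tables, runs, driver, indicator, world, decade
                )
            max_raw = max(raw.values())
            for driver, r in raw.items():
                norm = r / max_raw if max_raw > 0 else 0.0
                rows.append(
                    SensitivityResult(
                        driver=driver,
                        indicator=indicator,
                        world=world,
                        raw_range=r,
                        normalised=norm,
                        category=categorise(r),
                    )
                )
    return pd.DataFrame([r.__dict__ for r in rows])


def _group_column(group: str) -> str:
    return f"poverty_pct_{group}"


def attribute_poverty(
    tables: dict[str, pd.DataFrame],
    runs: Sequence[RunSpec],
    group: str,
    world: str,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
) -> AttributionResult:
    """Climatic vs non-climatic share of a group's decadal poverty change.

    Each driver's effect is the mean absolute difference of the decadal
    poverty change between its OAT runs and the parent world; the
    climatic share is the summed effect of {climate, SLR, cyclones} over
    the summed effect of all drivers, clipped to [0, 1]; the
    non-climatic share is its complement.  The extreme-year variant
    replaces the decadal mean with the decade's worst (maximum-poverty)
    year.  Shares are undefined (NaN) when no driver moves poverty.
    """
    col = _group_column(group)
    parent = tables[parent_run_id(world)]

    def change(table: pd.DataFrame, extreme: bool) -> float:
        base = decadal_mean(table[col], BASELINE_DECADE)
        if extreme:
            window = table[col].loc[decade[0]: decade[1]]
            value = float(window.max())
        else:
            value = decadal_mean(table[col], decade)
        return value - base

    def shares(extreme: bool) -> Optional[float]:
        parent_change = change(parent, extreme)
        effects = {}
        for driver in OAT_DRIVERS:
            ids = _driver_settings(runs, driver, world)[1:]  # OAT runs only
            if not ids:
                effects[driver] = 0.0
                continue
            diffs = [abs(change(tables[rid], extreme) - parent_change) for rid in ids]
            effects[driver] = float(np.mean(diffs))
        total = sum(effects.values())
        if total <= 0:
            return None
        clim = sum(effects[d] for d in CLIMATIC_DRIVERS)
        return float(np.clip(clim / total, 0.0, 1.0))

    clim_share = shares(extreme=False)
    extreme_share = shares(extreme=True)
    if clim_share is None:
        return AttributionResult(group, world, decade, float("nan"), float("nan"), extreme_share)
    return AttributionResult(
        household_group=group,
        world=world,
        decade=decade,
        climatic_share=clim_share,
        nonclimatic_share=1.0 - clim_share,
        extreme_year_climatic_share=extreme_share,
    )


def attribution_table(
    tables: dict[str, pd.DataFrame],
    runs: Sequence[RunSpec],
    worlds: Sequence[str] = ("positive", "negative"),
    groups: Sequence[str] = HOUSEHOLD_GROUPS6,
    decade: tuple[int, int] = ANALYSIS_DECADE_2050,
) -> pd.DataFrame:
    rows = []
    for world in worlds:
        for group in groups:
            res = attribute_poverty(tables, runs, group, world, decade)
            rows.append(
                {
                    "world": world,
                    "household_group": group,
                    "decade": f"{decade[0]}-{decade[1]}",
                    "climatic_share": res.climatic_share,
                    "nonclimatic_share": res.nonclimatic_share,
                    "extreme_year_climatic_share": res.extreme_year_climatic_share,
                }
            )
    return pd.DataFrame(rows)
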