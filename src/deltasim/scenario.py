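"""Transient driver series for the delta worlds.

All series cover the simulation period 1985-2050 (sea level to 2055 so the
full mid-century window 2040-2055 is available).  Anomalies follow a linear
ramp from the base-period midpoint (2007) to the mid-century midpoint
(2047); the ramp is normalised so that the contrast between the two
windows the storylines are defined on (2000-2015 base vs 2040-2055
mid-century) recovers the stated parameter exactly.  A 365-day (no-leap)
calendar is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    BASE_WINDOW,
    MIDCENTURY_WINDOW,
    MONSOON_MONTHS,
    OAT_DRIVERS,
    RAMP_WINDOW,
    SIM_END_YEAR,
    SIM_START_YEAR,
    SOCIO_VARIANTS,
    ConfigurationError,
    RunSpec,
    WorldConfig,
    derive_seed,
)

# Anomaly ramp endpoints: base-period midpoint to mid-century midpoint.
_RAMP_START = 2007
_RAMP_END = 2047

# No-leap month lengths and first day-of-year per month.
_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_START_DOY = np.concatenate([[1], 1 + np.cumsum(_MONTH_DAYS)[:-1]])


def month_of_doy(doy: np.ndarray) -> np.ndarray:
    """Month number (1-12) for day-of-year in a 365-day calendar."""
    return np.searchsorted(_MONTH_START_DOY, doy, side="right")


def _ramp(years: np.ndarray) -> np.ndarray:
    return np.clip((years - _RAMP_START) / (_RAMP_END - _RAMP_START), 0.0, 1.0)


def _window_means_of_ramp() -> tuple[float, float]:
    base = np.arange(BASE_WINDOW[0], BASE_WINDOW[1] + 1)
    mid = np.arange(MIDCENTURY_WINDOW[0], MIDCENTURY_WINDOW[1] + 1)
    return float(_ramp(base).mean()), float(_ramp(mid).mean())


# ---------------------------------------------------------------------------
# Sea level
# ---------------------------------------------------------------------------

def slr_series(config: WorldConfig, years: Optional[Iterable[int]] = None) -> pd.Series:
    """Annual sea-level offset (cm) relative to the year 2000.

    The trajectory is quadratic from zero in 2000 (accelerating rise),
    scaled so that the 2040-2055 mean equals the configured mid-century
    value.  Before 2000 the signed quadratic gives a small fall, keeping
    the series monotone.
    """
    if years is None:
        years = range(SIM_START_YEAR, MIDCENTURY_WINDOW[1] + 1)
    years = np.asarray(list(years))
    mid = np.arange(MIDCENTURY_WINDOW[0], MIDCENTURY_WINDOW[1] + 1) - 2000
    k = config.slr_midcentury_cm / float(np.mean(mid.astype(float) ** 2))
    dy = years - 2000
    values = k * np.sign(dy) * dy.astype(float) ** 2
    return pd.Series(values, index=pd.Index(years, name="year"), name="slr_cm")


# ---------------------------------------------------------------------------
# Daily climate
# ---------------------------------------------------------------------------

def generate_climate(
    config: WorldConfig,
    base_stats: pd.DataFrame,
    seed: Optional[int] = None,
    noise: bool = False,
    start_year: int = SIM_START_YEAR,
    end_year: int = SIM_END_YEAR,
) -> pd.DataFrame:
    """Daily weather series for the simulation period.

    Parameters
    ----------
    base_stats
        One annual cycle of daily climatology indexed by day-of-year
        (1..365) with columns ``temp_C`` and ``precip_mm``.
    noise
        When True, gamma-distributed daily rainfall variability is added
        (requires ``seed``); the anomaly schedule itself is deterministic.

    Returns a frame with columns ``year, doy, month, season, temp_C,
    precip_mm, discharge_index``, where season is ``monsoon`` (Jun-Oct) or
    ``dry``.  Temperature anomalies are additive, precipitation anomalies
    multiplicative; seasonal splits are applied first and each year is then
    rescaled so the annual target is met exactly, with the ramp normalised
    to reproduce the configured window contrast.
    """
    if noise and seed is None:
        raise ConfigurationError("a seed is required when weather noise is enabled")
    base_stats = base_stats.sort_index()
    if len(base_stats) != 365:
        raise ConfigurationError("base_stats must cover 365 days of year")

    years = np.arange(start_year, end_year + 1)
    n_years = len(years)
    doy = np.tile(np.arange(1, 366), n_years)
    year_col = np.repeat(years, 365)
    month = month_of_doy(doy)
    is_monsoon = np.isin(month, MONSOON_MONTHS)

    temp0 = np.tile(base_stats["temp_C"].to_numpy(), n_years)
    precip0 = np.tile(base_stats["precip_mm"].to_numpy(), n_years)

    r_base, r_mid = _window_means_of_ramp()
    d_r = r_mid - r_base
    ramp_y = _ramp(years)
    ramp = np.repeat(ramp_y, 365)

    # Temperature: adjust seasonal deltas by a common offset so the
    # day-weighted annual delta equals the annual target, then normalise
    # the ramp so the 2040-2055 minus 2000-2015 contrast is exact.
    tr = config.temp_rise_C
    n_m = int(np.isin(month_of_doy(np.arange(1, 366)), MONSOON_MONTHS).sum())
    n_d = 365 - n_m
    implied_annual = (n_m * tr.monsoon + n_d * tr.dry) / 365.0
    offset = implied_annual - tr.annual
    d_monsoon = tr.monsoon - offset
    d_dry = tr.dry - offset
    c_T = 1.0 / d_r
    temp_anom = np.where(is_monsoon, d_monsoon, d_dry) * c_T * ramp
    temp = temp0 + temp_anom

    # Precipitation: raw seasonal multiplicative factors, then a per-year
    # rescale to the exact annual factor A(y) = 1 + p_a * c_P * ramp(y),
    # with c_P solving the multiplicative window-contrast equation.
    pc = config.precip_change_frac
    f_season = np.where(is_monsoon, 1.0 + pc.monsoon * ramp, 1.0 + pc.dry * ramp)
    precip_seasonal = precip0 * f_season
    if pc.annual == 0.0:
        annual_factor_y = np.ones(n_years)
    else:
        c_P = 1.0 / (d_r - pc.annual * r_base)
        annual_factor_y = 1.0 + pc.annual * c_P * ramp_y
    base_total = float(precip0[:365].sum())
    seasonal_totals = precip_seasonal.reshape(n_years, 365).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        correction = np.where(
            seasonal_totals > 0, annual_factor_y * base_total / seasonal_totals, 1.0
        )
    precip = precip_seasonal * np.repeat(correction, 365)

    if noise:
        rng = np.random.default_rng(seed)
        # Gamma multiplicative noise, unit mean, preserves annual totals in
        # expectation only; kept off for deterministic target recovery.
        shape = 1.5
        precip = precip * rng.gamma(shape, 1.0 / shape, size=precip.size)

    # River discharge index: precipitation-driven, unit mean over the base
    # period; stands in for the upstream-hydrology boundary condition.
    base_mask = (year_col >= BASE_WINDOW[0]) & (year_col <= BASE_WINDOW[1])
    base_mean_precip = precip[base_mask].mean()
    discharge = precip / base_mean_precip if base_mean_precip > 0 else np.zeros_like(precip)

    return pd.DataFrame(
        {
            "year": year_col,
            "doy": doy,
            "month": month,
            "season": np.where(is_monsoon, "monsoon", "dry"),
            "temp_C": temp,
            "precip_mm": precip,
            "discharge_index": discharge,
        }
    )


# ---------------------------------------------------------------------------
# Cyclones
# ---------------------------------------------------------------------------

WIND_BANDS_KMH = {"strong": (140.0, 250.0), "weak": (80.0, 140.0)}


@dataclass(frozen=True)
class CycloneEvent:
    """A single landfalling cyclone in the synthetic event set."""

    year: int
    doy: int
    intensity_class: str  # "strong" | "weak"
    wind_speed_kmh: float
    landfall_position: float  # fraction of coastline, 0-1

    def __post_init__(self) -> None:
        lo, hi = WIND_BANDS_KMH[self.intensity_class]
        if not (lo <= self.wind_speed_kmh < hi or (self.intensity_class == "strong" and self.wind_speed_kmh >= lo)):
            raise ValueError("wind speed outside intensity class band")


def generate_cyclones(
    rate_strong: float,
    rate_weak: float,
    years: Sequence[int],
    seed: int,
    freq_multiplier: float = 1.0,
) -> list[CycloneEvent]:
    """Draw a cyclone event sequence from homogeneous Poisson processes.

    ``rate_strong`` and ``rate_weak`` are per-decade occurrence rates; the
    annual intensity is ``rate / 10 * freq_multiplier``.  Landfalls are
    uniform along the coast and wind speeds uniform within the class band.
    """
    if rate_strong < 0 or rate_weak < 0:
        raise ValueError("cyclone rates must be >= 0")
    if freq_multiplier < 0:
        raise ValueError("frequency multiplier must be >= 0")
    rng = np.random.default_rng(seed)
    events: list[CycloneEvent] = []
    for cls, rate in (("strong", rate_strong), ("weak", rate_weak)):
        lam = rate / 10.0 * freq_multiplier
        lo, hi = WIND_BANDS_KMH[cls]
        for year in years:
            n = rng.poisson(lam)
            for _ in range(n):
                events.append(
                    CycloneEvent(
                        year=int(year),
                        doy=int(rng.integers(1, 366)),
                        intensity_class=cls,
                        wind_speed_kmh=float(rng.uniform(lo, hi)),
                        landfall_position=float(rng.uniform(0.0, 1.0)),
                    )
                )
    events.sort(key=lambda e: (e.year, e.doy, e.intensity_class, e.wind_speed_kmh))
    return events


# ---------------------------------------------------------------------------
# Annual socio-economic series
# ---------------------------------------------------------------------------

def population_series(config: WorldConfig, years: Optional[Iterable[int]] = None) -> pd.Series:
    """Annual population (millions): constant to 2015, then linear to 2050."""
    if years is None:
        years = range(SIM_START_YEAR, SIM_END_YEAR + 1)
    years = np.asarray(list(years))
    t0, t1 = RAMP_WINDOW
    frac = np.clip((years - t0) / (t1 - t0), 0.0, 1.0)
    values = config.population_start_millions + frac * (
        config.population_2050_millions - config.population_start_millions
    )
    return pd.Series(values, index=pd.Index(years, name="year"), name="population_millions")


def embankment_series(
    initial_height_cm: float,
    config: WorldConfig,
    years: Iterable[int],
) -> pd.Series:
    """Annual embankment heights (cm) under the world's maintenance policy.

    Heights change by ``embankment_rate_cm_per_yr`` from the first year of
    the span and are floored at zero.
    """
    if initial_height_cm <= 0:
        raise ValueError("initial embankment height must be positive")
    years = np.asarray(list(years))
    heights = initial_height_cm + config.embankment_rate_cm_per_yr * (years - years[0])
    return pd.Series(
        np.maximum(heights, 0.0), index=pd.Index(years, name="year"), name="embankment_cm"
    )


def econ_index(
    config: WorldConfig,
    base_year: int,
    years: Optional[Iterable[int]] = None,
) -> pd.Series:
    """Annual economic multiplier: 1 up to ``base_year``, then compounding
    at the world's growth rate (scenarios diverge only after the base year)."""
    if years is None:
        years = range(SIM_START_YEAR, SIM_END_YEAR + 1)
    years = np.asarray(list(years))
    if not (years.min() <= base_year <= years.max()):
        raise ConfigurationError("base_year outside the series span")
    values = (1.0 + config.econ_growth_per_yr) ** np.maximum(years - base_year, 0)
    return pd.Series(values, index=pd.Index(years, name="year"), name="econ_index")


def rice_tolerance(config: WorldConfig, year: float) -> float:
    """Rice salt-stress threshold (dS/m) for a given year.

    Linear ramp from the start to the end tolerance over 2015-2050,
    clamped outside the ramp window.
    """
    t0, t1 = RAMP_WINDOW
    frac = min(max((year - t0) / (t1 - t0), 0.0), 1.0)
    return config.rice_salt_tolerance_start_dS_m + frac * (
        config.rice_salt_tolerance_end_dS_m - config.rice_salt_tolerance_start_dS_m
    )


def unit_production_multiplier(config: WorldConfig, year: float) -> float:
    """Crop unit-production multiplier, ramping linearly 1 -> mid-century value."""
    t0, t1 = RAMP_WINDOW
    frac = min(max((year - t0) / (t1 - t0), 0.0), 1.0)
    return 1.0 + frac * (config.unit_production_multiplier_midcentury - 1.0)


# ---------------------------------------------------------------------------
# Experiment design (62-run ensemble)
# ---------------------------------------------------------------------------

#: Natural socio-economic variant of each world.
WORLD_NATURAL_VARIANT = {"positive": "more_sustainable", "negative": "less_sustainable"}

#: Natural SLR level of each world.
WORLD_NATURAL_SLR = {"positive": "low", "negative": "high"}

SLR_LEVELS = ("low", "high")
CYCLONE_SEQUENCES = (0, 1, 2)


def enumerate_runs(master_seed: int = 0) -> list[RunSpec]:
    """Full experiment design: 62 runs.

    36 base scenarios (2 worlds x 3 cyclone sequences x 3 socio-economic
    variants x 2 SLR levels) plus 26 one-at-a-time overrides (13 per
    world): a no-climate-change run, the alternative SLR level, +/-50%
    cyclone frequency, the alternative embankment policy, and the two
    non-natural development variants for each of population, economy,
    land cover and farming.
    """
    runs: list[RunSpec] = []
    for world in ("positive", "negative"):
        for seq in CYCLONE_SEQUENCES:
            for variant in SOCIO_VARIANTS:
                for slr_level in SLR_LEVELS:
                    runs.append(
                        RunSpec(
                            run_id=f"{world}-base-c{seq}-{variant}-slr_{slr_level}",
                            parent_world=world,
                            overridden_driver=None,
                            override_level=None,
                            seed=master_seed,
                            design=(
                                ("cyclone_seq", seq),
                                ("socio_variant", variant),
                                ("slr_level", slr_level),
                            ),
                        )
                    )

    for world in ("positive", "negative"):
        natural_variant = WORLD_NATURAL_VARIANT[world]
        natural_slr = WORLD_NATURAL_SLR[world]
        parent_design = (
            ("cyclone_seq", 0),
            ("socio_variant", natural_variant),
            ("slr_level", natural_slr),
        )

        def oat(driver: str, level: str) -> RunSpec:
            return RunSpec(
                run_id=f"{world}-oat-{driver.replace(' ', '_')}-{level.replace(' ', '_').replace('%', 'pct').replace('+', 'plus').replace('-', 'minus')}",
                parent_world=world,
                overridden_driver=driver,
                override_level=level,
                seed=master_seed,
                design=parent_design,
            )

        runs.append(oat("climate", "no climate change"))
        other_slr = "high" if natural_slr == "low" else "low"
        runs.append(oat("SLR", other_slr))
        runs.append(oat("cyclones", "+50%"))
        runs.append(oat("cyclones", "-50%"))
        other_polder = "declining" if world == "positive" else "maintained"
        runs.append(oat("polder", other_polder))
        for driver in ("population", "economy", "land cover", "farming"):
            for variant in SOCIO_VARIANTS:
                if variant != natural_variant:
                    runs.append(oat(driver, variant))

    assert len(runs) == 62
    return runs


def parent_run_id(world: str) -> str:
    """The base run representing a world's own storyline (OAT reference)."""
    variant = WORLD_NATURAL_VARIANT[world]
    slr_level = WORLD_NATURAL_SLR[world]
    return f"{world}-base-c0-{variant}-slr_{slr_level}"


def runs_manifest(runs: Sequence[RunSpec]) -> pd.DataFrame:
    """Tabular run manifest (one row per run) for CSV export."""
    rows = []
    for r in runs:
        row = {
            "run_id": r.run_id,
            "parent_world": r.parent_world,
            "overridden_driver": r.overridden_driver or "",
            "override_level": r.override_level or "",
            "seed": r.seed,
        }
        row.update(r.design_dict)
        rows.append(row)
    return pd.DataFrame(rows)
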