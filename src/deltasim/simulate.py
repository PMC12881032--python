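"""Integrated simulation of one scenario run.

Couples the driver series (climate, sea level, cyclones, population,
economy, embankments, farming practice), the annual flood state, the
daily soil water/salt balance, seasonal crop production and the monthly
household microsimulation into one annual indicator table per run.

Spatial scale: union cells (daily soil, annual flood); households are
simulated per archetype at region scale with population weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import crops as crops_mod
from .config import (
    RAMP_WINDOW,
    RunSpec,
    SeasonalDelta,
    WorldConfig,
    derive_seed,
)
from .crops import DEFAULT_CROPS, flood_damage_factor, salt_stress_factor, season_yield, temp_stress_factor, total_rice_production, water_stress_factor
from .flood import FloodParams, FloodResult, UnionCell, coastal_water_level, simulate_flood
from .households import CopingParams, HouseholdArchetype, HouseholdState, monthly_income, optimise_coping
from .indicators import gdp_per_capita, gini, poverty_rate
from .scenario import (
    econ_index,
    generate_climate,
    generate_cyclones,
    month_of_doy,
    population_series,
    rice_tolerance,
    slr_series,
    unit_production_multiplier,
)
from .soil import SoilParams, SoilState, region_salinity, step_soil_day
from .synthregion import CROP_FRACTION, RegionBaseline, farm_month_weights, make_climatology, region_baseline

# ---------------------------------------------------------------------------
# Driver variants for the experiment design
# ---------------------------------------------------------------------------

VARIANT_POPULATION_2050 = {
    "more_sustainable": 14.0,
    "business_as_usual": 12.5,
    "less_sustainable": 11.0,
}
VARIANT_ECON_GROWTH = {
    "more_sustainable": 0.025,
    "business_as_usual": 0.0155,
    "less_sustainable": 0.006,
}
VARIANT_FARMING = {  # (unit production multiplier, rice tolerance end dS/m)
    "more_sustainable": (1.2, 13.0),
    "business_as_usual": (1.1, 9.5),
    "less_sustainable": (1.0, 6.0),
}
VARIANT_LAND_COVER_SHIFT = {  # fractional cropped-area change by 2050
    "more_sustainable": 0.10,
    "business_as_usual": 0.0,
    "less_sustainable": -0.10,
}
SLR_LEVEL_CM = {"low": 38.5, "high": 73.5}
EMBANKMENT_POLICY_RATE = {"maintained": 0.0, "declining": -3.0}
CYCLONE_MULTIPLIER = {"+50%": 1.5, "-50%": 0.5, "historic": 1.0}

ZERO_DELTA = SeasonalDelta(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class EffectiveDrivers:
    """Fully resolved drivers of one run, after design and OAT override."""

    config: WorldConfig  # effective parameter bundle
    land_cover_shift: float
    cyclone_multiplier: float
    cyclone_sequence: int
    no_climate_change: bool


def resolve_drivers(spec: RunSpec) -> EffectiveDrivers:
    """Apply the base-design axes and the OAT override to the parent world."""
    from .config import load_world

    base = load_world(spec.parent_world)
    design = spec.design_dict
    variant = design.get("socio_variant", "business_as_usual")
    slr_level = design.get("slr_level", "low" if spec.parent_world == "positive" else "high")
    seq = int(design.get("cyclone_seq", 0))

    pop_2050 = VARIANT_POPULATION_2050[variant]
    growth = VARIANT_ECON_GROWTH[variant]
    unit_mult, tol_end = VARIANT_FARMING[variant]
    land_shift = VARIANT_LAND_COVER_SHIFT[variant]
    slr_cm = SLR_LEVEL_CM[slr_level]
    emb_rate = base.embankment_rate_cm_per_yr
    cyc_mult = 1.0
    no_climate = False

    driver = spec.overridden_driver
    level = spec.override_level
    if driver == "climate":
        no_climate = True
    elif driver == "SLR":
        slr_cm = SLR_LEVEL_CM[level]
    elif driver == "cyclones":
        cyc_mult = CYCLONE_MULTIPLIER[level]
    elif driver == "polder":
        emb_rate = EMBANKMENT_POLICY_RATE[level]
    elif driver == "population":
        pop_2050 = VARIANT_POPULATION_2050[level]
    elif driver == "economy":
        growth = VARIANT_ECON_GROWTH[level]
    elif driver == "farming":
        unit_mult, tol_end = VARIANT_FARMING[level]
    elif driver == "land cover":
        land_shift = VARIANT_LAND_COVER_SHIFT[level]

    cfg = replace(
        base,
        slr_midcentury_cm=slr_cm,
        temp_rise_C=ZERO_DELTA if no_climate else base.temp_rise_C,
        precip_change_frac=ZERO_DELTA if no_climate else base.precip_change_frac,
        population_2050_millions=pop_2050,
        embankment_rate_cm_per_yr=emb_rate,
        unit_production_multiplier_midcentury=unit_mult,
        rice_salt_tolerance_end_dS_m=max(tol_end, base.rice_salt_tolerance_start_dS_m),
        econ_growth_per_yr=growth,
    )
    return EffectiveDrivers(
        config=cfg,
        land_cover_shift=land_shift,
        cyclone_multiplier=cyc_mult,
        cyclone_sequence=seq,
        no_climate_change=no_climate,
    )


# ---------------------------------------------------------------------------
# Simulation settings
# ---------------------------------------------------------------------------

@dataclass
class SimulationSettings:
    start_year: int = 2000
    end_year: int = 2050
    econ_base_year: int = 2015
    soil: SoilParams = field(default_factory=SoilParams)
    flood: FloodParams = field(default_factory=FloodParams)
    coping: CopingParams = field(default_factory=CopingParams)
    climatology: Optional[pd.DataFrame] = None
    income_scale: float = 1.0
    irrigation_fraction: float = 0.7  # of boro crop water deficit
    river_base_ec_dS_m: float = 0.8
    river_ec_slr_gain_per_m: float = 1.5
    river_ec_inland_efolding: float = 0.6
    flood_event_days: int = 5
    boro_unlock_water_factor: float = 0.5
    boro_area_fraction: float = 0.5
    rice_salt_slope_per_dS_m: float = 0.12
    # cyclone income/asset shock severities per intensity class
    shock_severity: dict = field(default_factory=lambda: {"strong": 0.5, "weak": 0.15})
    asset_exposure: dict = field(
        default_factory=lambda: {"farm_based": 0.4, "mixed": 0.25, "service": 0.15}
    )


# Season windows in day-of-year (no-leap): monsoon "aman" rice and dry
# "boro" rice (boro treated within the calendar year, Jan-Apr).
AMAN_DOYS = (166, 319)
BORO_DOYS = (1, 120)

HOUSEHOLD_GROUPS6 = (
    "farm_based-landless",
    "farm_based-landed",
    "mixed-landless",
    "mixed-landed",
    "service-landless",
    "service-landed",
)


def household_group6(arch: HouseholdArchetype) -> str:
    land = "landless" if arch.landholding_class == "landless" else "landed"
    return f"{arch.group}-{land}"


def _kc_profile(crop, season_doys: tuple[int, int]) -> np.ndarray:
    """Daily kc over a season window from the four-stage profile."""
    d0, d1 = season_doys
    n = d1 - d0 + 1
    stages = np.concatenate(
        [np.full(l, k) for l, k in zip(crop.stage_lengths_days, crop.kc_per_stage)]
    )
    if len(stages) >= n:
        return stages[:n]
    return np.concatenate([stages, np.full(n - len(stages), crop.kc_per_stage[-1])])


def run_simulation(
    spec: RunSpec,
    region: Sequence[UnionCell],
    archetypes: Sequence[HouseholdArchetype],
    settings: Optional[SimulationSettings] = None,
) -> pd.DataFrame:
    """Simulate one run and return the annual indicator table.

    Columns: the six headline indicators (plus annual-maximum soil
    salinity) and per-group poverty rates for the six household groups.
    Deterministic for identical (spec, settings).
    """
    if settings is None:
        settings = SimulationSettings()
    drv = resolve_drivers(spec)
    cfg = drv.config
    cells = list(region)
    n_cells = len(cells)
    areas = np.array([c.area_km2 for c in cells])
    coast_dist = np.array([c.coast_distance for c in cells])
    poldered = np.array([c.poldered for c in cells])
    emb0 = np.array([c.embankment_height_m for c in cells])

    y0, y1 = settings.start_year, settings.end_year
    years = np.arange(y0, y1 + 1)

    clim = settings.climatology if settings.climatology is not None else make_climatology()
    weather = generate_climate(
        cfg, clim, seed=derive_seed(spec.seed, "weather"), noise=False,
        start_year=y0, end_year=y1,
    )
    slr = slr_series(cfg, years)
    pop = population_series(cfg, years)
    econ = econ_index(cfg, settings.econ_base_year, years)
    cyclones = generate_cyclones(
        cfg.cyclone_rate_strong_per_decade,
        cfg.cyclone_rate_weak_per_decade,
        years,
        seed=derive_seed(spec.seed, "cyclones", drv.cyclone_sequence),
        freq_multiplier=drv.cyclone_multiplier,
    )
    events_by_year: dict[int, list] = {}
    for ev in cyclones:
        events_by_year.setdefault(ev.year, []).append(ev)

    baseline = region_baseline(cells)
    pop0 = pop.iloc[0]

    aman = DEFAULT_CROPS["aman_rice"]
    boro = DEFAULT_CROPS["boro_rice"]
    kc_aman = _kc_profile(aman, AMAN_DOYS)
    kc_boro = _kc_profile(boro, BORO_DOYS)

    soil_p = settings.soil
    state = SoilState(
        water_mm=np.full(n_cells, soil_p.field_capacity * 0.5 * 1000.0 * 0.8),
        salt_load=np.full(n_cells, soil_p.field_capacity * 0.5 * 1000.0 * 0.8 * 5.0),
        root_depth_m=0.5,
    )

    hh_state = {
        a.archetype_id: HouseholdState(
            savings=a.initial_savings * settings.income_scale,
            debt=0.0,
            assets_value=a.assets_value * settings.income_scale,
        )
        for a in archetypes
    }
    month_w = {a.archetype_id: farm_month_weights(a.seasonal_amplitude) for a in archetypes}

    records = []
    weather_by_year = dict(tuple(weather.groupby("year", sort=False)))

    for year in years:
        wy = weather_by_year[year]
        temp = wy["temp_C"].to_numpy()
        precip = wy["precip_mm"].to_numpy()
        doys = wy["doy"].to_numpy()
        annual_precip = float(precip.sum())
        discharge = float(wy["discharge_index"].mean())
        sea_cm = float(slr.loc[year])
        ramp_y = min(max((year - RAMP_WINDOW[0]) / (RAMP_WINDOW[1] - RAMP_WINDOW[0]), 0.0), 1.0)

        emb_y = np.where(
            poldered,
            np.maximum(emb0 + cfg.embankment_rate_cm_per_yr / 100.0 * max(0, year - RAMP_WINDOW[0]), 0.0),
            0.0,
        )
        cells_y = [
            replace(c, embankment_height_m=float(h)) for c, h in zip(cells, emb_y)
        ]
        events = events_by_year.get(int(year), [])
        flood_y: FloodResult = simulate_flood(
            cells_y, sea_cm, discharge, annual_precip, events, settings.flood
        )

        # Daily flood forcing from cyclone events: each event floods its
        # footprint for a few days with linearly receding depth.
        flood_depth_daily = np.zeros((365, n_cells))
        flood_ec = settings.flood.coast_salinity_dS_m * np.exp(
            -coast_dist / settings.flood.salinity_inland_efolding
        )
        elev = np.array([c.elevation_m for c in cells])
        for ev in events:
            level = coastal_water_level(cells_y, sea_cm, [ev], settings.flood)
            excess = np.maximum(level - elev - np.where(poldered, emb_y, 0.0), 0.0)
            for k in range(settings.flood_event_days):
                d = ev.doy - 1 + k
                if d < 365:
                    recede = 1.0 - k / settings.flood_event_days
                    flood_depth_daily[d] = np.maximum(flood_depth_daily[d], excess * recede)

        # Irrigation salinity for the year (saltier rivers with SLR, fresher inland).
        ec_irr = (
            settings.river_base_ec_dS_m
            * (1.0 + settings.river_ec_slr_gain_per_m * sea_cm / 100.0)
            * np.exp(-coast_dist / settings.river_ec_inland_efolding)
        )

        et0 = crops_mod.reference_et(temp, doys)
        in_aman = (doys >= AMAN_DOYS[0]) & (doys <= AMAN_DOYS[1])
        in_boro = (doys >= BORO_DOYS[0]) & (doys <= BORO_DOYS[1])
        kc = np.full(365, 0.5)
        kc[in_aman] = kc_aman
        kc[in_boro] = kc_boro
        etm = kc * et0

        ec_daily_sum = np.zeros(n_cells)
        ec_daily_max = np.zeros(n_cells)
        eta_aman = np.zeros(n_cells)
        eta_boro = np.zeros(n_cells)
        root = np.where(in_aman | in_boro, 0.5, 0.3)

        for d in range(365):
            state.root_depth_m = root[d]
            irr = np.zeros(n_cells)
            irr_ec = ec_irr
            if in_boro[d]:
                deficit = max(0.0, etm[d] - precip[d])
                irr = np.full(n_cells, settings.irrigation_fraction * deficit)
            state, diag = step_soil_day(
                state,
                soil_p,
                precip[d],
                etm[d],
                irrigation=(irr, irr_ec),
                flood=(flood_depth_daily[d] * 1000.0, flood_ec),
            )
            ec = np.asarray(state.ec_dS_m)
            ec_daily_sum += ec
            ec_daily_max = np.maximum(ec_daily_max, ec)
            if in_aman[d]:
                eta_aman += diag["et_actual"]
            if in_boro[d]:
                eta_boro += diag["et_actual"]

        ec_mean = ec_daily_sum / 365.0
        mean_sal = region_salinity(ec_mean, areas)
        max_sal = region_salinity(ec_daily_max, areas)

        # --- Crop production -------------------------------------------
        tol = rice_tolerance(cfg, year)
        mult = unit_production_multiplier(cfg, year)
        cropped = areas * CROP_FRACTION * (1.0 + drv.land_cover_shift * ramp_y)

        etm_aman = float(etm[in_aman].sum())
        etm_boro = float(etm[in_boro].sum())
        ec_aman = _period_mean_ec(ec_mean)  # proxy: annual mean per union
        wf_aman = np.array(
            [water_stress_factor(min(e, etm_aman), etm_aman, aman.ky) for e in eta_aman]
        )
        sf_aman = np.asarray(salt_stress_factor(ec_aman, tol, settings.rice_salt_slope_per_dS_m))
        tf_aman = temp_stress_factor(temp[in_aman], aman.temp_limits_C)
        ff_aman = np.array(
            [
                flood_damage_factor(flood_depth_daily[in_aman, i], aman.flood_kill_depth_m, aman.flood_kill_days)
                for i in range(n_cells)
            ]
        )
        yield_aman = (
            aman.potential_yield_t_ha * mult * wf_aman * sf_aman * tf_aman * ff_aman
        )

        wf_boro = np.array(
            [water_stress_factor(min(e, etm_boro), etm_boro, boro.ky) for e in eta_boro]
        )
        sf_boro = np.asarray(salt_stress_factor(ec_aman, tol, settings.rice_salt_slope_per_dS_m))
        tf_boro = temp_stress_factor(temp[in_boro], boro.temp_limits_C)
        yield_boro = boro.potential_yield_t_ha * mult * wf_boro * sf_boro * tf_boro
        boro_unlocked = wf_boro >= settings.boro_unlock_water_factor
        boro_area = cropped * settings.boro_area_fraction * boro_unlocked

        production_t = total_rice_production(
            np.concatenate([yield_aman, yield_boro]),
            np.concatenate([cropped, boro_area]),
        )
        farm_value_month = production_t * baseline.rice_price_per_t / 12.0

        # --- Households -------------------------------------------------
        pop_factor = float(pop0 / pop.loc[year])
        cropped_ratio = float(cropped.sum() * 100.0 / baseline.cropped_area_ha)
        econ_y = float(econ.loc[year])
        shock_by_month = np.zeros(13)
        for ev in events:
            m = int(month_of_doy(np.array([ev.doy]))[0])
            shock_by_month[m] = max(shock_by_month[m], settings.shock_severity[ev.intensity_class])

        poor_frac = {}
        hungry_frac = {}
        annual_income = {}
        for arch in archetypes:
            st = hh_state[arch.archetype_id]
            needs = arch.monthly_food_need + arch.monthly_nonfood_need
            line = baseline.poverty_line_per_capita * arch.members
            wgt = month_w[arch.archetype_id]
            poor_m = 0
            hungry_m = 0
            income_y = 0.0
            for m in range(1, 13):
                shock = shock_by_month[m]
                inc = monthly_income(
                    arch,
                    farm_value_month * pop_factor * (1.0 - shock),
                    baseline.labour_demand_pm * cropped_ratio * pop_factor * wgt[m - 1],
                    1.0 - 0.5 * shock,
                    1.0,
                    econ_y,
                    income_scale=settings.income_scale,
                    wage_rate=settings.coping.wage_rate,
                    month_weight_farm=wgt[m - 1],
                )
                if shock > 0:
                    st = replace(
                        st,
                        assets_value=st.assets_value
                        * (1.0 - settings.asset_exposure[arch.group] * shock),
                    )
                total_inc = sum(inc.values())
                _, st = optimise_coping(
                    st,
                    total_inc,
                    needs,
                    line,
                    food_need=arch.monthly_food_need,
                    fixed_costs=arch.fixed_livelihood_costs * settings.income_scale,
                    params=settings.coping,
                )
                poor_m += st.poor_this_month
                hungry_m += st.hungry_this_month
                income_y += total_inc
            hh_state[arch.archetype_id] = st
            poor_frac[arch.archetype_id] = poor_m / 12.0
            hungry_frac[arch.archetype_id] = hungry_m / 12.0
            annual_income[arch.archetype_id] = income_y

        pw = np.array([a.weight * a.members for a in archetypes])
        pf = np.array([poor_frac[a.archetype_id] for a in archetypes])
        incomes = np.array([annual_income[a.archetype_id] for a in archetypes])
        hw = np.array([a.weight for a in archetypes])
        members = np.array([a.members for a in archetypes])

        rec = {
            "year": int(year),
            "inundated_area_km2": flood_y.inundated_area_km2,
            "mean_soil_salinity_dS_m": mean_sal,
            "max_soil_salinity_dS_m": max_sal,
            "total_rice_t": production_t,
            "poverty_rate_pct": poverty_rate(pf, pw),
            "gini": gini(incomes, hw),
            "gdp_per_capita": gdp_per_capita(
                float(np.sum(hw * incomes)), float(np.sum(hw * members))
            ),
        }
        for g in HOUSEHOLD_GROUPS6:
            mask = np.array([household_group6(a) == g for a in archetypes])
            if mask.any():
                rec[f"poverty_pct_{g}"] = poverty_rate(pf[mask], pw[mask])
        records.append(rec)

    return pd.DataFrame(records).set_index("year")


def _period_mean_ec(ec_mean: np.ndarray) -> np.ndarray:
    return ec_mean
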