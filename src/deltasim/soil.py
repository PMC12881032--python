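"""Daily water and salt balance of the root zone, per union cell.

A single-bucket store: water enters as rain, irrigation, infiltrating
flood water and capillary rise, and leaves as evapotranspiration, deep
percolation (above field capacity) and surface drainage (above
saturation).  Salt travels with the water that carries it: inputs add
their conductivity-weighted load, percolation leaches a configurable
fraction of the dissolved load, surface drainage removes load at the
current concentration.  Soil salinity is the dissolved load divided by
the stored water, expressed directly in dS/m (the load unit is dS/m x mm
so the conversion is linear and exact).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SoilParams:
    porosity: float = 0.45
    field_capacity: float = 0.30
    wilting_point: float = 0.10
    root_zone_max_m: float = 1.0
    drainage_coeff_per_day: float = 0.1
    capillary_rate_mm_day: float = 0.2
    capillary_salinity_dS_m: float = 8.0
    leaching_efficiency: float = 0.9
    flood_infiltration_frac: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.wilting_point < self.field_capacity <= self.porosity <= 1.0):
            raise ValueError("need 0 <= wilting_point < field_capacity <= porosity <= 1")
        if not (0.0 <= self.leaching_efficiency <= 1.0):
            raise ValueError("leaching efficiency must be in [0, 1]")
        if min(self.drainage_coeff_per_day, self.capillary_rate_mm_day) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class SoilState:
    """Water depth (mm), dissolved salt load (dS/m x mm) and root depth (m)."""

    water_mm: ArrayLike
    salt_load: ArrayLike
    root_depth_m: ArrayLike = 0.5

    @property
    def ec_dS_m(self) -> ArrayLike:
        w = np.asarray(self.water_mm, dtype=float)
        s = np.asarray(self.salt_load, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ec = np.where(w > 0, s / np.maximum(w, 1e-12), 0.0)
        return ec if ec.ndim else float(ec)


def step_soil_day(
    state: SoilState,
    params: SoilParams,
    precip_mm: ArrayLike,
    et_demand_mm: ArrayLike,
    irrigation: tuple[ArrayLike, ArrayLike] = (0.0, 0.0),
    flood: tuple[ArrayLike, ArrayLike] = (0.0, 0.0),
    drainage_open: bool = True,
) -> tuple[SoilState, dict]:
    """Advance the soil store by one day.

    ``irrigation`` and ``flood`` are (water depth mm, EC dS/m) pairs; a
    fixed fraction of standing flood water infiltrates.  Returns the new
    state and a diagnostics dict holding every flux so that mass balance
    can be closed externally.  ET demand exceeding the store is capped
    and flagged (``et_capped``).
    """
    W = np.asarray(state.water_mm, dtype=float).copy()
    S = np.asarray(state.salt_load, dtype=float).copy()
    root = np.asarray(state.root_depth_m, dtype=float)

    P = np.maximum(np.asarray(precip_mm, dtype=float), 0.0)
    ET_dem = np.maximum(np.asarray(et_demand_mm, dtype=float), 0.0)
    irr_mm, irr_ec = (np.maximum(np.asarray(v, dtype=float), 0.0) for v in irrigation)
    flood_mm, flood_ec = (np.maximum(np.asarray(v, dtype=float), 0.0) for v in flood)
    sat_store = params.porosity * root * 1000.0
    fc_store = params.field_capacity * root * 1000.0
    wp_store = params.wilting_point * root * 1000.0

    # Inputs: rain and irrigation first, then flood infiltration capped
    # by the remaining pore space (a saturated profile takes no more).
    W = W + P + irr_mm
    S = S + irr_mm * irr_ec
    f_inf = np.minimum(
        flood_mm * params.flood_infiltration_frac, np.maximum(sat_store - W, 0.0)
    )
    W = W + f_inf
    S = S + f_inf * flood_ec

    # Capillary rise only while the profile is below field capacity.
    cap = np.where(W < fc_store, params.capillary_rate_mm_day, 0.0)
    W = W + cap
    S = S + cap * params.capillary_salinity_dS_m

    # Evapotranspiration removes water only, down to the wilting point.
    et_act = np.minimum(ET_dem, np.maximum(W - wp_store, 0.0))
    et_capped = np.any(et_act < ET_dem)
    W = W - et_act

    # Deep percolation above the field-capacity store leaches salt.
    perc = params.drainage_coeff_per_day * np.maximum(W - fc_store, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        perc_frac = np.where(W > 0, perc / np.maximum(W, 1e-12), 0.0)
    leached = params.leaching_efficiency * S * perc_frac
    W = W - perc
    S = S - leached

    # Surface drainage of water above saturation, at current concentration.
    drained = np.zeros_like(W)
    salt_drained = np.zeros_like(S)
    if drainage_open:
        drained = np.maximum(W - sat_store, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            conc = np.where(W > 0, S / np.maximum(W, 1e-12), 0.0)
        salt_drained = conc * drained
        W = W - drained
        S = S - salt_drained

    new_state = SoilState(water_mm=W, salt_load=S, root_depth_m=state.root_depth_m)
    diag = {
        "precip": P,
        "irrigation": irr_mm,
        "flood_infiltrated": f_inf,
        "capillary": cap,
        "et_actual": et_act,
        "et_capped": bool(et_capped),
        "percolation": perc,
        "salt_in": irr_mm * irr_ec + f_inf * flood_ec + cap * params.capillary_salinity_dS_m,
        "salt_leached": leached,
        "drained": drained,
        "salt_drained": salt_drained,
    }
    return new_state, diag


def annual_salinity_stats(daily_ec: np.ndarray) -> tuple[float, float]:
    """(annual maximum, annual mean) of a daily soil-salinity series."""
    arr = np.asarray(daily_ec, dtype=float)
    if arr.size == 0:
        raise ValueError("empty salinity series")
    return float(arr.max()), float(arr.mean())


def region_salinity(per_union_stat: np.ndarray, areas_km2: np.ndarray) -> float:
    """Area-weighted regional mean of a per-union salinity statistic."""
    areas = np.asarray(areas_km2, dtype=float)
    return float(np.average(np.asarray(per_union_stat, dtype=float), weights=areas))
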