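"""Crop production with water, salt, temperature and flood limitations.

Reference evapotranspiration uses the Hargreaves-Samani equation (the
only forcing generated is temperature); crop water demand follows the
FAO crop-coefficient approach and yield responds to water deficit through
the FAO-33 linear yield-response factor Ky.  Salinity stress is the
Maas-Hoffman threshold-slope response, temperature stress a trapezoidal
daily suitability, and flood damage a depth-duration kill rule.  The four
stress factors combine multiplicatively by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


@dataclass(frozen=True)
class CropParams:
    name: str
    stage_lengths_days: tuple[int, int, int, int]
    kc_per_stage: tuple[float, float, float, float]
    ky: float
    salt_threshold_dS_m: float
    salt_slope_per_dS_m: float
    temp_limits_C: tuple[float, float, float, float]  # (min, opt_lo, opt_hi, max)
    flood_kill_depth_m: float
    flood_kill_days: int
    potential_yield_t_ha: float

    def __post_init__(self) -> None:
        if min(self.stage_lengths_days) <= 0:
            raise ValueError("stage lengths must be positive")
        if min(self.kc_per_stage) <= 0 or self.ky <= 0:
            raise ValueError("kc and ky must be positive")
        if self.salt_slope_per_dS_m < 0 or self.salt_threshold_dS_m < 0:
            raise ValueError("salt response parameters must be >= 0")


# Default parameter sets.  Monsoon (aman) and dry-season (boro) rice follow
# FAO-56 style coefficients; flood tolerances are nominal placeholders in
# the absence of published values and are meant to be overridden in config.
DEFAULT_CROPS: dict[str, CropParams] = {
    "aman_rice": CropParams(
        name="aman_rice",
        stage_lengths_days=(30, 30, 60, 30),
        kc_per_stage=(1.05, 1.10, 1.20, 0.90),
        ky=1.1,
        salt_threshold_dS_m=6.0,
        salt_slope_per_dS_m=0.12,
        temp_limits_C=(12.0, 20.0, 32.0, 42.0),
        flood_kill_depth_m=0.6,
        flood_kill_days=6,
        potential_yield_t_ha=4.0,
    ),
    "boro_rice": CropParams(
        name="boro_rice",
        stage_lengths_days=(30, 30, 50, 30),
        kc_per_stage=(1.05, 1.10, 1.20, 0.90),
        ky=1.2,
        salt_threshold_dS_m=6.0,
        salt_slope_per_dS_m=0.12,
        temp_limits_C=(10.0, 18.0, 33.0, 42.0),
        flood_kill_depth_m=0.6,
        flood_kill_days=6,
        potential_yield_t_ha=5.0,
    ),
    # Brackish aquaculture ponds behave as a highly salt-tolerant "crop".
    "aquaculture": CropParams(
        name="aquaculture",
        stage_lengths_days=(30, 60, 120, 30),
        kc_per_stage=(1.0, 1.0, 1.0, 1.0),
        ky=0.5,
        salt_threshold_dS_m=25.0,
        salt_slope_per_dS_m=0.05,
        temp_limits_C=(10.0, 18.0, 34.0, 42.0),
        flood_kill_depth_m=1.5,
        flood_kill_days=10,
        potential_yield_t_ha=2.0,
    ),
}


def crops_to_csv(crops: dict[str, CropParams], path) -> None:
    """Write a crop parameter table to CSV (one row per crop)."""
    import pandas as pd

    rows = []
    for c in crops.values():
        rows.append(
            {
                "name": c.name,
                **{f"stage_len_{i+1}": v for i, v in enumerate(c.stage_lengths_days)},
                **{f"kc_{i+1}": v for i, v in enumerate(c.kc_per_stage)},
                "ky": c.ky,
                "salt_threshold_dS_m": c.salt_threshold_dS_m,
                "salt_slope_per_dS_m": c.salt_slope_per_dS_m,
                **dict(
                    zip(
                        ("temp_min_C", "temp_opt_lo_C", "temp_opt_hi_C", "temp_max_C"),
                        c.temp_limits_C,
                    )
                ),
                "flood_kill_depth_m": c.flood_kill_depth_m,
                "flood_kill_days": c.flood_kill_days,
                "potential_yield_t_ha": c.potential_yield_t_ha,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def crops_from_csv(path) -> dict[str, CropParams]:
    """Load a crop parameter table written by :func:`crops_to_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[str, CropParams] = {}
    for r in df.itertuples():
        out[str(r.name)] = CropParams(
            name=str(r.name),
            stage_lengths_days=tuple(int(getattr(r, f"stage_len_{i+1}")) for i in range(4)),
            kc_per_stage=tuple(float(getattr(r, f"kc_{i+1}")) for i in range(4)),
            ky=float(r.ky),
            salt_threshold_dS_m=float(r.salt_threshold_dS_m),
            salt_slope_per_dS_m=float(r.salt_slope_per_dS_m),
            temp_limits_C=(
                float(r.temp_min_C),
                float(r.temp_opt_lo_C),
                float(r.temp_opt_hi_C),
                float(r.temp_max_C),
            ),
            flood_kill_depth_m=float(r.flood_kill_depth_m),
            flood_kill_days=int(r.flood_kill_days),
            potential_yield_t_ha=float(r.potential_yield_t_ha),
        )
    return out


def extraterrestrial_radiation(doy: np.ndarray, latitude_deg: float) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56 eq. 21."""
    doy = np.asarray(doy, dtype=float)
    phi = np.deg2rad(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    return (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )


def reference_et(
    tmean_C: np.ndarray,
    doy: np.ndarray,
    latitude_deg: float = 22.5,
    diurnal_range_C: float = 10.0,
    tmax_C: np.ndarray | None = None,
    tmin_C: np.ndarray | None = None,
) -> np.ndarray:
    """Hargreaves-Samani reference evapotranspiration ET0 (mm/day).

    ET0 = 0.0023 (Tmean + 17.8) sqrt(Tmax - Tmin) Ra / lambda, with Ra
    converted to equivalent evaporation by 0.408.  When daily extremes
    are not supplied a fixed diurnal range is assumed.
    """
    tmean = np.asarray(tmean_C, dtype=float)
    if np.any(tmean < -10) or np.any(tmean > 50):
        raise ValueError("implausible mean temperature")
    if tmax_C is None:
        tmax = tmean + diurnal_range_C / 2.0
        tmin = tmean - diurnal_range_C / 2.0
    else:
        tmax = np.asarray(tmax_C, dtype=float)
        tmin = np.asarray(tmin_C, dtype=float)
    ra = extraterrestrial_radiation(doy, latitude_deg)
    et0 = 0.0023 * 0.408 * ra * (tmean + 17.8) * np.sqrt(np.maximum(tmax - tmin, 0.0))
    return np.maximum(et0, 0.0)


def water_stress_factor(eta: float, etm: float, ky: float) -> float:
    """FAO-33 yield response: 1 - Ky (1 - ETa/ETm), clipped to [0, 1]."""
    if etm <= 0:
        raise ValueError("maximum-ET must be positive")
    if not (0.0 <= eta <= etm * (1.0 + 1e-9)):
        raise ValueError("need 0 <= ETa <= ETm")
    return float(np.clip(1.0 - ky * (1.0 - eta / etm), 0.0, 1.0))


def salt_stress_factor(ec, threshold: float = 6.0, slope: float = 0.12):
    """Maas-Hoffman: full yield below the threshold, linear decline above."""
    ec_arr = np.asarray(ec, dtype=float)
    if np.any(ec_arr < 0) or threshold < 0 or slope < 0:
        raise ValueError("salinity inputs must be >= 0")
    f = np.where(ec_arr <= threshold, 1.0, np.maximum(0.0, 1.0 - slope * (ec_arr - threshold)))
    return f if f.ndim else float(f)


def temp_stress_factor(daily_temps_C: Sequence[float], limits: tuple[float, float, float, float]) -> float:
    """Mean daily trapezoidal temperature suitability over a growth period.

    Daily suitability is 1 inside the optimal band, declines linearly to 0
    at the absolute limits, and is 0 beyond them.
    """
    tmin, opt_lo, opt_hi, tmax = limits
    t = np.asarray(daily_temps_C, dtype=float)
    f = np.ones_like(t)
    below = t < opt_lo
    f[below] = np.clip((t[below] - tmin) / max(opt_lo - tmin, 1e-9), 0.0, 1.0)
    above = t > opt_hi
    f[above] = np.clip((tmax - t[above]) / max(tmax - opt_hi, 1e-9), 0.0, 1.0)
    return float(f.mean())


def flood_damage_factor(
    daily_depth_m: Sequence[float],
    kill_depth_m: float,
    kill_days: int,
) -> float:
    """Depth-duration flood damage over a season.

    Severity is the longest consecutive spell with standing water at or
    above the kill depth, as a fraction of the kill duration (capped at
    1); the factor is 1 - severity, so half the kill duration halves the
    yield and a spell reaching the kill duration destroys the crop.
    """
    depth = np.asarray(daily_depth_m, dtype=float)
    above = depth >= kill_depth_m
    longest = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    severity = min(1.0, longest / max(kill_days, 1))
    return 1.0 - severity


def season_yield(
    crop: CropParams,
    factors: Sequence[float],
    unit_multiplier: float = 1.0,
) -> float:
    """Actual yield (t/ha): potential x unit multiplier x product of stresses."""
    f = np.asarray(factors, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("stress factors must lie in [0, 1]")
    return float(crop.potential_yield_t_ha * unit_multiplier * np.prod(f))


def total_rice_production(
    yields_t_ha: np.ndarray,
    cropped_areas_km2: np.ndarray,
) -> float:
    """Regional production (tonnes): sum of yield x area, 1 km2 = 100 ha."""
    y = np.asarray(yields_t_ha, dtype=float)
    a = np.asarray(cropped_areas_km2, dtype=float)
    return float(np.sum(y * a * 100.0))
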