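"""Scenario configuration: world parameter bundles and run specifications.

A "world" is an internally consistent mid-century storyline for the delta,
expressed as a bundle of driver parameters (sea-level rise, climate
anomalies, cyclone occurrence rates, population, embankment maintenance,
farming practice and economic growth).  Two stock worlds are shipped:
``positive`` (improving trends) and ``negative`` (deteriorating trends).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import yaml

#: Simulation period covered by generated driver series.
SIM_START_YEAR = 1985
SIM_END_YEAR = 2050

#: Base (reference) period and mid-century window used to express anomalies.
BASE_WINDOW = (2000, 2015)
MIDCENTURY_WINDOW = (2040, 2055)

#: Window over which practice/embankment ramps are applied.
RAMP_WINDOW = (2015, 2050)

#: Month numbers of the monsoon season (June-October); the rest is "dry".
MONSOON_MONTHS = (6, 7, 8, 9, 10)


@dataclass(frozen=True)
class SeasonalDelta:
    """An anomaly expressed annually and per season (monsoon / dry)."""

    annual: float
    monsoon: float
    dry: float


@dataclass(frozen=True)
class WorldConfig:
    """Parameter bundle describing one mid-century world.

    Sea-level rise is relative to the year 2000; temperature and
    precipitation anomalies are mid-century (2040-2055) contrasts against
    the 2000-2015 base period.  Cyclone rates are per decade.
    """

    name: str
    slr_midcentury_cm: float
    temp_rise_C: SeasonalDelta
    precip_change_frac: SeasonalDelta
    cyclone_rate_strong_per_decade: float
    cyclone_rate_weak_per_decade: float
    population_start_millions: float
    population_2050_millions: float
    embankment_rate_cm_per_yr: float
    unit_production_multiplier_midcentury: float
    rice_salt_tolerance_start_dS_m: float
    rice_salt_tolerance_end_dS_m: float
    econ_growth_per_yr: float

    def __post_init__(self) -> None:
        if self.cyclone_rate_strong_per_decade < 0 or self.cyclone_rate_weak_per_decade < 0:
            raise ValueError("cyclone rates must be >= 0")
        if not (self.rice_salt_tolerance_end_dS_m >= self.rice_salt_tolerance_start_dS_m >= 0):
            raise ValueError("rice salt tolerance must satisfy end >= start >= 0")
        if self.population_start_millions <= 0 or self.population_2050_millions <= 0:
            raise ValueError("populations must be positive")
        if self.econ_growth_per_yr < 0:
            raise ValueError("economic growth must be >= 0")
        if self.unit_production_multiplier_midcentury <= 0:
            raise ValueError("unit production multiplier must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# The two stock storylines.  SLR: slow median vs fast high-end scenario;
# both worlds warm by ~2 C and dry, the negative world only slightly;
# population constant at 14 M vs declining to 11 M through outmigration;
# embankments maintained vs declining 3 cm/yr; improved crop varieties
# (+20% unit production, rice salt tolerance ramping 6->13 dS/m) vs
# traditional practice; 2.5%/yr vs 0.6%/yr economic growth.
_WORLDS: dict[str, WorldConfig] = {
    "positive": WorldConfig(
        name="positive",
        slr_midcentury_cm=38.5,
        temp_rise_C=SeasonalDelta(annual=1.8, monsoon=1.5, dry=2.2),
        precip_change_frac=SeasonalDelta(annual=-0.22, monsoon=-0.19, dry=-0.53),
        cyclone_rate_strong_per_decade=0.4,
        cyclone_rate_weak_per_decade=4.2,
        population_start_millions=14.0,
        population_2050_millions=14.0,
        embankment_rate_cm_per_yr=0.0,
        unit_production_multiplier_midcentury=1.2,
        rice_salt_tolerance_start_dS_m=6.0,
        rice_salt_tolerance_end_dS_m=13.0,
        econ_growth_per_yr=0.025,
    ),
    "negative": WorldConfig(
        name="negative",
        slr_midcentury_cm=73.5,
        temp_rise_C=SeasonalDelta(annual=1.9, monsoon=1.5, dry=2.5),
        precip_change_frac=SeasonalDelta(annual=-0.04, monsoon=-0.02, dry=-0.16),
        cyclone_rate_strong_per_decade=0.4,
        cyclone_rate_weak_per_decade=4.2,
        population_start_millions=14.0,
        population_2050_millions=11.0,
        embankment_rate_cm_per_yr=-3.0,
        unit_production_multiplier_midcentury=1.0,
        rice_salt_tolerance_start_dS_m=6.0,
        rice_salt_tolerance_end_dS_m=6.0,
        econ_growth_per_yr=0.006,
    ),
}


class ConfigurationError(ValueError):
    """Raised for unknown world names or invalid scenario configuration."""


def load_world(name: str) -> WorldConfig:
    """Return the parameter bundle for a named world.

    Parameters
    ----------
    name
        ``"positive"`` or ``"negative"`` (case-insensitive).
    """
    key = str(name).strip().lower()
    if key not in _WORLDS:
        raise ConfigurationError(
            f"unknown world {name!r}; valid options: {sorted(_WORLDS)}"
        )
    return _WORLDS[key]


def world_from_yaml(path) -> WorldConfig:
    """Load a WorldConfig from a YAML file mirroring the field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for fld in ("temp_rise_C", "precip_change_frac"):
        if isinstance(raw.get(fld), dict):
            raw[fld] = SeasonalDelta(**raw[fld])
    return WorldConfig(**raw)


def world_to_yaml(config: WorldConfig, path) -> None:
    """Write a WorldConfig to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Run specifications (experiment design)
# ---------------------------------------------------------------------------

#: Drivers that can be varied one at a time.
OAT_DRIVERS = (
    "climate",
    "SLR",
    "cyclones",
    "polder",
    "population",
    "economy",
    "land cover",
    "farming",
)

#: Drivers counted as climatic in the poverty attribution.
CLIMATIC_DRIVERS = ("climate", "SLR", "cyclones")

#: Socio-economic development variants used in the design.
SOCIO_VARIANTS = ("more_sustainable", "business_as_usual", "less_sustainable")


@dataclass(frozen=True)
class RunSpec:
    """One simulation of the ensemble.

    ``overridden_driver`` is ``None`` for the base scenarios; one-at-a-time
    (OAT) runs override exactly one driver of their parent world.  The
    ``design`` mapping records the base-scenario axes (cyclone sequence,
    socio-economic variant, SLR level) so that the 36-member base design is
    fully reproducible and user-editable.
    """

    run_id: str
    parent_world: str
    overridden_driver: Optional[str] = None
    override_level: Optional[str] = None
    seed: int = 0
    design: tuple = ()  # sorted (key, value) pairs; hashable

    def __post_init__(self) -> None:
        if self.overridden_driver is not None and self.overridden_driver not in OAT_DRIVERS:
            raise ConfigurationError(
                f"unknown driver {self.overridden_driver!r}; valid: {OAT_DRIVERS}"
            )

    @property
    def design_dict(self) -> dict:
        return dict(self.design)


def derive_seed(master_seed: int, *streams) -> int:
    """Derive a deterministic sub-stream seed below 2**31.

    Runs that share a master seed but differ in one driver keep every other
    driver's random stream identical (common random numbers), because each
    stream is keyed by name rather than by draw order.
    """
    import hashlib

    key = ":".join([str(master_seed), *map(str, streams)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)
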