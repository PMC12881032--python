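"""Reduced-form flood model over union cells, and its statistical emulator.

The flood model stands in for the high-fidelity coastal hydrodynamics: a
cell floods from the coast when the annual maximum water level (sea level
+ tide + cyclone surge) exceeds its ground elevation plus any embankment
freeboard, and from rivers/rain when the discharge-weighted precipitation
excess is large.  The emulator couples partial least squares regression
with canonical correlation analysis to learn the mapping from forcing
summaries to flood summaries, mirroring how surrogate models replace slow
physics-based models in integrated assessments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import CCA, PLSRegression

from .scenario import CycloneEvent


@dataclass(frozen=True)
class UnionCell:
    """One spatial unit (a 'union'): the model's cell."""

    union_id: str
    area_km2: float
    elevation_m: float
    poldered: bool
    embankment_height_m: float
    coast_distance: float  # fraction of maximum inland distance, 0 at coast
    population: float
    alongshore: float = 0.5  # position along the coastline, 0-1

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError("cell area must be positive")
        if self.embankment_height_m < 0:
            raise ValueError("embankment height must be >= 0")


@dataclass(frozen=True)
class FloodParams:
    """Free parameters of the reduced-form flood rule.

    The high-fidelity models these would be fitted against are external,
    so tide, surge and decay constants are configurable with defaults
    chosen to give a plausible mix of protected and unprotected flooding.
    """

    tide_amplitude_m: float = 1.0
    surge_height_m: dict = field(
        default_factory=lambda: {"strong": 3.5, "weak": 1.5}
    )
    surge_alongshore_halfwidth: float = 0.25
    surge_inland_efolding: float = 0.5  # coast_distance units
    fluvial_coeff: float = 0.5  # fraction per (discharge x m precip excess)
    precip_excess_threshold_mm: float = 1800.0
    polder_drainage_efficiency: float = 0.8  # fluvial suppression inside polders
    coast_salinity_dS_m: float = 25.0
    salinity_inland_efolding: float = 0.3
    fresh_flood_salinity_dS_m: float = 0.5


@dataclass
class FloodResult:
    """Annual-maximum flood state per cell plus the regional aggregate."""

    union_ids: list
    inundated_fraction: np.ndarray  # [0, 1] per cell
    mean_depth_m: np.ndarray
    floodwater_salinity_dS_m: np.ndarray
    areas_km2: np.ndarray

    @property
    def inundated_area_km2(self) -> float:
        return float(np.sum(self.inundated_fraction * self.areas_km2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "union_id": self.union_ids,
                "inundated_fraction": self.inundated_fraction,
                "mean_depth_m": self.mean_depth_m,
                "floodwater_salinity_dS_m": self.floodwater_salinity_dS_m,
                "area_km2": self.areas_km2,
            }
        )


def coastal_water_level(
    cells: Sequence[UnionCell],
    sea_level_cm: float,
    cyclones: Sequence[CycloneEvent],
    params: FloodParams,
) -> np.ndarray:
    """Annual maximum coastal water level (m above datum) at each cell.

    The base level is sea level plus tide amplitude; each cyclone adds a
    surge that decays along the coast away from its landfall and inland.
    """
    alongshore = np.array([c.alongshore for c in cells])
    inland = np.array([c.coast_distance for c in cells])
    base = sea_level_cm / 100.0 + params.tide_amplitude_m
    level = np.full(len(cells), base)
    hw = params.surge_alongshore_halfwidth
    for ev in cyclones:
        h = params.surge_height_m[ev.intensity_class]
        surge = (
            h
            * np.exp(-0.5 * ((alongshore - ev.landfall_position) / hw) ** 2)
            * np.exp(-inland / params.surge_inland_efolding)
        )
        level = np.maximum(level, base + surge)
    return level


def simulate_flood(
    cells: Sequence[UnionCell],
    sea_level_cm: float,
    discharge_index: float,
    annual_precip_mm: float,
    cyclones: Sequence[CycloneEvent],
    params: Optional[FloodParams] = None,
) -> FloodResult:
    """One calendar year of flooding for a list of cells.

    Coastal flooding: a poldered cell floods when the annual maximum
    water level exceeds elevation + embankment height; an unprotected
    cell floods when the water level exceeds elevation.  Depth is the
    positive excess.  Fluvial/pluvial flooding adds an inundated fraction
    proportional to discharge_index times the precipitation excess,
    suppressed inside polders by the drainage efficiency.  The two
    mechanisms are combined cell-wise by taking the larger footprint.
    """
    if params is None:
        params = FloodParams()
    cells = list(cells)
    n = len(cells)
    elev = np.array([c.elevation_m for c in cells])
    emb = np.array(
        [c.embankment_height_m if c.poldered else 0.0 for c in cells]
    )
    poldered = np.array([c.poldered for c in cells])
    inland = np.array([c.coast_distance for c in cells])
    areas = np.array([c.area_km2 for c in cells])

    level = coastal_water_level(cells, sea_level_cm, cyclones, params)
    coastal_excess = level - elev - emb
    coastal_flooded = coastal_excess > 0.0
    coastal_frac = coastal_flooded.astype(float)
    coastal_depth = np.where(coastal_flooded, coastal_excess, 0.0)

    excess_mm = max(0.0, annual_precip_mm - params.precip_excess_threshold_mm)
    fluvial_frac = np.clip(
        params.fluvial_coeff * max(discharge_index, 0.0) * excess_mm / 1000.0,
        0.0,
        1.0,
    ) * np.where(poldered, 1.0 - params.polder_drainage_efficiency, 1.0)
    fluvial_depth = 0.5 * fluvial_frac  # shallow ponding, m

    frac = np.maximum(coastal_frac, fluvial_frac)
    depth = np.maximum(coastal_depth, fluvial_depth)

    saline = params.coast_salinity_dS_m * np.exp(
        -inland / params.salinity_inland_efolding
    )
    salinity = np.where(
        coastal_flooded,
        saline,
        np.where(fluvial_frac > 0, params.fresh_flood_salinity_dS_m, 0.0),
    )

    return FloodResult(
        union_ids=[c.union_id for c in cells],
        inundated_fraction=frac,
        mean_depth_m=depth,
        floodwater_salinity_dS_m=salinity,
        areas_km2=areas,
    )


# ---------------------------------------------------------------------------
# PLS + CCA emulator
# ---------------------------------------------------------------------------

class Emulator:
    """Multivariate surrogate combining PLS regression with CCA.

    Inputs and outputs are standardised; PLS extracts ``n_components``
    latent directions of the input that covary with the outputs, CCA
    aligns those scores with the output space, and a linear map from the
    canonical input variates reconstructs the outputs.  With
    ``n_components = 0`` the emulator degenerates to the training-mean
    predictor.
    """

    def __init__(self, n_components: int, clip01_cols: Optional[Sequence[int]] = None):
        if n_components < 0:
            raise ValueError("n_components must be >= 0")
        self.n_components = n_components
        self.clip01_cols = list(clip01_cols) if clip01_cols is not None else []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "Emulator":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        n, p = X.shape
        q = Y.shape[1]
        k = self.n_components
        if n < k + 2:
            raise ValueError("need at least n_components + 2 training rows")
        self._x_mean, self._x_std = X.mean(0), X.std(0)
        self._y_mean, self._y_std = Y.mean(0), Y.std(0)
        self._x_std = np.where(self._x_std > 0, self._x_std, 1.0)
        self._y_std = np.where(self._y_std > 0, self._y_std, 1.0)
        Xs = (X - self._x_mean) / self._x_std
        Ys = (Y - self._y_mean) / self._y_std
        if k == 0:
            self._null = True
            return self
        self._null = False
        rank = np.linalg.matrix_rank(Xs)
        # PLS components are bounded by the input dimension and sample
        # size; the CCA stage caps itself at the output dimension below.
        if k > min(p, n - 1) or k > rank:
            raise ValueError(
                f"n_components={k} exceeds usable rank "
                f"(p={p}, n={n}, rank={rank})"
            )
        self._pls = PLSRegression(n_components=k, scale=False)
        self._pls.fit(Xs, Ys)
        T = self._pls.transform(Xs)
        kc = min(k, q, np.linalg.matrix_rank(T))
        self._cca = CCA(n_components=kc, max_iter=1000)
        with np.errstate(all="ignore"):
            self._cca.fit(T, Ys)
        U = self._cca.transform(T)
        # Linear reconstruction of the standardised outputs from the
        # canonical input variates (intercept-free: both are centred).
        A = np.column_stack([U, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, Ys, rcond=None)
        self._coef = coef
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_std
        T = self._pls.transform(Xs)
        return self._cca.transform(T)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._x_mean.size:
            raise ValueError(
                f"expected {self._x_mean.size} input columns, got {X.shape[1]}"
            )
        if self._null:
            Yhat = np.tile(self._y_mean, (X.shape[0], 1))
        else:
            U = self._transform(X)
            A = np.column_stack([U, np.ones(X.shape[0])])
            Yhat = A @ self._coef * self._y_std + self._y_mean
        for j in self.clip01_cols:
            Yhat[:, j] = np.clip(Yhat[:, j], 0.0, 1.0)
        return Yhat


def fit_emulator(
    inputs: np.ndarray,
    outputs: np.ndarray,
    n_components: int,
    clip01_cols: Optional[Sequence[int]] = None,
) -> Emulator:
    """Fit the PLS+CCA emulator on forcing/flood summary matrices."""
    return Emulator(n_components, clip01_cols=clip01_cols).fit(inputs, outputs)


def predict_emulator(model: Emulator, x: np.ndarray) -> np.ndarray:
    """Deterministic emulator prediction for one or more forcing rows."""
    return model.predict(x)
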