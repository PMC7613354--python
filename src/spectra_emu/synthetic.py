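"""Synthetic ground truth: a toy canopy spectral model and data generators.

Field campaigns that pair crop biophysical variables with hyperspectral
reflectance are rarely public, so this module provides a deterministic toy
canopy model mapping the six standard variables — leaf chlorophyll content
(LCC, ug/cm^2), leaf area index (LAI, m^2/m^2), fractional vegetation cover
(FVC), biomass (kg/m^2), leaf water content (LWC, g/cm^2) and canopy water
content (CWC, g/cm^2) — to reflectance on a chosen band grid.  It
reproduces the qualitative features the emulation benchmark relies on:

* a red edge near 715 nm (steep visible-to-NIR transition),
* chlorophyll absorption dips at 480 and 670 nm that saturate with LCC,
* water absorption near 1450 and 1940 nm scaling with CWC,
* a linear bare-soil line mixed in by canopy cover,
* elevated multiplicative noise inside the atmospheric water windows.

All constants are invented; they are a stand-in for field spectra, not a
physical radiative transfer model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .datasets import BandGrid, LabeledSpectralDataset
from .scene import VariableMapStack

__all__ = [
    "VARIABLE_NAMES",
    "ToyCanopyParams",
    "NoiseModel",
    "sensor_preset",
    "toy_canopy_spectrum",
    "generate_dataset",
    "generate_variable_maps",
    "WATER_WINDOWS_NM",
]

VARIABLE_NAMES = ["LCC", "LAI", "FVC", "biomass", "LWC", "CWC"]

VARIABLE_UNITS = {
    "LCC": "ug/cm^2",
    "LAI": "m^2/m^2",
    "FVC": "unitless",
    "biomass": "kg/m^2",
    "LWC": "g/cm^2",
    "CWC": "g/cm^2",
}

#: Atmospheric water-absorption windows (nm) where noise is elevated.
WATER_WINDOWS_NM = ((1350.0, 1460.0), (1790.0, 1960.0))

# Uniform sampling ranges of the independent variables; the rest are derived.
LAI_RANGE = (0.0, 7.0)
LCC_RANGE = (5.0, 80.0)
LWC_RANGE = (0.002, 0.03)

CANOPY_EXTINCTION = 0.5  # k in FVC = 1 - exp(-k * LAI)


@dataclass(frozen=True)
class ToyCanopyParams:
    """Constants of the toy canopy reflectance model (all invented)."""

    soil_base: float = 0.10
    soil_slope: float = 0.25
    vis_level: float = 0.05
    nir_level: float = 0.50
    red_edge_center: float = 715.0
    red_edge_width: float = 18.0
    chl_dip_red: tuple[float, float, float] = (670.0, 25.0, 0.75)  # center, sigma, amp
    chl_dip_blue: tuple[float, float, float] = (480.0, 35.0, 0.55)
    chl_half_saturation: float = 40.0
    water_dip_1: tuple[float, float, float] = (1450.0, 45.0, 1.0)
    water_dip_2: tuple[float, float, float] = (1940.0, 60.0, 1.4)
    water_extinction: float = 60.0  # beta multiplying CWC
    canopy_extinction: float = CANOPY_EXTINCTION


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise, elevated in the water windows."""

    sigma0: float = 0.01
    water_window_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be >= 0")
        if self.water_window_factor < 1:
            raise ValueError("water_window_factor must be >= 1")

    def sigma_per_band(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        in_window = np.zeros(wl.shape, dtype=bool)
        for lo, hi in WATER_WINDOWS_NM:
            in_window |= (wl >= lo) & (wl <= hi)
        return self.sigma0 * (1.0 + (self.water_window_factor - 1.0) * in_window)


def sensor_preset(label: str) -> BandGrid:
    """Band grids mimicking the two benchmark sensors.

    ``chris62``: 62 uniformly spaced centers on 400-1050 nm (VNIR
    spaceborne); ``hymap125``: 125 uniformly spaced centers on 430-2490 nm
    (full-range airborne).
    """
    if label == "chris62":
        return BandGrid(np.linspace(400.0, 1050.0, 62), "chris62", 1.0)
    if label == "hymap125":
        return BandGrid(np.linspace(430.0, 2490.0, 125), "hymap125", 1.0)
    raise ValueError(f"unknown sensor preset {label!r}")


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def toy_canopy_spectrum(
    variables: dict[str, float] | np.ndarray,
    grid: BandGrid,
    params: ToyCanopyParams = ToyCanopyParams(),
) -> np.ndarray:
    """Noiseless reflectance spectrum for one set of biophysical variables.

    The spectrum is a cover-weighted mixture of a linear soil line and a
    vegetation curve: logistic red-edge baseline, LCC-saturating
    chlorophyll dips, and CWC-driven water absorption.  The all-zero
    variable vector is the bare-soil convention and returns the pure soil
    line.  Output is clipped to [0, 1].
    """
    if isinstance(variables, dict):
        v = np.array([variables[name] for name in VARIABLE_NAMES], dtype=float)
    else:
        v = np.asarray(variables, dtype=float)
        if v.shape != (len(VARIABLE_NAMES),):
            raise ValueError(f"expected {len(VARIABLE_NAMES)} variables, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("variables must be finite")
    if np.any(v < 0):
        raise ValueError("variables must be non-negative")
    lcc, lai, _fvc, _biomass, _lwc, cwc = v
    wl = grid.wavelengths

    soil = np.clip(params.soil_base + params.soil_slope * (wl - 400.0) / 2000.0, 0.0, 1.0)

    base = params.vis_level + (params.nir_level - params.vis_level) / (
        1.0 + np.exp(-(wl - params.red_edge_center) / params.red_edge_width)
    )
    c1, s1, a1 = params.chl_dip_red
    c2, s2, a2 = params.chl_dip_blue
    chl = 1.0 - (lcc / (lcc + params.chl_half_saturation)) * (
        a1 * _gauss(wl, c1, s1) + a2 * _gauss(wl, c2, s2)
    )
    w1c, w1s, w1a = params.water_dip_1
    w2c, w2s, w2a = params.water_dip_2
    water = np.exp(
        -params.water_extinction
        * cwc
        * (w1a * _gauss(wl, w1c, w1s) + w2a * _gauss(wl, w2c, w2s))
    )
    veg = base * chl * water

    fvc_eff = 1.0 - np.exp(-params.canopy_extinction * lai)
    return np.clip(fvc_eff * veg + (1.0 - fvc_eff) * soil, 0.0, 1.0)


def _sample_variables(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n vegetation variable vectors with realistic collinearity.

    LAI, LCC and LWC are independent uniforms; FVC, CWC and biomass are
    derived from them, mirroring how these quantities co-vary in field
    campaigns (and deliberately stressing regressors with collinear
    inputs).
    """
    lai = rng.uniform(*LAI_RANGE, size=n)
    lcc = rng.uniform(*LCC_RANGE, size=n)
    lwc = rng.uniform(*LWC_RANGE, size=n)
    fvc = 1.0 - np.exp(-CANOPY_EXTINCTION * lai)
    cwc = lai * lwc
    biomass = 0.8 * lai * (1.0 + 0.1 * rng.standard_normal(n))
    biomass = np.clip(biomass, 0.0, None)
    return np.column_stack([lcc, lai, fvc, biomass, lwc, cwc])


def generate_dataset(
    n: int,
    grid: BandGrid | str = "hymap125",
    params: ToyCanopyParams = ToyCanopyParams(),
    noise: NoiseModel | None = None,
    soil_fraction: float = 0.2,
    seed: int = 0,
) -> LabeledSpectralDataset:
    """Generate a labeled dataset of n samples on the given band grid.

    A ``soil_fraction`` share of the samples (round(n * fraction), placed
    last) are bare-soil spectra with all six variables set to zero.
    Observed reflectance is the toy model times ``(1 + eta)`` with
    ``eta ~ N(0, sigma_b(lambda)^2)``; noisy values are clipped to
    [0, 1.2].  The generator is a pure function of its configuration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= soil_fraction < 1.0:
        raise ValueError("soil_fraction must lie in [0, 1)")
    if isinstance(grid, str):
        grid = sensor_preset(grid)
    if noise is None:
        noise = NoiseModel(seed=seed)

    rng = np.random.default_rng(seed)
    n_soil = int(round(soil_fraction * n))
    n_veg = n - n_soil
    X = np.zeros((n, len(VARIABLE_NAMES)))
    if n_veg:
        X[:n_veg] = _sample_variables(n_veg, rng)

    Y = np.empty((n, len(grid)))
    for i in range(n):
        Y[i] = toy_canopy_spectrum(X[i], grid, params)

    sigma = noise.sigma_per_band(grid.wavelengths)
    if noise.sigma0 > 0:
        noise_rng = np.random.default_rng(noise.seed)
        eta = noise_rng.standard_normal(Y.shape) * sigma
        Y = np.clip(Y * (1.0 + eta), 0.0, 1.2)

    return LabeledSpectralDataset(
        variable_names=list(VARIABLE_NAMES),
        X=X,
        Y=Y,
        band_grid=grid,
        variable_units=dict(VARIABLE_UNITS),
    )


def generate_variable_maps(
    rows: int,
    cols: int,
    pattern: str = "parcels",
    seed: int = 0,
    n_parcels: int = 25,
    soil_fraction: float = 0.2,
    nodata_fraction: float = 0.0,
    nodata_value: float = -999.0,
) -> VariableMapStack:
    """Generate a rows x cols stack of the six biophysical-variable maps.

    ``parcels`` tessellates the scene into Voronoi-style fields, each with
    one variable vector (some all-zero bare-soil parcels); ``smooth``
    draws per-variable smooth random fields with the derived variables
    (FVC, CWC, biomass) recomputed from LAI/LWC so the construction
    invariants hold pixel-wise.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rng = np.random.default_rng(seed)
    D = len(VARIABLE_NAMES)
    data = np.empty((rows, cols, D))

    if pattern == "parcels":
        n_parcels = max(1, min(n_parcels, rows * cols))
        centers = np.column_stack(
            [rng.uniform(0, rows, n_parcels), rng.uniform(0, cols, n_parcels)]
        )
        vectors = _sample_variables(n_parcels, rng)
        n_soil = int(round(soil_fraction * n_parcels))
        if n_soil:
            soil_idx = rng.choice(n_parcels, size=n_soil, replace=False)
            vectors[soil_idx] = 0.0
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d2 = ((pix[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        data = vectors[labels].reshape(rows, cols, D)
    elif pattern == "smooth":
        sigma_px = max(1.0, 0.08 * max(rows, cols))
        lai = _smooth_field(rows, cols, rng, sigma_px, LAI_RANGE)
        lcc = _smooth_field(rows, cols, rng, sigma_px, LCC_RANGE)
        lwc = _smooth_field(rows, cols, rng, sigma_px, LWC_RANGE)
        fvc = 1.0 - np.exp(-CANOPY_EXTINCTION * lai)
        cwc = lai * lwc
        biomass = 0.8 * lai
        data = np.stack([lcc, lai, fvc, biomass, lwc, cwc], axis=-1)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    mask = np.ones((rows, cols), dtype=bool)
    if nodata_fraction > 0:
        n_bad = int(round(nodata_fraction * rows * cols))
        if n_bad:
            bad = rng.choice(rows * cols, size=n_bad, replace=False)
            mask.ravel()[bad] = False
            flat = data.reshape(-1, D)
            flat[bad] = nodata_value
    return VariableMapStack(
        data=data,
        variable_names=list(VARIABLE_NAMES),
        nodata_value=nodata_value,
        mask=mask,
    )


def _smooth_field(
    rows: int,
    cols: int,
    rng: np.random.Generator,
    sigma_px: float,
    value_range: tuple[float, float],
) -> np.ndarray:
    raw = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), sigma_px)
    lo, hi = raw.min(), raw.max()
    unit = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    return value_range[0] + unit * (value_range[1] - value_range[0])
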