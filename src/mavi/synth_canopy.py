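"""Synthetic multi-angle canopy reflectance with known LAI.

A turbid-medium mixture of a leaf and a soil template through the gap
fraction ``P = exp(−G·LAI/cos θ)`` (G = 0.5, spherical leaf angles),
with a kernel-style multiplicative BRDF factor on the vegetation term:
minimum exactly at nadir, a back-scatter hotspot ramp, a mild forward
gain, and extra asymmetry confined to the visible bands so that the red
edge and NIR stay near-symmetric while visible bands are strongly
asymmetric.  Noise is multiplicative (reflectance is positive): one
calibration-style scalar per spectrum plus independent per-band jitter.

With noise off the generator is a pure function of
(scenario, vza, params).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from mavi.config import DEFAULT_VZAS
from mavi.errors import DataError
from mavi.spectral_core import (
    COVERAGE_LEVELS,
    MultiAngleDataset,
    NITROGEN_LEVELS,
    SampleRecord,
    Spectrum,
    STAGES,
    default_grid,
)

log = logging.getLogger(__name__)

G_FACTOR = 0.5  # extinction coefficient, spherical leaf-angle distribution


@dataclass(frozen=True)
class CanopyScenario:
    """One plot: LAI plus the drivers of its optical appearance."""

    lai: float
    chl_proxy: float        # relative pigment level in [0, 1], driven by nitrogen
    soil_brightness: float  # relative level in [0, 1], driven by coverage
    stage: str = "budding"

    def __post_init__(self) -> None:
        if not np.isfinite(self.lai) or self.lai <= 0:
            raise DataError(f"lai must be finite and > 0; got {self.lai}")
        if not 0.0 <= self.chl_proxy <= 1.0:
            raise DataError(f"chl_proxy must be in [0, 1]; got {self.chl_proxy}")
        if not 0.0 <= self.soil_brightness <= 1.0:
            raise DataError(f"soil_brightness must be in [0, 1]; got {self.soil_brightness}")
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class BrdfParams:
    """Angular multiplier shape parameters.

    The multiplier is >= 1 everywhere with its minimum exactly at nadir;
    ``hotspot_amp`` sets the back-scatter brightening at −60°,
    ``hotspot_width`` its ramp shape, ``forward_slope`` a small gain per
    forward degree, and ``band_asymmetry`` the extra hotspot weight
    applied to visible bands only.
    """

    hotspot_amp: float = 0.45
    hotspot_width: float = 60.0     # degrees; ramp exponent = 60/width
    forward_slope: float = 0.0005   # per degree, forward-scatter only
    band_asymmetry: float = 0.6     # visible-band extra hotspot weight
    noise_sd: float = 0.02          # multiplicative noise sd; 0 disables
    sym_amp: float = 0.35           # symmetric (sec θ − 1) amplitude
    nir_hotspot: float = 0.05       # residual hotspot weight outside the visible
    structure_sd: float = 0.25      # per-observation log-normal jitter of the angular term
    edge_shift_nm: float = 2.0      # apparent red-edge shift per unit (sec θ − 1)
    edge_jitter_nm: float = 2.5     # sd of the edge-shift jitter per unit (sec θ − 1)

    def __post_init__(self) -> None:
        if self.hotspot_width <= 0:
            raise DataError("hotspot_width must be positive")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        for name in ("hotspot_amp", "forward_slope", "band_asymmetry", "sym_amp", "nir_hotspot"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def _band_sensitivity(wavelength_nm: np.ndarray) -> np.ndarray:
    # angular sensitivity by band: strongly absorbing blue/red troughs
    # barely respond to view angle, green and NIR respond strongly
    wl = np.asarray(wavelength_nm, dtype=float)
    green = np.exp(-(((wl - 550.0) / 40.0) ** 2))
    nir = 1.0 / (1.0 + np.exp(-(wl - 725.0) / 12.0))
    return 0.25 + 0.75 * np.clip(green + nir, 0.0, 1.0)


def _asymmetry_weight(wavelength_nm: np.ndarray) -> np.ndarray:
    # hotspot asymmetry confined to the visible, peaking in the green
    wl = np.asarray(wavelength_nm, dtype=float)
    return np.exp(-(((wl - 550.0) / 60.0) ** 2))


def brdf_multiplier(vza_deg: float, wavelength_nm: np.ndarray, params: BrdfParams) -> np.ndarray:
    """Per-wavelength angular multiplier; 1 exactly at nadir."""
    if abs(vza_deg) >= 90.0:
        raise DataError(f"|vza| must be < 90 degrees; got {vza_deg}")
    theta = np.radians(vza_deg)
    sym = params.sym_amp * (1.0 / np.cos(theta) - 1.0)
    forward = params.forward_slope * vza_deg if vza_deg > 0 else 0.0
    if vza_deg < 0:
        ramp = (abs(vza_deg) / 60.0) ** (60.0 / params.hotspot_width)
        hot = params.hotspot_amp * ramp
    else:
        hot = 0.0
    sens = _band_sensitivity(wavelength_nm)
    asym = _asymmetry_weight(wavelength_nm)
    return 1.0 + sens * (sym + forward + params.nir_hotspot * hot) + params.band_asymmetry * asym * hot


def leaf_template(
    chl_proxy: float, grid: np.ndarray | None = None, edge_offset_nm: float = 0.0
) -> Spectrum:
    """Leaf-scale reflectance shape: blue and red troughs deepening with
    pigment level, a fixed green peak at 550 nm, a sigmoid red edge whose
    inflection shifts to longer wavelengths as pigment rises (the classic
    red-edge shift), and an NIR plateau near 0.45."""
    if not 0.0 <= chl_proxy <= 1.0:
        raise DataError(f"chl_proxy must be in [0, 1]; got {chl_proxy}")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    blue = 0.045 - 0.015 * chl_proxy
    green = 0.160 - 0.050 * chl_proxy
    red = 0.100 - 0.045 * chl_proxy  # stays well above blue: OPIVI's denominator
    knots = np.array([350.0, 450.0, 500.0, 550.0, 600.0, 670.0, 690.0])
    values = np.array(
        [blue + 0.005, blue, 0.5 * (blue + green), green, 0.5 * (green + red), red, red]
    )
    visible = PchipInterpolator(knots, values, extrapolate=False)
    vis = np.where(wl <= 690.0, visible(np.clip(wl, 350.0, 690.0)), red)
    nir = 0.45 - 0.03 * np.exp(-(((wl - 1200.0) / 80.0) ** 2))  # mild water feature
    edge_center = 706.0 + 14.0 * chl_proxy + edge_offset_nm  # red-edge shift with pigment
    edge = 1.0 / (1.0 + np.exp(-(wl - edge_center) / 11.0))
    return Spectrum(wl, vis * (1.0 - edge) + nir * edge)


def soil_template(soil_brightness: float, grid: np.ndarray | None = None) -> Spectrum:
    """Featureless soil line rising gently with wavelength, scaled by the
    relative brightness level."""
    if not 0.0 <= soil_brightness <= 1.0:
        raise DataError(f"soil_brightness must be in [0, 1]; got {soil_brightness}")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    base = 0.10 + 0.20 * (wl - 350.0) / 950.0
    return Spectrum(wl, base * (0.5 + soil_brightness))


def gap_fraction(lai: float, vza_deg: float, g: float = G_FACTOR) -> float:
    """P = exp(−g·LAI/cos θ), in (0, 1], decreasing in LAI and in sec θ."""
    if abs(vza_deg) >= 90.0:
        raise DataError(f"|vza| must be < 90 degrees; got {vza_deg}")
    return float(np.exp(-g * lai / np.cos(np.radians(vza_deg))))


def canopy_reflectance(
    scenario: CanopyScenario,
    vza_deg: float,
    brdf: BrdfParams = BrdfParams(),
    rng: np.random.Generator | int | None = None,
) -> Spectrum:
    """Top-of-canopy reflectance at one view zenith angle.

    ``R(λ, θ) = f(θ, λ)·(1 − P)·R_leaf(λ) + P·R_soil(λ)``, the BRDF
    factor acting on the vegetation term (bare soil is treated as
    Lambertian, so a vanishing LAI returns the soil template at every
    angle).  Noise is applied only when ``brdf.noise_sd > 0`` and an rng
    or seed is supplied.
    """
    if abs(vza_deg) >= 90.0:
        raise DataError(f"|vza| must be < 90 degrees; got {vza_deg}")
    grid = default_grid()
    noisy = brdf.noise_sd > 0 and rng is not None
    if noisy:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # oblique views lengthen the path through the canopy, shifting the
    # apparent red edge; jittered per observation when noise is on
    airmass = 1.0 / np.cos(np.radians(vza_deg)) - 1.0
    edge_offset = brdf.edge_shift_nm * airmass
    if noisy:
        edge_offset += float(rng.normal(0.0, brdf.edge_jitter_nm * airmass))
    leaf = leaf_template(scenario.chl_proxy, grid, edge_offset).reflectance
    soil = soil_template(scenario.soil_brightness, grid).reflectance
    p_gap = gap_fraction(scenario.lai, vza_deg)
    f = brdf_multiplier(vza_deg, grid, brdf)
    # anisotropy scales with shadowing, strongest at intermediate canopy
    # closure; per-observation structural jitter only when noise is on
    closure = 1.0 - gap_fraction(scenario.lai, 0.0)
    aniso = 0.5 + 3.0 * closure * (1.0 - closure)
    if noisy:
        aniso *= float(np.exp(rng.normal(0.0, brdf.structure_sd)))
    refl = (1.0 + aniso * (f - 1.0)) * (1.0 - p_gap) * leaf + p_gap * soil
    if noisy:
        scalar = rng.normal(0.0, brdf.noise_sd)
        per_band = rng.normal(0.0, brdf.noise_sd, size=grid.size)
        refl = refl * (1.0 + scalar) * (1.0 + per_band)
    return Spectrum(grid, np.clip(refl, 0.0, None))


#: Median LAI (cm^2/cm^2) by growth stage at the zero-nitrogen level.
STAGE_BASE_LAI = {"budding": 0.9, "flowering": 1.6}
#: Median soil-brightness level by coverage method (film mulch bright,
#: straw mulch dark).
COVERAGE_BRIGHTNESS = {"SM": 0.25, "FM": 0.75, "NM": 0.50}
LAI_NITROGEN_GAIN = 0.30   # median LAI multiplier step per nitrogen rank
LAI_SIGMA = 0.25           # log-normal sigma of LAI draws
CHL_BASE, CHL_STEP, CHL_SD = 0.15, 0.16, 0.04


def simulate_dataset(
    reps: int = 3,
    stages: Sequence[str] = ("budding", "flowering"),
    vzas: Sequence[float] = DEFAULT_VZAS,
    brdf: BrdfParams = BrdfParams(),
    seed: int = 0,
) -> MultiAngleDataset:
    """Full-factorial synthetic campaign: 5 nitrogen levels x 3 coverage
    methods x ``reps`` plots per stage, each observed at every VZA.

    Median LAI rises with nitrogen rank (log-normal draws) and is higher
    at flowering than at budding; pigment level tracks nitrogen;
    identical seeds give identical datasets.
    """
    if reps < 1:
        raise DataError("reps must be >= 1")
    if len(vzas) == 0:
        raise DataError("vza list must be non-empty")
    for stage in stages:
        if stage not in STAGES:
            raise DataError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    observations: dict[tuple[str, float], Spectrum] = {}
    metadata: dict[str, SampleRecord] = {}
    counter = 0
    for stage in stages:
        for n_rank, nitrogen in enumerate(NITROGEN_LEVELS):
            for coverage in COVERAGE_LEVELS:
                for _rep in range(reps):
                    counter += 1
                    sid = f"S{counter:04d}"
                    median_lai = STAGE_BASE_LAI[stage] * (1.0 + LAI_NITROGEN_GAIN * n_rank)
                    lai = float(median_lai * np.exp(rng.normal(0.0, LAI_SIGMA)))
                    chl = float(np.clip(CHL_BASE + CHL_STEP * n_rank + rng.normal(0.0, CHL_SD), 0.0, 1.0))
                    soil = float(
                        np.clip(COVERAGE_BRIGHTNESS[coverage] + rng.normal(0.0, 0.05), 0.0, 1.0)
                    )
                    scenario = CanopyScenario(lai=lai, chl_proxy=chl, soil_brightness=soil, stage=stage)
                    metadata[sid] = SampleRecord(sid, stage, nitrogen, coverage, lai)
                    for vza in vzas:
                        observations[(sid, float(vza))] = canopy_reflectance(scenario, vza, brdf, rng)
    log.info("simulated %d samples x %d VZAs = %d observations", counter, len(vzas), len(observations))
    return MultiAngleDataset(observations=observations, metadata=metadata)
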