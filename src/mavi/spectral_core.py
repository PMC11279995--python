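"""Core spectral types, Savitzky-Golay preprocessing, and tabular I/O.

A :class:`Spectrum` is reflectance on a strictly increasing wavelength
grid; a :class:`MultiAngleDataset` joins per-(sample, view-zenith-angle)
spectra to per-sample metadata including the measured leaf area index.
Long-format CSV is the on-disk interchange format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from mavi.config import WAVELENGTH_MAX, WAVELENGTH_MIN
from mavi.errors import DataError

log = logging.getLogger(__name__)

NITROGEN_LEVELS = ("N0", "N1", "N2", "N3", "N4")
#: Nitrogen application rates, kg per hectare, by level.
NITROGEN_RATES_KG_HM2 = {"N0": 0.0, "N1": 70.0, "N2": 140.0, "N3": 210.0, "N4": 280.0}
COVERAGE_LEVELS = ("SM", "FM", "NM")  # straw mulch, film mulch, no mulch
STAGES = ("budding", "flowering")

SPECTRA_COLUMNS = ["sample_id", "vza_deg", "wavelength_nm", "reflectance"]
METADATA_COLUMNS = ["sample_id", "stage", "nitrogen", "coverage", "lai"]


@dataclass(frozen=True)
class Spectrum:
    """Reflectance over a strictly increasing wavelength grid (nm)."""

    wavelength_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "reflectance", refl)
        if wl.ndim != 1 or refl.ndim != 1 or wl.size != refl.size:
            raise DataError("wavelength and reflectance must be 1-D arrays of equal length")
        if wl.size < 2:
            raise DataError("a spectrum needs at least two grid points")
        if not np.all(np.diff(wl) > 0):
            raise DataError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise DataError("reflectance contains non-finite values")
        if np.any(refl < 0):
            raise DataError("reflectance contains negative values")

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        steps = np.diff(self.wavelength_nm)
        return bool(np.allclose(steps, steps[0], rtol=rtol, atol=1e-9))


@dataclass(frozen=True)
class AngularObservation:
    """One spectrum observed at a signed view zenith angle.

    Negative angles are back-scatter (sun side, toward the hotspot),
    positive angles forward-scatter, zero nadir.
    """

    sample_id: str
    vza_deg: float
    spectrum: Spectrum


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: growth stage, treatment, and measured LAI."""

    sample_id: str
    stage: str
    nitrogen: str
    coverage: str
    lai: float  # cm^2 / cm^2

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.nitrogen not in NITROGEN_LEVELS:
            raise DataError(f"unknown nitrogen level {self.nitrogen!r}; expected one of {NITROGEN_LEVELS}")
        if self.coverage not in COVERAGE_LEVELS:
            raise DataError(f"unknown coverage {self.coverage!r}; expected one of {COVERAGE_LEVELS}")
        if not np.isfinite(self.lai) or self.lai <= 0:
            raise DataError(f"lai must be finite and > 0; got {self.lai}")


@dataclass
class MultiAngleDataset:
    """Samples x view zenith angles -> spectra, joined to metadata."""

    observations: dict[tuple[str, float], Spectrum] = field(default_factory=dict)
    metadata: dict[str, SampleRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        orphans = sorted({sid for sid, _ in self.observations} - set(self.metadata))
        if orphans:
            raise DataError(f"observations reference samples without metadata: {orphans}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted({sid for sid, _ in self.observations})

    @property
    def vzas(self) -> list[float]:
        return sorted({vza for _, vza in self.observations})

    def __len__(self) -> int:
        return len(self.observations)

    def spectrum(self, sample_id: str, vza_deg: float) -> Spectrum:
        try:
            return self.observations[(sample_id, float(vza_deg))]
        except KeyError:
            raise DataError(f"no observation for sample {sample_id!r} at VZA {vza_deg}") from None

    def lai_series(self, sample_ids: Iterable[str] | None = None) -> pd.Series:
        ids = list(sample_ids) if sample_ids is not None else self.sample_ids
        return pd.Series({sid: self.metadata[sid].lai for sid in ids}, name="lai")

    def metadata_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": rec.sample_id,
                "stage": rec.stage,
                "nitrogen": rec.nitrogen,
                "coverage": rec.coverage,
                "lai": rec.lai,
            }
            for rec in self.metadata.values()
        ]
        return pd.DataFrame(rows, columns=METADATA_COLUMNS).sort_values("sample_id").reset_index(drop=True)


def sg_smooth(spectrum: Spectrum, window_length: int = 15, poly_order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothing on a uniform wavelength grid.

    ``poly_order`` defaults to 2 (a quadratic filter), which leaves any
    polynomial of degree <= 2 unchanged.  ``window_length`` counts grid
    points and must be odd and larger than ``poly_order``.
    """
    if window_length % 2 == 0:
        raise DataError(f"window_length must be odd; got {window_length}")
    if window_length <= poly_order:
        raise DataError(f"window_length ({window_length}) must exceed poly_order ({poly_order})")
    if window_length > len(spectrum):
        raise DataError(
            f"window_length {window_length} exceeds spectrum length {len(spectrum)}"
        )
    if not spectrum.is_uniform():
        raise DataError("Savitzky-Golay smoothing requires a uniform wavelength grid")
    smoothed = savgol_filter(spectrum.reflectance, window_length, poly_order, mode="interp")
    # the filter can produce tiny negative excursions on noisy near-zero data
    smoothed = np.clip(smoothed, 0.0, None)
    return Spectrum(spectrum.wavelength_nm, smoothed)


def band_reflectance(spectrum: Spectrum, wavelength_nm: float) -> float:
    """Reflectance at a wavelength, linearly interpolated between the
    bracketing grid points; exact at grid nodes."""
    lo, hi = spectrum.range_nm
    if not lo <= wavelength_nm <= hi:
        raise DataError(
            f"wavelength {wavelength_nm} nm outside spectrum range [{lo}, {hi}] nm"
        )
    return float(np.interp(wavelength_nm, spectrum.wavelength_nm, spectrum.reflectance))


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear resampling onto ``grid``; grid must lie inside the spectrum."""
    lo, hi = spectrum.range_nm
    if grid[0] < lo or grid[-1] > hi:
        raise DataError(
            f"target grid [{grid[0]}, {grid[-1]}] nm extends beyond spectrum range [{lo}, {hi}] nm"
        )
    return Spectrum(grid, np.interp(grid, spectrum.wavelength_nm, spectrum.reflectance))


def default_grid(step_nm: float = 1.0) -> np.ndarray:
    """Uniform working grid over 350-1300 nm."""
    n = int(round((WAVELENGTH_MAX - WAVELENGTH_MIN) / step_nm))
    return WAVELENGTH_MIN + step_nm * np.arange(n + 1)


def _coerce_percent(values: np.ndarray) -> tuple[np.ndarray, bool]:
    # reflectance fractions expected; percent inputs auto-detected
    if np.nanmax(values) > 1.5:
        return values / 100.0, True
    return values, False


def read_dataset(
    spectra_table: str | Path | pd.DataFrame,
    metadata_table: str | Path | pd.DataFrame,
    duplicates: str = "average",
) -> MultiAngleDataset:
    """Build a dataset from long-format spectra and a metadata table.

    ``duplicates`` controls what happens when several rows share one
    (sample, vza, wavelength) key: ``"average"`` treats them as replicate
    scans and averages them (the default), ``"error"`` rejects the input.
    """
    if duplicates not in ("average", "error"):
        raise DataError(f"duplicates must be 'average' or 'error'; got {duplicates!r}")
    spectra = (
        pd.read_csv(spectra_table) if not isinstance(spectra_table, pd.DataFrame) else spectra_table.copy()
    )
    meta = (
        pd.read_csv(metadata_table) if not isinstance(metadata_table, pd.DataFrame) else metadata_table.copy()
    )
    missing = set(SPECTRA_COLUMNS) - set(spectra.columns)
    if missing:
        raise DataError(f"spectra table missing columns: {sorted(missing)}")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise DataError(f"metadata table missing columns: {sorted(missing)}")

    spectra = spectra.copy()
    spectra["sample_id"] = spectra["sample_id"].astype(str)
    refl, was_percent = _coerce_percent(spectra["reflectance"].to_numpy(dtype=float))
    if was_percent:
        log.warning("reflectance maximum exceeds 1.5; interpreting values as percent and rescaling by 1/100")
    spectra["reflectance"] = refl

    key = ["sample_id", "vza_deg", "wavelength_nm"]
    dup_mask = spectra.duplicated(key, keep=False)
    if dup_mask.any():
        if duplicates == "error":
            bad = spectra.loc[dup_mask, key].drop_duplicates().head(5)
            raise DataError(f"duplicate (sample, vza, wavelength) rows, e.g.:\n{bad}")
        n_before = len(spectra)
        spectra = spectra.groupby(key, as_index=False)["reflectance"].mean()
        log.info("averaged %d replicate rows into %d unique rows", n_before, len(spectra))

    records: dict[str, SampleRecord] = {}
    for row in meta.itertuples(index=False):
        sid = str(row.sample_id)
        if sid in records:
            raise DataError(f"duplicate metadata row for sample {sid!r}")
        records[sid] = SampleRecord(sid, str(row.stage), str(row.nitrogen), str(row.coverage), float(row.lai))

    orphans = sorted(set(spectra["sample_id"]) - set(records))
    if orphans:
        raise DataError(f"spectra reference samples without metadata: {orphans}")

    observations: dict[tuple[str, float], Spectrum] = {}
    for (sid, vza), group in spectra.groupby(["sample_id", "vza_deg"], sort=True):
        group = group.sort_values("wavelength_nm")
        observations[(str(sid), float(vza))] = Spectrum(
            group["wavelength_nm"].to_numpy(dtype=float),
            group["reflectance"].to_numpy(dtype=float),
        )
    used = {sid for sid, _ in observations}
    metadata = {sid: rec for sid, rec in records.items() if sid in used}
    unused = set(records) - used
    if unused:
        log.info("metadata for %d samples has no spectra and is dropped", len(unused))
    return MultiAngleDataset(observations=observations, metadata=metadata)


def write_dataset(dataset: MultiAngleDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize a dataset back to (spectra, metadata) long-format frames.

    Round-trip stable: ``read_dataset(*write_dataset(ds))`` reproduces
    every value exactly.
    """
    chunks = []
    for (sid, vza), spec in sorted(dataset.observations.items()):
        chunks.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "vza_deg": vza,
                    "wavelength_nm": spec.wavelength_nm,
                    "reflectance": spec.reflectance,
                }
            )
        )
    spectra = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=SPECTRA_COLUMNS)
    )
    return spectra[SPECTRA_COLUMNS], dataset.metadata_frame()


def preprocess(
    dataset: MultiAngleDataset,
    grid_step_nm: float = 1.0,
    sg_window: int = 15,
    sg_polyorder: int = 2,
) -> MultiAngleDataset:
    """Resample every observation to the uniform working grid, then
    Savitzky-Golay smooth.  Replicate averaging (if any) happens earlier,
    at read time."""
    grid = default_grid(grid_step_nm)
    observations = {
        key: sg_smooth(resample(spec, grid), sg_window, sg_polyorder)
        for key, spec in dataset.observations.items()
    }
    return MultiAngleDataset(observations=observations, metadata=dict(dataset.metadata))
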