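"""Vegetation index registry and evaluation.

Sixteen validated indices, including OPIVI — the angle-insensitive
index (R720 − R450)/(R660 − R450) built by folding the blue band into a
normalized-difference structure.  Each index is evaluated from point-band
reflectances sampled (with linear interpolation) off a spectrum.

Bands are cited by wavelength in nm; evaluators receive a mapping
``{wavelength: reflectance}`` restricted to their declared bands.
Divisions go through :func:`_ratio`, which raises
:class:`~mavi.errors.UndefinedIndexError` on a vanishing denominator
instead of returning NaN or inf.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from mavi.config import WAVELENGTH_MAX, WAVELENGTH_MIN
from mavi.errors import DataError, UndefinedIndexError
from mavi.spectral_core import MultiAngleDataset, Spectrum, band_reflectance

log = logging.getLogger(__name__)

#: Absolute tolerance below which a denominator counts as zero.
DENOM_TOL = 1e-12


def _ratio(num: float, den: float, context: str) -> float:
    if abs(den) < DENOM_TOL:
        raise UndefinedIndexError(f"{context}: denominator {den!r} below tolerance {DENOM_TOL}")
    return num / den


@dataclass(frozen=True)
class IndexDefinition:
    """A named index formula over point-band reflectances."""

    name: str
    band_class: str  # "two" | "three" | "four"
    required_bands: tuple[float, ...]
    evaluator: Callable[[Mapping[float, float]], float]
    formula: str = ""

    def __post_init__(self) -> None:
        for band in self.required_bands:
            if not WAVELENGTH_MIN <= band <= WAVELENGTH_MAX:
                raise DataError(f"{self.name}: band {band} nm outside working range")

    def __call__(self, bands: Mapping[float, float]) -> float:
        return self.evaluator(bands)


def _pri(b):
    return _ratio(b[570] - b[531], b[570] + b[531], "PRI")


def _ri_db(b):
    return _ratio(b[735], b[720], "RI-dB")


def _savi(b):
    return 1.5 * _ratio(b[870] - b[680], b[870] + b[680] + 0.5, "SAVI")


def _ndre(b):
    return _ratio(b[790] - b[720], b[790] + b[720], "NDRE")


def _dvi(b):
    return b[860] - b[560]


def _vlopt(b):
    # squared R800 as printed; see vlopt_variant for the linear reading
    return (1 + 0.45) * _ratio(b[800] ** 2 + 1, b[670] + 0.45, "Vlopt")


def _vlopt_linear(b):
    return (1 + 0.45) * _ratio(b[800] + 1, b[670] + 0.45, "Vlopt")


def _mnd705(b):
    return _ratio(b[750] - b[705], b[750] + b[705] - 2 * b[445], "mND705")


def _ndda(b):
    return _ratio(b[680] + b[756] - 2 * b[718], b[756] - b[680], "NDDA")


def _mtci(b):
    return _ratio(b[754] - b[709], b[709] - b[681], "MTCI")


def _evi1(b):
    return 2.5 * _ratio(b[860] - b[645], 1 + b[860] + 6 * b[645] - 7.5 * b[470], "EVI-1")


def _ddn(b):
    return 2.5 * b[710] - b[660] - b[760]


def _opivi(b):
    return _ratio(b[720] - b[450], b[660] - b[450], "OPIVI")


def _vog2(b):
    return _ratio(b[734] - b[747], b[715] - b[726], "VOG-2")


def _dd(b):
    return (b[749] - b[720]) - (b[701] - b[672])


def _rep(b):
    return b[700] + 40.0 * _ratio((b[670] + b[780]) / 2 - b[700], b[740] - b[700], "REP")


def _tcari(b):
    return 3.0 * ((b[700] - b[670]) - 0.2 * (b[700] - b[550]) * _ratio(b[700], b[670], "TCARI"))


def _osavi(b):
    return 1.16 * _ratio(b[800] - b[670], b[800] + b[670] + 0.16, "OSAVI")


def _ccii(b):
    return _ratio(_tcari(b), _osavi(b), "CCII")


def _defn(name, band_class, bands, fn, formula):
    return IndexDefinition(name, band_class, tuple(float(x) for x in bands), fn, formula)


#: The validated registry.  TCARI and OSAVI inside CCII follow their
#: literature-standard forms (an external assumption, since only the
#: ratio is cited by name).
REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        _defn("PRI", "two", (531, 570), _pri, "(R570 - R531)/(R570 + R531)"),
        _defn("RI-dB", "two", (720, 735), _ri_db, "R735/R720"),
        _defn("SAVI", "two", (680, 870), _savi, "1.5*(R870 - R680)/(R870 + R680 + 0.5)"),
        _defn("NDRE", "two", (720, 790), _ndre, "(R790 - R720)/(R790 + R720)"),
        _defn("DVI", "two", (560, 860), _dvi, "R860 - R560"),
        _defn("Vlopt", "two", (670, 800), _vlopt, "(1 + 0.45)*(R800^2 + 1)/(R670 + 0.45)"),
        _defn("mND705", "three", (445, 705, 750), _mnd705, "(R750 - R705)/(R750 + R705 - 2*R445)"),
        _defn("NDDA", "three", (680, 718, 756), _ndda, "(R680 + R756 - 2*R718)/(R756 - R680)"),
        _defn("MTCI", "three", (681, 709, 754), _mtci, "(R754 - R709)/(R709 - R681)"),
        _defn("EVI-1", "three", (470, 645, 860), _evi1, "2.5*(R860 - R645)/(1 + R860 + 6*R645 - 7.5*R470)"),
        _defn("DDn", "three", (660, 710, 760), _ddn, "2.5*R710 - R660 - R760"),
        _defn("OPIVI", "three", (450, 660, 720), _opivi, "(R720 - R450)/(R660 - R450)"),
        _defn("VOG-2", "four", (715, 726, 734, 747), _vog2, "(R734 - R747)/(R715 - R726)"),
        _defn("DD", "four", (672, 701, 720, 749), _dd, "(R749 - R720) - (R701 - R672)"),
        _defn("REP", "four", (670, 700, 740, 780), _rep, "R700 + 40*[(R670 + R780)/2 - R700]/(R740 - R700)"),
        _defn("CCII", "four", (550, 670, 700, 800), _ccii, "TCARI/OSAVI"),
    ]
}

_VLOPT_LINEAR = _defn("Vlopt", "two", (670, 800), _vlopt_linear, "(1 + 0.45)*(R800 + 1)/(R670 + 0.45)")


def get_definition(name: str, vlopt_variant: str = "printed") -> IndexDefinition:
    if name == "Vlopt" and vlopt_variant == "r800_linear":
        return _VLOPT_LINEAR
    try:
        return REGISTRY[name]
    except KeyError:
        raise DataError(
            f"unregistered index {name!r}; registry: {', '.join(sorted(REGISTRY))}"
        ) from None


def sample_bands(spectrum: Spectrum, bands: Iterable[float]) -> dict[float, float]:
    """Interpolated reflectance at each requested band."""
    return {float(b): band_reflectance(spectrum, float(b)) for b in bands}


def compute_index(name: str, spectrum: Spectrum, vlopt_variant: str = "printed") -> float:
    """Evaluate one registered index on a spectrum.

    Raises :class:`UndefinedIndexError` when the formula's denominator
    vanishes, and :class:`DataError` for unknown names or bands outside
    the spectrum's range.  Never returns a non-finite value.
    """
    defn = get_definition(name, vlopt_variant)
    value = defn(sample_bands(spectrum, defn.required_bands))
    if not math.isfinite(value):
        raise UndefinedIndexError(f"{name}: non-finite value {value!r}")
    return float(value)


def opivi(spectrum: Spectrum) -> float:
    """OPIVI = (R720 − R450)/(R660 − R450): invariant under any affine
    transform R → aR + b (a ≠ 0) of the whole spectrum."""
    return compute_index("OPIVI", spectrum)


def compute_index_table(
    dataset: MultiAngleDataset,
    names: Sequence[str] | None = None,
    vlopt_variant: str = "printed",
) -> pd.DataFrame:
    """Evaluate indices for every (sample, VZA) observation.

    Returns a tidy frame ``sample_id, vza_deg, index, value``; undefined
    cells are stored as NaN and their count logged.
    """
    if len(dataset) == 0:
        raise DataError("dataset has no observations")
    if names is None or len(names) == 0:
        names = list(REGISTRY)
    defns = [get_definition(name, vlopt_variant) for name in names]
    rows = []
    n_undefined = 0
    for (sid, vza), spectrum in sorted(dataset.observations.items()):
        for defn in defns:
            try:
                value = defn(sample_bands(spectrum, defn.required_bands))
                if not math.isfinite(value):
                    raise UndefinedIndexError(f"{defn.name}: non-finite value")
            except UndefinedIndexError:
                value = float("nan")
                n_undefined += 1
            rows.append((sid, vza, defn.name, value))
    if n_undefined:
        log.warning("%d undefined index cells stored as missing", n_undefined)
    return pd.DataFrame(rows, columns=["sample_id", "vza_deg", "index", "value"])


def vitable_pivot(vitable: pd.DataFrame, index_name: str) -> pd.DataFrame:
    """Samples x VZAs matrix of one index's values."""
    sub = vitable[vitable["index"] == index_name]
    if sub.empty:
        raise DataError(f"index {index_name!r} not present in the table")
    return sub.pivot(index="sample_id", columns="vza_deg", values="value")
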