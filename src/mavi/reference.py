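"""Published benchmark correlation profiles.

Per-angle Pearson correlation coefficients between three vegetation
indices (EVI-1, OPIVI, REP) and measured LAI, as published for a winter
oilseed rape field experiment, in four sub-datasets: two growth stages
and two treatment slices (nitrogen rates, overlay/coverage mode).  Each
profile lists nine values ordered by view zenith angle
−60, −45, −30, −15, 0, +15, +30, +45, +60 degrees.

These rows are regression anchors for the angular-stability statistics:
DR computed on them must rank OPIVI strictly most stable in every
sub-dataset.
"""

from __future__ import annotations

REFERENCE_VZAS = (-60.0, -45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0, 60.0)

PUBLISHED_R_BY_ANGLE: dict[str, dict[str, tuple[float, ...]]] = {
    "bolting": {
        "EVI-1": (0.70, 0.75, 0.81, 0.85, 0.80, 0.74, 0.72, 0.69, 0.69),
        "OPIVI": (0.74, 0.78, 0.81, 0.82, 0.81, 0.81, 0.78, 0.75, 0.74),
        "REP": (0.72, 0.74, 0.80, 0.81, 0.80, 0.76, 0.72, 0.69, 0.68),
    },
    "flowering": {
        "EVI-1": (0.54, 0.58, 0.65, 0.70, 0.64, 0.60, 0.58, 0.57, 0.53),
        "OPIVI": (0.78, 0.79, 0.83, 0.85, 0.83, 0.80, 0.78, 0.75, 0.76),
        "REP": (0.68, 0.71, 0.75, 0.78, 0.76, 0.74, 0.72, 0.69, 0.67),
    },
    "n_rates": {
        "EVI-1": (0.62, 0.67, 0.72, 0.74, 0.70, 0.64, 0.62, 0.60, 0.59),
        "OPIVI": (0.77, 0.78, 0.82, 0.82, 0.82, 0.81, 0.76, 0.77, 0.76),
        "REP": (0.61, 0.64, 0.71, 0.74, 0.70, 0.65, 0.62, 0.61, 0.60),
    },
    "overlay": {
        "EVI-1": (0.72, 0.76, 0.81, 0.82, 0.81, 0.75, 0.72, 0.70, 0.69),
        "OPIVI": (0.80, 0.82, 0.85, 0.86, 0.85, 0.84, 0.81, 0.79, 0.77),
        "REP": (0.76, 0.78, 0.80, 0.85, 0.82, 0.76, 0.74, 0.72, 0.73),
    },
}
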