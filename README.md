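# mavi — multi-angle vegetation index toolkit

Tools for analysing multi-angle hyperspectral canopy reflectance:

- **spectral_core** — spectrum/dataset types, Savitzky–Golay smoothing
  (quadratic by default), band interpolation, long-format CSV I/O with
  replicate averaging and percent auto-detection.
- **vi_library** — a validated registry of 16 vegetation indices
  (PRI, RI-dB, SAVI, NDRE, DVI, Vlopt, mND705, NDDA, MTCI, EVI-1, DDn,
  OPIVI, VOG-2, DD, REP, CCII) evaluated from interpolated point bands;
  undefined denominators raise instead of propagating NaN.
- **angular_analysis** — angle-sensitivity statistics: percent change vs
  nadir, one-way ANOVA across view zenith angles (VZAs), Pearson r with
  LAI per angle within sub-datasets, and the DR stability statistic
  `(max − min)/mean` over a correlation profile (smaller = more stable).
- **lai_models** — a shared deterministic 70/30 split, per-angle OLS
  lines, and multi-angle regressors (RBF SVR; gradient-boosted trees
  with depth 5 and learning rate 0.01; random forest with 500 trees and
  mtry 3), with R²/RMSE on train and held-out test sets.
- **synth_canopy** — a synthetic multi-angle canopy generator
  (leaf/soil mixing through the gap fraction `exp(−0.5·LAI/cos θ)` with
  a kernel-style BRDF factor: nadir minimum, back-scatter hotspot,
  visible-band asymmetry, view-dependent apparent red-edge shift) so the
  whole pipeline runs without field data.
- **cli / pipeline** — staged command-line workflow.

## CLI

```sh
# synthesize a campaign: 45 plots/stage (5 N levels x 3 coverages x 3 reps)
mavi simulate --reps 3 --stages budding,flowering --noise 0.02 --seed 7 \
     --out spectra.csv --meta meta.csv

# smooth + evaluate indices
mavi indices --in spectra.csv --meta meta.csv --names OPIVI,NDRE,EVI-1,REP \
     --out vitable.csv

# angle-sensitivity report (amplitudes, ANOVA, r by angle, DR)
mavi stability --vitable vitable.csv --meta meta.csv --out report/

# multi-angle LAI model on OPIVI at the three best angles
mavi fit --vitable vitable.csv --meta meta.csv --index OPIVI \
     --angles -30,-15,0 --model rf --seed 7 --out fit.json

# everything in one go (synthetic unless --in/--meta given)
mavi run --seed 7 --out report/
```

Spectra CSV is long format (`sample_id,vza_deg,wavelength_nm,reflectance`,
reflectance as fractions, VZA signed: negative = back-scatter);
metadata CSV is `sample_id,stage,nitrogen,coverage,lai`.  A YAML config
(`--config`) can override any default; exit codes are 0/2/3 for
success/config error/data error.

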