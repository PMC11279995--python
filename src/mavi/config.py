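"""Run configuration: defaults, YAML round-trip, and validation.

All tunable numbers in the toolkit live here so that a run is
reproducible from its config plus a seed alone.  Defaults are logged at
run start by the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from mavi.errors import ConfigError

log = logging.getLogger(__name__)

#: Default signed view zenith angles (degrees).  Negative angles view
#: from the sun's side (back-scatter, toward the hotspot), positive
#: angles the opposite side (forward-scatter), zero is nadir.
DEFAULT_VZAS: tuple[float, ...] = (-60.0, -45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0, 60.0)

#: Working spectral range (nm) after preprocessing.
WAVELENGTH_MIN = 350.0
WAVELENGTH_MAX = 1300.0


@dataclass
class RunConfig:
    """Complete configuration for an end-to-end run."""

    # spectral preprocessing
    grid_step_nm: float = 1.0
    sg_window: int = 15          # grid points, must be odd
    sg_polyorder: int = 2        # quadratic filter
    vzas: tuple[float, ...] = DEFAULT_VZAS

    # index evaluation
    index_names: tuple[str, ...] = ()        # empty = full registry
    vlopt_variant: str = "printed"           # "printed" | "r800_linear"
    denominator_tol: float = 1e-12

    # LAI modelling
    train_fraction: float = 0.7
    split_seed: int = 0
    model_seed: int = 0
    multiangle_vzas: tuple[float, ...] = (-30.0, -15.0, 0.0)
    multiangle_index: str = "OPIVI"
    model_kinds: tuple[str, ...] = ("svr_rbf", "gbt", "rf")
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    gbt_max_depth: int = 5
    gbt_learning_rate: float = 0.01
    gbt_n_estimators: int = 500
    gbt_alpha: float = 0.0       # exposed; sklearn backend ignores L1 term
    gbt_lambda: float = 1.0      # exposed; sklearn backend ignores L2 term
    rf_n_trees: int = 500
    rf_mtry: int = 3

    # simulation
    sim_reps: int = 3
    sim_stages: tuple[str, ...] = ("budding", "flowering")
    sim_noise_sd: float = 0.02
    sim_seed: int = 0

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ConfigError(
                f"sg_window must be odd and > sg_polyorder; got "
                f"window={self.sg_window}, polyorder={self.sg_polyorder}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(f"train_fraction must be in (0, 1); got {self.train_fraction}")
        if self.vlopt_variant not in ("printed", "r800_linear"):
            raise ConfigError(f"unknown vlopt_variant {self.vlopt_variant!r}")
        if self.grid_step_nm <= 0:
            raise ConfigError("grid_step_nm must be positive")
        if len(self.vzas) == 0:
            raise ConfigError("vzas must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            value = d[f.name]
            if isinstance(value, list):
                value = tuple(value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a key-value mapping")
        return cls.from_dict(raw)

    def log_defaults(self) -> None:
        for key, value in sorted(self.to_dict().items()):
            log.info("config %s = %r", key, value)
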