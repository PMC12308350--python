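"""Run configuration: validated key-value settings with literature defaults.

Model/assay keys mirror the conventional symbols (kon, koff, D, rAb, rtot,
Ainit, Vwell, T0, Trad) so a configuration file reads like the parameter
table it encodes.  Unknown keys are rejected rather than ignored: a silent
typo in, say, ``koff`` would otherwise run the default unnoticed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .dose_response import BindingSystem, dose_grid
from .params import AssayGeometry, ModelParameters, RateParameters

__all__ = ["ConfigError", "RunConfig", "load_config"]

#: configuration schema version; bump on incompatible key changes
SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration: unknown key, bad type or out-of-range value."""


@dataclass
class RunConfig:
    """All settings of one run.  Defaults are the literature values."""

    # model / assay parameters (laboratory units)
    kon: float = 1e5          # s^-1 M^-1
    koff: float = 1e-4        # s^-1
    D: float = 1e-14          # m^2 s^-1
    rAb: float = 12.5e-9      # m
    rtot: float = 1e4         # antigens per cell
    Ainit: float = 1e-10      # M
    Vwell: float = 150e-6     # litres
    T0: float = 2e5           # cells
    Trad: float = 8e-6        # m
    k2_mode: str = "diffusion"

    # experiment settings
    experiment: str = "equilibrium"
    signal: str = "total_bound"
    dose_min: float = 1e-13
    dose_max: float = 1e-3
    dose_points: int = 121
    doses: list[float] = field(
        default_factory=lambda: [1e-11, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5]
    )
    rtot_min: float = 1e3
    rtot_max: float = 1e6
    rtot_points: int = 7
    kd_min: float = 1e-10
    kd_max: float = 1e-6
    kd_points: int = 9
    n_samples: int = 1024
    scale: str = "log"
    seed: int = 0
    out_dir: str = "."
    verbose: bool = False
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        positive = ("kon", "koff", "D", "rAb", "rtot", "Vwell", "T0", "Trad",
                    "dose_min", "dose_max", "rtot_min", "rtot_max", "kd_min", "kd_max")
        for name in positive:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or value <= 0:
                raise ConfigError(f"{name}: must be a positive number, got {value!r}")
        if self.Ainit < 0:
            raise ConfigError(f"Ainit: must be nonnegative, got {self.Ainit!r}")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"schema_version: expected {SCHEMA_VERSION}, got {self.schema_version!r}"
            )
        if self.scale not in ("log", "linear"):
            raise ConfigError(f"scale: must be 'log' or 'linear', got {self.scale!r}")
        if self.k2_mode not in ("diffusion", "proximity"):
            raise ConfigError(f"k2_mode: must be 'diffusion' or 'proximity', got {self.k2_mode!r}")

    # --- assembled model objects -------------------------------------------
    def geometry(self) -> AssayGeometry:
        return AssayGeometry(v_well=self.Vwell, t0=self.T0, t_rad=self.Trad)

    def rates(self) -> RateParameters:
        return RateParameters(kon=self.kon, koff=self.koff, d_antigen=self.D, r_ab=self.rAb)

    def system(self) -> BindingSystem:
        return BindingSystem(
            rates=self.rates(), geometry=self.geometry(), rtot=self.rtot, k2_mode=self.k2_mode
        )

    def model_parameters(self) -> ModelParameters:
        return self.system().at_dose(self.Ainit)

    def grid(self):
        return dose_grid(self.dose_min, self.dose_max, self.dose_points)

    def snapshot(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as err:
            raise ConfigError(str(err)) from err


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Read a YAML configuration file, applying any overrides on top."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig.from_dict(data)
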