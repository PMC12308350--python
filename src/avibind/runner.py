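"""Experiment dispatch: one entry point that turns a RunConfig into files.

Experiments
-----------
equilibrium      single equilibrium solve, JSON record
dose_sweep       bivalent + monovalent metric curves across the dose grid (CSV)
dose_antigen_map equilibrium metrics over an (rtot, Ainit) grid (CSV)
sensitivity      dose-resolved Sobol total/first-order indices (CSV)
avidity_map      ΔEC50 over an (rtot, KD) grid at the configured D (CSV)
ec50             EC50 of the configured signal (JSON)
delta_ec50       monovalent-vs-bivalent EC50 shift (JSON)

Every output file is accompanied by a ``*_record.json`` holding the exact
configuration snapshot, package version and solver diagnostics, so any result
can be regenerated from its record alone.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ConfigError, RunConfig
from .dose_response import avidity_map, delta_ec50, ec50, metric_map, sweep_dose, sweep_frame
from .equilibrium import solve_bivalent_equilibrium
from .params import derive_rates
from .sensitivity import default_ranges, sensitivity_experiment

__all__ = ["ResultRecord", "run", "EXPERIMENTS"]

log = logging.getLogger("avibind")

_CSV_KW = {"index": False, "float_format": "%.12g"}


@dataclass(frozen=True)
class ResultRecord:
    """Provenance of one run: config snapshot, outputs, diagnostics."""

    experiment: str
    config: dict
    version: str
    timestamp: str
    outputs: list[str]
    diagnostics: dict

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _log_derived(config: RunConfig) -> dict:
    derived = derive_rates(config.geometry(), config.rates(), k2_mode=config.k2_mode)
    info = {
        "sigma": derived.sigma,
        "k1": derived.k1,
        "k2": derived.k2,
        "K21": derived.k21,
    }
    log.info("derived rates: %s", ", ".join(f"{k}={v:.6g}" for k, v in info.items()))
    return info


def _run_equilibrium(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    params = config.model_parameters()
    eq = solve_bivalent_equilibrium(params)
    path = out_dir / "equilibrium.json"
    path.write_text(eq.to_json(params))
    return [path], {
        "residual_monovalent": eq.residual_monovalent,
        "residual_crosslink": eq.residual_crosslink,
        "method": eq.method,
    }


def _run_dose_sweep(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    system = config.system()
    grid = config.grid()
    frame = pd.concat(
        [sweep_frame(system, grid, "bivalent"), sweep_frame(system, grid, "monovalent")],
        ignore_index=True,
    )
    path = out_dir / "dose_sweep.csv"
    frame.to_csv(path, **_CSV_KW)
    return [path], {"n_doses": len(grid)}


def _run_dose_antigen_map(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    rtot_grid = np.logspace(
        np.log10(config.rtot_min), np.log10(config.rtot_max), config.rtot_points
    )
    frame = metric_map(rtot_grid, config.grid(), rates=config.rates(),
                       geometry=config.geometry(), k2_mode=config.k2_mode)
    path = out_dir / "dose_antigen_map.csv"
    frame.to_csv(path, **_CSV_KW)
    return [path], {"n_cells": len(frame)}


def _run_sensitivity(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    table = sensitivity_experiment(
        config.doses,
        ranges=default_ranges(config.scale),
        n=config.n_samples,
        seed=config.seed,
        geometry=config.geometry(),
    )
    path = out_dir / "sensitivity.csv"
    table.to_csv(path, **_CSV_KW)
    return [path], {"n_samples": config.n_samples, "n_doses": len(config.doses)}


def _run_avidity_map(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    rtot_grid = np.logspace(
        np.log10(config.rtot_min), np.log10(config.rtot_max), config.rtot_points
    )
    kd_grid = np.logspace(np.log10(config.kd_min), np.log10(config.kd_max), config.kd_points)
    frame = avidity_map(
        rtot_grid, kd_grid, config.D, signal_kind=config.signal, kon=config.kon,
        grid=config.grid(), geometry=config.geometry(), k2_mode=config.k2_mode,
    )
    path = out_dir / "avidity_map.csv"
    frame.to_csv(path, **_CSV_KW)
    return [path], {"n_failures": int((frame["error"] != "").sum())}


def _run_ec50(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    curve = sweep_dose(config.system(), config.grid(), config.signal)
    result = ec50(curve)
    path = out_dir / "ec50.json"
    path.write_text(json.dumps(asdict(result) | {"signal": config.signal}, indent=2))
    return [path], {"ec50": result.ec50}


def _run_delta_ec50(config: RunConfig, out_dir: Path) -> tuple[list[Path], dict]:
    shift = delta_ec50(config.system(), config.grid(), config.signal)
    path = out_dir / "delta_ec50.json"
    path.write_text(json.dumps(asdict(shift) | {"signal": config.signal}, indent=2))
    return [path], {"delta_ec50": shift.delta_ec50}


EXPERIMENTS = {
    "equilibrium": _run_equilibrium,
    "dose_sweep": _run_dose_sweep,
    "dose_antigen_map": _run_dose_antigen_map,
    "sensitivity": _run_sensitivity,
    "avidity_map": _run_avidity_map,
    "ec50": _run_ec50,
    "delta_ec50": _run_delta_ec50,
}


def run(config: RunConfig) -> ResultRecord:
    """Execute the configured experiment and write its outputs."""
    if config.experiment not in EXPERIMENTS:
        raise ConfigError(
            f"experiment: unknown name {config.experiment!r}; "
            f"expected one of {sorted(EXPERIMENTS)}"
        )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    diagnostics = {"derived": _log_derived(config)}
    outputs, extra = EXPERIMENTS[config.experiment](config, out_dir)
    diagnostics.update(extra)
    record = ResultRecord(
        experiment=config.experiment,
        config=config.snapshot(),
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        outputs=[str(p) for p in outputs],
        diagnostics=diagnostics,
    )
    record.write(out_dir / f"{config.experiment}_record.json")
    return record
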