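"""Dose sweeps, EC50 extraction and avidity (ΔEC50) maps.

The avidity effect -- the apparent affinity gain from engaging two antigens at
once -- is quantified by comparing dose-response curves of the bivalent model
against its one-armed analogue (k2 = 0) with all other parameters identical:

    ΔEC50 = log10(EC50_monovalent / EC50_bivalent)

EC50 is defined directly on the model curve: the first dose (log-linearly
interpolated) at which the signal crosses half of its maximum over the dose
grid.  The bivalent total-bound curve is biphasic (a bivalent plateau followed
by a monovalent-driven rise), which makes the "first crossing" convention and
the grid's upper dose bound part of the definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equilibrium import (
    EquilibriumError,
    solve_bivalent_equilibrium,
    solve_monovalent_equilibrium,
)
from .metrics import BindingMetrics, compute_metrics
from .params import AssayGeometry, ModelParameters, RateParameters, derive_rates

__all__ = [
    "BindingSystem",
    "dose_grid",
    "ResponseCurve",
    "EC50Result",
    "AvidityShift",
    "sweep_dose",
    "sweep_frame",
    "crossing_dose",
    "ec50",
    "delta_ec50",
    "avidity_map",
    "metric_map",
    "SIGNAL_KINDS",
]

SIGNAL_KINDS = ("occupancy", "bound_ratio", "total_bound", "a1_frac", "a2_frac")


@dataclass(frozen=True)
class BindingSystem:
    """An antibody/antigen/assay combination, dose left free.

    Bundles the assay geometry, the laboratory-unit rates and the antigen
    density so that per-dose model parameters can be generated for sweeps.
    """

    rates: RateParameters = field(default_factory=RateParameters)
    geometry: AssayGeometry = field(default_factory=AssayGeometry)
    rtot: float = 1e4
    k2_mode: str = "diffusion"

    def at_dose(self, ainit: float) -> ModelParameters:
        return ModelParameters.from_assay(
            self.geometry, self.rates, self.rtot, ainit, k2_mode=self.k2_mode
        )

    @property
    def derived(self):
        return derive_rates(self.geometry, self.rates, k2_mode=self.k2_mode)

    def equilibrium_metrics(self, ainit: float, valency: str = "bivalent") -> BindingMetrics:
        """Equilibrium summary metrics at one dose."""
        if self.rtot == 0:  # no antigens: nothing can bind at any dose
            return BindingMetrics(
                a1_frac=None, a2_frac=None, occupancy=0.0, bound_ratio=0.0,
                total_bound=0.0, no_binding=True,
            )
        params = self.at_dose(ainit)
        if valency == "bivalent":
            eq = solve_bivalent_equilibrium(params)
            a1, a2 = eq.a1, eq.a2
        elif valency == "monovalent":
            a1, a2 = solve_monovalent_equilibrium(params.monovalent()), 0.0
        else:
            raise ValueError(f"valency must be 'bivalent' or 'monovalent', got {valency!r}")
        return compute_metrics(a1, a2, self.rtot)


def dose_grid(lo: float = 1e-13, hi: float = 1e-3, num: int = 121) -> np.ndarray:
    """Log-spaced molar dose grid (default 1e-13 ... 1e-3 M, 121 points)."""
    if lo <= 0 or hi <= lo:
        raise ValueError(f"need 0 < lo < hi, got ({lo}, {hi})")
    return np.logspace(np.log10(lo), np.log10(hi), num)


@dataclass(frozen=True)
class ResponseCurve:
    """A signal evaluated on a dose grid."""

    doses: np.ndarray
    signal: np.ndarray
    signal_kind: str

    def __post_init__(self) -> None:
        if len(self.doses) != len(self.signal):
            raise ValueError("doses and signal must have equal length")


@dataclass(frozen=True)
class EC50Result:
    """Half-maximal dose of a response curve."""

    ec50: float
    max_signal: float
    crossing_index: int


@dataclass(frozen=True)
class AvidityShift:
    """Avidity effect of one parameter set: ΔEC50 = log10(EC50_mono/EC50_biv)."""

    delta_ec50: float
    ec50_monovalent: float
    ec50_bivalent: float


def _signal_value(m: BindingMetrics, kind: str) -> float:
    if kind not in SIGNAL_KINDS:
        raise ValueError(f"unknown signal kind {kind!r}; expected one of {SIGNAL_KINDS}")
    value = getattr(m, kind)
    return float("nan") if value is None else float(value)


def sweep_dose(
    system: BindingSystem,
    grid: np.ndarray,
    signal_kind: str = "total_bound",
    valency: str = "bivalent",
) -> ResponseCurve:
    """Equilibrium signal across a dose grid."""
    values = np.empty(len(grid))
    for i, dose in enumerate(grid):
        try:
            values[i] = _signal_value(system.equilibrium_metrics(dose, valency), signal_kind)
        except EquilibriumError as err:
            raise EquilibriumError(f"equilibrium failed at dose {dose:.3e} M: {err}") from err
    return ResponseCurve(doses=np.asarray(grid, dtype=float), signal=values, signal_kind=signal_kind)


def sweep_frame(system: BindingSystem, grid: np.ndarray, valency: str = "bivalent") -> pd.DataFrame:
    """All equilibrium metrics across a dose grid, as a long-friendly table."""
    rows = []
    for dose in grid:
        m = system.equilibrium_metrics(dose, valency)
        rows.append(
            {
                "ainit": dose,
                "rtot": system.rtot,
                "kon": system.rates.kon,
                "koff": system.rates.koff,
                "d_antigen": system.rates.d_antigen,
                "valency": valency,
                "a1_frac": np.nan if m.a1_frac is None else m.a1_frac,
                "a2_frac": np.nan if m.a2_frac is None else m.a2_frac,
                "occupancy": m.occupancy,
                "bound_ratio": m.bound_ratio,
                "total_bound": m.total_bound,
            }
        )
    return pd.DataFrame(rows)


def crossing_dose(curve: ResponseCurve, threshold: float) -> tuple[float, int]:
    """First dose at which the signal reaches ``threshold``.

    Log-linear in dose: the crossing is interpolated linearly in signal against
    log10(dose) within the bracketing grid interval.  Returns (dose, index of
    the interval's left edge).  Raises ValueError if the curve never reaches
    the threshold.
    """
    s = curve.signal
    above = np.nonzero(s >= threshold)[0]
    if len(above) == 0:
        raise ValueError(f"signal never reaches {threshold}")
    i = int(above[0])
    if i == 0:
        return float(curve.doses[0]), 0
    x0, x1 = np.log10(curve.doses[i - 1]), np.log10(curve.doses[i])
    y0, y1 = s[i - 1], s[i]
    frac = 0.0 if y1 == y0 else (threshold - y0) / (y1 - y0)
    return float(10.0 ** (x0 + frac * (x1 - x0))), i - 1


def ec50(curve: ResponseCurve) -> EC50Result:
    """Half-maximal dose: first crossing of 0.5 x the curve's grid maximum."""
    finite = curve.signal[np.isfinite(curve.signal)]
    if len(finite) == 0 or np.max(finite) <= 0:
        raise ValueError("EC50 undefined: curve has no positive maximum")
    max_signal = float(np.max(finite))
    dose, idx = crossing_dose(curve, 0.5 * max_signal)
    return EC50Result(ec50=dose, max_signal=max_signal, crossing_index=idx)


def delta_ec50(
    system: BindingSystem, grid: np.ndarray, signal_kind: str = "total_bound"
) -> AvidityShift:
    """Avidity shift between the bivalent model and its one-armed analogue."""
    ec_biv = ec50(sweep_dose(system, grid, signal_kind, valency="bivalent"))
    ec_mono = ec50(sweep_dose(system, grid, signal_kind, valency="monovalent"))
    return AvidityShift(
        delta_ec50=float(np.log10(ec_mono.ec50 / ec_biv.ec50)),
        ec50_monovalent=ec_mono.ec50,
        ec50_bivalent=ec_biv.ec50,
    )


def avidity_map(
    rtot_grid: np.ndarray,
    kd_grid: np.ndarray,
    d_antigen: float,
    signal_kind: str = "total_bound",
    kon: float = 1e5,
    grid: np.ndarray | None = None,
    geometry: AssayGeometry | None = None,
    k2_mode: str = "diffusion",
) -> pd.DataFrame:
    """ΔEC50 over an (rtot, KD) grid at fixed diffusion coefficient.

    The affinity axis is traversed by fixing ``kon`` and setting
    ``koff = KD * kon``, so that KD also propagates into K2 = k2/koff as the
    avidity physics requires.  Per-cell failures are recorded in the ``error``
    column rather than aborting the map.
    """
    if grid is None:
        grid = dose_grid()
    if geometry is None:
        geometry = AssayGeometry()
    rows = []
    for rtot in rtot_grid:
        for kd in kd_grid:
            rates = RateParameters(kon=kon, koff=kd * kon, d_antigen=d_antigen)
            system = BindingSystem(rates=rates, geometry=geometry, rtot=rtot, k2_mode=k2_mode)
            row = {"rtot": rtot, "kd": kd, "d_antigen": d_antigen, "signal_kind": signal_kind}
            try:
                shift = delta_ec50(system, grid, signal_kind)
                row.update(
                    delta_ec50=shift.delta_ec50,
                    ec50_monovalent=shift.ec50_monovalent,
                    ec50_bivalent=shift.ec50_bivalent,
                    error="",
                )
            except (ValueError, EquilibriumError) as err:
                row.update(
                    delta_ec50=np.nan, ec50_monovalent=np.nan, ec50_bivalent=np.nan, error=str(err)
                )
            rows.append(row)
    return pd.DataFrame(rows)


def metric_map(
    rtot_grid: np.ndarray,
    ainit_grid: np.ndarray,
    rates: RateParameters | None = None,
    geometry: AssayGeometry | None = None,
    k2_mode: str = "diffusion",
) -> pd.DataFrame:
    """Equilibrium metrics over an (rtot, Ainit) grid at fixed rates."""
    if rates is None:
        rates = RateParameters()
    if geometry is None:
        geometry = AssayGeometry()
    frames = []
    for rtot in rtot_grid:
        system = BindingSystem(rates=rates, geometry=geometry, rtot=rtot, k2_mode=k2_mode)
        frames.append(sweep_frame(system, np.asarray(ainit_grid, dtype=float)))
    return pd.concat(frames, ignore_index=True)
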