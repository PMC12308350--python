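"""Mass-action kinetics of bivalent antibody binding.

State variables (molecules per cell): free antigens ``r``, free antibodies
``a0``, monovalently bound antibodies ``a1``, bivalently bound antibodies
``a2``.  The full system is

    dr/dt  = -2 k1 r a0 + koff a1 - k2 r a1 + 2 koff a2
    da0/dt = -2 k1 r a0 + koff a1
    da1/dt =  2 k1 r a0 - koff a1 - k2 r a1 + 2 koff a2
    da2/dt =  k2 r a1 - 2 koff a2

The statistical factors of 2 reflect that the two arms are identical and
independent: a free antibody can bind with either arm, and a bivalently bound
antibody can release either arm.  Antibody and antigen numbers are conserved
(a0+a1+a2 = Atot, r+a1+2 a2 = rtot), which reduces the dynamics to (a1, a2);
the reduced system is what gets integrated, the full one exists for testing.

Time scales span sub-second (high dose) to days (doses ~1e-12 M), so steady
state is found with a stiff implicit integrator on geometrically growing
horizons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ModelParameters

__all__ = [
    "BindingState",
    "ConvergenceError",
    "rhs_full",
    "rhs_reduced",
    "jacobian_reduced",
    "simulate",
    "integrate_to_steady_state",
]


@dataclass(frozen=True)
class BindingState:
    """Molecule numbers of one binding configuration at time ``t``."""

    r: float
    a0: float
    a1: float
    a2: float
    t: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.a0, self.a1, self.a2])


class ConvergenceError(RuntimeError):
    """Steady state was not reached within the maximum horizon.

    Carries the last integrated state in ``last_state``.
    """

    def __init__(self, message: str, last_state: BindingState):
        super().__init__(message)
        self.last_state = last_state


def rhs_full(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives (dr, da0, da1, da2) of the full four-variable system."""
    r, a0, a1, a2 = np.asarray(state, dtype=float)
    if min(r, a0, a1, a2) < 0:
        raise ValueError(f"state components must be nonnegative, got {(r, a0, a1, a2)}")
    bind1 = 2.0 * params.k1 * r * a0
    unbind1 = params.koff * a1
    bind2 = params.k2 * r * a1
    unbind2 = 2.0 * params.koff * a2
    return np.array(
        [
            -bind1 + unbind1 - bind2 + unbind2,
            -bind1 + unbind1,
            bind1 - unbind1 - bind2 + unbind2,
            bind2 - unbind2,
        ]
    )


def rhs_reduced(a1: float, a2: float, params: ModelParameters) -> np.ndarray:
    """Time derivatives (da1, da2) after eliminating r and a0 by conservation."""
    if a1 < 0 or a2 < 0:
        raise ValueError(f"bound pools must be nonnegative, got {(a1, a2)}")
    if a1 + 2 * a2 > params.rtot * (1 + 1e-9) + 1e-9:
        raise ValueError("antigen conservation violated: a1 + 2*a2 > rtot")
    if a1 + a2 > params.atot * (1 + 1e-9) + 1e-9:
        raise ValueError("antibody conservation violated: a1 + a2 > atot")
    return _rhs_reduced_unchecked(np.array([a1, a2]), params)


def _rhs_reduced_unchecked(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    a1, a2 = y
    r = params.rtot - a1 - 2.0 * a2
    a0 = params.atot - a1 - a2
    da2 = params.k2 * r * a1 - 2.0 * params.koff * a2
    da1 = 2.0 * params.k1 * r * a0 - params.koff * a1 - da2
    return np.array([da1, da2])


def jacobian_reduced(y: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the reduced system; used by the implicit integrator."""
    a1, a2 = y
    k1, k2, koff = params.k1, params.k2, params.koff
    r = params.rtot - a1 - 2.0 * a2
    a0 = params.atot - a1 - a2
    # d(da2)/d(a1, a2)
    j21 = k2 * (r - a1)
    j22 = -2.0 * k2 * a1 - 2.0 * koff
    # d(da1)/d(a1, a2) = d/d. [2 k1 r a0 - koff a1] - d(da2)/d.
    j11 = -2.0 * k1 * (a0 + r) - koff - j21
    j12 = -2.0 * k1 * (2.0 * a0 + r) - j22
    return np.array([[j11, j12], [j21, j22]])


def _derivative_noise_floor(y: np.ndarray, params: ModelParameters) -> float:
    """Achievable precision of the reduced rhs at a computed state.

    The free pools enter as differences against the totals, so the state is
    only known to O(eps * max(rtot, atot)); propagated through the dynamics
    this bounds how small the evaluated derivative can get.
    """
    jac_norm = float(np.linalg.norm(jacobian_reduced(y, params)))
    scale = max(params.rtot, params.atot, 1.0)
    return 64.0 * np.finfo(float).eps * jac_norm * scale


def _to_state(y: np.ndarray, params: ModelParameters, t: float) -> BindingState:
    a1, a2 = (max(v, 0.0) for v in y)
    return BindingState(
        r=max(params.rtot - a1 - 2.0 * a2, 0.0),
        a0=max(params.atot - a1 - a2, 0.0),
        a1=a1,
        a2=a2,
        t=t,
    )


def simulate(
    params: ModelParameters,
    t_end: float,
    y0: tuple[float, float] = (0.0, 0.0),
    n_points: int = 200,
    rtol: float = 1e-10,
) -> pd.DataFrame:
    """Integrate the reduced system and return the trajectory.

    Returns a DataFrame with columns ``t, r, a0, a1, a2`` (suitable for direct
    CSV export).  Initial condition defaults to everything unbound.
    """
    scale = max(params.rtot, params.atot, 1.0)
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(
        lambda t, y: _rhs_reduced_unchecked(y, params),
        (0.0, t_end),
        np.asarray(y0, dtype=float),
        method="BDF",
        jac=lambda t, y: jacobian_reduced(y, params),
        rtol=rtol,
        atol=1e-12 * scale,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    a1, a2 = sol.y
    return pd.DataFrame(
        {
            "t": sol.t,
            "r": params.rtot - a1 - 2.0 * a2,
            "a0": params.atot - a1 - a2,
            "a1": a1,
            "a2": a2,
        }
    )


def integrate_to_steady_state(
    params: ModelParameters,
    rel_tol: float = 1e-10,
    abs_tol: float = 1e-12,
    max_time: float = 1e14,
    rtol: float = 1e-10,
) -> BindingState:
    """Long-time limit of the reduced system from the all-unbound state.

    Convergence requires both (i) the reduced derivative norm to fall below
    ``abs_tol`` or the evaluation noise floor (the Jacobian norm times machine
    epsilon times the molecule totals -- smaller residuals are unobtainable in
    float64 because the free pools are differences against the totals), and
    (ii) the state to change by less than ``rel_tol`` relatively over the last
    doubling of integration time.

    Raises :class:`ConvergenceError` (carrying the last state) if the horizon
    exceeds ``max_time`` without meeting both criteria.
    """
    if params.atot == 0 or params.rtot == 0:
        return BindingState(r=params.rtot, a0=params.atot, a1=0.0, a2=0.0, t=0.0)

    scale = max(params.rtot, params.atot, 1.0)
    y = np.zeros(2)
    t = 0.0
    # initial horizon: resolve the fast binding transient
    rate0 = 2.0 * params.k1 * params.atot + params.koff + params.k2 * params.rtot
    horizon = min(10.0 / rate0 if rate0 > 0 else 1.0, 1e6)
    while t < max_time:
        sol = solve_ivp(
            lambda tt, yy: _rhs_reduced_unchecked(yy, params),
            (t, t + horizon),
            y,
            method="BDF",
            jac=lambda tt, yy: jacobian_reduced(yy, params),
            rtol=rtol,
            atol=1e-13 * scale,
        )
        if not sol.success:
            raise ConvergenceError(
                f"integration failed at t={t:.3g}: {sol.message}", _to_state(y, params, t)
            )
        y_new = sol.y[:, -1]
        t = sol.t[-1]
        deriv_norm = float(np.linalg.norm(_rhs_reduced_unchecked(y_new, params)))
        noise_floor = _derivative_noise_floor(y_new, params)
        plateau = float(np.linalg.norm(y_new - y)) <= rel_tol * (np.linalg.norm(y_new) + 1.0)
        y = y_new
        if deriv_norm <= max(abs_tol, noise_floor) and plateau:
            return _to_state(y, params, t)
        horizon *= 8.0
    raise ConvergenceError(
        f"no steady state within t={max_time:.3g} s", _to_state(y, params, t)
    )
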