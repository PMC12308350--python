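"""Equilibrium binding states via the scaled cubic.

At steady state the reduced kinetics collapse to two algebraic conditions.
With the dimensionless ("hat") scaling Â1 = K2·A1*, Â2 = K2·A2*,
r̂ = K2·rtot, Â = K2·Atot (K1 = k1/koff, K2 = k2/koff, K21 = K2/K1), the
cross-linking balance gives

    Â2 = Â1 (r̂ - Â1) / (2 (1 + Â1)),

and substituting it into the monovalent balance and multiplying through by
(1 + Â1)^2 yields a cubic in Â1:

    (1 - K21) x^3 + 2 (1 - Â - K21) x^2
      + (2 Â (r̂ - 1) - K21 - r̂^2 - 2 r̂) x + 2 Â r̂ = 0.

For the physiological regime K21 = k2·sigma/kon >> 1 the coefficient sequence
has exactly one sign change, so by Descartes' rule of signs the cubic has
exactly one real positive root -- the unique stable equilibrium.  The solver
takes the closed-form roots, polishes with Newton, and falls back to bracketed
root finding on the unscaled variable whenever root selection or the residual
check is ambiguous (e.g. K21 near 1).

The monovalent analogue (k2 = 0) reduces to a quadratic solved in closed form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .params import ModelParameters

__all__ = [
    "EquilibriumError",
    "CubicCoefficients",
    "EquilibriumResult",
    "a2_from_a1",
    "build_cubic",
    "solve_bivalent_equilibrium",
    "solve_monovalent_equilibrium",
    "steady_state_residuals",
]

_RESIDUAL_TOL = 1e-8


class EquilibriumError(RuntimeError):
    """No acceptable equilibrium root could be identified."""


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients (c3 x^3 + c2 x^2 + c1 x + c0) of the scaled cubic.

    ``alpha`` is the linear coefficient of the monic form (divided through by
    1 - K21), kept for reference; it is NaN in the degenerate case K21 = 1.
    """

    c3: float
    c2: float
    c1: float
    c0: float
    alpha: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c3, self.c2, self.c1, self.c0])

    def sign_changes(self) -> int:
        coeffs = [c for c in self.as_array() if c != 0.0]
        return int(np.sum(np.diff(np.sign(coeffs)) != 0))


def a2_from_a1(a1_hat: float, rtot_hat: float) -> float:
    """Scaled bivalent pool Â2 from Â1 at the cross-linking balance."""
    if a1_hat < 0:
        raise ValueError(f"scaled pool must be nonnegative, got {a1_hat}")
    if a1_hat > rtot_hat * (1 + 1e-12):
        raise ValueError(f"scaled pool {a1_hat} exceeds scaled antigen total {rtot_hat}")
    return a1_hat * (rtot_hat - a1_hat) / (2.0 * (1.0 + a1_hat))


def build_cubic(rtot_hat: float, ainit_hat: float, k21: float) -> CubicCoefficients:
    """Cubic in Â1 whose positive root is the bivalent equilibrium.

    ``ainit_hat`` is the scaled antibody total K2·Atot (= K2·sigma·Ainit).
    """
    if not math.isfinite(k21):
        raise ValueError(f"K21 must be finite, got {k21}")
    c3 = 1.0 - k21
    c2 = 2.0 * (1.0 - ainit_hat - k21)
    c1 = 2.0 * ainit_hat * (rtot_hat - 1.0) - k21 - rtot_hat**2 - 2.0 * rtot_hat
    c0 = 2.0 * ainit_hat * rtot_hat
    alpha = c1 / c3 if c3 != 0.0 else math.nan
    return CubicCoefficients(c3=c3, c2=c2, c1=c1, c0=c0, alpha=alpha)


def steady_state_residuals(
    a1: float,
    a2: float,
    params: ModelParameters,
    r: float | None = None,
    a0: float | None = None,
) -> tuple[float, float]:
    """Relative residuals of the two steady-state balances at (a1, a2).

    Each residual is normalised by the largest constituent flux term, so values
    well below 1 mean the balance holds to that relative precision.  The free
    pools ``r`` and ``a0`` may be supplied explicitly; recovering them by
    subtraction (the default) loses precision when nearly all of one species
    is bound, e.g. deep in the tight-binding regime.
    """
    if r is None:
        r = params.rtot - a1 - 2.0 * a2
    if a0 is None:
        a0 = params.atot - a1 - a2
    terms2 = (params.k2 * r * a1, 2.0 * params.koff * a2)
    res2 = terms2[0] - terms2[1]
    terms1 = (2.0 * params.k1 * r * a0, params.koff * a1)
    res1 = terms1[0] - terms1[1]
    scale2 = max(*(abs(t) for t in terms2), 1e-300)
    scale1 = max(*(abs(t) for t in terms1), 1e-300)
    return abs(res1) / scale1, abs(res2) / scale2


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium molecule numbers with solver diagnostics."""

    a1: float
    a2: float
    r: float
    a0: float
    residual_monovalent: float
    residual_crosslink: float
    method: str

    def to_json(self, params: ModelParameters | None = None) -> str:
        record = {"equilibrium": asdict(self)}
        if params is not None:
            record["inputs"] = asdict(params)
        return json.dumps(record, indent=2, sort_keys=True)


def _result(
    a1: float,
    a2: float,
    params: ModelParameters,
    method: str,
    r: float | None = None,
    a0: float | None = None,
) -> EquilibriumResult:
    if r is None:
        r = max(params.rtot - a1 - 2.0 * a2, 0.0)
    if a0 is None:
        a0 = max(params.atot - a1 - a2, 0.0)
    res1, res2 = steady_state_residuals(a1, a2, params, r=r, a0=a0)
    return EquilibriumResult(
        a1=a1,
        a2=a2,
        r=r,
        a0=a0,
        residual_monovalent=res1,
        residual_crosslink=res2,
        method=method,
    )


def _conservation_solve(params: ModelParameters) -> tuple[float, float, float, float]:
    """Equilibrium via the free pools (r, a0); conditioning-safe fallback.

    Writing the balances as a1 = 2 K1 r a0 and a2 = K1 K2 r^2 a0 makes both
    rate equations hold identically; the remaining conditions are the two
    conservation laws.  Antibody conservation gives a0(r) in closed form, and
    antigen conservation becomes a scalar root-finding problem in r with no
    subtractive cancellation in any term.
    """
    big_k1 = params.k1 / params.koff
    big_k2 = params.k2 / params.koff
    k1k2 = big_k1 * big_k2

    def free_antibody(r: float) -> float:
        return params.atot / (1.0 + 2.0 * big_k1 * r + k1k2 * r * r)

    def antigen_gap(r: float) -> float:
        a0 = free_antibody(r)
        return r * (1.0 + 2.0 * big_k1 * a0 + 2.0 * k1k2 * r * a0) - params.rtot

    lo = params.rtot * 1e-300
    r = brentq(antigen_gap, lo, params.rtot, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    a0 = free_antibody(r)
    a1 = 2.0 * big_k1 * r * a0
    a2 = k1k2 * r * r * a0
    return a1, a2, r, a0


def solve_bivalent_equilibrium(params: ModelParameters) -> EquilibriumResult:
    """Unique positive equilibrium (A1*, A2*) of the bivalent model, in molecules.

    Solves the scaled cubic in closed form, selects the real positive root that
    respects both conservation laws, polishes it with Newton iterations and
    verifies the steady-state residuals; falls back to bracketed root finding
    in the unscaled variable if selection or residuals fail.
    """
    if params.koff <= 0:
        raise ValueError("equilibrium requires koff > 0")
    if params.atot == 0 or params.rtot == 0:
        return _result(0.0, 0.0, params, method="trivial")
    if params.k2 == 0:
        a1 = solve_monovalent_equilibrium(params)
        return _result(a1, 0.0, params, method="monovalent")

    big_k2 = params.k2 / params.koff
    k21 = params.k2 / params.k1 if params.k1 > 0 else math.inf
    rtot_hat = big_k2 * params.rtot
    ainit_hat = big_k2 * params.atot
    x_max = big_k2 * min(params.rtot, params.atot)

    a1 = None
    method = "cubic"
    if math.isfinite(k21) and abs(1.0 - k21) > 1e-9 * k21:
        cubic = build_cubic(rtot_hat, ainit_hat, k21)
        roots = np.roots(cubic.as_array())
        real = roots[np.abs(roots.imag) <= 1e-9 * (np.abs(roots.real) + 1.0)].real
        candidates = [x for x in real if 0.0 < x <= x_max * (1.0 + 1e-9)]
        if len(candidates) == 1:
            x = float(min(candidates[0], x_max))
            # Newton polish on the cubic
            c = cubic.as_array()
            dc = np.polyder(c)
            for _ in range(3):
                fx = np.polyval(c, x)
                dfx = np.polyval(dc, x)
                if dfx == 0.0:
                    break
                step = fx / dfx
                if not (0.0 <= x - step <= x_max):
                    break
                x -= step
            a1 = x / big_k2
        elif len(candidates) > 1:
            # Descartes argument violated numerically -- defer to the bracket.
            a1 = None

    if a1 is not None:
        a2 = a2_from_a1(big_k2 * a1, rtot_hat) / big_k2
        res1, res2 = steady_state_residuals(a1, a2, params)
        if max(res1, res2) <= _RESIDUAL_TOL:
            return _result(a1, a2, params, method=method)

    a1, a2, r, a0 = _conservation_solve(params)
    result = _result(a1, a2, params, method="conservation", r=r, a0=a0)
    conservation_gap = max(
        abs(r + a1 + 2.0 * a2 - params.rtot) / params.rtot,
        abs(a0 + a1 + a2 - params.atot) / params.atot,
    )
    if max(result.residual_monovalent, result.residual_crosslink, conservation_gap) > 1e-6:
        raise EquilibriumError(
            f"equilibrium residuals too large ({result.residual_monovalent:.2e}, "
            f"{result.residual_crosslink:.2e}, conservation {conservation_gap:.2e}) "
            f"for params {params}"
        )
    return result


def solve_monovalent_equilibrium(params: ModelParameters) -> float:
    """Equilibrium A1* of the one-armed model (k2 = 0), in molecules.

    Closed-form root of 2 K1 (rtot - A1)(Atot - A1) = A1 lying in
    [0, min(rtot, Atot)], evaluated in the numerically stable form.
    """
    if params.koff <= 0:
        raise ValueError("equilibrium requires koff > 0")
    if params.atot == 0 or params.rtot == 0 or params.k1 == 0:
        return 0.0
    two_k1 = 2.0 * params.k1 / params.koff
    b = two_k1 * (params.rtot + params.atot) + 1.0
    c = two_k1 * params.rtot * params.atot
    disc = b * b - 4.0 * two_k1 * c
    if disc < 0:
        raise EquilibriumError(f"negative discriminant for params {params}")
    # smaller root, stable against cancellation
    return 2.0 * c / (b + math.sqrt(disc))
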