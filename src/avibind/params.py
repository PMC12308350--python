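"""Unit conversions and derived rate constants.

The model works internally in "molecules per cell, seconds": molar antibody
concentrations and laboratory assay geometry are converted at the boundary into
per-cell molecule numbers and per-molecule rates.  The conversion hinges on the
"mAb molecules per cell" factor

    sigma = Vwell * Na / T0        [M^-1 cell^-1]

so that an antibody dose ``Ainit`` (molar) corresponds to ``Atot = Ainit * sigma``
antibody molecules available to one target cell, and the solution on-rate
``kon`` (s^-1 M^-1) becomes the per-molecule rate ``k1 = kon / sigma``.

Two estimators are provided for the cross-linking rate ``k2`` of the second
antibody arm:

* ``k2_diffusion`` -- the default: binding of the second arm is limited by
  antigen diffusion on the membrane, ``k2 = D / (4 pi Trad^2)`` (a first-hitting
  time estimate for a diffusing antigen finding the free arm of a bound
  antibody).
* ``k2_proximity`` -- the alternative: antigens are immobile and the rate is set
  by the free-antigen concentration within reach of the bound arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "AssayGeometry",
    "RateParameters",
    "DerivedRates",
    "ModelParameters",
    "conversion_factor",
    "antibodies_per_cell",
    "k1_from_kon",
    "k2_diffusion",
    "k2_proximity",
    "arm_reach_fraction",
    "derive_rates",
]

#: Avogadro's number (mol^-1), fixed at the precision used throughout.
AVOGADRO = 6.02214e23

#: Prefactor of the proximity (immobile-antigen) k2 estimator, taken as printed.
_PROXIMITY_PREFACTOR = 38e3


@dataclass(frozen=True)
class AssayGeometry:
    """Physical geometry of the binding assay.

    Parameters
    ----------
    v_well : float
        Reaction well volume in litres (default 150 µl).
    t0 : float
        Number of target cells in the well (default 2e5).
    t_rad : float
        Target cell radius in metres (default 8 µm).
    """

    v_well: float = 150e-6
    t0: float = 2e5
    t_rad: float = 8e-6

    def __post_init__(self) -> None:
        if self.v_well <= 0:
            raise ValueError(f"well volume must be positive, got {self.v_well}")
        if self.t0 < 1:
            raise ValueError(f"target cell count must be >= 1, got {self.t0}")
        if self.t_rad <= 0:
            raise ValueError(f"cell radius must be positive, got {self.t_rad}")


@dataclass(frozen=True)
class RateParameters:
    """Laboratory-unit binding parameters of one antibody/antigen pair.

    Parameters
    ----------
    kon : float
        Solution association rate (s^-1 M^-1).
    koff : float
        Per-arm dissociation rate (s^-1).
    d_antigen : float
        Antigen diffusion coefficient on the membrane (m^2 s^-1).
    r_ab : float
        Antibody arm-to-arm reach (metres); IgG is ~12-13 nm.
    """

    kon: float = 1e5
    koff: float = 1e-4
    d_antigen: float = 1e-14
    r_ab: float = 12.5e-9

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "d_antigen", "r_ab"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")


def conversion_factor(geometry: AssayGeometry) -> float:
    """Molecules-per-cell conversion factor sigma = Vwell * Na / T0 (M^-1 cell^-1)."""
    return geometry.v_well * AVOGADRO / geometry.t0


def antibodies_per_cell(ainit: float, sigma: float) -> float:
    """Total antibody molecules per target cell, Atot = Ainit * sigma.

    ``ainit`` is the initial antibody concentration in molar.
    """
    if ainit < 0:
        raise ValueError(f"antibody concentration must be nonnegative, got {ainit}")
    if sigma <= 0:
        raise ValueError(f"conversion factor must be positive, got {sigma}")
    return ainit * sigma


def k1_from_kon(kon: float, sigma: float) -> float:
    """Per-molecule association rate k1 = kon / sigma (s^-1 per antibody)."""
    if kon < 0:
        raise ValueError(f"kon must be nonnegative, got {kon}")
    if sigma <= 0:
        raise ValueError(f"conversion factor must be positive, got {sigma}")
    return kon / sigma


def k2_diffusion(d_antigen: float, t_rad: float) -> float:
    """Diffusion-limited second-arm rate k2 = D / (4 pi Trad^2) (s^-1 per antigen)."""
    if d_antigen < 0:
        raise ValueError(f"diffusion coefficient must be nonnegative, got {d_antigen}")
    if t_rad <= 0:
        raise ValueError(f"cell radius must be positive, got {t_rad}")
    return d_antigen / (4.0 * math.pi * t_rad**2)


def k2_proximity(kon: float, t_rad: float, r_ab: float) -> float:
    """Immobile-antigen second-arm rate estimate.

    Assumes the second binding event is limited by the concentration of free
    antigen within reach of the bound arm:

        k2 = 38e3 * kon / (pi * Na * Trad^2 * rAb)

    Provided as an alternative to :func:`k2_diffusion`, not the default.
    """
    if kon < 0:
        raise ValueError(f"kon must be nonnegative, got {kon}")
    if t_rad <= 0 or r_ab <= 0:
        raise ValueError("cell radius and arm reach must be positive")
    return _PROXIMITY_PREFACTOR * kon / (math.pi * AVOGADRO * t_rad**2 * r_ab)


def arm_reach_fraction(r_ab: float, t_rad: float) -> float:
    """Area swept by one antibody arm as a fraction of the cell surface.

    The disc of radius ``r_ab`` reachable by the free arm, over the cell surface
    ``4 pi Trad^2``: ``rAb^2 / (4 Trad^2)``.  For IgG on a typical tumour cell
    this is ~6e-7, which motivates treating antigen diffusion (not static
    proximity) as the rate-limiting step for cross-linking.
    """
    if r_ab < 0:
        raise ValueError(f"arm reach must be nonnegative, got {r_ab}")
    if t_rad <= 0:
        raise ValueError(f"cell radius must be positive, got {t_rad}")
    return r_ab**2 / (4.0 * t_rad**2)


@dataclass(frozen=True)
class DerivedRates:
    """Per-cell number-unit rates derived from laboratory parameters.

    ``big_k1 = k1/koff`` and ``big_k2 = k2/koff`` are the scaled association
    constants of the first and second binding step; ``k21 = big_k2/big_k1``
    controls the equilibrium structure (one positive root when k21 >> 1).
    """

    sigma: float
    k1: float
    k2: float
    big_k1: float
    big_k2: float
    k21: float


def derive_rates(
    geometry: AssayGeometry,
    rates: RateParameters,
    k2_mode: str = "diffusion",
) -> DerivedRates:
    """Compute sigma, k1, k2 and the equilibrium constants K1, K2, K21.

    ``k2_mode`` selects the cross-linking estimator: ``"diffusion"`` (default)
    or ``"proximity"``.
    """
    sigma = conversion_factor(geometry)
    k1 = k1_from_kon(rates.kon, sigma)
    if k2_mode == "diffusion":
        k2 = k2_diffusion(rates.d_antigen, geometry.t_rad)
    elif k2_mode == "proximity":
        k2 = k2_proximity(rates.kon, geometry.t_rad, rates.r_ab)
    else:
        raise ValueError(f"unknown k2_mode {k2_mode!r}; use 'diffusion' or 'proximity'")
    if rates.koff > 0:
        big_k1 = k1 / rates.koff
        big_k2 = k2 / rates.koff
        k21 = big_k2 / big_k1 if big_k1 > 0 else math.inf
    else:
        big_k1 = big_k2 = k21 = math.nan
    return DerivedRates(sigma=sigma, k1=k1, k2=k2, big_k1=big_k1, big_k2=big_k2, k21=k21)


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the per-cell binding model, in molecules and seconds.

    Fields
    ------
    k1 : per-antibody association rate (s^-1)
    k2 : per-antigen cross-linking rate (s^-1)
    koff : per-arm dissociation rate (s^-1)
    rtot : total antigens per cell (molecules)
    atot : total antibodies available to the cell (molecules)
    """

    k1: float
    k2: float
    koff: float
    rtot: float
    atot: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "koff", "rtot", "atot"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")

    @classmethod
    def from_assay(
        cls,
        geometry: AssayGeometry,
        rates: RateParameters,
        rtot: float,
        ainit: float,
        k2_mode: str = "diffusion",
    ) -> "ModelParameters":
        """Build per-cell model parameters from laboratory units."""
        derived = derive_rates(geometry, rates, k2_mode=k2_mode)
        atot = antibodies_per_cell(ainit, derived.sigma)
        return cls(k1=derived.k1, k2=derived.k2, koff=rates.koff, rtot=rtot, atot=atot)

    def monovalent(self) -> "ModelParameters":
        """The one-armed analogue of these parameters (k2 = 0)."""
        return ModelParameters(k1=self.k1, k2=0.0, koff=self.koff, rtot=self.rtot, atot=self.atot)
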