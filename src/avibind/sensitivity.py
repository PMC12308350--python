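"""Variance-based (Sobol) global sensitivity analysis.

First-order indices S_i measure the share of output variance a parameter
explains on its own; total-order indices ST_i add all of its interactions.
Estimation uses the Saltelli cross-sampling design built on a scrambled Sobol
quasi-random sequence: two base matrices A and B of N samples each, plus the
matrices AB_i (A with column i taken from B) and, when second-order indices
are requested, BA_i -- N(2n+2) model evaluations for n parameters.

Estimators (outputs are centred first, which matters when the output nearly
saturates and the variance is small):

    S_i  = mean(f_B * (f_ABi - f_A)) / V          (Saltelli)
    ST_i = mean((f_A - f_ABi)^2) / (2 V)           (Jansen)
    S_ij = [mean(f_BAi * f_ABj) - mean(f_A * f_B)] / V - S_i - S_j

An inert "dummy" parameter is carried through the whole design; its indices
estimate the Monte-Carlo noise floor, so a real parameter is only credibly
influential if its index clears the dummy's.

Parameter uncertainty ranges default to the literature spans (each >= 2
decades), sampled log-uniformly; linear-uniform sampling is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .equilibrium import solve_bivalent_equilibrium
from .metrics import compute_metrics
from .params import AssayGeometry, ModelParameters, RateParameters

__all__ = [
    "ParameterRange",
    "default_ranges",
    "SaltelliDesign",
    "sample_parameters",
    "evaluate_outputs",
    "SobolResult",
    "sobol_indices",
    "sensitivity_experiment",
    "OUTPUT_NAMES",
]

OUTPUT_NAMES = ("occupancy", "bound_ratio", "total_bound")


@dataclass(frozen=True)
class ParameterRange:
    """Sampling range of one input; ``scale`` is 'log' or 'linear'."""

    lower: float
    upper: float
    scale: str = "log"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got ({self.lower}, {self.upper})")
        if self.scale not in ("log", "linear"):
            raise ValueError(f"scale must be 'log' or 'linear', got {self.scale!r}")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError("log-scaled range requires positive bounds")

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        if self.scale == "log":
            lo, hi = np.log10(self.lower), np.log10(self.upper)
            return 10.0 ** (lo + u * (hi - lo))
        return self.lower + u * (self.upper - self.lower)


def default_ranges(scale: str = "log") -> dict[str, ParameterRange]:
    """Literature uncertainty ranges for the binding parameters, plus a dummy."""
    return {
        "kon": ParameterRange(1e4, 1e6, scale),
        "koff": ParameterRange(1e-6, 1e-3, scale),
        "rtot": ParameterRange(1e4, 1e6, scale),
        "d_antigen": ParameterRange(1e-15, 1e-13, scale),
        "dummy": ParameterRange(0.0, 1.0, "linear"),
    }


@dataclass(frozen=True)
class SaltelliDesign:
    """A Saltelli cross-sampling design in physical parameter units."""

    names: tuple[str, ...]
    n_base: int
    seed: int
    second_order: bool
    u_a: np.ndarray = field(repr=False)  # (N, n) unit-hypercube base matrices
    u_b: np.ndarray = field(repr=False)
    ranges: dict[str, ParameterRange] = field(repr=False)

    def _scale(self, u: np.ndarray) -> np.ndarray:
        x = np.empty_like(u)
        for j, name in enumerate(self.names):
            x[:, j] = self.ranges[name].from_unit(u[:, j])
        return x

    @property
    def a(self) -> np.ndarray:
        return self._scale(self.u_a)

    @property
    def b(self) -> np.ndarray:
        return self._scale(self.u_b)

    def ab(self, i: int) -> np.ndarray:
        u = self.u_a.copy()
        u[:, i] = self.u_b[:, i]
        return self._scale(u)

    def ba(self, i: int) -> np.ndarray:
        u = self.u_b.copy()
        u[:, i] = self.u_a[:, i]
        return self._scale(u)

    @property
    def matrix(self) -> np.ndarray:
        """All evaluation rows stacked: A, B, AB_0..AB_{n-1} (and BA_i)."""
        n = len(self.names)
        blocks = [self.a, self.b] + [self.ab(i) for i in range(n)]
        if self.second_order:
            blocks += [self.ba(i) for i in range(n)]
        return np.vstack(blocks)


def sample_parameters(
    ranges: dict[str, ParameterRange] | None = None,
    n: int = 1024,
    seed: int = 0,
    second_order: bool = True,
) -> SaltelliDesign:
    """Draw a Saltelli design of base size ``n`` (a power of two).

    ``n`` must be a power of two to preserve the balance properties of the
    Sobol sequence.  The full design has n*(2d+2) rows with second-order
    blocks (default) or n*(d+2) without, for d parameters.
    """
    if ranges is None:
        ranges = default_ranges()
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"base sample size must be a power of two, got {n}")
    names = tuple(ranges)
    d = len(names)
    sampler = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
    z = sampler.random(n)
    return SaltelliDesign(
        names=names,
        n_base=n,
        seed=seed,
        second_order=second_order,
        u_a=z[:, :d],
        u_b=z[:, d:],
        ranges=dict(ranges),
    )


def evaluate_outputs(
    matrix: np.ndarray,
    names: tuple[str, ...],
    ainit: float,
    geometry: AssayGeometry | None = None,
) -> pd.DataFrame:
    """Equilibrium outputs (occupancy, bound ratio, total bound) per design row.

    Rows give values for the named parameters; ``dummy`` (and any name not
    used by the model) is inert by construction.  The antibody dose ``ainit``
    (molar) is held fixed across the design.  A failed equilibrium aborts the
    evaluation: within the default ranges the solver should never fail, so a
    failure indicates a configuration error rather than a row to impute.
    """
    if geometry is None:
        geometry = AssayGeometry()
    idx = {name: j for j, name in enumerate(names)}
    out = np.empty((len(matrix), len(OUTPUT_NAMES)))
    for i, row in enumerate(np.asarray(matrix, dtype=float)):
        rates = RateParameters(
            kon=row[idx["kon"]], koff=row[idx["koff"]], d_antigen=row[idx["d_antigen"]]
        )
        params = ModelParameters.from_assay(geometry, rates, row[idx["rtot"]], ainit)
        eq = solve_bivalent_equilibrium(params)
        m = compute_metrics(eq.a1, eq.a2, params.rtot)
        out[i] = (m.occupancy, m.bound_ratio, m.total_bound)
    return pd.DataFrame(out, columns=list(OUTPUT_NAMES))


@dataclass(frozen=True)
class SobolResult:
    """Sensitivity indices for one scalar output.

    ``table`` is indexed by parameter name with columns S1, ST, S1_err, ST_err
    (bootstrap standard errors).  ``second_order``, when computed, holds S_ij
    indexed by parameter pairs.  ``zero_variance`` flags a saturated output
    whose indices are undefined (NaN).
    """

    output: str
    table: pd.DataFrame
    n_base: int
    seed: int
    zero_variance: bool
    second_order: pd.DataFrame | None = None


def _index_estimates(f_a, f_b, f_ab):
    """S1 and ST for every parameter from centred block evaluations."""
    v = np.var(np.concatenate([f_a, f_b]))
    s1 = np.array([np.mean(f_b * (f_ab[i] - f_a)) for i in range(len(f_ab))]) / v
    st = np.array([0.5 * np.mean((f_a - f_ab[i]) ** 2) for i in range(len(f_ab))]) / v
    return s1, st


def sobol_indices(
    design: SaltelliDesign,
    outputs: pd.DataFrame | np.ndarray,
    n_boot: int = 100,
    boot_seed: int = 0,
    second_order: bool = False,
) -> dict[str, SobolResult]:
    """Sobol indices from design-ordered output values.

    ``outputs`` must hold one value per row of ``design.matrix`` (one column
    per output).  Returns a result per output column.
    """
    names = design.names
    d = len(names)
    n = design.n_base
    values = pd.DataFrame(outputs)
    expected = n * (2 * d + 2 if design.second_order else d + 2)
    if len(values) != expected:
        raise ValueError(f"expected {expected} output rows, got {len(values)}")
    if second_order and not design.second_order:
        raise ValueError("design was sampled without second-order blocks")

    rng = np.random.default_rng(boot_seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    results: dict[str, SobolResult] = {}
    for col in values.columns:
        f = values[col].to_numpy(dtype=float)
        f = f - np.mean(f[: 2 * n])
        f_a, f_b = f[:n], f[n : 2 * n]
        f_ab = [f[(2 + i) * n : (3 + i) * n] for i in range(d)]
        v = np.var(np.concatenate([f_a, f_b]))
        if v <= 0.0:
            table = pd.DataFrame(
                np.nan, index=list(names), columns=["S1", "ST", "S1_err", "ST_err"]
            )
            results[str(col)] = SobolResult(
                output=str(col), table=table, n_base=n, seed=design.seed, zero_variance=True
            )
            continue
        s1, st = _index_estimates(f_a, f_b, f_ab)
        boot = np.empty((n_boot, 2, d))
        for k, idx in enumerate(boot_idx):
            boot[k] = _index_estimates(f_a[idx], f_b[idx], [fi[idx] for fi in f_ab])
        s1_err, st_err = boot.std(axis=0)
        table = pd.DataFrame(
            {"S1": s1, "ST": st, "S1_err": s1_err, "ST_err": st_err}, index=list(names)
        )
        s2_table = None
        if second_order:
            f_ba = [f[(2 + d + i) * n : (3 + d + i) * n] for i in range(d)]
            base = np.mean(f_a * f_b)
            rows = []
            for i in range(d):
                for j in range(i + 1, d):
                    vij = np.mean(f_ba[i] * f_ab[j]) - base
                    rows.append((names[i], names[j], vij / v - s1[i] - s1[j]))
            s2_table = pd.DataFrame(rows, columns=["param_i", "param_j", "S2"])
        results[str(col)] = SobolResult(
            output=str(col),
            table=table,
            n_base=n,
            seed=design.seed,
            zero_variance=False,
            second_order=s2_table,
        )
    return results


def sensitivity_experiment(
    ainit_list,
    ranges: dict[str, ParameterRange] | None = None,
    n: int = 1024,
    seed: int = 0,
    geometry: AssayGeometry | None = None,
    n_boot: int = 100,
) -> pd.DataFrame:
    """Dose-resolved sensitivity table for all three outputs.

    One Saltelli design (without second-order blocks; total-order indices do
    not need them) is evaluated at each fixed dose in ``ainit_list``.  Returns
    a long-format table with columns output, ainit, parameter, S1, ST, S1_err,
    ST_err, N, seed.
    """
    design = sample_parameters(ranges, n=n, seed=seed, second_order=False)
    matrix = design.matrix
    rows = []
    for ainit in ainit_list:
        outputs = evaluate_outputs(matrix, design.names, ainit, geometry=geometry)
        for result in sobol_indices(design, outputs, n_boot=n_boot, boot_seed=seed).values():
            for param, rec in result.table.iterrows():
                rows.append(
                    {
                        "output": result.output,
                        "ainit": ainit,
                        "parameter": param,
                        "S1": rec["S1"],
                        "ST": rec["ST"],
                        "S1_err": rec["S1_err"],
                        "ST_err": rec["ST_err"],
                        "N": n,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
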