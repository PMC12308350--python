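"""Equilibrium summary quantities.

Five numbers summarise a binding state (A1*, A2*) on a cell carrying ``rtot``
antigens:

* ``a1_frac``, ``a2_frac`` -- fractions of bound antibodies that are mono- and
  bivalently attached (undefined when nothing is bound; see ``no_binding``);
* ``occupancy`` -- fraction of antigens engaged by any arm, (A1 + 2 A2)/rtot;
* ``bound_ratio`` -- bound antibodies per antigen, (A1 + A2)/rtot;
* ``total_bound`` -- absolute bound antibody count, A1 + A2.

Occupancy and the bound counts are the proxies used for effector-function
(e.g. ADCC) potency; the package does not model the effector response itself.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BindingMetrics", "compute_metrics", "METRIC_NAMES"]

METRIC_NAMES = ("a1_frac", "a2_frac", "occupancy", "bound_ratio", "total_bound")


@dataclass(frozen=True)
class BindingMetrics:
    """Summary of one equilibrium binding state.

    When no antibody is bound the valency fractions are undefined;
    ``no_binding`` is then True and ``a1_frac``/``a2_frac`` are None rather
    than a 0/0 sentinel.
    """

    a1_frac: float | None
    a2_frac: float | None
    occupancy: float
    bound_ratio: float
    total_bound: float
    no_binding: bool


def compute_metrics(a1: float, a2: float, rtot: float) -> BindingMetrics:
    """Summary metrics from bound pools ``a1``, ``a2`` on ``rtot`` antigens."""
    if a1 < 0 or a2 < 0:
        raise ValueError(f"bound pools must be nonnegative, got {(a1, a2)}")
    if rtot <= 0:
        raise ValueError(f"rtot must be positive, got {rtot}")
    engaged = a1 + 2.0 * a2
    if engaged > rtot * (1.0 + 1e-9):
        raise ValueError(f"occupancy constraint violated: a1 + 2*a2 = {engaged} > rtot = {rtot}")
    bound = a1 + a2
    if bound == 0.0:
        return BindingMetrics(
            a1_frac=None,
            a2_frac=None,
            occupancy=0.0,
            bound_ratio=0.0,
            total_bound=0.0,
            no_binding=True,
        )
    return BindingMetrics(
        a1_frac=a1 / bound,
        a2_frac=a2 / bound,
        occupancy=min(engaged / rtot, 1.0),
        bound_ratio=bound / rtot,
        total_bound=bound,
        no_binding=False,
    )
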