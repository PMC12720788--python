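"""Quadratic 1:1 binding occupancy and saturation planning.

For total protein [P]0, total ligand [I]0 and dissociation constant KD,
the equilibrium complex concentration of a 1:1 complex is the physical
root of the quadratic mass-balance

    [PI] = ( [P]0 + [I]0 + KD - sqrt(([P]0 + [I]0 + KD)^2 - 4 [P]0 [I]0) ) / 2

and the fractional occupancy is theta = [PI] / [P]0.  Concentrations are
unit-agnostic but must share one unit.  Used to verify that HDX labelling
conditions keep the protein essentially saturated with ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BindingResult",
    "complex_concentration",
    "ligand_for_occupancy",
    "occupancy_mixture_weights",
]


@dataclass(frozen=True)
class BindingResult:
    """Equilibrium outcome of 1:1 binding: complex concentration ``pi``
    (same units as the inputs) and fractional occupancy ``theta``."""

    pi: float
    theta: float


def complex_concentration(kd: float, p0: float, i0: float) -> BindingResult:
    """Equilibrium [PI] and occupancy theta from the quadratic mass balance.

    Evaluated in the numerically stable form
    ``2 p0 i0 / (b + sqrt(b^2 - 4 p0 i0))`` with ``b = p0 + i0 + kd``,
    which avoids catastrophic cancellation when ``4 p0 i0 << b^2``.
    """
    if min(kd, p0, i0) < 0:
        raise ValueError("kd, p0 and i0 must be non-negative")
    if p0 == 0:
        raise ValueError("p0 must be positive")
    if i0 == 0:
        return BindingResult(pi=0.0, theta=0.0)
    b = p0 + i0 + kd
    disc = max(b * b - 4.0 * p0 * i0, 0.0)
    pi = 2.0 * p0 * i0 / (b + math.sqrt(disc))
    pi = min(pi, p0, i0)
    return BindingResult(pi=pi, theta=pi / p0)


def ligand_for_occupancy(kd: float, p0: float, theta_target: float) -> float:
    """Smallest total ligand concentration achieving occupancy
    ``theta_target``.

    Closed form from the mass balance: free ligand at occupancy theta is
    theta*kd/(1-theta), bound ligand is theta*p0, hence

        i0 = theta * p0 + theta * kd / (1 - theta).
    """
    if min(kd, p0) < 0 or p0 == 0:
        raise ValueError("kd must be >= 0 and p0 > 0")
    if not 0 < theta_target < 1:
        raise ValueError(
            "theta_target must lie in (0, 1); full occupancy is unreachable "
            "at finite ligand when kd > 0"
        )
    return theta_target * p0 + theta_target * kd / (1.0 - theta_target)


def occupancy_mixture_weights(result: BindingResult) -> tuple[float, float]:
    """(bound, unbound) population weights for an occupancy mixture."""
    if not 0 <= result.theta <= 1:
        raise ValueError("theta outside [0, 1]")
    return result.theta, 1.0 - result.theta
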