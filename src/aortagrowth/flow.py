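"""Closed-form hemodynamic and mesh-verification formulas.

The wall fields consumed by the stress metrics come from steady
peak-systolic RANS simulations performed elsewhere; no flow is solved here.
This module holds the closed-form quantities used to configure and verify
such a setup: inlet mean velocity through the effective valve orifice, the
inlet Reynolds number, the dimensionless wall distance y+ of the first mesh
node, the grid convergence index (GCI) of a refinement pair, and the outlet
flow-split sanity check.

Unit conventions at the interfaces: flow rate in L/min, diameters in mm,
wall distance in m, stresses in Pa, density in kg/m^3, viscosity in Pa*s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "GciInputs",
    "inlet_velocity",
    "reynolds",
    "y_plus",
    "y_plus_ok",
    "gci",
    "check_outflow_split",
    "DEFAULT_OUTFLOW_SPLIT",
]

#: physiological outlet flow fractions (descending aorta, brachiocephalic
#: trunk, left carotid, left subclavian).
DEFAULT_OUTFLOW_SPLIT = {
    "descending": 0.691,
    "brachiocephalic": 0.193,
    "left_carotid": 0.052,
    "left_subclavian": 0.064,
}

L_PER_MIN_TO_M3_PER_S = 1e-3 / 60.0
MM_TO_M = 1e-3


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid at systolic shear
    rates: density 1054 kg/m^3, dynamic viscosity 3.5 cP."""

    density: float = 1054.0       # kg/m^3
    viscosity: float = 3.5e-3     # Pa*s

    def __post_init__(self):
        if not (self.density > 0 and self.viscosity > 0):
            raise ValueError("fluid properties must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Peak-systole inflow and outlet split applied uniformly to a cohort."""

    q_in_l_min: float = 25.0
    turbulence_intensity: float = 0.05
    outflow_split: dict = field(default_factory=lambda: dict(DEFAULT_OUTFLOW_SPLIT))
    valve_diameter_mm: float | None = None  # per patient

    def __post_init__(self):
        if not self.q_in_l_min > 0:
            raise ValueError("inlet flow must be positive")
        ok, residual = check_outflow_split(self.outflow_split)
        if not ok:
            raise ValueError(f"outflow split invalid (residual {residual:.2e})")
        if self.valve_diameter_mm is not None and not self.valve_diameter_mm > 0:
            raise ValueError("valve diameter must be positive")


def inlet_velocity(q_in_l_min: float, diameter_mm: float) -> float:
    """Mean inlet velocity (m/s) through a circular orifice: V = 4Q/(pi D^2)."""
    if not (q_in_l_min > 0 and diameter_mm > 0):
        raise ValueError("flow rate and diameter must be positive")
    q = q_in_l_min * L_PER_MIN_TO_M3_PER_S
    d = diameter_mm * MM_TO_M
    return 4.0 * q / (np.pi * d * d)


def reynolds(fluid: FluidProperties, q_in_l_min: float,
             diameter_mm: float) -> float:
    """Inlet Reynolds number rho V D / mu based on the effective valve
    diameter (equivalently 4 rho Q / (pi mu D))."""
    v = inlet_velocity(q_in_l_min, diameter_mm)
    return fluid.density * v * diameter_mm * MM_TO_M / fluid.viscosity


def y_plus(fluid: FluidProperties, wall_distance_m: float,
           tau_s: float) -> float:
    """Dimensionless wall distance y+ = rho y u_tau / mu with friction
    velocity u_tau = sqrt(tau_s / rho)."""
    if wall_distance_m < 0 or tau_s < 0:
        raise ValueError("wall distance and shear stress must be >= 0")
    u_tau = np.sqrt(tau_s / fluid.density)
    return fluid.density * wall_distance_m * u_tau / fluid.viscosity


def y_plus_ok(fluid: FluidProperties, wall_distance_m: float, tau_s: float,
              limit: float = 4.0) -> bool:
    """Near-wall resolution criterion: first-node y+ below ``limit``."""
    return y_plus(fluid, wall_distance_m, tau_s) < limit


@dataclass(frozen=True)
class GciInputs:
    """A coarse/fine solution pair for the grid convergence index."""

    phi_coarse: float
    phi_fine: float
    refinement_ratio: float = 2.04
    safety_factor: float = 2.0
    order: float = 2.0

    def __post_init__(self):
        if self.phi_fine == 0:
            raise ValueError("fine-mesh value must be nonzero")
        if not self.refinement_ratio > 1:
            raise ValueError("refinement ratio must exceed 1")
        if not self.safety_factor >= 1:
            raise ValueError("safety factor must be >= 1")
        if not self.order >= 1:
            raise ValueError("discretization order must be >= 1")


def gci(inputs: GciInputs) -> tuple[float, float]:
    """Relative refinement change and grid convergence index.

    ``eps = (phi_coarse - phi_fine) / phi_fine`` and
    ``GCI = Fs |eps| / (r^p - 1)``, both as fractions.  The magnitude of eps
    is used so the index is non-negative regardless of the change's sign.
    """
    eps = (inputs.phi_coarse - inputs.phi_fine) / inputs.phi_fine
    index = (inputs.safety_factor * abs(eps)
             / (inputs.refinement_ratio ** inputs.order - 1.0))
    return float(eps), float(index)


def check_outflow_split(split: dict, tol: float = 1e-6) -> tuple[bool, float]:
    """Check that outlet fractions are positive and sum to one.

    Returns ``(ok, residual)`` with ``residual = |sum - 1|``.
    """
    values = np.asarray(list(split.values()), dtype=float)
    residual = float(abs(values.sum() - 1.0))
    ok = bool(np.all(values > 0) and residual <= tol)
    return ok, residual
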