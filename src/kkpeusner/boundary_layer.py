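"""Concentration-boundary-layer (CBL) physics.

Conversion between the CP attenuation coefficient zeta and the layer
thickness delta, solution density differences, the concentration
Rayleigh number, and classification of the convective regime of a
horizontal membrane system.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .core import Environment

__all__ = [
    "RAYLEIGH_CRIT_RIGID_FREE",
    "DELTA_RHO_CRIT",
    "ConvectionRegime",
    "LayerState",
    "ConvectionAssessment",
    "zeta_from_delta",
    "delta_from_zeta",
    "density_difference",
    "rayleigh_number",
    "classify_convection",
]

#: critical concentration Rayleigh number for a rigid membrane surface
#: and a free liquid interior (rigid-free boundaries), dimensionless
RAYLEIGH_CRIT_RIGID_FREE = 1100.6

#: density difference rho_h - rho_l at which the reference
#: glucose/ethanol CBL complex is configuration-independent, kg/m^3
DELTA_RHO_CRIT = 0.046

_SYMMETRY_TOL = 1e-9  # m; simplified formulas assume delta_l == delta_h


class ConvectionRegime(str, Enum):
    STABLE = "stable_nonconvective"
    UNSTABLE = "unstable_convective"
    CRITICAL = "critical"


@dataclass(frozen=True)
class LayerState:
    """Boundary-layer thicknesses and per-solute CP coefficients for one configuration."""

    delta_l: float
    delta_h: float
    zeta1: float
    zeta2: float
    configuration: str

    def __post_init__(self) -> None:
        if self.delta_l < 0 or self.delta_h < 0:
            raise ValueError("layer thicknesses must be non-negative")
        for name in ("zeta1", "zeta2"):
            z = getattr(self, name)
            if not 0.0 < z <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {z}")


@dataclass(frozen=True)
class ConvectionAssessment:
    """Outcome of the hydrodynamic-stability check of the CBL complex."""

    configuration: str
    delta_rho: float  # rho_h - rho_l, kg/m^3
    rayleigh: float | None
    rayleigh_crit: float
    regime: ConvectionRegime

    def to_dict(self) -> dict:
        return {
            "configuration": self.configuration,
            "delta_rho": self.delta_rho,
            "rayleigh": self.rayleigh,
            "rayleigh_crit": self.rayleigh_crit,
            "regime": self.regime.value,
        }


def zeta_from_delta(
    omega_ij: float,
    D_l: float,
    D_h: float,
    delta_l: float,
    delta_h: float,
    env: Environment,
) -> float:
    """CP coefficient from boundary-layer thicknesses.

    zeta = 1 / (1 + RT * omega * (delta_l/D_l + delta_h/D_h)); with
    symmetric layers and a single diffusion coefficient this reduces to
    zeta = D / (D + 2 RT omega delta).  Strictly decreasing in each
    thickness; equals 1 when both layers vanish.
    """
    if omega_ij <= 0:
        raise ValueError("omega must be positive")
    if D_l <= 0 or D_h <= 0:
        raise ValueError("diffusion coefficients must be positive")
    if delta_l < 0 or delta_h < 0:
        raise ValueError("layer thicknesses must be non-negative")
    return 1.0 / (1.0 + env.RT * omega_ij * (delta_l / D_l + delta_h / D_h))


def delta_from_zeta(zeta: float, omega_ij: float, D_ij: float, env: Environment) -> float:
    """Symmetric boundary-layer thickness from the CP coefficient.

    delta = D (1 - zeta) / (2 RT omega zeta); exact inverse of
    :func:`zeta_from_delta` under the symmetric-layer assumption
    delta_l == delta_h.
    """
    if not 0.0 < zeta <= 1.0:
        raise ValueError(f"zeta must lie in (0, 1], got {zeta}")
    if omega_ij <= 0 or D_ij <= 0:
        raise ValueError("omega and D must be positive")
    return D_ij * (1.0 - zeta) / (2.0 * env.RT * omega_ij * zeta)


def density_difference(dC1: float, dC2: float, env: Environment) -> float:
    """rho_h - rho_l from the density-concentration partials, kg/m^3.

    Linearised mixture density: (drho/dC1) * dC1 + (drho/dC2) * dC2.
    For glucose/ethanol the partials have opposite signs, so the sign
    of the result switches along the glucose concentration sweep.
    """
    return env.drho_dC1 * dC1 + env.drho_dC2 * dC2


def rayleigh_number(delta_rho: float, delta: float, env: Environment) -> float:
    """Concentration Rayleigh number R_C = g * delta_rho * delta^3 / (rho nu D11)."""
    if delta < 0:
        raise ValueError("layer thickness must be non-negative")
    if env.D11 is None:
        raise ValueError("env.D11 is required for the Rayleigh number")
    if env.rho_ref <= 0 or env.nu <= 0 or env.D11 <= 0:
        raise ValueError("rho_ref, nu and D11 must be positive")
    return env.g * delta_rho * delta**3 / (env.rho_ref * env.nu * env.D11)


def classify_convection(
    configuration: str,
    delta_rho: float,
    rayleigh: float | None = None,
    rayleigh_crit: float = RAYLEIGH_CRIT_RIGID_FREE,
    delta_rho_crit: float = DELTA_RHO_CRIT,
    tol: float = 1e-3,
) -> ConvectionAssessment:
    """Hydrodynamic stability of the CBL complex for one configuration.

    Classification keys on the bulk density difference rho_h - rho_l
    relative to its critical value (the physically causal quantity for
    a horizontal membrane in gravity); the Rayleigh number, when given,
    is carried along as a secondary indicator.  Configuration A holds
    the dilute solution above the membrane, so for delta_rho below
    critical the lighter solution sits underneath and the layer complex
    is unstable; configuration B is its mirror image.
    """
    if configuration not in ("A", "B"):
        raise ValueError(f"configuration must be 'A' or 'B', got {configuration!r}")
    if abs(delta_rho - delta_rho_crit) <= tol:
        regime = ConvectionRegime.CRITICAL
    else:
        below = delta_rho < delta_rho_crit
        unstable = below if configuration == "A" else not below
        regime = ConvectionRegime.UNSTABLE if unstable else ConvectionRegime.STABLE
    return ConvectionAssessment(
        configuration=configuration,
        delta_rho=delta_rho,
        rayleigh=rayleigh,
        rayleigh_crit=rayleigh_crit,
        regime=regime,
    )
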