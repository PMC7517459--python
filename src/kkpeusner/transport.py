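"""Forward Kedem-Katchalsky flux equations under concentration polarization.

The volume flux and the two solute fluxes of a ternary non-electrolyte
system, each practical coefficient attenuated by its CP coefficient;
setting every zeta to 1 recovers the classical well-stirred equations.
Evaluations are quasi-stationary point calculations: bath
concentrations are treated as fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BathState, CPCoefficientSet, Environment, MembranePracticalCoefficients

__all__ = ["FluxVector", "ForceVector", "kk_fluxes", "forces_from_baths"]


@dataclass(frozen=True)
class FluxVector:
    """Volume flux Jv (m/s) and solute fluxes J1, J2 (mol/(m^2 s))."""

    Jv: float
    J1: float
    J2: float
    configuration: str = "homogeneous"

    def as_array(self) -> np.ndarray:
        return np.array([self.Jv, self.J1, self.J2])


@dataclass(frozen=True)
class ForceVector:
    """Conjugate thermodynamic forces of the resistance representation.

    X1 = dP - dpi1 - dpi2 (Pa), X2 = dpi1/c1bar and X3 = dpi2/c2bar
    (J/mol).  The log-mean construction makes Xk+1 = RT ln(Ckh/Ckl)
    exactly.
    """

    X1: float
    X2: float
    X3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X1, self.X2, self.X3])


def forces_from_baths(baths: BathState, env: Environment) -> ForceVector:
    """Thermodynamic forces (X1, X2, X3) from bath concentrations and dP."""
    dpi1, dpi2 = baths.delta_pi(env)
    return ForceVector(
        X1=baths.dP - dpi1 - dpi2,
        X2=dpi1 / baths.c1bar,
        X3=dpi2 / baths.c2bar,
    )


def fluxes_from_forces(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    forces: ForceVector,
    c1bar: float,
    c2bar: float,
    advective_c1_in_J2: bool = False,
) -> FluxVector:
    """Evaluate the flux equations with forces given directly.

    This is the linear conductance map (Jv, J1, J2) = L (X1, X2, X3) at
    fixed mean concentrations; :func:`kk_fluxes` composes it with
    :func:`forces_from_baths`, and the resistance-matrix inversion
    oracle probes it column by column at unit forces.

    ``advective_c1_in_J2`` reproduces a typographic reading in which the
    advective term of J2 carries c1bar instead of c2bar; the default
    c2bar is the form consistent with the resistance-matrix
    sub-formulas and the standard K-K structure.
    """
    dpi1 = c1bar * forces.X2
    dpi2 = c2bar * forces.X3
    dP = forces.X1 + dpi1 + dpi2
    Jv = cp.zeta_p * membrane.Lp * (
        dP - cp.zeta_v1 * membrane.sigma1 * dpi1 - cp.zeta_v2 * membrane.sigma2 * dpi2
    )
    J1 = (
        cp.zeta_s11 * membrane.omega11 * dpi1
        + cp.zeta_s12 * membrane.omega12 * dpi2
        + c1bar * (1.0 - cp.zeta_a1 * membrane.sigma1) * Jv
    )
    c_adv = c1bar if advective_c1_in_J2 else c2bar
    J2 = (
        cp.zeta_s21 * membrane.omega21 * dpi1
        + cp.zeta_s22 * membrane.omega22 * dpi2
        + c_adv * (1.0 - cp.zeta_a2 * membrane.sigma2) * Jv
    )
    return FluxVector(Jv=Jv, J1=J1, J2=J2, configuration=cp.configuration)


def kk_fluxes(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    baths: BathState,
    env: Environment,
    advective_c1_in_J2: bool = False,
) -> FluxVector:
    """Volume and solute fluxes for one configuration under CP.

    Jv = zeta_p Lp (dP - zeta_v1 sigma1 dpi1 - zeta_v2 sigma2 dpi2),
    J1 = zeta_s11 w11 dpi1 + zeta_s12 w12 dpi2 + c1bar (1 - zeta_a1 sigma1) Jv,
    J2 = zeta_s21 w21 dpi1 + zeta_s22 w22 dpi2 + c2bar (1 - zeta_a2 sigma2) Jv.
    """
    forces = forces_from_baths(baths, env)
    return fluxes_from_forces(
        membrane,
        cp,
        forces,
        baths.c1bar,
        baths.c2bar,
        advective_c1_in_J2=advective_c1_in_J2,
    )
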