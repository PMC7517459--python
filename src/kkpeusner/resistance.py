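"""The 3x3 Peusner resistance matrix of the ternary Kedem-Katchalsky system.

Inverting the flux-force conductance map of the CP-attenuated
Kedem-Katchalsky equations expresses the forces
(dP - dpi1 - dpi2, dpi1/c1bar, dpi2/c2bar) in terms of the fluxes
(Jv, J1, J2); the coefficients of that map form the resistance matrix
R^r for configuration r (A, B, or the homogeneous well-stirred limit).

Two variants coexist:

* ``strict_inverse`` (default) is the exact inverse of the conductance
  map and is dimensionally homogeneous row by row; it backs the
  determinant, coupling and energy statistics.
* ``as_printed`` reproduces the published coefficient sub-formulas,
  whose first-column entries R21 and R31 omit the 1/c1bar and 1/c2bar
  factors the exact inversion carries (their printed unit, N s/m^3,
  matches the unscaled forms).  Use it to reproduce published
  magnitudes.

The published R31 sub-formula also lacks a factor omega21 in its first
term by dimensional analysis and symmetry with R21; both variants
include it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import (
    BathState,
    CPCoefficientSet,
    Environment,
    MembranePracticalCoefficients,
    RFormIntermediates,
)
from .transport import ForceVector, fluxes_from_forces

__all__ = [
    "SingularPermeabilityError",
    "ResistanceMatrix",
    "rform_intermediates",
    "rform_coefficients",
    "rform_determinant",
    "invert_conductance_oracle",
]

Variant = Literal["strict_inverse", "as_printed"]

_GAMMA_FLOOR = 1e-30  # (mol/(N s))^2; below this the system is treated as singular


class SingularPermeabilityError(ValueError):
    """Raised when the zeta-weighted permeability determinant vanishes."""


@dataclass(frozen=True)
class ResistanceMatrix:
    """3x3 resistance coefficients with their provenance.

    ``entries[i, j]`` couples force i+1 to flux j+1.  ``det`` is the
    closed-form determinant for the strict variant (units
    m^3 N^3 s^3 / mol^4) and the direct 3x3 determinant for the printed
    variant.  Mean concentrations are stored so dimensionless coupling
    degrees can be formed from either variant.
    """

    entries: np.ndarray
    variant: Variant
    configuration: str
    c1bar: float
    c2bar: float
    det: float

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (3, 3):
            raise ValueError("entries must be a 3x3 matrix")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, idx):
        return self.entries[idx]

    def to_strict(self) -> "ResistanceMatrix":
        """Return the strict-inverse rescaling of this matrix."""
        if self.variant == "strict_inverse":
            return self
        entries = self.entries.copy()
        entries[1, 0] /= self.c1bar
        entries[2, 0] /= self.c2bar
        return ResistanceMatrix(
            entries=entries,
            variant="strict_inverse",
            configuration=self.configuration,
            c1bar=self.c1bar,
            c2bar=self.c2bar,
            det=float(np.linalg.det(entries)),
        )


def rform_intermediates(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    c1bar: float,
    c2bar: float,
) -> RFormIntermediates:
    """alpha1..alpha4 and the zeta-weighted permeability determinant gamma."""
    alpha1 = cp.zeta_s12 * membrane.omega12 * (1.0 - cp.zeta_a2 * membrane.sigma2) * c2bar
    alpha2 = cp.zeta_s22 * membrane.omega22 * (1.0 - cp.zeta_a1 * membrane.sigma1) * c1bar
    alpha3 = cp.zeta_s21 * membrane.omega21 * (1.0 - cp.zeta_a1 * membrane.sigma1) * c1bar
    alpha4 = cp.zeta_s11 * membrane.omega11 * (1.0 - cp.zeta_a2 * membrane.sigma2) * c2bar
    gamma = (
        cp.zeta_s11 * membrane.omega11 * cp.zeta_s22 * membrane.omega22
        - cp.zeta_s12 * membrane.omega12 * cp.zeta_s21 * membrane.omega21
    )
    if abs(gamma) < _GAMMA_FLOOR:
        raise SingularPermeabilityError(
            "zeta-weighted permeability determinant vanishes; the resistance form "
            "requires omega11*zeta_s11*omega22*zeta_s22 != omega12*zeta_s12*omega21*zeta_s21"
        )
    return RFormIntermediates(alpha1=alpha1, alpha2=alpha2, alpha3=alpha3, alpha4=alpha4, gamma=gamma)


def rform_coefficients(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    c1bar: float,
    c2bar: float,
    variant: Variant = "strict_inverse",
) -> ResistanceMatrix:
    """Closed-form resistance matrix for one configuration.

    With every zeta equal to 1 the CP sub-formulas collapse exactly to
    the homogeneous (well-stirred) coefficients.
    """
    if variant not in ("strict_inverse", "as_printed"):
        raise ValueError(f"unknown variant {variant!r}")
    if c1bar <= 0 or c2bar <= 0:
        raise ValueError("mean concentrations must be positive")
    inter = rform_intermediates(membrane, cp, c1bar, c2bar)
    a1, a2, a3, a4, g = inter.alpha1, inter.alpha2, inter.alpha3, inter.alpha4, inter.gamma
    one_v1 = 1.0 - cp.zeta_v1 * membrane.sigma1
    one_v2 = 1.0 - cp.zeta_v2 * membrane.sigma2
    one_a1 = 1.0 - cp.zeta_a1 * membrane.sigma1
    one_a2 = 1.0 - cp.zeta_a2 * membrane.sigma2

    R11 = 1.0 / (cp.zeta_p * membrane.Lp) - (one_v1 * (a1 - a2) + one_v2 * (a3 - a4)) / g
    R12 = (cp.zeta_s21 * membrane.omega21 * one_v2 - cp.zeta_s22 * membrane.omega22 * one_v1) / g
    R13 = (cp.zeta_s12 * membrane.omega12 * one_v1 - cp.zeta_s11 * membrane.omega11 * one_v2) / g
    R21 = (
        cp.zeta_s12 * membrane.omega12 * one_a2 * c2bar
        - cp.zeta_s22 * membrane.omega22 * one_a1 * c1bar
    ) / g
    R22 = cp.zeta_s22 * membrane.omega22 / (g * c1bar)
    R23 = -cp.zeta_s12 * membrane.omega12 / (g * c1bar)
    R31 = (
        cp.zeta_s21 * membrane.omega21 * one_a1 * c1bar
        - cp.zeta_s11 * membrane.omega11 * one_a2 * c2bar
    ) / g
    R32 = -cp.zeta_s21 * membrane.omega21 / (g * c2bar)
    R33 = cp.zeta_s11 * membrane.omega11 / (g * c2bar)

    entries = np.array([[R11, R12, R13], [R21, R22, R23], [R31, R32, R33]])
    if variant == "strict_inverse":
        entries[1, 0] /= c1bar
        entries[2, 0] /= c2bar
        det = 1.0 / (cp.zeta_p * membrane.Lp * c1bar * c2bar * g)
    else:
        det = float(np.linalg.det(entries))
    return ResistanceMatrix(
        entries=entries,
        variant=variant,
        configuration=cp.configuration,
        c1bar=c1bar,
        c2bar=c2bar,
        det=det,
    )


def rform_determinant(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    c1bar: float,
    c2bar: float,
) -> float:
    """Closed-form determinant of the strict resistance matrix.

    det R = [zeta_p Lp c1bar c2bar gamma]^-1, whose sign follows the
    sign of the zeta-weighted permeability determinant gamma.
    """
    inter = rform_intermediates(membrane, cp, c1bar, c2bar)
    return 1.0 / (cp.zeta_p * membrane.Lp * c1bar * c2bar * inter.gamma)


def invert_conductance_oracle(
    membrane: MembranePracticalCoefficients,
    cp: CPCoefficientSet,
    baths: BathState,
    env: Environment,
    cond_limit: float = 1e12,
) -> np.ndarray:
    """Numerical inverse of the flux-force conductance map.

    Builds L column by column by evaluating the forward flux equations
    at unit forces (holding the mean concentrations of ``baths`` fixed)
    and inverts it numerically.  Serves as an implementation-independent
    oracle for the closed-form strict resistance matrix.
    """
    c1bar, c2bar = baths.c1bar, baths.c2bar
    cols = []
    for unit in (ForceVector(1, 0, 0), ForceVector(0, 1, 0), ForceVector(0, 0, 1)):
        cols.append(fluxes_from_forces(membrane, cp, unit, c1bar, c2bar).as_array())
    L = np.column_stack(cols)
    cond = np.linalg.cond(L)
    # L entries span ~12 orders of magnitude in SI, so the raw condition
    # number is large even for perfectly regular systems; rescale rows
    # to judge true singularity.
    scale = np.abs(L).max(axis=1)
    if np.any(scale == 0) or np.linalg.cond(L / scale[:, None]) > cond_limit:
        raise SingularPermeabilityError(
            f"conductance map is numerically singular (condition number {cond:.3e})"
        )
    return np.linalg.inv(L)
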