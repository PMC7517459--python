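"""Domain types, physical constants and the Nephrophan reference parameter set.

All quantities are strict SI: concentrations in mol/m^3, pressures in Pa,
lengths in m, permeabilities in mol/(N s), hydraulic permeability in
m^3/(N s).  Presentation scalings (1e11, 1e9, ...) belong to report
formatting, never to the stored values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "GAS_CONSTANT",
    "MembranePracticalCoefficients",
    "BathState",
    "Environment",
    "CPCoefficientSet",
    "RFormIntermediates",
    "log_mean_concentration",
    "osmotic_pressure_difference",
    "nephrophan_fixture",
]

#: molar gas constant, J/(mol K), at the 4-significant-digit precision
#: conventional in the membrane-transport literature (RT = 2478.8 J/mol
#: at 298.15 K)
GAS_CONSTANT = 8.314


@dataclass(frozen=True)
class MembranePracticalCoefficients:
    """Practical ("black box") transport coefficients of the membrane.

    Parameters
    ----------
    Lp : float
        Hydraulic permeability, m^3/(N s).
    sigma1, sigma2 : float
        Reflection coefficients of solutes 1 and 2, dimensionless,
        within [0, 1].
    omega11, omega22 : float
        Diagonal solute permeabilities, mol/(N s).
    omega12, omega21 : float
        Cross permeabilities (solute k driven by the osmotic force of
        the other solute), mol/(N s).
    """

    Lp: float
    sigma1: float
    sigma2: float
    omega11: float
    omega12: float
    omega21: float
    omega22: float

    def __post_init__(self) -> None:
        if self.Lp <= 0:
            raise ValueError(f"Lp must be positive, got {self.Lp}")
        for name in ("sigma1", "sigma2"):
            s = getattr(self, name)
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {s}")
        if self.omega11 <= 0 or self.omega22 <= 0:
            raise ValueError("diagonal permeabilities omega11, omega22 must be positive")
        if self.gamma == 0.0:
            raise ValueError("permeability determinant omega11*omega22 - omega12*omega21 must be nonzero")

    @property
    def gamma(self) -> float:
        """Permeability determinant omega11*omega22 - omega12*omega21, (mol/(N s))^2."""
        return self.omega11 * self.omega22 - self.omega12 * self.omega21


@dataclass(frozen=True)
class Environment:
    """Physical constants and solution properties shared across operations.

    Diffusion coefficients are optional: only D11 is published for the
    reference glucose/ethanol system, so operations that need a D value
    take it explicitly or read the matching attribute and fail loudly
    when it is None.
    """

    R_gas: float = GAS_CONSTANT
    T: float = 298.15  # K; not fixed by the reference data set, configurable
    g: float = 9.81  # m/s^2
    nu: float = 1.063e-6  # kinematic viscosity, m^2/s
    rho_ref: float = 998.3  # reference solution density, kg/m^3
    drho_dC1: float = 0.06  # kg/mol
    drho_dC2: float = -0.0095  # kg/mol
    D11: float | None = 0.69e-9  # m^2/s
    D12: float | None = None
    D21: float | None = None
    D22: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.g < 0:
            raise ValueError("gravitational acceleration must be non-negative")
        if self.nu <= 0 or self.rho_ref <= 0:
            raise ValueError("nu and rho_ref must be positive")
        for name in ("D11", "D22"):
            d = getattr(self, name)
            if d is not None and d <= 0:
                raise ValueError(f"{name} must be positive when given, got {d}")

    @property
    def RT(self) -> float:
        """Product R*T, J/mol."""
        return self.R_gas * self.T


def log_mean_concentration(Ch: float, Cl: float) -> float:
    """Logarithmic mean concentration (Ch - Cl)/ln(Ch/Cl), mol/m^3.

    The mean intramembrane concentration of the Kedem-Katchalsky
    formalism.  Continuous at Ch == Cl (returns the common value).

    >>> round(log_mean_concentration(33.44, 1.0), 2)
    9.24
    """
    if Ch <= 0 or Cl <= 0:
        raise ValueError(f"concentrations must be positive, got ({Ch}, {Cl})")
    if Ch == Cl:
        return float(Cl)
    return (Ch - Cl) / math.log(Ch / Cl)


def osmotic_pressure_difference(Ch: float, Cl: float, env: Environment) -> float:
    """Van 't Hoff osmotic pressure difference RT*(Ch - Cl), Pa."""
    return env.RT * (Ch - Cl)


@dataclass(frozen=True)
class BathState:
    """Bulk (well-mixed) bath concentrations and the hydrostatic pressure step.

    Chamber h holds the concentrated solutions, chamber l the dilute
    ones; dP = Ph - Pl in Pa.
    """

    C1h: float
    C1l: float
    C2h: float
    C2l: float
    dP: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C1h", "C1l", "C2h", "C2l"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.C1h < self.C1l or self.C2h < self.C2l:
            raise ValueError("chamber h concentrations must not be below chamber l")

    @property
    def c1bar(self) -> float:
        """Log-mean concentration of solute 1, mol/m^3."""
        return log_mean_concentration(self.C1h, self.C1l)

    @property
    def c2bar(self) -> float:
        """Log-mean concentration of solute 2, mol/m^3."""
        return log_mean_concentration(self.C2h, self.C2l)

    def delta_pi(self, env: Environment) -> tuple[float, float]:
        """(Delta pi_1, Delta pi_2) osmotic pressure differences, Pa."""
        return (
            osmotic_pressure_difference(self.C1h, self.C1l, env),
            osmotic_pressure_difference(self.C2h, self.C2l, env),
        )

    def with_C1h(self, C1h: float) -> "BathState":
        return replace(self, C1h=C1h)


_ZETA_FIELDS = (
    "zeta_p",
    "zeta_v1",
    "zeta_v2",
    "zeta_a1",
    "zeta_a2",
    "zeta_s11",
    "zeta_s12",
    "zeta_s21",
    "zeta_s22",
)


@dataclass(frozen=True)
class CPCoefficientSet:
    """The nine concentration-polarization coefficients of one configuration.

    Each zeta is the ratio of a practical coefficient measured with
    boundary layers present to its well-stirred value, hence lies in
    (0, 1]: zeta_p scales hydraulic permeability, zeta_v* the osmotic
    (reflection) terms, zeta_a* the advective terms and zeta_s** the
    diffusive permeability matrix.
    """

    zeta_p: float = 1.0
    zeta_v1: float = 1.0
    zeta_v2: float = 1.0
    zeta_a1: float = 1.0
    zeta_a2: float = 1.0
    zeta_s11: float = 1.0
    zeta_s12: float = 1.0
    zeta_s21: float = 1.0
    zeta_s22: float = 1.0
    configuration: str = "homogeneous"

    def __post_init__(self) -> None:
        for name in _ZETA_FIELDS:
            z = getattr(self, name)
            if not 0.0 < z <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {z}")

    @classmethod
    def homogeneous(cls, configuration: str = "homogeneous") -> "CPCoefficientSet":
        """Well-stirred limit: every zeta exactly 1."""
        return cls(configuration=configuration)

    @classmethod
    def reduced(cls, zeta1: float, zeta2: float, configuration: str) -> "CPCoefficientSet":
        """Two-parameter reduction valid for the Nephrophan/glucose/ethanol system.

        Hydraulic and advective polarization are absent
        (zeta_p = zeta_a1 = zeta_a2 = 1) while the solute-1 channel
        shares zeta1 and the solute-2 channel shares zeta2:
        zeta_v1 = zeta_s11 = zeta_s12 = zeta1 and
        zeta_v2 = zeta_s22 = zeta_s21 = zeta2.
        """
        return cls(
            zeta_v1=zeta1,
            zeta_s11=zeta1,
            zeta_s12=zeta1,
            zeta_v2=zeta2,
            zeta_s22=zeta2,
            zeta_s21=zeta2,
            configuration=configuration,
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _ZETA_FIELDS}


@dataclass(frozen=True)
class RFormIntermediates:
    """The alpha/gamma sub-expressions feeding the resistance matrix.

    alpha1..alpha4 mix permeabilities with mean concentrations,
    mol^2/(N s m^3); gamma is the zeta-weighted permeability
    determinant, (mol/(N s))^2.
    """

    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma == 0.0:
            raise ValueError("gamma must be nonzero")


@dataclass(frozen=True)
class FixtureSystem:
    """Bundle returned by :func:`nephrophan_fixture`."""

    membrane: MembranePracticalCoefficients
    env: Environment
    baths: BathState


def nephrophan_fixture(C1h: float = 33.44, dP: float = 0.0) -> FixtureSystem:
    """Reference parameter set: Nephrophan membrane, glucose (1) in aqueous ethanol (2).

    Membrane coefficients are concentration-independent for this
    membrane.  Baths: C2h = 201 mol/m^3, C1l = C2l = 1 mol/m^3, with
    C1h configurable over the studied 1..101 mol/m^3 range (the default
    33.44 mol/m^3 gives the critical mean concentration
    c1bar = 9.24 mol/m^3).
    """
    if not 1.0 <= C1h <= 101.0:
        raise ValueError(f"C1h should lie in the studied range [1, 101] mol/m^3, got {C1h}")
    membrane = MembranePracticalCoefficients(
        Lp=4.9e-12,
        sigma1=0.068,
        sigma2=0.025,
        omega11=0.8e-9,
        omega12=0.81e-13,
        omega21=1.63e-12,
        omega22=1.43e-9,
    )
    env = Environment()
    baths = BathState(C1h=C1h, C1l=1.0, C2h=201.0, C2l=1.0, dP=dP)
    return FixtureSystem(membrane=membrane, env=env, baths=baths)
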