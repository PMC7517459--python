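"""Empirical concentration dependence of the CP coefficients zeta(c1bar).

For the reference glucose/ethanol system the measured CP coefficients
sit on plateaus at low and high glucose concentration and swing
monotonically between them, with the curves of the two membrane
configurations crossing at the critical mean concentration
c1bar = 9.24 mol/m^3 where zeta = 0.234.  Only the plateaus, the
breakpoints and the crossing are published; the transition shape is
modelled here as a monotone piecewise-cubic (PCHIP) interpolant through
those anchors, clamped to the plateaus outside the transition window.
Profiles are deterministic functions with no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = ["ZetaProfile", "make_reference_profiles", "evaluate_profile"]

#: mean glucose concentration at which the A and B curves cross, mol/m^3
CROSSING_C1BAR = 9.24
#: shared CP coefficient value at the crossing, dimensionless
CROSSING_ZETA = 0.234


@dataclass(frozen=True)
class ZetaProfile:
    """Monotone plateau-transition-plateau model of zeta(c1bar) for one configuration.

    ``direction`` is "decreasing" when the low-concentration plateau is
    the high zeta value (configuration A of the reference system) and
    "increasing" for the mirror case (configuration B).
    """

    plateau_low: float
    plateau_high: float
    crossing_concentration: float
    crossing_zeta: float
    transition_start: float
    transition_end: float
    direction: Literal["decreasing", "increasing"]
    configuration: str = ""
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.plateau_low < self.crossing_zeta < self.plateau_high:
            raise ValueError("crossing zeta must lie strictly between the plateaus")
        if not self.transition_start < self.crossing_concentration < self.transition_end:
            raise ValueError("crossing concentration must lie inside the transition window")
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError(f"unknown direction {self.direction!r}")
        start_val, end_val = (
            (self.plateau_high, self.plateau_low)
            if self.direction == "decreasing"
            else (self.plateau_low, self.plateau_high)
        )
        interp = PchipInterpolator(
            [self.transition_start, self.crossing_concentration, self.transition_end],
            [start_val, self.crossing_zeta, end_val],
            extrapolate=False,
        )
        object.__setattr__(self, "_interp", interp)

    def __call__(self, c1bar):
        return evaluate_profile(self, c1bar)


def evaluate_profile(profile: ZetaProfile, c1bar):
    """Evaluate zeta(c1bar): plateau value outside the transition window, PCHIP inside.

    Accepts scalars or arrays; the result is continuous, monotone and
    bounded by [plateau_low, plateau_high].
    """
    c = np.asarray(c1bar, dtype=float)
    if np.any(c <= 0):
        raise ValueError("c1bar must be positive")
    start_val = profile.plateau_high if profile.direction == "decreasing" else profile.plateau_low
    end_val = profile.plateau_low if profile.direction == "decreasing" else profile.plateau_high
    out = np.where(
        c <= profile.transition_start,
        start_val,
        np.where(c >= profile.transition_end, end_val, profile._interp(c)),
    )
    # PCHIP through monotone anchors is monotone but guard rounding
    out = np.clip(out, profile.plateau_low, profile.plateau_high)
    return float(out) if np.isscalar(c1bar) else out


def make_reference_profiles(
    plateau_low: float = 0.03,
    plateau_high: float = 0.5,
    crossing_concentration: float = CROSSING_C1BAR,
    crossing_zeta: float = CROSSING_ZETA,
    transition_start_A: float = 4.0,
    transition_start_B: float = 5.41,
    transition_end: float = 12.72,
) -> tuple[ZetaProfile, ZetaProfile]:
    """The measured glucose/ethanol CP profiles for configurations A and B.

    Configuration A: zeta constant at 0.5 for c1bar <= 4 mol/m^3,
    monotone decrease through (9.24, 0.234), constant at 0.03 above
    12.72 mol/m^3.  Configuration B mirrors it (plateau 0.03 below
    5.41 mol/m^3, rising to 0.5 above 12.72).  Both solutes share the
    same profile in each configuration.
    """
    profile_a = ZetaProfile(
        plateau_low=plateau_low,
        plateau_high=plateau_high,
        crossing_concentration=crossing_concentration,
        crossing_zeta=crossing_zeta,
        transition_start=transition_start_A,
        transition_end=transition_end,
        direction="decreasing",
        configuration="A",
    )
    profile_b = ZetaProfile(
        plateau_low=plateau_low,
        plateau_high=plateau_high,
        crossing_concentration=crossing_concentration,
        crossing_zeta=crossing_zeta,
        transition_start=transition_start_B,
        transition_end=transition_end,
        direction="increasing",
        configuration="B",
    )
    return profile_a, profile_b
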