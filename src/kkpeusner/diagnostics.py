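"""Configuration-difference diagnostics xi_ij and xi_det.

xi_ij = (R_ij^A - R_ij^B) / R_ij compares the resistance coefficients
of the two orientations of the horizontal membrane against the
well-stirred baseline; xi_det does the same for the determinants.
These ratios localise natural-convection effects: a zero entry marks
the critical (configuration-independent) state, and the sign tells
which orientation carries the larger resistance.

The authoritative definition is the entrywise ratio of actual matrices
(:func:`xi_coefficients`).  The published simplified closed forms for
the reduced CP model (:func:`xi_simplified`) are provided exactly as
printed; for the entries that scale as 1/zeta they carry the opposite
sign from the matrix-based definition (their magnitudes agree), a
documented inconsistency in the source formulas that this module
surfaces rather than silently fixes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary_layer import delta_from_zeta
from .core import Environment, MembranePracticalCoefficients
from .resistance import ResistanceMatrix

__all__ = [
    "XiSummary",
    "xi_coefficients",
    "xi_simplified",
    "zeta_difference_factors",
    "classify_signs",
]

#: absolute tolerance below which a xi entry is treated as zero (critical state)
XI_ZERO_TOL = 1e-3


@dataclass(frozen=True)
class XiSummary:
    """xi matrix, xi_det, and their sign classification.

    ``signs`` holds "negative"/"zero"/"positive" per entry (zero within
    ``zero_tol``); ``interpretation`` maps the sign to the direction of
    the natural-convection flux: negative -> "convection_up", zero ->
    "critical", positive -> "convection_down".  ``undefined`` flags
    entries whose homogeneous denominator vanished.
    """

    xi: np.ndarray
    xi_det: float
    signs: np.ndarray
    interpretation: np.ndarray
    undefined: np.ndarray
    zero_tol: float = XI_ZERO_TOL


_SIGN_LABELS = {-1: "negative", 0: "zero", 1: "positive"}
_INTERPRETATION = {-1: "convection_up", 0: "critical", 1: "convection_down"}


def _classify(xi: np.ndarray, zero_tol: float) -> tuple[np.ndarray, np.ndarray]:
    sign_codes = np.where(np.abs(xi) <= zero_tol, 0, np.sign(xi)).astype(int)
    signs = np.vectorize(_SIGN_LABELS.get)(sign_codes)
    interp = np.vectorize(_INTERPRETATION.get)(sign_codes)
    return signs, interp


def _summary_from_xi(xi: np.ndarray, xi_det: float, undefined: np.ndarray, zero_tol: float) -> XiSummary:
    signs, interp = _classify(xi, zero_tol)
    return XiSummary(
        xi=xi,
        xi_det=xi_det,
        signs=signs,
        interpretation=interp,
        undefined=undefined,
        zero_tol=zero_tol,
    )


def xi_coefficients(
    R_A: ResistanceMatrix,
    R_B: ResistanceMatrix,
    R_hom: ResistanceMatrix,
    zero_tol: float = XI_ZERO_TOL,
) -> XiSummary:
    """Entrywise (R^A - R^B)/R with determinant analogue.

    Swapping A and B negates every entry.  A vanishing homogeneous
    entry makes the corresponding ratio undefined; it is flagged and
    returned as NaN rather than crashing or propagating silently.
    """
    if not (R_A.variant == R_B.variant == R_hom.variant):
        raise ValueError("matrices must share the same variant")
    denom = R_hom.entries
    undefined = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(undefined, np.nan, (R_A.entries - R_B.entries) / denom)
    xi_det = np.nan if R_hom.det == 0.0 else (R_A.det - R_B.det) / R_hom.det
    return _summary_from_xi(xi, xi_det, undefined, zero_tol)


def xi_simplified(
    zeta_A: float,
    zeta_B: float,
    membrane: MembranePracticalCoefficients,
    c1bar: float,
    c2bar: float,
    zero_tol: float = XI_ZERO_TOL,
) -> XiSummary:
    """Published closed forms of xi for the reduced single-zeta CP model.

    Assumes zeta_p = zeta_a = 1 and a single shared zeta per
    configuration (valid when the two solutes polarize alike and the
    cross permeabilities are small).  With f = (zA - zB)/(zA zB):

    * xi11 = f * Lp [c1 w22 (1-s1) + c2 w11 (1-s2)]
              / (w11 w22 + Lp [w22 c1 (1-s1)^2 + w11 c2 (1-s2)^2])
    * xi12 = f/(1-s1), xi13 = f/(1-s2)
    * xi21 = xi31 = -f, xi22 = xi23 = xi32 = xi33 = +f
    * xi_det = (zA^2 - zB^2)/(zA^2 zB^2)

    Signs are kept exactly as printed; see the module docstring for the
    known sign inconsistency against :func:`xi_coefficients`.
    """
    for name, z in (("zeta_A", zeta_A), ("zeta_B", zeta_B)):
        if not 0.0 < z <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {z}")
    f = (zeta_A - zeta_B) / (zeta_A * zeta_B)
    Lp, s1, s2 = membrane.Lp, membrane.sigma1, membrane.sigma2
    w11, w22 = membrane.omega11, membrane.omega22
    xi11 = (
        f
        * Lp
        * (c1bar * w22 * (1.0 - s1) + c2bar * w11 * (1.0 - s2))
        / (w11 * w22 + Lp * (w22 * c1bar * (1.0 - s1) ** 2 + w11 * c2bar * (1.0 - s2) ** 2))
    )
    xi12 = f / (1.0 - s1)
    xi13 = f / (1.0 - s2)
    xi = np.array(
        [
            [xi11, xi12, xi13],
            [-f, f, f],
            [-f, f, f],
        ]
    )
    xi_det = (zeta_A**2 - zeta_B**2) / (zeta_A**2 * zeta_B**2)
    return _summary_from_xi(xi, xi_det, np.zeros((3, 3), dtype=bool), zero_tol)


def zeta_difference_factors(
    zeta_A: float,
    zeta_B: float,
    omega_ij: float,
    D_ij: float,
    env: Environment,
) -> tuple[float, float]:
    """The two boundary-layer difference factors driving the simplified xi.

    Expressed through the symmetric layer thicknesses delta^r implied by
    the zeta values:

    * first factor  (zA - zB)/(zA zB)       = 2 RT w (dB - dA)/D
    * second factor (zA^2 - zB^2)/(zA^2 zB^2)
        = (4 RT w / D^2) [D (dB - dA) + RT w (dB^2 - dA^2)]

    Both identities hold exactly under the symmetric-layer CP model, so
    the return values are computed from the thicknesses and agree with
    direct zeta arithmetic to rounding.
    """
    dA = delta_from_zeta(zeta_A, omega_ij, D_ij, env)
    dB = delta_from_zeta(zeta_B, omega_ij, D_ij, env)
    rtw = env.RT * omega_ij
    first = 2.0 * rtw * (dB - dA) / D_ij
    second = 4.0 * rtw / D_ij**2 * (D_ij * (dB - dA) + rtw * (dB**2 - dA**2))
    return first, second


def classify_signs(
    summary: XiSummary,
    R_A: ResistanceMatrix,
    R_B: ResistanceMatrix,
    R_hom: ResistanceMatrix,
    rel_tol: float = 1e-9,
) -> pd.DataFrame:
    """Tabulate, per matrix entry and for the determinant, which ordering criterion applies.

    Each row records the common sign of (R^A, R^B, R) for that entry,
    the ordering of R^A against R^B (equal within ``rel_tol`` of the
    homogeneous magnitude), the ordering of the homogeneous value
    against both, the resulting xi sign and its convective
    interpretation.
    """
    rows = []
    labels = [(i, j) for i in range(3) for j in range(3)]
    for i, j in labels:
        a, b, h = R_A.entries[i, j], R_B.entries[i, j], R_hom.entries[i, j]
        rows.append(_criteria_row(f"xi_{i + 1}{j + 1}", a, b, h, summary.xi[i, j], rel_tol))
    rows.append(_criteria_row("xi_det", R_A.det, R_B.det, R_hom.det, summary.xi_det, rel_tol))
    return pd.DataFrame(rows)


def _criteria_row(entry: str, a: float, b: float, h: float, xi: float, rel_tol: float) -> dict:
    scale = max(abs(a), abs(b), abs(h), 1e-300)
    if abs(a - b) <= rel_tol * scale:
        ordering = "A=B"
    else:
        ordering = "A>B" if a > b else "A<B"
    base = {-1: "negative", 0: "zero", 1: "positive"}[int(np.sign(h))] if h != 0 else "zero"
    hom_vs = (
        "hom between" if min(a, b) <= h <= max(a, b) else ("hom below both" if h < min(a, b) else "hom above both")
    )
    if np.isnan(xi):
        xi_sign, interp = "undefined", "undefined"
    elif abs(xi) <= XI_ZERO_TOL:
        xi_sign, interp = "zero", "critical"
    else:
        xi_sign = "positive" if xi > 0 else "negative"
        interp = "convection_down" if xi > 0 else "convection_up"
    return {
        "entry": entry,
        "base_sign": base,
        "ordering": ordering,
        "hom_position": hom_vs,
        "xi": xi,
        "xi_sign": xi_sign,
        "interpretation": interp,
    }
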