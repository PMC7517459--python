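"""Kedem-Caplan-Peusner coupling degrees, energy conversion and Q_R.

For an index pair (i, j) of the resistance matrix, the degree of
coupling r_ij = -R_ij / sqrt(R_ii R_jj) measures how strongly the two
flux-force channels interact (|r| = 1 is complete coupling), the
energy-conversion efficiency e_ij = r_ji^2 / (1 + sqrt(1 - r_ij r_ji))^2
bounds the fraction of dissipation convertible between them, and
Peusner's Q_R = r_ij r_ji / (2 - r_ij r_ji) is a symmetric coupling
parameter in [0, 1].

These statistics are dimensionless only on the strict-inverse matrix;
the ``reduced`` mode (default) therefore rescales a printed-variant
matrix before forming ratios.  The ``literal`` mode applies the ratio
to the entries exactly as stored, which on a printed matrix makes the
first-column coupling degrees dimensional and typically > 1 - it is
retained for auditing only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .resistance import ResistanceMatrix

__all__ = [
    "PAIRS",
    "CouplingSummary",
    "degree_of_coupling",
    "energy_conversion",
    "e_max",
    "qr_parameter",
    "coupling_sweep_summary",
]

#: the six ordered off-diagonal index pairs, 1-based
PAIRS = ((1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2))

CROSSING_BISECTION_TOL = 1e-3  # mol/m^3


@dataclass(frozen=True)
class CouplingSummary:
    """Coupling statistics of one resistance matrix.

    ``r`` maps each ordered pair (i, j) to the degree of coupling,
    ``e`` to the energy-conversion efficiency e_ij (built from r_ji and
    the product r_ij r_ji), and ``q`` maps each unordered pair to Q_R.
    """

    r: dict[tuple[int, int], float]
    e: dict[tuple[int, int], float]
    q: dict[tuple[int, int], float]
    reduction: Literal["literal", "reduced"]
    configuration: str


def degree_of_coupling(
    matrix: ResistanceMatrix,
    i: int,
    j: int,
    reduction: Literal["literal", "reduced"] = "reduced",
) -> float:
    """Degree of coupling r_ij = -R_ij / sqrt(R_ii R_jj) (1-based indices)."""
    if not (1 <= i <= 3 and 1 <= j <= 3):
        raise ValueError("indices must be 1, 2 or 3")
    if reduction == "reduced":
        matrix = matrix.to_strict()
    elif reduction != "literal":
        raise ValueError(f"unknown reduction {reduction!r}")
    rii = matrix.entries[i - 1, i - 1]
    rjj = matrix.entries[j - 1, j - 1]
    if rii <= 0 or rjj <= 0:
        raise ValueError("diagonal resistance entries must be positive")
    return -matrix.entries[i - 1, j - 1] / sqrt(rii * rjj)


def energy_conversion(r_ij: float, r_ji: float) -> float:
    """Energy-conversion efficiency e_ij = r_ji^2 / (1 + sqrt(1 - r_ij r_ji))^2.

    Equals e_max(r) when r_ij == r_ji == r.
    """
    product = r_ij * r_ji
    if product > 1.0:
        raise ValueError(f"r_ij * r_ji must not exceed 1, got {product}")
    return r_ji**2 / (1.0 + sqrt(1.0 - product)) ** 2


def e_max(r: float) -> float:
    """Maximum energy-conversion efficiency r^2 / (1 + sqrt(1 - r^2))^2 of a symmetric pair."""
    if abs(r) > 1.0:
        raise ValueError(f"|r| must not exceed 1, got {r}")
    return r**2 / (1.0 + sqrt(1.0 - r**2)) ** 2


def qr_parameter(r_ij: float, r_ji: float) -> float:
    """Peusner coupling parameter Q_R = r_ij r_ji / (2 - r_ij r_ji).

    Monotone increasing in the product r_ij r_ji; equals 1 at complete
    coupling (product 1).
    """
    product = r_ij * r_ji
    if product >= 2.0:
        raise ValueError(f"r_ij * r_ji must be below 2, got {product}")
    return product / (2.0 - product)


def coupling_statistics(
    matrix: ResistanceMatrix,
    reduction: Literal["literal", "reduced"] = "reduced",
) -> CouplingSummary:
    """All pairwise coupling statistics of one matrix."""
    r = {(i, j): degree_of_coupling(matrix, i, j, reduction) for i, j in PAIRS}
    e = {(i, j): energy_conversion(r[(i, j)], r[(j, i)]) for i, j in PAIRS}
    q = {(i, j): qr_parameter(r[(i, j)], r[(j, i)]) for (i, j) in PAIRS if i < j}
    return CouplingSummary(r=r, e=e, q=q, reduction=reduction, configuration=matrix.configuration)


def coupling_sweep_summary(
    c1bar_grid: Sequence[float],
    matrices_A: Sequence[ResistanceMatrix],
    matrices_B: Sequence[ResistanceMatrix],
    reduction: Literal["literal", "reduced"] = "reduced",
) -> dict[tuple[int, int], dict]:
    """Per-pair range and A/B crossing summary over a concentration grid.

    For every ordered pair, reports the min/max of r over the grid for
    each configuration and the concentration at which the A and B
    series cross (bisection on a cubic interpolation of their
    difference); ``crossing`` is None when the grid does not bracket a
    sign change.
    """
    grid = np.asarray(c1bar_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("c1bar_grid must be strictly increasing with at least two points")
    if not (len(grid) == len(matrices_A) == len(matrices_B)):
        raise ValueError("grid and matrix sequences must have equal length")
    out: dict[tuple[int, int], dict] = {}
    for i, j in PAIRS:
        series_a = np.array([degree_of_coupling(m, i, j, reduction) for m in matrices_A])
        series_b = np.array([degree_of_coupling(m, i, j, reduction) for m in matrices_B])
        out[(i, j)] = {
            "r_A_min": float(series_a.min()),
            "r_A_max": float(series_a.max()),
            "r_B_min": float(series_b.min()),
            "r_B_max": float(series_b.max()),
            "crossing": _find_crossing(grid, series_a - series_b),
        }
    return out


def _find_crossing(grid: np.ndarray, diff: np.ndarray) -> float | None:
    """Concentration where the interpolated difference changes sign, or None."""
    sign = np.sign(diff)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) == 0:
        # a grid node may sit exactly on the crossing
        zeros = np.nonzero(sign == 0)[0]
        return float(grid[zeros[0]]) if len(zeros) else None
    spline = CubicSpline(grid, diff)
    k = idx[0]
    return float(brentq(spline, grid[k], grid[k + 1], xtol=CROSSING_BISECTION_TOL))
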