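"""Concentration sweeps and configuration-file round-tripping.

A sweep walks the bath concentration C1h of solute 1 over a grid
(everything else held fixed), evaluates boundary-layer state,
resistance matrices for configurations A, B and the homogeneous limit,
the xi diagnostics, convection classification, fluxes and coupling
statistics at every point, and returns one tidy pandas row per grid
point.  Sweeps are fully deterministic.

Parameter sets round-trip through a flat YAML config file with
documented keys (membrane.Lp, membrane.sigma1, ..., environment.T,
baths.C1h, ..., sweep.c1h_grid, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .boundary_layer import classify_convection, delta_from_zeta, density_difference, rayleigh_number
from .core import BathState, CPCoefficientSet, Environment, MembranePracticalCoefficients
from .coupling import PAIRS, degree_of_coupling, energy_conversion, qr_parameter
from .diagnostics import xi_coefficients
from .profiles import ZetaProfile, evaluate_profile
from .resistance import rform_coefficients
from .transport import kk_fluxes

__all__ = ["SweepSpec", "run_sweep", "write_sweep_csv", "save_config", "load_config"]


def _default_grid() -> tuple[float, ...]:
    # studied bath range: C1h from 1 to 101 mol/m^3 in steps of 2
    return tuple(float(x) for x in np.arange(1.0, 101.0 + 1e-9, 2.0))


@dataclass(frozen=True)
class SweepSpec:
    """What to sweep and how to attenuate the coefficients.

    ``cp_source``: "homogeneous" (all zeta = 1 in both configurations),
    "profiles" (evaluate the supplied zeta(c1bar) profiles per
    configuration), or "explicit" (fixed (zeta1, zeta2) pairs per
    configuration).
    """

    c1h_grid: tuple[float, ...] = field(default_factory=_default_grid)
    C2h: float = 201.0
    C1l: float = 1.0
    C2l: float = 1.0
    dP: float = 0.0
    cp_source: Literal["homogeneous", "profiles", "explicit"] = "profiles"
    variant: Literal["strict_inverse", "as_printed"] = "strict_inverse"
    zeta_A: tuple[float, float] = (1.0, 1.0)
    zeta_B: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        grid = tuple(float(x) for x in self.c1h_grid)
        if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("c1h_grid must be non-empty and strictly increasing")
        object.__setattr__(self, "c1h_grid", grid)
        if self.cp_source not in ("homogeneous", "profiles", "explicit"):
            raise ValueError(f"unknown cp_source {self.cp_source!r}")


def _zetas_at(
    spec: SweepSpec,
    c1bar: float,
    profiles: tuple[ZetaProfile, ZetaProfile] | None,
) -> tuple[tuple[float, float], tuple[float, float]]:
    if spec.cp_source == "homogeneous":
        return (1.0, 1.0), (1.0, 1.0)
    if spec.cp_source == "explicit":
        return spec.zeta_A, spec.zeta_B
    if profiles is None:
        raise ValueError("cp_source='profiles' requires zeta profiles for A and B")
    za = evaluate_profile(profiles[0], c1bar)
    zb = evaluate_profile(profiles[1], c1bar)
    return (za, za), (zb, zb)


def run_sweep(
    spec: SweepSpec,
    membrane: MembranePracticalCoefficients,
    env: Environment,
    profiles: tuple[ZetaProfile, ZetaProfile] | None = None,
) -> pd.DataFrame:
    """Evaluate the full diagnostic battery along the C1h grid.

    Any error while evaluating a grid point is recorded in that row's
    ``error`` column and the sweep continues.
    """
    rows = []
    for c1h in spec.c1h_grid:
        row: dict = {"C1h": c1h}
        try:
            row.update(_evaluate_point(spec, membrane, env, profiles, c1h))
        except Exception as exc:  # noqa: BLE001 - attach to row, keep sweeping
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    df = pd.DataFrame(rows)
    if "error" not in df.columns:
        df["error"] = ""
    else:
        df["error"] = df["error"].fillna("")
    return df


def _evaluate_point(
    spec: SweepSpec,
    membrane: MembranePracticalCoefficients,
    env: Environment,
    profiles: tuple[ZetaProfile, ZetaProfile] | None,
    c1h: float,
) -> dict:
    baths = BathState(C1h=c1h, C1l=spec.C1l, C2h=spec.C2h, C2l=spec.C2l, dP=spec.dP)
    c1bar, c2bar = baths.c1bar, baths.c2bar
    (z1a, z2a), (z1b, z2b) = _zetas_at(spec, c1bar, profiles)
    out = {
        "C1bar": c1bar,
        "C2bar": c2bar,
        "zeta1_A": z1a,
        "zeta2_A": z2a,
        "zeta1_B": z1b,
        "zeta2_B": z2b,
    }

    cp_a = CPCoefficientSet.reduced(z1a, z2a, "A")
    cp_b = CPCoefficientSet.reduced(z1b, z2b, "B")
    cp_h = CPCoefficientSet.homogeneous()

    drho = density_difference(c1h - spec.C1l, spec.C2h - spec.C2l, env)
    out["delta_rho"] = drho
    if env.D11 is not None:
        for label, z1 in (("A", z1a), ("B", z1b)):
            delta = delta_from_zeta(z1, membrane.omega11, env.D11, env)
            assessment = classify_convection(label, drho, rayleigh_number(drho, delta, env))
            out[f"delta_{label}"] = delta
            out[f"rayleigh_{label}"] = assessment.rayleigh
            out[f"regime_{label}"] = assessment.regime.value

    mats = {}
    for label, cp in (("A", cp_a), ("B", cp_b), ("hom", cp_h)):
        mat = rform_coefficients(membrane, cp, c1bar, c2bar, variant=spec.variant)
        mats[label] = mat
        for i in range(3):
            for j in range(3):
                out[f"R{i + 1}{j + 1}_{label}"] = mat.entries[i, j]
        out[f"Rdet_{label}"] = mat.det
        flux = kk_fluxes(membrane, cp, baths, env)
        out[f"Jv_{label}"] = flux.Jv
        out[f"J1_{label}"] = flux.J1
        out[f"J2_{label}"] = flux.J2

    summary = xi_coefficients(mats["A"], mats["B"], mats["hom"])
    for i in range(3):
        for j in range(3):
            out[f"xi_{i + 1}{j + 1}"] = summary.xi[i, j]
            out[f"xi_sign_{i + 1}{j + 1}"] = summary.signs[i, j]
    out["xi_det"] = summary.xi_det

    for label, mat in mats.items():
        r = {(i, j): degree_of_coupling(mat, i, j, "reduced") for i, j in PAIRS}
        for i, j in PAIRS:
            out[f"r{i}{j}_{label}"] = r[(i, j)]
            out[f"e{i}{j}_{label}"] = energy_conversion(r[(i, j)], r[(j, i)])
            if i < j:
                out[f"QR{i}{j}_{label}"] = qr_parameter(r[(i, j)], r[(j, i)])
    return out


def write_sweep_csv(df: pd.DataFrame, path, comment: str | None = None) -> None:
    """Write a sweep table as CSV with a leading unit-annotation comment line.

    Comma separated, '.' decimal, floats in scientific notation with 10
    significant digits: byte-identical across repeated runs of the same
    sweep.
    """
    header = comment or (
        "# units: concentrations mol/m^3, delta m, delta_rho kg/m^3, R11/R21/R31 Ns/m^3 "
        "(strict: R21, R31 scaled by mean concentrations), R12/R13 Ns/mol, "
        "R22/R23/R32/R33 m^3Ns/mol^2, Rdet m^3N^3s^3/mol^4, Jv m/s, J1/J2 mol/(m^2 s), "
        "xi/r/e/QR dimensionless"
    )
    with open(path, "w", newline="") as fh:
        fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, index=False, float_format="%.10e")


_MEMBRANE_KEYS = ("Lp", "sigma1", "sigma2", "omega11", "omega12", "omega21", "omega22")
_ENV_KEYS = ("R_gas", "T", "g", "nu", "rho_ref", "drho_dC1", "drho_dC2", "D11", "D12", "D21", "D22")
_BATH_KEYS = ("C1h", "C1l", "C2h", "C2l", "dP")
_SWEEP_KEYS = ("c1h_grid", "C2h", "C1l", "C2l", "dP", "cp_source", "variant", "zeta_A", "zeta_B")


def save_config(
    path,
    membrane: MembranePracticalCoefficients,
    env: Environment,
    baths: BathState | None = None,
    spec: SweepSpec | None = None,
) -> None:
    """Serialize parameter sets to a flat YAML config file."""
    doc: dict = {
        "membrane": {k: getattr(membrane, k) for k in _MEMBRANE_KEYS},
        "environment": {k: getattr(env, k) for k in _ENV_KEYS},
    }
    if baths is not None:
        doc["baths"] = {k: getattr(baths, k) for k in _BATH_KEYS}
    if spec is not None:
        doc["sweep"] = {
            "c1h_grid": list(spec.c1h_grid),
            "C2h": spec.C2h,
            "C1l": spec.C1l,
            "C2l": spec.C2l,
            "dP": spec.dP,
            "cp_source": spec.cp_source,
            "variant": spec.variant,
            "zeta_A": list(spec.zeta_A),
            "zeta_B": list(spec.zeta_B),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> dict:
    """Load a config file back into domain objects.

    Returns a dict with keys "membrane", "environment" and, when
    present in the file, "baths" and "sweep".  Raises KeyError naming
    the offending key on malformed input.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: dict = {}
    try:
        out["membrane"] = MembranePracticalCoefficients(**{k: doc["membrane"][k] for k in _MEMBRANE_KEYS})
        env_kwargs = {k: doc["environment"][k] for k in _ENV_KEYS if k in doc["environment"]}
        out["environment"] = Environment(**env_kwargs)
        if "baths" in doc:
            out["baths"] = BathState(**{k: doc["baths"][k] for k in _BATH_KEYS})
        if "sweep" in doc:
            s = doc["sweep"]
            out["sweep"] = SweepSpec(
                c1h_grid=tuple(s["c1h_grid"]),
                C2h=s["C2h"],
                C1l=s["C1l"],
                C2l=s["C2l"],
                dP=s["dP"],
                cp_source=s["cp_source"],
                variant=s["variant"],
                zeta_A=tuple(s["zeta_A"]),
                zeta_B=tuple(s["zeta_B"]),
            )
    except KeyError as exc:
        raise KeyError(f"config file {path} is missing key {exc}") from exc
    return out
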