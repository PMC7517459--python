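# kkpeusner

Network-thermodynamic resistance form of the Kedem–Katchalsky equations
for membrane transport of ternary non-electrolyte solutions under
concentration polarization.

## The problem

A selective membrane in a horizontal plane separates two ternary
non-electrolyte solutions (solvent plus two solutes).  Osmotic and
hydrostatic driving forces push a volume flux `Jv` and solute fluxes
`J1`, `J2` through it.  Because the solutions next to the membrane are
not stirred, concentration boundary layers (CBLs) build up on both
faces and soak up part of the driving forces — concentration
polarization (CP).  With gravity in play, the system behaves
differently in its two orientations: configuration **A** has the dilute
solution above the membrane, **B** the reverse.  Whichever orientation
puts the lighter solution underneath loses hydrodynamic stability and
natural convection stirs the layers away.

The package is for membrane biophysicists who want to evaluate this
model quantitatively: compute fluxes, transform them into the
resistance (Peusner) representation, and diagnose where natural
convection switches on along a concentration sweep.

## The model

The CP-attenuated Kedem–Katchalsky equations, with practical
coefficients `Lp` (hydraulic permeability), `σ1, σ2` (reflection) and
`ω_kf` (solute permeabilities), each scaled by a CP coefficient
`ζ ∈ (0, 1]`:

```
Jv = ζp Lp (ΔP − ζv1 σ1 Δπ1 − ζv2 σ2 Δπ2)
J1 = ζs11 ω11 Δπ1 + ζs12 ω12 Δπ2 + C̄1 (1 − ζa1 σ1) Jv
J2 = ζs21 ω21 Δπ1 + ζs22 ω22 Δπ2 + C̄2 (1 − ζa2 σ2) Jv
```

where `Δπk = RT (Ckh − Ckl)` and `C̄k` is the log-mean concentration.
Inverting this linear map expresses the forces
`(ΔP − Δπ1 − Δπ2, Δπ1/C̄1, Δπ2/C̄2)` through the fluxes; the
coefficients of the inverse are the 3×3 **resistance matrix** `R^r`
(r = A, B, or the homogeneous well-stirred limit), with determinant
`det R = [ζp Lp C̄1 C̄2 (ζs11 ω11 ζs22 ω22 − ζs12 ω12 ζs21 ω21)]⁻¹`.

On top of the matrix the package computes

* `ξij = (Rij^A − Rij^B)/Rij` — configuration-difference diagnostics
  whose zeros mark the critical (orientation-independent) state and
  whose signs give the direction of the natural-convection flux,
* degrees of coupling `r_ij = −R_ij/√(R_ii R_jj)`, energy-conversion
  efficiencies `e_ij = r_ji²/(1 + √(1 − r_ij r_ji))²` and Peusner's
  coupling parameter `Q_R = r_ij r_ji/(2 − r_ij r_ji)`,
* CBL physics: `ζ = D/(D + 2RTωδ)` against the layer thickness `δ`,
  solution density differences, and the concentration Rayleigh number
  `R_C = g Δρ δ³/(ρ ν D11)` for the convective-stability check.

The bundled reference parameter set (`nephrophan_fixture`) describes
the Nephrophan cellulose-acetate membrane with glucose (solute 1) in
aqueous ethanol (solute 2): `Lp = 4.9e−12 m³/(N s)`, `σ1 = 0.068`,
`σ2 = 0.025`, `ω11 = 0.8e−9`, `ω22 = 1.43e−9`, `ω12 = 0.81e−13`,
`ω21 = 1.63e−12 mol/(N s)`.

## Worked example

`python examples/resistance_and_coupling.py` prints (abridged):

```
c1bar = 21.67 mol/m^3 (well-stirred):
[[ 2.526e+11 -1.164e+09 -6.818e+08]
 [-1.165e+09  5.768e+07 -3.267e+03]
 [-6.811e+08 -3.778e+04  1.854e+07]]
  R11 = 2.53 x 10^11 Ns/m^3   (hydraulic resistance)
  R12 = -1.16 x 10^9 Ns/mol   (glucose diffusion resistance)
  det R = 2.183e+26 m^3 N^3 s^3 / mol^4
  r12 = 0.305, r21 = 0.305   (volume/glucose degree of coupling)
  e12 = 0.0244   (energy-conversion efficiency)
  Q_R = 0.0488   (Peusner coupling parameter)
```

`R11` is the hydraulic resistance of the membrane at the top of the
studied glucose range; the negative off-diagonals say that solute
gradients drag volume flow along.  The volume/glucose pair is weakly
coupled (`r12 ≈ 0.3`), so at most a couple of percent of the
dissipation in one channel is convertible into the other
(`e12 ≈ 0.024`).

Other examples: `fluxes_single_point.py` (forward fluxes and the
force-reconstruction identity), `boundary_layers_and_convection.py`
(ζ↔δ, Rayleigh number, stability of both orientations),
`concentration_sweep.py` (full diagnostic table over the glucose sweep,
written as CSV).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the reference parameter set alone, the maxima of the
dimensionless volume/glucose coupling degree `r12` and of the `Q_R`
parameter over the studied homogeneous concentration range (mean
glucose up to 21.67 mol/m³, ethanol fixed at 37.71 mol/m³) and writes
them as JSON.  The pipeline is deterministic; `--seed` is recorded for
batch-runner compatibility.

See `docs/methods.md` for model assumptions, numerical choices and
known limitations.
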