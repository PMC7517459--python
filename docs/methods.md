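# Methods

## Model

The package evaluates stationary, isothermal transport of a ternary
non-electrolyte solution (solvent + two solutes) across a flat,
isotropic, electroneutral membrane in a horizontal plane.  Transport is
described by the practical Kedem–Katchalsky coefficients — hydraulic
permeability `Lp`, reflection coefficients `σ1, σ2`, and the 2×2 solute
permeability matrix `ω_kf` — treated as concentration-independent
membrane constants.  Concentration polarization is modelled
multiplicatively: each practical coefficient is scaled by a coefficient
`ζ ∈ (0, 1]` that compares the layered system to its well-stirred
limit.  Nine ζ values (hydraulic, two osmotic, two advective, four
diffusive) describe one orientation of the system; the well-stirred
limit has all nine equal to 1.

The resistance (Peusner) representation is obtained by inverting the
flux–force conductance map of the flux equations.  Two variants of the
3×3 matrix are kept side by side:

* **strict_inverse** (default): the exact inverse of the conductance
  map.  It satisfies the reconstruction identity `R · J = X` to
  rounding, its determinant has the closed form
  `[ζp Lp C̄1 C̄2 γζ]⁻¹` with
  `γζ = ζs11 ω11 ζs22 ω22 − ζs12 ω12 ζs21 ω21`, and every derived
  statistic (coupling degrees, efficiencies, Q_R) is dimensionless.
* **as_printed**: the published sub-formula set, whose first-column
  entries `R21` and `R31` are larger than the strict ones by factors
  `C̄1` and `C̄2` respectively (their published unit, N s/m³, matches
  the unscaled forms).  This variant reproduces published coefficient
  magnitudes; it is not used for determinants or coupling statistics.

The published `R31` sub-formula lacks a factor `ω21` in its first term;
dimensional analysis and symmetry with `R21` require it, and both
variants include it.  The published determinant typography is ambiguous
between a product and a reciprocal; the reciprocal reading is
implemented because it equals the brute-force 3×3 determinant of the
strict matrix and obeys the stated sign rule (det shares the sign of
γζ).  The advective term of the second solute's flux uses `C̄2`; an
`advective_c1_in_J2` toggle reproduces the alternative `C̄1` reading
verbatim for auditability.

## Reference system and parameters

`nephrophan_fixture()` bundles the Nephrophan cellulose-acetate
membrane with glucose (solute 1) in 201 mol/m³ aqueous ethanol
(solute 2):

| quantity | value | unit |
|---|---|---|
| Lp | 4.9e−12 | m³/(N s) |
| σ1, σ2 | 0.068, 0.025 | – |
| ω11, ω22 | 0.8e−9, 1.43e−9 | mol/(N s) |
| ω12, ω21 | 0.81e−13, 1.63e−12 | mol/(N s) |
| D11 | 0.69e−9 | m²/s |
| ν | 1.063e−6 | m²/s |
| ρ | 998.3 | kg/m³ |
| ∂ρ/∂C1, ∂ρ/∂C2 | 0.06, −0.0095 | kg/mol |
| baths | C2h = 201, C1l = C2l = 1, C1h ∈ [1, 101] | mol/m³ |

The working temperature is not part of the published parameter set;
the default is T = 298.15 K (configurable), and the gas constant is
kept at the 4-digit literature convention R = 8.314 J/(mol K) so that
RT = 2478.8 J/mol at the default temperature.  Only D11 of the
diffusion matrix is published; D12, D21, D22 stay unset in the fixture
and any operation needing them takes an explicit value.

## CP profiles (synthetic transition shape)

The measured concentration dependence of ζ is published only as
plateaus, breakpoints and a crossing: configuration A falls from 0.5
(below C̄1 = 4 mol/m³) to 0.03 (above 12.72), configuration B rises
from 0.03 (below 5.41) to 0.5 (above 12.72), and both curves pass
through ζ = 0.234 at C̄1 = 9.24 mol/m³.  `make_reference_profiles`
honours every printed anchor exactly and fills the unspecified
transition with a monotone piecewise-cubic (PCHIP) interpolant, clamped
to the plateaus outside the window.  Both solutes share one profile per
configuration, as measured for this system.  Consequences: quantities
pinned by the anchors (plateau values, the crossing location, sign
changes of every ξ at the crossing) are faithful, while curve shapes
*between* anchors — e.g. the exact height of interior maxima of the
B-configuration coupling curves — are a modelling choice and are not
asserted against published interior values.

The ζ↔δ conversion assumes symmetric layers (δ on both faces equal)
and diffusion coefficients independent of concentration and
orientation.  Published figure pairs that link specific ζ values to
specific δ values are mutually inconsistent with the closed form at any
plausible temperature (e.g. ζ = 0.234 with δ = 1.3 mm, where the
closed form gives 0.57 mm); the formulas are implemented as stated and
such cross-figure numbers are treated as independent empirical inputs
(the Rayleigh evaluation at the critical state uses the measured
δ = 1.3 mm, not the converted one).

## Convection classification

The classifier keys on the bulk density difference Δρ = ρh − ρl
relative to its critical value (default 0.046 kg/m³ for the reference
system, absolute tolerance 1e−3 kg/m³), because Δρ is the physically
causal quantity for a horizontal layer in gravity.  Configuration A is
unstable below the critical Δρ and stable above; B mirrors it; within
tolerance the state is critical and orientation-independent.  The
concentration Rayleigh number (critical value 1100.6 for rigid–free
boundaries, configurable) is computed and reported as a secondary
indicator but does not drive the classification, since the two criteria
are not reconciled in the source material.

## ξ diagnostics: authoritative vs simplified

The authoritative ξ is the entrywise matrix ratio
`(R^A − R^B)/R` (`xi_coefficients`).  The published simplified closed
forms for the reduced single-ζ model (`xi_simplified`) are implemented
exactly as printed.  Numerically the two agree in magnitude to better
than 5% across ζ ∈ [0.05, 0.95], but the printed forms carry the
opposite sign for every entry except the (2,1) and (3,1) positions —
an internal inconsistency of the source formula set.  The matrix-based
definition is self-consistent with the ordering criteria (e.g.
ξ11 < 0 exactly when R11^A < R11^B with positive entries) and is what
sweeps and classifications use; the simplified forms are retained as
documented approximations, with the sign discrepancy surfaced in tests
rather than silently corrected.

A vanishing homogeneous denominator makes the corresponding ξ entry
undefined; it is flagged and returned as NaN instead of raising or
propagating silently.  The "ξ = 0" critical-state detection uses an
absolute tolerance of 1e−3 (configurable).

## Coupling statistics

Degrees of coupling are formed from the strict (dimensionless) matrix
by default; the `literal` mode applies the ratio to the stored entries
of whatever matrix it is given, which on the printed variant produces
dimensional values > 1 and exists only for auditing.  The minus sign is
applied uniformly (off-diagonal resistances are negative here, giving
positive coupling degrees).  `e(r, r) = e_max(r)` holds identically,
and `Q_R(r, r) = r²/(2 − r²)`.

The entrywise bound |r_ij| ≤ 1 is a second-law theorem only for
reciprocal (Onsager) matrices.  Concentration polarization breaks
reciprocity, and for strongly reflective membranes (σ ≳ 0.2) with very
asymmetric polarization (ζ1 ≪ ζ2) the bound can fail; a test documents
a concrete violation at σ1 = 0.5.  For the leaky reference membrane
(σ1 = 0.068) the bound holds over the full studied range, which is
what the bounded-statistics property tests assert (draws restricted to
σ ≤ 0.15).

A/B crossing detection in sweep summaries uses a cubic interpolation
of the A−B difference and Brent root-finding with tolerance
1e−3 mol/m³.

## Numerical choices

* Singularity guard: |γζ| < 1e−30 (SI) raises `SingularPermeabilityError`
  naming the violated condition instead of returning infinities.
* The inversion oracle builds the conductance map column by column at
  unit forces and row-rescales before judging conditioning, since raw
  SI entries span ~12 orders of magnitude.
* Log-mean concentration returns the common value at Ch = Cl (the
  continuous limit) rather than erroring.
* Sweeps are specified in the bath concentration C1h (the mean C̄1 is
  derived and reported alongside); per-row errors are attached to the
  row's `error` column and the sweep continues.
* CSV output uses 10-significant-digit scientific notation and a
  leading unit-comment line; repeated runs are byte-identical.

## What a green test establishes

Closed-form anchors (log-means, density difference, Rayleigh number,
homogeneous resistance endpoints, coupling maxima) are reproduced at
the published precision.  Structure-level properties (strict matrix =
numerical inverse, homogeneous collapse, determinant closed form,
crossing and sign-change behaviour, ζ↔δ round trip, coupling bounds)
hold over randomized parameter draws.  What is *not* established:
coefficient values under CP at interior concentrations, which depend on
the unpublished experimental ζ curves and enter only through the
modelled profile shape; and several published interior/figure-level
values that cannot be reproduced from the published closed forms with
the published parameters (homogeneous det R endpoints as printed,
R22/R33 crossing values, ξ11 extrema, e-range maxima).  These are
excluded from value-level assertions and the formulas are implemented
as stated.

## Known limitations

* No transient CBL growth, no hydrodynamic (Navier–Stokes/Boussinesq)
  modelling of convection onset — the Rayleigh number is a diagnostic,
  not a simulation.
* Non-electrolytes only; no temperature-dependent parameter models.
* The profile transition shape between published anchors is a modelling
  choice (monotone PCHIP); interior curve features inherit it.
* The eight alternative network-thermodynamic matrix representations
  (conductance and hybrid forms) are out of scope.
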