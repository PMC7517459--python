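"""Boundary-layer thickness, Rayleigh number and convective stability.

Walks the chain delta -> zeta -> density difference -> Rayleigh number
for the critical state of the reference system (mean glucose
9.24 mol/m^3), where the solution densities in the two chambers match
and the boundary-layer complex is the same in both orientations.
"""

from kkpeusner import (
    classify_convection,
    delta_from_zeta,
    density_difference,
    nephrophan_fixture,
    rayleigh_number,
    zeta_from_delta,
)

fixture = nephrophan_fixture()  # C1h = 33.44 -> c1bar = 9.24 mol/m^3
env, membrane, baths = fixture.env, fixture.membrane, fixture.baths

zeta_crit = 0.234  # measured configuration-independent CP coefficient
delta = delta_from_zeta(zeta_crit, membrane.omega11, env.D11, env)
print(f"zeta = {zeta_crit} -> symmetric layer thickness delta = {delta * 1e3:.3f} mm")
back = zeta_from_delta(membrane.omega11, env.D11, env.D11, delta, delta, env)
print(f"round trip zeta({delta * 1e3:.3f} mm) = {back:.3f}")

drho = density_difference(baths.C1h - baths.C1l, baths.C2h - baths.C2l, env)
print(f"\ndensity difference rho_h - rho_l = {drho:.3f} kg/m^3")

# the measured layer thickness at the critical state is 1.3 mm
rc = rayleigh_number(drho, 1.3e-3, env)
print(f"concentration Rayleigh number R_C = {rc:.1f} (critical rigid-free value 1100.6)")

print("\nstability of the layer complex vs orientation:")
for drho_case, state in [(-8.0, "ethanol-dominated baths"), (drho, "critical state"), (5.0, "glucose-dominated baths")]:
    a = classify_convection("A", drho_case)
    b = classify_convection("B", drho_case)
    print(f"  drho = {drho_case:+.3f} kg/m^3 ({state}):  A -> {a.regime.value},  B -> {b.regime.value}")

print(
    "\nWhichever orientation puts the lighter solution underneath loses "
    "hydrodynamic stability; at the critical density difference the "
    "orientation stops mattering."
)
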