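"""Shape of the proposed stationary law across the three DV-vs-d regimes.

DV < d piles mass onto the boundary (the discreteness-induced-transition
regime), DV = d is flat on each mass shell, DV > d concentrates around the
deterministic fixed point.
"""

from tkmodel import (
    ScaledParameters,
    boundary_mass,
    mode_set,
    ode_fixed_point,
    pi_tilde_full,
    regime_classify,
)

for V in (20, 200, 2000):
    sp = ScaledParameters(D=0.01, V=V, kappa_prime=(1.0, 1.001))
    rates = sp.to_rates()
    modes = mode_set(rates)
    print(f"V = {V:5d}  regime {regime_classify(sp):>5}  mode(s) {sorted(modes)}")

sp = ScaledParameters(D=0.01, V=20, kappa_prime=(1.0, 1.001))
rates = sp.to_rates()
p_hi = pi_tilde_full((0, 40), rates)
p_lo = pi_tilde_full((40, 0), rates)
print(f"\nDIT regime peaks near total mass dV = 40:")
print(f"  Pi~(0, 40) = {p_hi:.5f}  >  Pi~(40, 0) = {p_lo:.5f}  (ratio {p_hi/p_lo:.4f})")
print(f"  boundary mass = {boundary_mass(rates):.3f}")
print(f"  fixed point of the ODE for comparison: {ode_fixed_point(rates).a_star}")
print(
    "\nEven a 0.1% asymmetry makes the all-species-2 boundary peak higher;"
    "\nthe strict argmax sits at total mass 39 because the Poisson mass law"
    "\nties its modes at 39 and 40 and the shell law breaks the tie downward."
)
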