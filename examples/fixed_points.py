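"""Deterministic fixed points of the two-species autocatalytic network.

The mass-action ODE relaxes onto the conservation line a1 + a2 = 2V; for
asymmetric rates the drift zero on that line solves a quadratic.  With
D = 0.01 and V = 2000 the fixed point slides towards the faster catalyst as
the asymmetry grows.
"""

from tkmodel import ScaledParameters, ode_fixed_point, ode_rhs

for k2p in (1.0, 1.001, 1.01, 1.1):
    rates = ScaledParameters(D=0.01, V=2000, kappa_prime=(1.0, k2p)).to_rates()
    fp = ode_fixed_point(rates)
    print(
        f"kappa'_2 = {k2p:<6} a* = ({fp.a_star[0]:9.2f}, {fp.a_star[1]:9.2f})"
        f"   |drift| = {max(abs(ode_rhs(fp.a_star, rates))):.1e}"
    )

print(
    "\nEach row is the stable molecule-count pair (a1*, a2*); their sum is"
    "\nalways 2V = 4000 (inflow/outflow balance), and even a 0.1% rate"
    "\nasymmetry moves hundreds of molecules to the faster species."
)
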