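# Methods

## The model

`tkmodel` studies the open autocatalytic (Togashi–Kaneko) reaction network
on `d >= 2` molecular species:

```
A_i + A_j  ->  2 A_i     rate kappa_i * a_i * a_j      (i != j, mass action)
0          ->  A_i       rate lam_i
A_i        ->  0         rate delta * a_i
```

as a continuous-time Markov chain on the lattice `N^d`.  The single shared
outflow rate `delta` is a modelling requirement, not a convenience: it makes
the total mass `n = sum(a_i)` itself a Markov chain (a linear death process
with immigration) with Poisson stationary law `nu = Poisson(sum(lam)/delta)`.
Unequal per-species outflow rates break this lumpability and are rejected at
parameter validation.

Two parametrizations are interchangeable: the raw rates above, and the
volume-scaled form `kappa_i = kappa'_i / V`, `lam_i = D*V`, `delta = D`,
in which the Poisson mean is `d*V` and the product `D*V` against `d` decides
the shape of the stationary law (see *Regimes* below).

## The proposed stationary law

With symmetric rates (`kappa_i = kappa` for all i) the stationary law is
known exactly: `Pi(a) = nu(n) * pi(a|n)` with `pi(.|n)` the
Dirichlet-multinomial distribution on the mass shell, concentrations
`alpha_j = delta*lam_j/(kappa*sum(lam))`.  For asymmetric rates no exact
form is known.  The package evaluates the proposed approximation

```
Pi~(a) = nu(n) * pi~_n(a),
pi~_n(a)  proportional to  [prod_i kappa_i^{a_i}] * DirMult(a; n, alpha),
alpha_j = delta*lam_j/(kappa_j*sum(lam)),
```

normalized on each shell by the partition function
`u(alpha, kappa, n) = E[(sum_i kappa_i xi_i)^n]`, `xi ~ DirMult(n, alpha)`.
This is exactly the stationary law of the Moran model with genic selection:
restricted to a shell of mass `n`, the chain's catalysis moves are Moran
reproduction events with per-pair rate `kappa/n` (hence Moran fitness
`n*kappa`), and identifying each outflow with the next inflow supplies
parent-independent mutation at `v*p_j = delta*lam_j/sum(lam)`.  The
per-pair `1/n` normalization matters when mapping parameters between the
two models; `moran_stationary` takes Moran-convention fitnesses.

All pmf evaluation happens in log space through `lgamma`; ascending
factorials are `Gamma(alpha+a)/Gamma(alpha)` in log form.  Under volume
scaling with `V = 2000` the Gamma arguments reach several thousand, where
direct ratios would overflow long before the pmf values themselves become
extreme.

## The error functional

`B*(a) = (A* Pi~)(a) / Pi~(a)` — the adjoint generator (the right-hand side
of the chemical master equation) applied to the proposal, relative to the
proposal — vanishes identically exactly when `Pi~` is stationary.  The
relative form is the informative one: `Pi~` spans hundreds of orders of
magnitude over the support, so the raw residual `A*Pi~` is dominated by the
high-probability region regardless of local accuracy.  Grids additionally
record the raw residual for diagnostics.

Three routes are implemented and cross-validated:

* **oracle** (any d): the definitional flux balance, assembled from
  one-step pmf *ratios* `exp(log Pi~(b) - log Pi~(a))` so that it stays
  finite deep in the Poisson tails.
* **closed form** (d = 2): the flux decomposition grouped by source shell
  (`n-1`, `n`, `n+1`).  Every cross-shell pmf ratio reduces to a rational
  factor times one of two ratios of terminating Gauss hypergeometric values
  of consecutive degree, `F_n/F_{n-1}` and `F_n/F_{n+1}` with
  `F_m = 2F1(-m, alpha_1; 1-alpha_2-m; kappa_1/kappa_2)`.  This form is
  valid for arbitrary (unequal) inflow vectors.
* **scaled** (d = 2): the same five-term expression written directly in
  `(D, V, kappa')`, where the equal inflows `lam_i = D*V` collapse the
  shell-below terms; kept as an independent code path and required to agree
  with the raw closed form to 1e-9 relative.

Agreement between routes is asserted at `1e-6` relative to the *total exit
rate* at the state — the natural magnitude of the flux sums being
cancelled — because the oracle loses digits exactly where B* is smallest.

Empirically (and in the test suite): B* is zero to rounding in the
symmetric case; for asymmetric rates the deviations are confined to the
lattice edges `a1 <= 1` or `a2 <= 1`, decay by roughly a factor 6 per step
into the interior, shrink to zero as the rate ratio approaches 1, and on
the interior scale linearly in `D` at fixed `V`.  On the edges themselves
the deviation is set by `kappa_2 * a_1 * (1 - kappa_1/kappa_2)`-type terms,
not by `D`: the O(D) accuracy statement is an interior statement, which is
where the distinction matters because the DIT boundary rays `a_i = 0`
(where `Pi~` piles its mass) are *not* part of the deviating edge set's
worst states.

## Hypergeometric kernel

The terminating series `2F1(-n, x; y; z)` is evaluated by signed
log-magnitude accumulation (log-sum-exp over positive and negative term
groups).  If the two groups cancel enough to threaten the kernel's
ten-significant-digit contract (more than ~5 decimal digits of
cancellation), the sum is redone in exact rational arithmetic on the exact
binary values of the float inputs (`fractions.Fraction`) — an exact
fallback rather than a fixed extended precision.  A `y` equal to a
nonpositive integer above `-(n-1)` puts a Pochhammer pole inside the sum
and is a hard error naming the offending term.

For the partition-function argument pattern (`x = alpha_1 > 0`,
`y = 1 - alpha_2 - n`, `z > 0`) there is a sign-free identity,

```
2F1(-n, a1; 1-a2-n; z) = sum_i C(n,i) z^i (a1)^(i) (a2)^(n-i) / (a2)^(n),
```

a positive Beta-binomial-weighted sum evaluated by log-sum-exp.  Ratio
pairs use the alternating route up to degree 200 and this weighted route
beyond, where it is immune to cancellation; the two routes are
cross-checked against each other and against an exact-rational oracle in
the tests.  (For this argument pattern the "alternating" series is in fact
sign-definite — `(y)_(i)` contributes `(-1)^i` — so both routes are stable;
the fallback matters for genuinely alternating general arguments.)

## Simulation

`gillespie_simulate` draws exact SSA paths: exponential holding times at
the total exit rate, next reaction by inverse-CDF over a fixed transition
ordering (catalysis pairs in lexicographic `(i, j)` order, inflows,
outflows).  Two uniforms per jump are consumed from a seeded PCG64 stream,
making trajectories bit-reproducible given `(params, a0, t_end, seed)`.
A total-rate ceiling of `1e12` aborts runaway states with a report rather
than silently losing precision in the exponential clock.

Occupation measures are always sojourn-weighted (time in state, not jump
counts): the comparison target is a stationary law, and jump-chain
frequencies would be biased by the state-dependent exit rates.  The default
burn-in is `t_end/10`.

The deterministic counterpart `da/dt = (+/-)(kappa_1-kappa_2) a_1 a_2 +
lam_i - delta a_i` relaxes onto the conservation line
`a_1 + a_2 = sum(lam)/delta`; `ode_fixed_point` reduces to the scalar
quadratic `c a^2 - (cT + delta) a + lam_1` on that line (`c = kappa_2 -
kappa_1`), picks the root with negative reduced-drift slope (the stable
one), and applies a Newton polish so the reported residual is at rounding
level (asserted `<= 1e-9`).

## Regimes, modes and a deliberate precision caveat

With `alpha'_i = D*V/(d*kappa'_i)`, the shell laws are U-shaped for
`D*V < d` (all concentrations below 1): mass piles onto the boundary rays
where one species is absent — the discreteness-induced-transition (DIT)
picture, in which the chain rests on an axis and occasionally flips.  For
`D*V > d` the law is unimodal near the deterministic fixed point;
`D*V = d` is the flat knife edge.  `regime_classify` compares `D*V` with
`d` at tolerance 1e-12.

`mode_set` is a strict global argmax over a truncated support (Poisson
upper-tail mass at most the requested `eps`, coverage of at least
`1 - 1e-9` enforced); ties are returned as a set, with tie detection at
12-significant-digit equality of the probabilities, because symmetric
configurations produce exact ties.  One consequence worth stating plainly:
at integer Poisson mean `mu` the mass law ties `nu(mu-1) = nu(mu)`
*exactly*, and the shell-conditional factor strictly prefers the smaller
shell (`Pi(0,n)/Pi(0,n-1) = (mu/n)(alpha_2+n-1)/(|alpha|+n-1) < 1` at
`n = mu`).  So in the DIT configuration `D=0.01, V=20` the strict global
mode is `(0, 39)`, one molecule short of the nominal `dV = 40`; "modes at
total mass dV" is correct only at +/-1 resolution in n.  The package
reports the strict argmax and does not round it up.  `local_modes` (states
no lower than any one-reaction neighbour) identifies both boundary peaks in
asymmetric DIT configurations, where the strict argmax alone would hide the
lower peak.

## Truncation and tables

Distribution tables keep shells up to the Poisson `1 - eps` quantile
(default `eps = 1e-9`, one-sided: the lower tail starts at 0) and record
the truncated mass; table validation requires probabilities plus truncation
to sum to 1 within 1e-10 and the truncation to stay below its ceiling.
Total-variation comparisons count truncated mass as maximally mismatched.

## Fixtures and study conditions

`generate_fixture` draws seeded parameter sets per regime with `D = 0.01`
throughout, `V ~ U[10, 50]` (DIT), `V = d/D` exactly (knife edge) or
`V ~ U[500, 3000]` (unimodal), and a log-uniform asymmetry ratio
`kappa'_2/kappa'_1` in `[1.0001, 1.1]` — the span of asymmetries the study
conditions exercise.

Test and example horizons: the occupation-convergence checks run the DIT
configuration `(D = 0.01, V = 20, kappa' = (1, 1.01))` to `t_end = 4e5`
time units (~3 million jumps, a few seconds of wall time), where the
total-variation distance to the proposed law is ~0.03 and still falling;
short-horizon contrasts use `5e4`.  These sizes were chosen as the point
where the Monte-Carlo error is comfortably below the 0.1 acceptance band
while the suite stays quick to run.

## What the synthetic setups do and do not show

All inputs are parameter sets; there is no external data.  The simulations
are exact draws from the very CTMC the formulas describe, so agreement
between occupation measures and `Pi~` validates the formula's accuracy *for
this model family* — it says nothing about model misspecification, about
`d > 2` closed forms (only the oracle route exists there), or about rate
laws beyond mass action.  The boundary deviations of B* are reported as
computed; whether they reflect a genuine defect of the proposal at the
axes or an artefact of the relative measure is left open here.

## Known limitations

* The closed-form and scaled B* routes, the distribution tables, the mode
  search and the fixed-point solver are d = 2; the oracle, the simulator,
  the Moran machinery and the partition function are general d.
* `partition_function` returns the linear-scale value and can underflow for
  extreme degrees under volume scaling; `log_partition_function` is the
  stable interface.
* No sampling from `Pi~` (evaluation only), no tau-leaping or hybrid
  acceleration, no switching-time statistics.
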