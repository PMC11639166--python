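"""The B* error functional of the proposed stationary distribution.

``B*(a) = (A* Pi~)(a) / Pi~(a)`` is the relative residual of the proposed
law under the adjoint generator: identically zero exactly when ``Pi~`` is
stationary.  It is computed three ways:

* ``bstar_oracle`` - the definitional route for any d: probability fluxes
  of the adjoint applied to ``Pi~``, assembled from pmf ratios in log space;
* ``bstar_closed_form`` - the d=2 closed form: five terms built from
  ratios of terminating Gauss hypergeometric values of consecutive degree;
* ``bstar_scaled`` - the same five terms written directly in the scaled
  ``(D, V, kappa')`` parametrization.

The closed form is algebraically identical to the oracle; agreement to
1e-6 (relative to the total exit rate at the state) is the standing
cross-validation.  In the symmetric case all routes vanish identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .hyp import hyp2f1_neg_int, hyp2f1_ratio_pair
from .model import _predecessors, tk_transitions
from .parameters import RateParameters, ScaledParameters, as_state
from .stationary import alpha_from_rates, log_pi_tilde_full

__all__ = [
    "BStarGrid",
    "bstar_oracle",
    "bstar_closed_form",
    "bstar_scaled",
    "bstar_grid",
    "exit_rate",
]

State = tuple[int, ...]


def exit_rate(a: Sequence[int], params: RateParameters) -> float:
    """Total rate out of ``a``: the natural magnitude scale for B*."""
    return sum(rate for _, rate in tk_transitions(a, params))


def bstar_oracle(a: Sequence[int], params: RateParameters) -> float:
    """Definitional ``A* Pi~ / Pi~`` via one-step pmf ratios (any d >= 2).

    Each in-flux term is ``rate * exp(log Pi~(b) - log Pi~(a))``; working
    with ratios keeps the evaluation finite deep in the tails where the
    pmf itself underflows.
    """
    a = as_state(a, params.d)
    lp_a = log_pi_tilde_full(a, params)
    terms = []
    for b, rate in _predecessors(a, params):
        terms.append(rate * math.exp(log_pi_tilde_full(b, params) - lp_a))
    for _, rate in tk_transitions(a, params):
        terms.append(-rate)
    if terms and all(t == 0.0 for t in terms):
        raise FloatingPointError(f"all flux terms underflowed at state {a}")
    return float(math.fsum(terms))


@lru_cache(maxsize=65536)
def _ratio_pair_cached(n: int, alpha1: float, alpha2: float, z: float) -> tuple[float, float]:
    return hyp2f1_ratio_pair(n, alpha1, alpha2, z)


def bstar_closed_form(a: Sequence[int], params: RateParameters) -> float:
    """Closed-form B* for d=2 from hypergeometric ratio pairs.

    Assembles the flux decomposition ``(L_{n-1} + L_n + L_{n+1} - R_n)``
    relative to the shell-conditional pmf: each pmf ratio across shells
    reduces to a rational factor times one of the two consecutive-degree
    ``2F1`` ratios, so the whole expression needs only the ratio pair at
    degree ``n``.  Valid for any inflow vector; vanishes identically for
    symmetric autocatalytic rates.
    """
    if params.d != 2:
        raise ValueError("closed form exists for d=2 only; use bstar_oracle")
    a1, a2 = as_state(a, 2)
    n = a1 + a2
    al1, al2 = alpha_from_rates(params).alpha
    k1, k2 = params.kappa
    l1, l2 = params.lam
    delta = params.delta
    L = l1 + l2
    z = k1 / k2
    # exit rate: inflows + outflows + both catalysis channels
    exit_total = L + n * delta + (k1 + k2) * a1 * a2
    # one shell down: outflow sources, weighted by the next-inflow identity
    lower = 0.0
    # within-shell: catalysis sources
    within = 0.0
    if n > 0:
        r_minus, r_plus = _ratio_pair_cached(n, al1, al2, z)
        if a1 > 0:
            lower += (n * delta / L) * l1 * (a1 * k2 * (al2 + n - 1)) / (
                n * k1 * (al1 + a1 - 1)
            ) * r_minus
        if a2 > 0:
            lower += (n * delta / L) * l2 * (a2 / n) * (al2 + n - 1) / (
                al2 + a2 - 1
            ) * r_minus
        if a2 >= 2:
            within += k1 * (a2 - 1) * a2 * (al1 + a1) / (al2 + a2 - 1)
        if a1 >= 2:
            within += k2 * a1 * (a1 - 1) * (al2 + a2) / (al1 + a1 - 1)
    else:
        _, r_plus = 1.0, 1.0 / hyp2f1_neg_int(1, al1, -al2, z)
    # one shell up: inflow sources
    upper = L * r_plus * (z * (al1 + a1) + (al2 + a2)) / (al2 + n)
    return lower + within + upper - exit_total


def bstar_scaled(a: Sequence[int], scaled: ScaledParameters) -> float:
    """Five-term closed-form B* written directly in scaled ``(D, V, kappa')``.

    Under the volume scaling ``alpha_i = D*V/(d*kappa'_i)``, the inflows are
    equal (``lam_i = D*V``), total inflow is ``d*D*V``,
    ``kappa_2 = kappa'_2/V`` and ``z = kappa'_1/kappa'_2``; the flux
    decomposition then collapses to five terms in the two ratio values.
    The sign convention matches the definitional oracle.
    """
    if scaled.d != 2:
        raise ValueError("closed form exists for d=2 only; use bstar_oracle")
    a1, a2 = as_state(a, 2)
    n = a1 + a2
    d = 2
    dv = scaled.D * scaled.V
    alpha1 = dv / (d * scaled.kappa_prime[0])
    alpha2 = dv / (d * scaled.kappa_prime[1])
    z = scaled.kappa_prime[0] / scaled.kappa_prime[1]
    kappa2 = scaled.kappa_prime[1] / scaled.V
    L = d * dv
    if n == 0:
        return 0.0  # in-flux L * r_plus * (z*alpha1+alpha2)/alpha2 equals L exactly
    r_minus, r_plus = _ratio_pair_cached(n, alpha1, alpha2, z)
    # a*alpha/(a-1+alpha) hits 0/0 at a=0 when alpha=1 (the DV=d regime)
    s1 = 0.0 if a1 == 0 else a1 * alpha1 / (a1 - 1 + alpha1)
    s2 = 0.0 if a2 == 0 else a2 * alpha2 / (a2 - 1 + alpha2)
    s = s1 + s2
    t1 = -L * (1.0 - r_plus)
    t2 = kappa2 * (n - 1 + alpha2) * s * (r_minus - 1.0)
    t3 = kappa2 * s * (a1 * (1.0 - z) - alpha2)
    t4 = kappa2 * s1 * (z - 1.0)
    t5 = (L / (n + alpha2)) * r_plus * (a1 * (z - 1.0) + alpha2)
    return t1 + t2 + t3 + t4 + t5


@dataclass
class BStarGrid:
    """B* evaluated over a finite region, with its extremum bookkeeping."""

    values: dict[State, float]
    method: str
    params: dict

    @property
    def max_abs(self) -> float | None:
        if not self.values:
            return None
        return max(abs(v) for v in self.values.values())

    @property
    def argmax(self) -> State | None:
        if not self.values:
            return None
        return max(self.values, key=lambda k: abs(self.values[k]))

    def to_tsv(self, path: str | Path) -> None:
        lines = ["a_1\ta_2\tbstar"]
        for (x, y), v in self.values.items():
            lines.append(f"{x}\t{y}\t{v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def summary(self) -> dict:
        return {
            "method": self.method,
            "max_abs": self.max_abs,
            "argmax": list(self.argmax) if self.argmax is not None else None,
            "empty": not self.values,
            "params": self.params,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary()) + "\n")


def bstar_grid(
    params: RateParameters | ScaledParameters,
    region: Iterable[Sequence[int]],
    method: str = "closed_form",
) -> BStarGrid:
    """Evaluate B* at every state of ``region`` with the chosen method."""
    if method == "scaled":
        if not isinstance(params, ScaledParameters):
            raise ValueError("method 'scaled' needs ScaledParameters")
        fn = lambda a: bstar_scaled(a, params)
        echo = params.to_dict()
    else:
        rates = params.to_rates() if isinstance(params, ScaledParameters) else params
        echo = rates.to_dict()
        if method == "closed_form":
            fn = lambda a: bstar_closed_form(a, rates)
        elif method == "oracle":
            fn = lambda a: bstar_oracle(a, rates)
        else:
            raise ValueError(f"unknown method {method!r}")
    values = {as_state(a): fn(a) for a in region}
    return BStarGrid(values=values, method=method, params=echo)
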