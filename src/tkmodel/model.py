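"""Transition structure of the TK and Moran continuous-time Markov chains.

States live on the lattice ``E = N^d``.  Transitions and their mass-action
rates follow the reaction scheme: catalysis ``a -> a - e_j + e_i`` at rate
``kappa_i * a_i * a_j`` (i != j), inflow ``a -> a + e_i`` at rate ``lam_i``,
outflow ``a -> a - e_i`` at rate ``delta * a_i``.  Self-catalysis (i == j)
is a no-op and never emitted.

The adjoint of the generator, applied to a probability function, gives the
right-hand side of the chemical master equation; a distribution is
stationary exactly when the adjoint annihilates it (global balance).
"""

from __future__ import annotations

from typing import Callable, Sequence

from .parameters import MoranParameters, RateParameters, as_state

__all__ = [
    "tk_transitions",
    "moran_transitions",
    "lumped_transitions",
    "apply_adjoint",
]

State = tuple[int, ...]
Transition = tuple[State, float]


def tk_transitions(a: Sequence[int], params: RateParameters) -> list[Transition]:
    """All transitions with positive rate out of state ``a``.

    Ordering is fixed (catalysis pairs in lexicographic ``(i, j)`` order,
    then inflows, then outflows) so that inverse-CDF reaction selection in
    the simulator is reproducible.
    """
    a = as_state(a, params.d)
    d = params.d
    out: list[Transition] = []
    for i in range(d):
        for j in range(d):
            if i == j:
                continue
            rate = params.kappa[i] * a[i] * a[j]
            if rate > 0:
                target = list(a)
                target[j] -= 1
                target[i] += 1
                out.append((tuple(target), rate))
    for i in range(d):
        target = list(a)
        target[i] += 1
        out.append((tuple(target), params.lam[i]))
    for i in range(d):
        if a[i] > 0:
            target = list(a)
            target[i] -= 1
            out.append((tuple(target), params.delta * a[i]))
    return out


def moran_transitions(a: Sequence[int], params: MoranParameters) -> list[Transition]:
    """Transitions of the Moran chain: ``a -> a - e_i + e_j`` at rate
    ``a_i * (kappa_j * a_j / n + v * p_j)``.

    Total mass is conserved in every target; the self-replacement term
    (i == j) is a no-op and excluded.
    """
    a = as_state(a, params.d)
    if sum(a) != params.n:
        raise ValueError(f"state mass {sum(a)} != population size {params.n}")
    n = params.n
    out: list[Transition] = []
    for i in range(params.d):
        if a[i] == 0:
            continue
        for j in range(params.d):
            if i == j:
                continue
            rate = a[i] * (params.kappa[j] * a[j] / n + params.v * params.p[j])
            if rate > 0:
                target = list(a)
                target[i] -= 1
                target[j] += 1
                out.append((tuple(target), rate))
    return out


def lumped_transitions(n: int, params: RateParameters) -> tuple[float, float]:
    """Birth and death rates of the total-mass chain at mass ``n``.

    The total-mass process is a linear death process with immigration:
    births at rate ``sum(lam)``, deaths at rate ``n * delta``.  Its
    stationary law is Poisson with mean ``sum(lam)/delta``.
    """
    n = int(n)
    if n < 0:
        raise ValueError("total mass must be nonnegative")
    return params.total_inflow, n * params.delta


def _predecessors(a: State, params: RateParameters) -> list[tuple[State, float]]:
    """States ``b`` with a one-reaction transition ``b -> a`` and its rate.

    Neighbours outside ``N^d`` contribute nothing (indicator convention);
    they are simply not generated.
    """
    d = params.d
    preds: list[tuple[State, float]] = []
    # catalysis b -> b - e_j + e_i = a, i.e. b = a - e_i + e_j, rate kappa_i*b_i*b_j
    for i in range(d):
        for j in range(d):
            if i == j or a[i] == 0:
                continue
            b = list(a)
            b[i] -= 1
            b[j] += 1
            rate = params.kappa[i] * b[i] * b[j]
            if rate > 0:
                preds.append((tuple(b), rate))
    # inflow b -> b + e_i = a, i.e. b = a - e_i, rate lam_i
    for i in range(d):
        if a[i] > 0:
            b = list(a)
            b[i] -= 1
            preds.append((tuple(b), params.lam[i]))
    # outflow b -> b - e_i = a, i.e. b = a + e_i, rate delta*b_i
    for i in range(d):
        b = list(a)
        b[i] += 1
        preds.append((tuple(b), params.delta * b[i]))
    return preds


def apply_adjoint(
    p: Callable[[State], float], a: Sequence[int], params: RateParameters
) -> float:
    """Evaluate ``(A* p)(a)``: probability in-flux minus out-flux at ``a``.

    ``p`` must be evaluable at ``a`` and at every lattice neighbour reachable
    by one reaction.  For the true stationary distribution the result is
    zero at every state (global balance).
    """
    a = as_state(a, params.d)
    pa = p(a)
    if pa < 0:
        raise ValueError(f"p({a}) = {pa} is negative; probabilities only")
    flux = 0.0
    for b, rate in _predecessors(a, params):
        pb = p(b)
        if pb < 0:
            raise ValueError(f"p({b}) = {pb} is negative; probabilities only")
        flux += rate * pb
    for _, rate in tk_transitions(a, params):
        flux -= rate * pa
    return flux
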