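"""Stationary laws of the TK network and the Moran model.

The total mass ``n = sum(a)`` of the open TK network is a linear
death-with-immigration chain whose stationary law ``nu`` is Poisson with
mean ``sum(lam)/delta``.  Conditioned on a mass shell ``E_n``, the exact
stationary law in the symmetric case (all ``kappa_i`` equal) is
Dirichlet-multinomial with concentrations

    alpha_j = delta * lam_j / (kappa_j * sum(lam)),

and the full stationary distribution factorizes as ``Pi(a) = nu(n) *
pi(a | n)``.  For asymmetric rates the proposed approximation keeps the
product form but tilts each shell by the selection weight
``prod_i kappa_i^{a_i}``, normalized by the partition function

    u(alpha, kappa, n) = E[(sum_i kappa_i xi_i)^n],  xi ~ DirMult(n, alpha),

which is exactly the stationary law of the Moran model with genic selection
(fitnesses ``kappa``) when ``alpha_j = n v p_j / kappa_j``.  All pmf values
are assembled in log space from log-gamma terms; concentrations reach
thousands under volume scaling and direct Gamma ratios would overflow.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import poisson

from .hyp import log_hyp2f1_weighted
from .parameters import MoranParameters, RateParameters, as_state

__all__ = [
    "AlphaParameters",
    "DistributionTable",
    "alpha_from_rates",
    "moran_alpha",
    "dirichlet_multinomial_pmf",
    "partition_function",
    "log_partition_function",
    "pi_tilde_conditional",
    "pi_tilde_full",
    "log_pi_tilde_full",
    "symmetric_exact_pi",
    "moran_stationary",
    "total_mass_stationary",
    "pi_tilde_table",
    "mode_set",
    "local_modes",
    "boundary_mass",
]

State = tuple[int, ...]


@dataclass(frozen=True)
class AlphaParameters:
    """Dirichlet-multinomial concentration vector with its provenance.

    ``source`` records which correspondence produced it: the exact
    symmetric law, the asymmetric tilt, or the Moran model.
    """

    alpha: tuple[float, ...]
    source: str = "asymmetric"

    def __post_init__(self):
        if any(not (a > 0) for a in self.alpha):
            raise ValueError("concentration parameters must be positive")
        if self.source not in ("symmetric", "asymmetric", "moran"):
            raise ValueError(f"unknown source tag {self.source!r}")


def alpha_from_rates(params: RateParameters) -> AlphaParameters:
    """Concentrations ``alpha_j = delta*lam_j/(kappa_j*sum(lam))``."""
    s = params.total_inflow
    alpha = tuple(params.delta * params.lam[j] / (params.kappa[j] * s) for j in range(params.d))
    return AlphaParameters(alpha, "symmetric" if params.symmetric else "asymmetric")


def moran_alpha(params: MoranParameters) -> AlphaParameters:
    """Moran-model concentrations ``alpha_j = n*v*p_j/kappa_j``.

    A zero mutation-target probability gives ``alpha_j = 0``: type j can
    then never be recreated once lost, and all mass with ``a_j > 0``
    vanishes from the stationary law.  Zeros are handled downstream.
    """
    alpha = tuple(params.n * params.v * params.p[j] / params.kappa[j] for j in range(params.d))
    if all(a > 0 for a in alpha):
        return AlphaParameters(alpha, "moran")
    # bypass the positivity check: zero concentrations are meaningful here
    obj = object.__new__(AlphaParameters)
    object.__setattr__(obj, "alpha", alpha)
    object.__setattr__(obj, "source", "moran")
    return obj


def _log_poch(alpha: float, a: int) -> float:
    """log ascending factorial ``alpha^(a) = Gamma(alpha+a)/Gamma(alpha)``."""
    if alpha == 0.0:
        return 0.0 if a == 0 else -math.inf
    return gammaln(alpha + a) - gammaln(alpha)


def _compositions(n: int, d: int) -> Iterable[State]:
    """All states of the mass shell ``E_n`` in ``d`` coordinates."""
    if d == 1:
        yield (n,)
        return
    for head in range(n + 1):
        for tail in _compositions(n - head, d - 1):
            yield (head, *tail)


def dirichlet_multinomial_pmf(a: Sequence[int], n: int, alpha: AlphaParameters | Sequence[float]) -> float:
    """Dirichlet-multinomial pmf at ``a`` on the shell ``E_n``."""
    al = alpha.alpha if isinstance(alpha, AlphaParameters) else tuple(alpha)
    a = as_state(a, len(al))
    if sum(a) != n:
        raise ValueError(f"state mass {sum(a)} != n={n}")
    tot = sum(al)
    lp = (
        gammaln(n + 1) - sum(gammaln(ai + 1) for ai in a)
        + gammaln(tot) - gammaln(n + tot)
        + sum(_log_poch(al[i], a[i]) for i in range(len(al)))
    )
    return float(np.exp(lp))


# -- shell weights and partition function ------------------------------------


@lru_cache(maxsize=4096)
def _log_shell_d2(kappa: tuple[float, float], alpha: tuple[float, float], n: int):
    """Log selection-weighted DirMult weights on a d=2 shell, as an array
    over ``a1 = 0..n``, together with their log-sum (the log weight total).

    The shared factor Gamma(|alpha|)/Gamma(|alpha|+n) is omitted: it cancels
    between weight and normalizer.
    """
    i = np.arange(n + 1)
    lw = (
        i * math.log(kappa[0]) + (n - i) * math.log(kappa[1])
        + gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + gammaln(alpha[0] + i) - gammaln(alpha[0])
        + gammaln(alpha[1] + n - i) - gammaln(alpha[1])
    )
    return lw, float(logsumexp(lw))


@lru_cache(maxsize=512)
def _log_shell_general(kappa: tuple[float, ...], alpha: tuple[float, ...], n: int):
    d = len(kappa)
    states = list(_compositions(n, d))
    lw = np.array(
        [
            sum(a[i] * math.log(kappa[i]) for i in range(d))
            + gammaln(n + 1) - sum(gammaln(ai + 1) for ai in a)
            + sum(_log_poch(alpha[i], a[i]) for i in range(d))
            for a in states
        ]
    )
    return tuple(states), lw, float(logsumexp(lw))


def log_partition_function(
    alpha: AlphaParameters | Sequence[float],
    kappa: Sequence[float],
    n: int,
    method: str = "bruteforce",
) -> float:
    """``log u(alpha, kappa, n)`` with ``u = E[(sum kappa_i xi_i)^n]``."""
    al = tuple(alpha.alpha if isinstance(alpha, AlphaParameters) else alpha)
    kap = tuple(float(k) for k in kappa)
    n = int(n)
    if n < 0:
        raise ValueError("n must be nonnegative")
    tot = sum(al)
    lg = gammaln(tot) - gammaln(n + tot)
    if method == "bruteforce":
        if len(kap) == 2:
            _, lsum = _log_shell_d2(kap, al, n)
        else:
            _, _, lsum = _log_shell_general(kap, al, n)
        return lg + lsum
    if method == "hypergeometric":
        if len(kap) != 2:
            raise ValueError("hypergeometric closed form exists for d=2 only")
        # u = G * (alpha2)^(n) * kappa2^n * 2F1(-n, a1; 1-a2-n; k1/k2)
        return (
            lg
            + gammaln(al[1] + n) - gammaln(al[1])
            + n * math.log(kap[1])
            + log_hyp2f1_weighted(n, al[0], al[1], kap[0] / kap[1])
        )
    raise ValueError(f"unknown method {method!r}")


def partition_function(
    alpha: AlphaParameters | Sequence[float],
    kappa: Sequence[float],
    n: int,
    method: str = "bruteforce",
) -> float:
    return float(np.exp(log_partition_function(alpha, kappa, n, method)))


# -- pmf evaluation ----------------------------------------------------------


def _log_pi_tilde_conditional(a: State, params: RateParameters) -> float:
    n = sum(a)
    al = alpha_from_rates(params).alpha
    if params.d == 2:
        lw, lsum = _log_shell_d2(params.kappa, al, n)
        return float(lw[a[0]] - lsum)
    states, lw, lsum = _log_shell_general(params.kappa, al, n)
    return float(lw[states.index(a)] - lsum)


def pi_tilde_conditional(a: Sequence[int], params: RateParameters) -> float:
    """Shell-conditional stationary law: selection-weighted
    Dirichlet-multinomial, normalized by the partition function.

    Reduces exactly to the Dirichlet-multinomial when the autocatalytic
    rates are symmetric.
    """
    a = as_state(a, params.d)
    return float(np.exp(_log_pi_tilde_conditional(a, params)))


def _log_poisson(n: int, mu: float) -> float:
    return n * math.log(mu) - mu - math.lgamma(n + 1)


def log_pi_tilde_full(a: Sequence[int], params: RateParameters) -> float:
    a = as_state(a, params.d)
    n = sum(a)
    return _log_poisson(n, params.mean_mass) + _log_pi_tilde_conditional(a, params)


def pi_tilde_full(a: Sequence[int], params: RateParameters) -> float:
    """Proposed stationary distribution ``Pi~(a) = nu(n) * pi~_n(a)``.

    ``nu`` is the Poisson total-mass law; the shell factor carries the
    autocatalytic tilt.  Exact in the symmetric case.
    """
    return float(np.exp(log_pi_tilde_full(a, params)))


def symmetric_exact_pi(a: Sequence[int], params: RateParameters) -> float:
    """Exact stationary probability for symmetric autocatalytic rates."""
    if not params.symmetric:
        raise ValueError(
            "exact stationary law requires symmetric kappa; use pi_tilde_full "
            "for the asymmetric approximation"
        )
    return pi_tilde_full(a, params)


def moran_stationary(a: Sequence[int], params: MoranParameters) -> float:
    """Stationary pmf of the Moran model with genic selection on ``E_n``."""
    a = as_state(a, params.d)
    if sum(a) != params.n:
        raise ValueError(f"state mass {sum(a)} != population size {params.n}")
    al = moran_alpha(params).alpha
    kap = params.kappa
    if params.d == 2 and all(x > 0 for x in al):
        lw, lsum = _log_shell_d2(kap, al, params.n)
        return float(np.exp(lw[a[0]] - lsum))
    states, lw, lsum = _log_shell_general(kap, al, params.n)
    return float(np.exp(lw[states.index(a)] - lsum))


def total_mass_stationary(n: int, params: RateParameters) -> float:
    """Poisson(sum(lam)/delta) pmf of the total-mass chain at ``n``."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return float(poisson.pmf(n, params.mean_mass))


# -- distribution tables -----------------------------------------------------


@dataclass
class DistributionTable:
    """Sparse probability table over a truncated support.

    ``support`` holds states (integer tuples, or plain integers for the
    lumped chain); ``truncation_mass`` is the probability left outside.
    """

    prob: dict
    truncation_mass: float = 0.0
    ceiling: float = 1e-9

    def __post_init__(self):
        vals = np.fromiter(self.prob.values(), dtype=float, count=len(self.prob))
        if (vals < 0).any():
            raise ValueError("probabilities must be nonnegative")
        total = vals.sum() + self.truncation_mass
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"probabilities + truncation mass sum to {total}, not 1")
        if self.truncation_mass > self.ceiling:
            raise ValueError(
                f"truncation mass {self.truncation_mass:.3e} exceeds ceiling {self.ceiling:.3e}"
            )

    @property
    def support(self) -> list:
        return list(self.prob)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        first = next(iter(self.prob), (0,))
        d = len(first) if isinstance(first, tuple) else 1
        lines = ["\t".join([f"a_{i+1}" for i in range(d)] + ["probability"])]
        for state, p in self.prob.items():
            coords = state if isinstance(state, tuple) else (state,)
            lines.append("\t".join([str(c) for c in coords] + [repr(float(p))]))
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, truncation_mass: float = 0.0, ceiling: float = 1e-9):
        rows = Path(path).read_text().strip().split("\n")
        prob = {}
        for line in rows[1:]:
            *coords, p = line.split("\t")
            key = tuple(int(c) for c in coords)
            prob[key if len(key) > 1 else key[0]] = float(p)
        return cls(prob, truncation_mass, ceiling)

    def to_json(self, path: str | Path) -> None:
        data = {
            "truncation_mass": self.truncation_mass,
            "ceiling": self.ceiling,
            "prob": [[list(k) if isinstance(k, tuple) else [k], repr(float(v))] for k, v in self.prob.items()],
        }
        Path(path).write_text(json.dumps(data) + "\n")

    @classmethod
    def from_json(cls, path: str | Path):
        data = json.loads(Path(path).read_text())
        prob = {}
        for coords, v in data["prob"]:
            key = tuple(coords)
            prob[key if len(key) > 1 else key[0]] = float(v)
        return cls(prob, data["truncation_mass"], data["ceiling"])


def _shell_range(params: RateParameters, eps: float) -> int:
    """Largest n kept so that the Poisson upper tail holds at most ``eps``."""
    return int(poisson.isf(eps, params.mean_mass))


def pi_tilde_table(params: RateParameters, eps: float = 1e-9) -> DistributionTable:
    """Tabulate the proposed stationary law on shells ``n <= isf(eps)``."""
    if params.d != 2:
        raise NotImplementedError("tables are tabulated for d=2")
    nmax = _shell_range(params, eps)
    mu = params.mean_mass
    al = alpha_from_rates(params).alpha
    prob: dict[State, float] = {}
    lognu = poisson.logpmf(np.arange(nmax + 1), mu)
    for n in range(nmax + 1):
        lw, lsum = _log_shell_d2(params.kappa, al, n)
        pvals = np.exp(lw - lsum + lognu[n])
        for i in range(n + 1):
            prob[(i, n - i)] = float(pvals[i])
    trunc = float(poisson.sf(nmax, mu))
    return DistributionTable(prob, truncation_mass=trunc, ceiling=max(1e-9, eps * 1.01))


def _round_sig(x: float, sig: int = 12) -> float:
    return float(f"{x:.{sig}g}")


def mode_set(params: RateParameters, eps: float = 1e-10) -> set[State]:
    """Global argmax states of the proposed stationary law over a truncated
    support; exact ties (after rounding to 12 significant digits) are all
    returned.  The truncation must cover at least ``1 - 1e-9`` of the
    Poisson total-mass law.
    """
    if params.d != 2:
        raise NotImplementedError("mode search is implemented for d=2")
    nmax = _shell_range(params, eps)
    mu = params.mean_mass
    if poisson.sf(nmax, mu) > 1e-9:
        raise ValueError("truncated support covers less than 1-1e-9 of the mass")
    al = alpha_from_rates(params).alpha
    best: list[tuple[float, State]] = []
    best_lp = -math.inf
    lognu = poisson.logpmf(np.arange(nmax + 1), mu)
    for n in range(nmax + 1):
        lw, lsum = _log_shell_d2(params.kappa, al, n)
        lp = lw - lsum + lognu[n]
        shell_max = float(np.max(lp))
        if shell_max <= best_lp - 1e-9:
            continue
        for i in np.nonzero(lp >= shell_max - 1e-9)[0]:
            best.append((float(lp[i]), (int(i), n - int(i))))
        best_lp = max(best_lp, shell_max)
    pmax = _round_sig(math.exp(best_lp))
    return {a for lp, a in best if _round_sig(math.exp(lp)) == pmax}


def local_modes(params: RateParameters, eps: float = 1e-10) -> set[State]:
    """States at which the proposed stationary law is at least as large as
    at every one-reaction lattice neighbour (d=2)."""
    if params.d != 2:
        raise NotImplementedError("mode search is implemented for d=2")
    nmax = _shell_range(params, eps)
    mu = params.mean_mass
    al = alpha_from_rates(params).alpha
    lognu = poisson.logpmf(np.arange(nmax + 2), mu)
    shells = []
    for n in range(nmax + 2):
        lw, lsum = _log_shell_d2(params.kappa, al, n)
        shells.append(lw - lsum + lognu[n])
    modes: set[State] = set()
    for n in range(nmax + 1):
        lp = shells[n]
        for i in range(n + 1):
            v = lp[i]
            neigh = []
            if i > 0:
                neigh.append(lp[i - 1])  # catalysis towards species 2
            if i < n:
                neigh.append(lp[i + 1])  # catalysis towards species 1
            neigh.append(shells[n + 1][i + 1])  # inflow of species 1
            neigh.append(shells[n + 1][i])      # inflow of species 2
            if n > 0:
                if i > 0:
                    neigh.append(shells[n - 1][i - 1])  # outflow of species 1
                if i < n:
                    neigh.append(shells[n - 1][i])      # outflow of species 2
            if all(v >= x for x in neigh):
                modes.add((i, n - i))
    return modes


def boundary_mass(params: RateParameters, eps: float = 1e-9) -> float:
    """Probability mass of the proposed law on the boundary
    ``{a1 = 0} | {a2 = 0}`` (d=2): the weight of the DIT resting states."""
    if params.d != 2:
        raise NotImplementedError("d=2 only")
    nmax = _shell_range(params, eps)
    mu = params.mean_mass
    al = alpha_from_rates(params).alpha
    lognu = poisson.logpmf(np.arange(nmax + 1), mu)
    total = 0.0
    for n in range(nmax + 1):
        lw, lsum = _log_shell_d2(params.kappa, al, n)
        lp = lw - lsum + lognu[n]
        total += float(np.exp(lp[0]))
        if n > 0:
            total += float(np.exp(lp[n]))
    return total
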