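"""Stochastic simulation and deterministic analysis of the TK network.

``gillespie_simulate`` draws exact sample paths of the CTMC (stochastic
simulation algorithm): exponential holding times at the total exit rate,
next reaction by inverse-CDF over the fixed transition ordering (catalysis
pairs lexicographic, then inflows, then outflows).  Two uniforms are
consumed per jump from a seeded PCG64 stream, so trajectories are
bit-reproducible given the seed.

``occupation_distribution`` turns a path into the time-weighted (sojourn,
not jump-counted) occupancy over a window; by ergodicity this converges to
the stationary law.  ``simulate_lumped`` runs the one-dimensional
total-mass birth-death chain directly.

The deterministic (mass-action ODE) counterpart has drift

    da1/dt = (kappa_1 - kappa_2) a1 a2 + lam_1 - delta a1
    da2/dt = (kappa_2 - kappa_1) a1 a2 + lam_2 - delta a2,

whose trajectories relax onto the conservation line
``a1 + a2 = (lam_1+lam_2)/delta``; the fixed point solves a scalar
quadratic there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import tk_transitions
from .parameters import RateParameters, as_state
from .stationary import DistributionTable

__all__ = [
    "Trajectory",
    "OccupationSummary",
    "FixedPoint",
    "gillespie_simulate",
    "simulate_lumped",
    "occupation_distribution",
    "ode_rhs",
    "ode_fixed_point",
]

_RATE_CEILING = 1e12  # total-rate guard against runaway states
_CHUNK = 1 << 16


@dataclass
class Trajectory:
    """A sample path: state ``states[k]`` is held on ``[times[k], times[k+1])``.

    ``times[0]`` is 0; the final state is held until ``t_end``.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    t_end: float

    def __post_init__(self):
        if self.states.ndim == 1:
            self.states = self.states[:, None]

    @property
    def n_jumps(self) -> int:
        return len(self.times) - 1

    def to_tsv(self, path: str | Path) -> None:
        d = self.states.shape[1]
        header = "time\t" + "\t".join(f"a_{i+1}" for i in range(d))
        lines = [header]
        for t, row in zip(self.times, self.states):
            lines.append("\t".join([repr(float(t))] + [str(int(x)) for x in row]))
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class OccupationSummary:
    """Time-weighted fraction of a window spent in each state."""

    occupancy: dict
    burn_in: float

    def __post_init__(self):
        total = sum(self.occupancy.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"occupancy sums to {total}, not 1")
        if any(v < 0 for v in self.occupancy.values()):
            raise ValueError("occupancy fractions must be nonnegative")

    def as_table(self) -> DistributionTable:
        return DistributionTable(dict(self.occupancy), truncation_mass=0.0)

    def mass(self, predicate) -> float:
        return sum(v for k, v in self.occupancy.items() if predicate(k))


def _grow(times: list[np.ndarray], states: list[np.ndarray], d: int):
    times.append(np.empty(_CHUNK))
    states.append(np.empty((_CHUNK, d), dtype=np.int64))


def gillespie_simulate(
    params: RateParameters,
    a0: Sequence[int],
    t_end: float,
    seed: int,
    max_jumps: int | None = None,
) -> Trajectory:
    """Exact SSA path of the TK chain from ``a0`` over ``[0, t_end]``."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    a = list(as_state(a0, params.d))
    d = params.d
    rng = np.random.default_rng(seed)
    k1 = params.kappa[0] if d == 2 else None
    k2 = params.kappa[1] if d == 2 else None
    l1, l2 = (params.lam[0], params.lam[1]) if d == 2 else (None, None)
    delta = params.delta

    t_chunks: list[np.ndarray] = []
    s_chunks: list[np.ndarray] = []
    _grow(t_chunks, s_chunks, d)
    t_chunks[-1][0] = 0.0
    s_chunks[-1][0] = a
    fill = 1

    t = 0.0
    jumps = 0
    u = rng.random(2 * _CHUNK)
    ui = 0
    while True:
        if d == 2:
            a1, a2 = a
            c1 = k1 * a1 * a2
            c2 = k2 * a1 * a2
            o1 = delta * a1
            o2 = delta * a2
            total = c1 + c2 + l1 + l2 + o1 + o2
        else:
            trans = tk_transitions(a, params)
            total = sum(r for _, r in trans)
        if not total < _RATE_CEILING:
            raise OverflowError(f"total rate {total} at state {tuple(a)} exceeds ceiling")
        if ui + 2 > u.size:
            u = rng.random(2 * _CHUNK)
            ui = 0
        t += -math.log1p(-u[ui]) / total
        ui += 1
        if t >= t_end:
            break
        r = u[ui] * total
        ui += 1
        if d == 2:
            if r < c1:
                a[0] += 1
                a[1] -= 1
            elif r < c1 + c2:
                a[0] -= 1
                a[1] += 1
            elif r < c1 + c2 + l1:
                a[0] += 1
            elif r < c1 + c2 + l1 + l2:
                a[1] += 1
            elif r < c1 + c2 + l1 + l2 + o1:
                a[0] -= 1
            else:
                a[1] -= 1
        else:
            acc = 0.0
            for target, rate in trans:
                acc += rate
                if r < acc:
                    a = list(target)
                    break
            else:
                a = list(trans[-1][0])
        if fill == _CHUNK:
            _grow(t_chunks, s_chunks, d)
            fill = 0
        t_chunks[-1][fill] = t
        s_chunks[-1][fill] = a
        fill += 1
        jumps += 1
        if max_jumps is not None and jumps >= max_jumps:
            break
    t_chunks[-1] = t_chunks[-1][:fill]
    s_chunks[-1] = s_chunks[-1][:fill]
    return Trajectory(
        times=np.concatenate(t_chunks),
        states=np.concatenate(s_chunks),
        seed=seed,
        t_end=float(min(t_end, t)) if max_jumps is not None else float(t_end),
    )


def simulate_lumped(
    params: RateParameters, n0: int, t_end: float, seed: int
) -> Trajectory:
    """SSA path of the total-mass birth-death chain (immigration at
    ``sum(lam)``, per-capita death at ``delta``)."""
    if n0 < 0:
        raise ValueError("n0 must be nonnegative")
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    birth = params.total_inflow
    delta = params.delta
    n = int(n0)
    times = [0.0]
    states = [n]
    t = 0.0
    u = rng.random(2 * _CHUNK)
    ui = 0
    while True:
        total = birth + n * delta
        if not total < _RATE_CEILING:
            raise OverflowError(f"total rate {total} at mass {n} exceeds ceiling")
        if ui + 2 > u.size:
            u = rng.random(2 * _CHUNK)
            ui = 0
        t += -math.log1p(-u[ui]) / total
        ui += 1
        if t >= t_end:
            break
        if u[ui] * total < birth:
            n += 1
        else:
            n -= 1
        ui += 1
        times.append(t)
        states.append(n)
    return Trajectory(
        times=np.asarray(times), states=np.asarray(states, dtype=np.int64), seed=seed, t_end=float(t_end)
    )


def occupation_distribution(traj: Trajectory, burn_in: float = 0.0) -> OccupationSummary:
    """Sojourn-weighted occupancy of ``traj`` over ``[burn_in, t_end]``."""
    if not burn_in < traj.t_end:
        raise ValueError("burn-in must leave a nonempty window before t_end")
    times = traj.times
    ends = np.append(times[1:], traj.t_end)
    durations = np.clip(ends, burn_in, traj.t_end) - np.clip(times, burn_in, traj.t_end)
    keep = durations > 0
    states = traj.states[keep]
    durations = durations[keep]
    uniq, inverse = np.unique(states, axis=0, return_inverse=True)
    weights = np.bincount(inverse, weights=durations)
    weights /= weights.sum()
    occupancy = {}
    for row, w in zip(uniq, weights):
        key = tuple(int(x) for x in row)
        occupancy[key if len(key) > 1 else key[0]] = float(w)
    return OccupationSummary(occupancy=occupancy, burn_in=float(burn_in))


# -- deterministic counterpart ----------------------------------------------


@dataclass
class FixedPoint:
    """Stable fixed point of the two-species mass-action ODE."""

    a_star: tuple[float, float]
    residual: float

    def __post_init__(self):
        if self.residual > 1e-9:
            raise ValueError(f"fixed-point residual {self.residual:.2e} exceeds 1e-9")


def ode_rhs(a: Sequence[float], params: RateParameters) -> np.ndarray:
    """Two-component deterministic drift at (possibly non-integer) ``a``."""
    if params.d != 2:
        raise ValueError("the deterministic reduction is for d=2")
    a1, a2 = float(a[0]), float(a[1])
    k1, k2 = params.kappa
    l1, l2 = params.lam
    return np.array(
        [
            (k1 - k2) * a1 * a2 + l1 - params.delta * a1,
            (k2 - k1) * a1 * a2 + l2 - params.delta * a2,
        ]
    )


def ode_fixed_point(params: RateParameters) -> FixedPoint:
    """Stable root of the drift on the conservation line
    ``a1 + a2 = (lam_1+lam_2)/delta``.

    The reduced drift is the quadratic ``g(a1) = c a1^2 - (c T + delta) a1
    + lam_1`` with ``c = kappa_2 - kappa_1`` and ``T`` the line total; the
    stable root has ``g'(a1*) < 0``.  One Newton polish keeps the residual
    at rounding level.
    """
    if params.d != 2:
        raise ValueError("the deterministic reduction is for d=2")
    k1, k2 = params.kappa
    l1, l2 = params.lam
    delta = params.delta
    T = (l1 + l2) / delta
    c = k2 - k1
    if c == 0.0:
        a1 = l1 / delta
    else:
        b = c * T + delta
        disc = b * b - 4.0 * c * l1
        if disc < 0:
            raise ValueError("no real fixed point on the conservation line")
        sq = math.sqrt(disc)
        # numerically stable roots of c*x^2 - b*x + l1
        q = 0.5 * (b + math.copysign(sq, b))
        roots = sorted({q / c, l1 / q if q != 0 else math.inf})
        stable = [r for r in roots if -1e-9 <= r <= T * (1 + 1e-12) and 2 * c * r - b < 0]
        if not stable:
            raise ValueError(f"no stable root inside [0, {T}]; roots {roots}")
        a1 = float(stable[0])
        for _ in range(3):  # Newton polish on g
            g = c * a1 * a1 - b * a1 + l1
            gp = 2 * c * a1 - b
            a1 -= g / gp
    a_star = (a1, T - a1)
    residual = float(np.max(np.abs(ode_rhs(a_star, params))))
    return FixedPoint(a_star=a_star, residual=residual)
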