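"""Parameter sets for the Togashi-Kaneko (TK) network and the Moran model.

The TK network couples d molecular species through autocatalysis
``A_i + A_j -> 2 A_i`` (rate constant ``kappa_i``, mass action) with inflow
``0 -> A_i`` (rate ``lam_i``) and outflow ``A_i -> 0`` (rate ``delta`` per
molecule).  A single, species-independent outflow rate is required: it makes
the total-mass process a Markov chain in its own right (lumpability), which
everything downstream relies on.

Two equivalent parametrizations are supported: the raw rates
(:class:`RateParameters`) and the volume-scaled form
(:class:`ScaledParameters`) with ``kappa_i = kappa'_i / V``,
``lam_i = D * V`` and ``delta = D``, which indexes system size by the volume
``V`` and the openness of the system by ``D``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "RateParameters",
    "ScaledParameters",
    "MoranParameters",
    "as_state",
    "total_mass",
    "load_parameters",
    "save_parameters",
]


def _positive_vector(name: str, values: Sequence[float]) -> tuple[float, ...]:
    vec = tuple(float(v) for v in values)
    if any(not (v > 0) for v in vec):
        raise ValueError(f"all entries of {name} must be positive, got {vec}")
    return vec


@dataclass(frozen=True)
class RateParameters:
    """Raw mass-action rates of the TK network.

    Parameters
    ----------
    d : int
        Number of species, at least 2.
    kappa : sequence of float
        Autocatalytic rate constants ``kappa_i`` (per molecule pair per time).
    lam : sequence of float
        Inflow rates ``lam_i`` (molecules per time).
    delta : float
        Outflow rate per molecule, shared by all species (lumpability).
    """

    d: int
    kappa: tuple[float, ...]
    lam: tuple[float, ...]
    delta: float

    def __init__(self, d: int, kappa: Sequence[float], lam: Sequence[float], delta: float):
        object.__setattr__(self, "d", int(d))
        object.__setattr__(self, "kappa", _positive_vector("kappa", kappa))
        object.__setattr__(self, "lam", _positive_vector("lam", lam))
        object.__setattr__(self, "delta", float(delta))
        if self.d < 2:
            raise ValueError(f"need at least two species, got d={self.d}")
        if len(self.kappa) != self.d or len(self.lam) != self.d:
            raise ValueError("kappa and lam must have length d")
        if not self.delta > 0:
            raise ValueError("delta must be positive")

    @property
    def total_inflow(self) -> float:
        return sum(self.lam)

    @property
    def mean_mass(self) -> float:
        """Mean of the Poisson stationary law of the total-mass chain."""
        return self.total_inflow / self.delta

    @property
    def symmetric(self) -> bool:
        return all(k == self.kappa[0] for k in self.kappa)

    def to_dict(self) -> dict:
        return {"d": self.d, "kappa": list(self.kappa), "lam": list(self.lam), "delta": self.delta}


@dataclass(frozen=True)
class ScaledParameters:
    """Volume-scaled parametrization of the TK network.

    Maps losslessly to raw rates as ``kappa_i = kappa'_i/V``,
    ``lam_i = D*V``, ``delta = D``.  Under this scaling the Poisson
    total-mass mean is ``d*V`` and the shape of the stationary law is
    governed by ``D*V`` versus ``d`` (see :func:`tkmodel.reports.regime_classify`).
    """

    D: float
    V: float
    kappa_prime: tuple[float, ...]

    def __init__(self, D: float, V: float, kappa_prime: Sequence[float]):
        object.__setattr__(self, "D", float(D))
        object.__setattr__(self, "V", float(V))
        object.__setattr__(self, "kappa_prime", _positive_vector("kappa_prime", kappa_prime))
        if not self.D > 0 or not self.V > 0:
            raise ValueError("D and V must be positive")
        if len(self.kappa_prime) < 2:
            raise ValueError("need at least two species")

    @property
    def d(self) -> int:
        return len(self.kappa_prime)

    def to_rates(self) -> RateParameters:
        d = self.d
        return RateParameters(
            d=d,
            kappa=[k / self.V for k in self.kappa_prime],
            lam=[self.D * self.V] * d,
            delta=self.D,
        )

    def to_dict(self) -> dict:
        return {"D": self.D, "V": self.V, "kappa_prime": list(self.kappa_prime)}


@dataclass(frozen=True)
class MoranParameters:
    """Moran model with genic selection and parent-independent mutation.

    A population of fixed size ``n`` with ``d`` types; type ``i`` reproduces
    at rate ``kappa_i`` (its offspring replaces a uniformly chosen
    individual) and mutates to type ``j`` at rate ``v * p_j``.
    """

    n: int
    kappa: tuple[float, ...]
    v: float
    p: tuple[float, ...]

    def __init__(self, n: int, kappa: Sequence[float], v: float, p: Sequence[float]):
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "kappa", _positive_vector("kappa", kappa))
        object.__setattr__(self, "v", float(v))
        pv = tuple(float(x) for x in p)
        object.__setattr__(self, "p", pv)
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        if not self.v > 0:
            raise ValueError("mutation rate v must be positive")
        if len(pv) != len(self.kappa):
            raise ValueError("p and kappa must have the same length")
        if any(x < 0 for x in pv) or abs(sum(pv) - 1.0) > 1e-12:
            raise ValueError("p must be a probability vector")

    @property
    def d(self) -> int:
        return len(self.kappa)


def as_state(a: Sequence[int], d: int | None = None) -> tuple[int, ...]:
    """Validate and freeze a species-count vector into an integer tuple."""
    state = tuple(int(x) for x in a)
    if any(int(x) != x for x in a):
        raise ValueError(f"state must be integer-valued, got {a!r}")
    if any(x < 0 for x in state):
        raise ValueError(f"state must be nonnegative, got {state}")
    if d is not None and len(state) != d:
        raise ValueError(f"state has dimension {len(state)}, expected {d}")
    return state


def total_mass(a: Sequence[int]) -> int:
    return int(sum(as_state(a)))


# -- config I/O --------------------------------------------------------------
# Round trip is lossless: floats are written as decimal text with repr
# precision (17 significant digits), which json/yaml read back exactly.


def load_parameters(path: str | Path) -> RateParameters | ScaledParameters:
    """Read a parameter set from a JSON or YAML config.

    Raw-rate configs carry keys ``d, kappa, lam, delta``; scaled configs
    carry ``D, V, kappa_prime``.  Mixing the two key sets is an error.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    raw = {"d", "kappa", "lam", "delta"} & set(data)
    scaled = {"D", "V", "kappa_prime"} & set(data)
    if raw and scaled:
        raise ValueError(f"{path}: mixes raw-rate and scaled parameter keys")
    if scaled:
        return ScaledParameters(D=data["D"], V=data["V"], kappa_prime=data["kappa_prime"])
    if raw:
        return RateParameters(d=data["d"], kappa=data["kappa"], lam=data["lam"], delta=data["delta"])
    raise ValueError(f"{path}: no recognizable parameter keys")


def save_parameters(params: RateParameters | ScaledParameters, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
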