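"""Terminating Gauss hypergeometric polynomials for the partition function.

For d = 2 species, the partition function of the selection-weighted
Dirichlet-multinomial law reduces to a terminating Gauss series

    2F1(-n, x; y; z) = sum_{i=0}^{n} (-1)^i C(n,i) (x)_(i)/(y)_(i) z^i,

with ``(x)_(i)`` the ascending factorial, evaluated at ``x = alpha_1``,
``y = 1 - alpha_2 - n`` and ``z = kappa_1/kappa_2``.  Ratios of consecutive
such values (degree n against n-1 and n+1) carry the n-dependence of the
normalizer through the error functional.

Two evaluation routes are provided.  The general alternating series is
accumulated as signed log-magnitudes, with an exact-rational fallback
(stdlib fractions on the exact binary values of the inputs) whenever the
estimated cancellation threatens the ten-significant-digit contract.  For the parameter
pattern above there is also a sign-free form,

    2F1(-n, a1; 1-a2-n; z) = sum_i C(n,i) z^i (a1)_(i) (a2)_(n-i) / (a2)_(n),

a Beta-binomial-weighted positive sum evaluated by log-sum-exp; it is the
default for large degrees, where it is immune to cancellation.
"""

from __future__ import annotations

from fractions import Fraction
from math import exp, inf, isfinite, log

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = ["hyp2f1_neg_int", "hyp2f1_ratio_pair", "log_hyp2f1_weighted"]

#: degrees above which the sign-free weighted-sum route is used for ratios
_WEIGHTED_ROUTE_MIN_N = 200

#: decimal digits of cancellation tolerated before the exact-rational fallback.
#: Each lost digit amplifies the ~1e-16 accumulation error; 5 keeps the
#: float route at >= 10 significant digits, the kernel's accuracy contract.
_MAX_CANCEL_DIGITS = 5.0


def _check_pole(n: int, y: float) -> None:
    if y == round(y) and -(n - 1) <= y <= 0:
        i = int(-y) + 1  # first index whose Pochhammer factor y+i-1 vanishes
        raise ZeroDivisionError(
            f"(y)_(i) has a pole inside the sum: y={y} vanishes at term index i={i}"
        )


def _hyp2f1_exact(n: int, x: float, y: float, z: float) -> float:
    """Exact-rational evaluation of the terminating series (fallback)."""
    xf, yf, zf = Fraction(x), Fraction(y), Fraction(z)
    total = Fraction(0)
    term = Fraction(1)
    for i in range(n + 1):
        if i > 0:
            term *= Fraction(-(n - i + 1), i) * (xf + i - 1) / (yf + i - 1) * zf
        total += term
    return float(total)


def hyp2f1_neg_int(n: int, x: float, y: float, z: float) -> float:
    """Terminating ``2F1(-n, x; y; z)`` via the alternating finite sum.

    Terms are accumulated as signed log-magnitudes; if positive and negative
    groups cancel enough to threaten ten significant digits of accuracy the
    sum is redone in exact rational arithmetic.

    Raises
    ------
    ZeroDivisionError
        If ``y`` is a nonpositive integer in ``{0, -1, ..., -(n-1)}``, which
        puts a pole of ``(y)_(i)`` inside the sum.
    """
    n = int(n)
    if n < 0:
        raise ValueError("degree n must be a nonnegative integer")
    if not z > 0:
        raise ValueError("z must be positive")
    if n == 0:
        return 1.0
    _check_pole(n, y)

    logs = np.empty(n + 1)
    signs = np.empty(n + 1)
    lt, st = 0.0, 1.0
    logs[0], signs[0] = lt, st
    logz = log(z)
    for i in range(1, n + 1):
        num = x + i - 1
        den = y + i - 1
        st *= -np.sign(num) * np.sign(den)
        if num == 0:  # (x)_(i) vanishes from here on
            logs[i:] = -inf
            signs[i:] = 1.0
            break
        lt += log(n - i + 1) - log(i) + log(abs(num)) - log(abs(den)) + logz
        logs[i], signs[i] = lt, st

    total_log, total_sign = logsumexp(logs, b=signs, return_sign=True)
    peak = float(np.max(logs))
    if total_sign == 0 or not isfinite(total_log):
        return _hyp2f1_exact(n, x, y, z)
    lost_digits = (peak - total_log) / log(10.0)
    if lost_digits > _MAX_CANCEL_DIGITS:
        return _hyp2f1_exact(n, x, y, z)
    return float(total_sign * exp(total_log))


def log_hyp2f1_weighted(n: int, alpha1: float, alpha2: float, z: float) -> float:
    """``log 2F1(-n, alpha1; 1-alpha2-n; z)`` via the positive weighted sum.

    Valid for ``alpha1, alpha2 > 0`` and ``z > 0``; every term is positive,
    so the log-sum-exp accumulation loses no digits to sign alternation.
    """
    n = int(n)
    if n < 0:
        raise ValueError("degree n must be a nonnegative integer")
    if not (alpha1 > 0 and alpha2 > 0 and z > 0):
        raise ValueError("weighted route requires alpha1, alpha2, z > 0")
    i = np.arange(n + 1)
    terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * log(z)
        + gammaln(alpha1 + i) - gammaln(alpha1)
        + gammaln(alpha2 + n - i) - gammaln(alpha2 + n)
    )
    return float(logsumexp(terms))


def hyp2f1_ratio_pair(
    n: int, alpha1: float, alpha2: float, z: float
) -> tuple[float, float]:
    """The two ratios of consecutive-degree ``2F1`` values in the error
    functional, ``(F_n/F_{n-1}, F_n/F_{n+1})`` where

        F_m = 2F1(-m, alpha1; 1-alpha2-m; z).

    Both are finite and positive for ``n >= 1``, ``alpha1, alpha2 > 0`` and
    ``z > 0``; for the near-symmetric configurations of interest they sit
    close to 1.
    """
    n = int(n)
    if n < 1:
        raise ValueError("ratios need degree n >= 1")
    if not (alpha1 > 0 and alpha2 > 0):
        raise ValueError("alpha1 and alpha2 must be positive")
    if n > _WEIGHTED_ROUTE_MIN_N:
        lo = log_hyp2f1_weighted(n, alpha1, alpha2, z)
        # F_m enters the adjacent-degree values with alpha2 fixed: the
        # 1/(alpha2)_(m) normalizer of the weighted form is part of F_m.
        lm = log_hyp2f1_weighted(n - 1, alpha1, alpha2, z)
        lp = log_hyp2f1_weighted(n + 1, alpha1, alpha2, z)
        return exp(lo - lm), exp(lo - lp)
    fn = hyp2f1_neg_int(n, alpha1, 1 - alpha2 - n, z)
    fm = hyp2f1_neg_int(n - 1, alpha1, 2 - alpha2 - n, z)
    fp = hyp2f1_neg_int(n + 1, alpha1, -alpha2 - n, z)
    return fn / fm, fn / fp
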