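"""Bounded outlyingness functions on standardized log ratios.

Classical robust weight functions (Tukey biweight, Huber, Hampel) map a
standardized residual to a downweight in [0, 1], discarding the sign. For
outlier *diagnostics* the sign matters — positive means the nominator
dominates, negative the denominator — so each weight function omega is
"adjusted" into an odd outlyingness function

    omega*(u) = (1 - omega(|u|)) * sign(u)

with values in [-1, 1]: 0 marks a typical log ratio, +/-1 an extreme one.
The three families differ in their zero plateau and saturation behaviour:

* adjusted Tukey: 0 only at u = 0, saturates exactly at |u| >= c;
* adjusted Huber: 0 on the whole interval [-k, k], approaches +/-1 only
  asymptotically;
* adjusted Hampel: 0 on [-c1, c1], exactly +/-1 beyond c3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .robust_estimators import tukey_biweight_weight

__all__ = [
    "TUKEY_C",
    "HUBER_K",
    "HAMPEL_C1",
    "HAMPEL_C2",
    "HAMPEL_C3",
    "OutlyingnessFunctionSpec",
    "adjusted_tukey",
    "adjusted_huber",
    "adjusted_hampel",
    "get_function",
]

TUKEY_C = 4.685
HUBER_K = 1.345
# standard-normal quantiles z_0.95, z_0.975, z_0.99, rounded to 4 decimals
HAMPEL_C1 = 1.6449
HAMPEL_C2 = 1.9600
HAMPEL_C3 = 2.3263


def _as_float_array(u):
    return np.asarray(u, dtype=float)


def _finalize(out):
    return float(out) if out.ndim == 0 else out


def adjusted_tukey(u, c: float = TUKEY_C):
    """Adjusted Tukey biweight outlyingness: (1 - omega_c(u)) * sign(u).

    Odd, 0 at u = 0, strictly increasing on [0, c], exactly +/-1 for
    |u| >= c. (The printed form omega_c(u)*sgn(-u) + sgn(u) with the
    convention sgn(0) = 1 would give 2 at the origin; continuity and
    oddness force the value 0 there, which is what this implements.)
    """
    if c <= 0:
        raise ValueError("c must be positive")
    u = _as_float_array(u)
    out = np.sign(u) * (1.0 - tukey_biweight_weight(u, c))
    out = np.where(np.isinf(u), np.sign(u), out)  # saturate degenerate sentinels
    return _finalize(out)


def adjusted_huber(u, k: float = HUBER_K):
    """Adjusted Huber outlyingness: (omega_k(u) - 1) * sgn(-u) with omega_k = min(1, k/|u|).

    Odd, identically 0 on [-k, k], monotone on all of R, tending to +/-1
    as u -> +/-inf without ever attaining it (for finite u).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    u = _as_float_array(u)
    absu = np.abs(u)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.minimum(1.0, np.where(absu > 0, k / np.where(absu > 0, absu, 1.0), 1.0))
    out = np.sign(u) * (1.0 - w)
    out = np.where(np.isinf(u), np.sign(u), out)
    return _finalize(out)


def _hampel_weight(absu, c1, c2, c3):
    # four-branch Hampel weight on |u|: 1, c1/|u|, (c1/|u|)(c3-|u|)/(c3-c2), 0
    safe = np.where(absu > 0, absu, 1.0)
    w = np.ones_like(absu)
    mid = (absu > c1) & (absu <= c2)
    desc = (absu > c2) & (absu < c3)
    with np.errstate(over="ignore", invalid="ignore"):
        # discarded np.where branches may overflow for huge |u|
        w = np.where(mid, c1 / safe, w)
        w = np.where(desc, (c1 / safe) * (c3 - absu) / (c3 - c2), w)
    w = np.where(absu >= c3, 0.0, w)
    return w


def adjusted_hampel(u, c1: float = HAMPEL_C1, c2: float = HAMPEL_C2,
                    c3: float = HAMPEL_C3):
    """Adjusted Hampel outlyingness: (omega_h(u) - 1) * sgn(-u).

    Odd, 0 on [-c1, c1], piecewise continuous and nondecreasing on [0, c3],
    exactly +/-1 for |u| >= c3.
    """
    if not (0 < c1 < c2 < c3):
        raise ValueError("require 0 < c1 < c2 < c3")
    u = _as_float_array(u)
    absu = np.abs(u)
    out = np.sign(u) * (1.0 - _hampel_weight(absu, c1, c2, c3))
    out = np.where(np.isinf(u), np.sign(u), out)
    return _finalize(out)


@dataclass(frozen=True)
class OutlyingnessFunctionSpec:
    """Named outlyingness family with its tuning constants.

    family : {"tukey", "huber", "hampel"}
    c : Tukey cutoff (default 4.685); k : Huber corner (default 1.345);
    c1 < c2 < c3 : Hampel knots (defaults are the 0.95/0.975/0.99
    standard-normal quantiles).
    """

    family: str = "tukey"
    c: float = TUKEY_C
    k: float = HUBER_K
    c1: float = HAMPEL_C1
    c2: float = HAMPEL_C2
    c3: float = HAMPEL_C3

    def __post_init__(self):
        if self.family not in ("tukey", "huber", "hampel"):
            raise ValueError(f"unknown outlyingness family {self.family!r}")
        if self.c <= 0 or self.k <= 0:
            raise ValueError("c and k must be positive")
        if not (0 < self.c1 < self.c2 < self.c3):
            raise ValueError("require 0 < c1 < c2 < c3")


def get_function(spec: OutlyingnessFunctionSpec):
    """Return the adjusted outlyingness function of `spec`, constants bound, vectorized."""
    if spec.family == "tukey":
        return lambda u: adjusted_tukey(u, spec.c)
    if spec.family == "huber":
        return lambda u: adjusted_huber(u, spec.k)
    if spec.family == "hampel":
        return lambda u: adjusted_hampel(u, spec.c1, spec.c2, spec.c3)
    raise ValueError(f"unknown outlyingness family {spec.family!r}")
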