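"""Robust location/scale of a reference sample of log ratios.

The scale is the median absolute deviation with the conventional
normal-consistency factor 1.483; the location is a one-step Tukey-biweight
weighted mean started from the median/MAD pair (a single reweighting pass,
no iteration). These are the ingredients of the standardization

    y_tilde = (y - center) / scale

applied to every pairwise log ratio before the outlyingness function.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MAD_CONSTANT",
    "mad",
    "tukey_biweight_weight",
    "robust_center_scale",
    "standardize",
]

# normal-consistency factor for the MAD, as conventionally printed
MAD_CONSTANT = 1.483


def mad(values) -> float:
    """Median absolute deviation, scaled by 1.483.

    MAD(y) = 1.483 * median_i |y_i - median_j(y_j)|.  Returns 0 whenever at
    least half the values coincide with the median (zero robust spread).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    med = np.median(values)
    return MAD_CONSTANT * float(np.median(np.abs(values - med)))


def tukey_biweight_weight(u, c: float = 4.685):
    """Tukey's biweight weight function omega_c(u) = (1 - (u/c)^2)^2 on |u| < c, else 0.

    Even, equal to 1 at u = 0, identically 0 for |u| >= c (strict inequality
    at the cutoff). Vectorized; infinite inputs get weight 0.
    """
    if c <= 0:
        raise ValueError("tuning constant c must be positive")
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = np.abs(u) < c
    t = u[inside] / c
    out[inside] = (1.0 - t * t) ** 2
    if out.ndim == 0:
        return float(out)
    return out


def robust_center_scale(reference_values, c: float = 4.685):
    """One-step robust (center, scale) of a reference sample.

    scale is the MAD; center is the biweight-weighted mean with weights
    omega_c((y_i - median)/scale). If the MAD is 0 the pair is degenerate:
    the center falls back to the median and the caller must route values
    around the standardization (see ``standardize_slice``).

    Returns
    -------
    (center, scale, degenerate) : (float, float, bool)
    """
    y = np.asarray(reference_values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 reference values")
    med = float(np.median(y))
    s = mad(y)
    if s == 0.0:
        return med, 0.0, True
    with np.errstate(over="ignore"):
        v = tukey_biweight_weight((y - med) / s, c)
    vsum = v.sum()
    # the median itself always carries weight 1, so the weights cannot all vanish
    assert vsum > 0, "all-zero biweight weights are impossible for finite data"
    return float(np.sum(v * y) / vsum), s, False


def standardize(y, center: float, scale: float):
    """Affine standardization (y - center) / scale; requires scale > 0."""
    if scale <= 0:
        raise ValueError("scale must be positive; degenerate pairs are handled upstream")
    return (np.asarray(y, dtype=float) - center) / scale
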