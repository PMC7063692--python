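"""Naive, self-contained reference implementation of the outlyingness pipeline.

Deliberately written as explicit loops over every (sample, nominator,
denominator) triple, with scalar robust statistics derived straight from
the defining formulas, and materializing the full n x d x d array. It
shares no code with the package's streaming implementation and serves as
the independent oracle the streaming path is compared against bit for bit.
"""

import numpy as np


def naive_center_scale(y, c):
    """Scalar one-step biweight center and MAD scale of a 1-D sample."""
    y = np.asarray(y, dtype=float)
    med = np.median(y)
    s = 1.483 * np.median(np.abs(y - med))
    if s == 0.0:
        return med, 0.0
    v = np.empty(len(y))
    for i, yi in enumerate(y):
        u = (yi - med) / s
        v[i] = (1.0 - (u / c) ** 2) ** 2 if abs(u) < c else 0.0
    return np.sum(v * y) / np.sum(v), s


def naive_outlyingness_array(X, groups, reference, func, c=4.685):
    """Full n x d x d array W*[i, j, k] by triple loop."""
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n, d = X.shape
    ref_rows = np.nonzero(groups == reference)[0]
    L = np.log(X)
    Wstar = np.zeros((n, d, d))
    for j in range(d):
        for k in range(d):
            if j == k:
                continue  # y~_ijj := 0, so w*_ijj = 0
            y = L[:, j] - L[:, k]
            center, s = naive_center_scale(y[ref_rows], c)
            for i in range(n):
                if s == 0.0:
                    diff = y[i] - center
                    u = 0.0 if diff == 0.0 else np.copysign(np.inf, diff)
                else:
                    u = (y[i] - center) / s
                Wstar[i, j, k] = func(u)
    return Wstar


def naive_outlyingness_matrix(X, groups, reference, func, c=4.685,
                              include_diagonal=True):
    """Aggregate the naive array by the median over the denominator index."""
    Wstar = naive_outlyingness_array(X, groups, reference, func, c)
    n, d, _ = Wstar.shape
    W = np.empty((n, d))
    for i in range(n):
        for j in range(d):
            vals = Wstar[i, j, :] if include_diagonal else np.delete(Wstar[i, j, :], j)
            W[i, j] = np.median(vals)
    return W
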