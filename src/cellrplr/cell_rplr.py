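"""The cell-rPLR algorithm: cellwise outlyingness from robust pairwise log ratios.

For an n x d table of positive abundances with grouped samples, the method

1. forms all pairwise log ratios y_ijk = ln(x_ij) - ln(x_ik);
2. robustly centers and scales each (j, k) pair using only the reference
   (majority) group, so group differences survive standardization;
3. maps the standardized ratios through a bounded odd outlyingness function
   into w*_ijk in [-1, 1];
4. aggregates w_ij = median_k(w*_ij1, ..., w*_ijd), giving the n x d
   outlyingness matrix W.

Because every quantity is a within-sample ratio, a per-sample multiplicative
size effect (e.g. urine dilution) cancels exactly: no normalization is
needed, which is the point of the method.

The estimator :class:`CellRPLR` follows the scikit-learn contract: ``fit``
learns the per-pair robust centers/scales from the reference group of the
training table, ``transform`` maps any table with the same features to its
outlyingness matrix. The conceptual n x d x d array W* is never
materialized during ``transform`` — slices over the nominator index j are
streamed, so working memory is O(n d) on top of the O(d^2) fitted
parameters — but is available from :meth:`outlyingness_array` for small
problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import GroupedDataMatrix, majority_group
from .outlyingness_functions import (
    HAMPEL_C1,
    HAMPEL_C2,
    HAMPEL_C3,
    HUBER_K,
    TUKEY_C,
    OutlyingnessFunctionSpec,
    get_function,
)
from .robust_estimators import MAD_CONSTANT, tukey_biweight_weight

__all__ = [
    "CellRPLR",
    "StandardizedLogRatioSlice",
    "OutlyingnessMatrix",
    "logratio_slice",
    "standardize_slice",
    "outlyingness_matrix",
    "outlyingness_array_full",
]


@dataclass
class StandardizedLogRatioSlice:
    """Standardized log ratios y~_ijk for one fixed nominator feature j."""

    j: int
    values: np.ndarray          # n x d, column k = j all zeros
    centers: np.ndarray         # d robust centers (reference group)
    scales: np.ndarray          # d robust scales (MAD, >= 0)
    degenerate_mask: np.ndarray  # d flags where scale == 0 (diagonal excluded)


@dataclass
class OutlyingnessMatrix:
    """Aggregated n x d cellwise outlyingness matrix W, entries in [-1, 1]."""

    values: np.ndarray
    reference_group: object
    function_spec: OutlyingnessFunctionSpec
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    groups: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.feature_ids)


def _validate_positive_matrix(X):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D samples-by-features matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite (no NaN/inf)")
    if np.any(X <= 0):
        raise ValueError("all abundances must be strictly positive")
    return X


def _pairwise_center_scale(Lr, c):
    """Robust (center, scale) of log ratios for every pair j < k, mirrored.

    Lr : reference-group rows of ln(X), shape (n_ref, d). Returns d x d
    arrays (centers, scales, degenerate) with exact antisymmetry
    centers[k, j] = -centers[j, k]; only pairs j < k are computed.
    """
    n_ref, d = Lr.shape
    centers = np.zeros((d, d))
    scales = np.zeros((d, d))
    degenerate = np.zeros((d, d), dtype=bool)
    for j in range(d - 1):
        Y = Lr[:, [j]] - Lr[:, j + 1:]            # n_ref x (d-j-1)
        med = np.median(Y, axis=0)
        s = MAD_CONSTANT * np.median(np.abs(Y - med), axis=0)
        deg = s == 0.0
        safe = np.where(deg, 1.0, s)
        v = tukey_biweight_weight((Y - med) / safe, c)
        center = np.sum(v * Y, axis=0) / np.sum(v, axis=0)
        center = np.where(deg, med, center)
        centers[j, j + 1:] = center
        scales[j, j + 1:] = s
        degenerate[j, j + 1:] = deg
    centers = centers - centers.T                 # lower triangle = -upper
    scales = scales + scales.T
    degenerate = degenerate | degenerate.T
    return centers, scales, degenerate


def _standardize_slice_values(L, j, centers_j, scales_j, degenerate_j):
    """Standardized y~ values for slice j from precomputed pair statistics."""
    Y = L[:, [j]] - L
    safe = np.where(scales_j > 0, scales_j, 1.0)
    U = (Y - centers_j) / safe
    # degenerate pairs (zero MAD): 0 at the center, +/-inf elsewhere so the
    # outlyingness saturates at +/-1; the diagonal (Y identically 0, center
    # 0) falls through this branch to exact zeros
    zero_scale = scales_j == 0.0
    if zero_scale.any():
        D = Y[:, zero_scale] - centers_j[zero_scale]
        U[:, zero_scale] = np.where(D > 0, np.inf, np.where(D < 0, -np.inf, 0.0))
    U[:, j] = 0.0
    return Y, U


class CellRPLR(TransformerMixin, BaseEstimator):
    """Cellwise outlyingness scores from robust pairwise log ratios.

    Parameters
    ----------
    function : {"tukey", "huber", "hampel"}, default="tukey"
        Adjusted outlyingness family applied to the standardized log ratios.
    c, k, c1, c2, c3 : float
        Tuning constants of the three families (Tukey cutoff, Huber corner,
        Hampel knots); defaults are the conventional choices. ``c`` is also
        the biweight constant of the one-step location estimator.
    reference : "auto" or group label, default="auto"
        Group whose samples define the robust centers and scales; "auto"
        selects the majority group.
    tie_break : {"first_label", "seeded_random"}, default="first_label"
        Tie rule between equally large majority groups ("auto" only).
    include_diagonal : bool, default=True
        Whether the identically-zero term w*_ijj enters the median over k.
    random_state : int or None
        Seed for the "seeded_random" tie rule.

    Attributes
    ----------
    centers_, scales_ : ndarray of shape (d, d)
        Robust center/scale of the log ratio of features (j, k) in the
        reference group; exactly antisymmetric / symmetric.
    degenerate_mask_ : ndarray of shape (d, d) of bool
        Pairs whose reference MAD is zero (standardization saturates).
    reference_group_ : label of the group used for standardization.
    n_features_in_ : int

    Examples
    --------
    >>> est = CellRPLR(function="hampel")
    >>> W = est.fit_transform(X, groups)   # n x d, entries in [-1, 1]
    """

    def __init__(self, function="tukey", c=TUKEY_C, k=HUBER_K,
                 c1=HAMPEL_C1, c2=HAMPEL_C2, c3=HAMPEL_C3,
                 reference="auto", tie_break="first_label",
                 include_diagonal=True, random_state=None):
        self.function = function
        self.c = c
        self.k = k
        self.c1 = c1
        self.c2 = c2
        self.c3 = c3
        self.reference = reference
        self.tie_break = tie_break
        self.include_diagonal = include_diagonal
        self.random_state = random_state

    def _function_spec(self) -> OutlyingnessFunctionSpec:
        return OutlyingnessFunctionSpec(family=self.function, c=self.c,
                                        k=self.k, c1=self.c1, c2=self.c2,
                                        c3=self.c3)

    def fit(self, X, y):
        """Learn per-pair robust centers/scales from the reference group.

        Parameters
        ----------
        X : array-like of shape (n, d), strictly positive abundances.
        y : array-like of shape (n,), group label per sample (>= 2 groups).
        """
        X = _validate_positive_matrix(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],):
            raise ValueError("y must hold one group label per sample")
        spec = self._function_spec()  # validates constants early
        if self.reference == "auto":
            ref = majority_group(y, tie_break=self.tie_break,
                                 seed=self.random_state)
        else:
            ref = self.reference
            if not np.any(y == ref):
                raise ValueError(f"reference group {ref!r} not present in y")
        mask = y == ref
        if mask.sum() < 2:
            raise ValueError("reference group needs at least 2 samples")
        Lr = np.log(X[mask])
        self.centers_, self.scales_, self.degenerate_mask_ = \
            _pairwise_center_scale(Lr, self.c)
        self.reference_group_ = ref
        self.n_features_in_ = X.shape[1]
        self._spec = spec
        return self

    def _check_X(self, X):
        check_is_fitted(self, "centers_")
        X = _validate_positive_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        return X

    def transform(self, X):
        """Aggregated outlyingness matrix W of shape (n, d), entries in [-1, 1].

        Computed one nominator slice at a time; the full n x d x d array is
        never held in memory.
        """
        X = self._check_X(X)
        L = np.log(X)
        n, d = L.shape
        func = get_function(self._spec)
        W = np.empty((n, d))
        for j in range(d):
            Wstar = self._slice_outlyingness(L, j, func)
            if self.include_diagonal:
                W[:, j] = np.median(Wstar, axis=1)
            else:
                W[:, j] = np.median(np.delete(Wstar, j, axis=1), axis=1)
        return W

    def _slice_outlyingness(self, L, j, func):
        _, U = _standardize_slice_values(L, j, self.centers_[j],
                                         self.scales_[j],
                                         self.degenerate_mask_[j])
        return func(U)

    def standardized_slice(self, X, j) -> StandardizedLogRatioSlice:
        """Standardized log ratios y~_i j k for one fixed nominator feature j."""
        X = self._check_X(X)
        if not 0 <= j < self.n_features_in_:
            raise IndexError(f"feature index {j} out of range")
        L = np.log(X)
        _, U = _standardize_slice_values(L, j, self.centers_[j],
                                         self.scales_[j],
                                         self.degenerate_mask_[j])
        return StandardizedLogRatioSlice(
            j=j, values=U, centers=self.centers_[j].copy(),
            scales=self.scales_[j].copy(),
            degenerate_mask=self.degenerate_mask_[j].copy())

    def outlyingness_slice(self, X, j):
        """One n x d slice w*_i j k of the outlyingness array, for fixed j."""
        X = self._check_X(X)
        if not 0 <= j < self.n_features_in_:
            raise IndexError(f"feature index {j} out of range")
        return self._slice_outlyingness(np.log(X), j, get_function(self._spec))

    def outlyingness_array(self, X, element_budget=10**8):
        """The full n x d x d array W* (small problems only).

        Raises MemoryError when n*d*d exceeds ``element_budget``; large
        problems must use :meth:`transform`, which streams slices.
        """
        X = self._check_X(X)
        n, d = X.shape
        if n * d * d > element_budget:
            raise MemoryError(
                f"n*d^2 = {n * d * d} exceeds the element budget "
                f"{element_budget}; use transform(), which streams slices")
        return np.stack([self.outlyingness_slice(X, j) for j in range(d)],
                        axis=1)


# ---------------------------------------------------------------------------
# function-level surface over the estimator


def logratio_slice(X: GroupedDataMatrix, j: int) -> np.ndarray:
    """Pairwise log ratios y_ijk = ln(x_ij / x_ik) for fixed j, over all i, k."""
    if not 0 <= j < X.n_features:
        raise IndexError(f"feature index {j} out of range")
    L = np.log(X.values)
    return L[:, [j]] - L


def standardize_slice(Y, groups, reference, c: float = TUKEY_C, j: int | None = None):
    """Robustly standardize one log-ratio slice against a reference group.

    Per column k, (center, scale) are computed from the reference group's
    rows only and applied to all rows. ``j`` (the slice's own feature index,
    if it indexes a column of Y) is forced to zero and never flagged.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    mask = groups == reference
    if not mask.any():
        raise ValueError(f"reference label {reference!r} absent")
    if mask.sum() < 2:
        raise ValueError("reference group needs at least 2 samples")
    Yr = Y[mask]
    med = np.median(Yr, axis=0)
    s = MAD_CONSTANT * np.median(np.abs(Yr - med), axis=0)
    deg = s == 0.0
    safe = np.where(deg, 1.0, s)
    v = tukey_biweight_weight((Yr - med) / safe, c)
    center = np.sum(v * Yr, axis=0) / np.sum(v, axis=0)
    center = np.where(deg, med, center)
    U = (Y - center) / safe
    if deg.any():
        D = Y[:, deg] - center[deg]
        U[:, deg] = np.where(D > 0, np.inf, np.where(D < 0, -np.inf, 0.0))
    if j is not None:
        U[:, j] = 0.0
        deg = deg.copy()
        deg[j] = False
    return StandardizedLogRatioSlice(j=-1 if j is None else j, values=U,
                                     centers=center, scales=s,
                                     degenerate_mask=deg)


def _make_estimator(X: GroupedDataMatrix, spec: OutlyingnessFunctionSpec,
                    reference, include_diagonal=True, seed=None) -> CellRPLR:
    est = CellRPLR(function=spec.family, c=spec.c, k=spec.k, c1=spec.c1,
                   c2=spec.c2, c3=spec.c3, reference=reference,
                   include_diagonal=include_diagonal, random_state=seed)
    return est.fit(X.values, X.groups)


def outlyingness_matrix(X: GroupedDataMatrix,
                        spec: OutlyingnessFunctionSpec | None = None,
                        reference="auto", include_diagonal=True,
                        seed=None) -> OutlyingnessMatrix:
    """Run the full cell-rPLR pipeline on a grouped table, returning W."""
    spec = spec or OutlyingnessFunctionSpec()
    est = _make_estimator(X, spec, reference, include_diagonal, seed)
    W = est.transform(X.values)
    return OutlyingnessMatrix(values=W, reference_group=est.reference_group_,
                              function_spec=spec, sample_ids=X.sample_ids,
                              feature_ids=X.feature_ids, groups=X.groups)


def outlyingness_array_full(X: GroupedDataMatrix,
                            spec: OutlyingnessFunctionSpec | None = None,
                            reference="auto", element_budget=10**8,
                            seed=None) -> np.ndarray:
    """The full n x d x d outlyingness array W* (explicit small-d accessor)."""
    spec = spec or OutlyingnessFunctionSpec()
    est = _make_estimator(X, spec, reference, seed=seed)
    return est.outlyingness_array(X.values, element_budget=element_budget)
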