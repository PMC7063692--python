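"""Biomarker identification from the outlyingness matrix (two-group setting).

For two groups the per-feature statistic

    m_j = median(w_j, group 1) - median(w_j, group 2)

compares the groups' typical outlyingness of feature j; since all w_ij live
on the common scale [-1, 1], the m_j are directly comparable across
features and a descending sort yields a biomarker ranking.

Significance comes from a permutation test: the feature index is permuted
independently within each sample's slice of the outlyingness array
(identically across the denominator index k, so the permutation commutes
with the median aggregation and reduces to shuffling each row of W),
destroying the group structure carried by the reference-group
standardization while keeping each sample's outlyingness profile. The
p-value of feature j is the proportion of replicates whose statistic
reaches the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .cell_rplr import CellRPLR, OutlyingnessMatrix
from .outlyingness_functions import (
    HAMPEL_C1,
    HAMPEL_C2,
    HAMPEL_C3,
    HUBER_K,
    TUKEY_C,
)

__all__ = [
    "BiomarkerResult",
    "group_difference",
    "rank_variables",
    "permute_rows",
    "permutation_test",
    "RPLRBiomarker",
]


@dataclass
class BiomarkerResult:
    """Per-feature biomarker statistics.

    m : d-vector of group median differences m_j
    ranks : d-vector, 1 = most important (per the chosen mode)
    p_values : d-vector of permutation p-values (granularity 1/B)
    B : number of permutation replicates
    seed : RNG seed used
    alternative : "signed_as_printed" or "absolute"
    """

    m: np.ndarray
    ranks: np.ndarray
    p_values: np.ndarray
    B: int
    seed: object
    alternative: str
    feature_ids: np.ndarray | None = None


def _two_group_masks(groups, order=None):
    groups = np.asarray(groups)
    _, idx = np.unique(groups, return_index=True)
    labels = groups[np.sort(idx)]
    if len(labels) != 2:
        raise ValueError(
            f"biomarker identification requires exactly 2 groups, got {len(labels)}")
    if order is not None:
        if set(order) != set(labels):
            raise ValueError(f"order {order!r} does not match labels {set(labels)!r}")
        labels = np.asarray(order)
    return groups == labels[0], groups == labels[1]


def _as_w(W):
    if isinstance(W, OutlyingnessMatrix):
        return W.values
    return np.asarray(W, dtype=float)


def group_difference(W, groups, order=None) -> np.ndarray:
    """m_j = median of group-1 outlyingness minus median of group-2, per feature.

    Group 1 is the first label in order of appearance unless ``order``
    (a pair of labels) says otherwise; exchanging the group roles negates
    every m_j.
    """
    Wv = _as_w(W)
    m1, m2 = _two_group_masks(groups, order)
    if not (m1.any() and m2.any()):
        raise ValueError("both groups need at least one sample")
    return np.median(Wv[m1], axis=0) - np.median(Wv[m2], axis=0)


def rank_variables(m, mode: str = "descending_absolute") -> np.ndarray:
    """Ranks 1..d, 1 = most important; ties broken by feature order (stable).

    mode "descending_signed" sorts by m_j, "descending_absolute" by |m_j|.
    """
    m = np.asarray(m, dtype=float)
    if mode == "descending_signed":
        key = -m
    elif mode == "descending_absolute":
        key = -np.abs(m)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    order = np.argsort(key, kind="stable")
    ranks = np.empty(len(m), dtype=int)
    ranks[order] = np.arange(1, len(m) + 1)
    return ranks


def permute_rows(W, rng) -> np.ndarray:
    """One permutation replicate: shuffle the feature index within each row.

    This is the single place defining the permutation scheme: each sample
    row receives its own independent permutation of the d feature indices,
    applied identically across the denominator index k of the underlying
    array, which after the median aggregation is exactly a row-wise column
    shuffle of W.
    """
    return rng.permuted(np.asarray(W, dtype=float), axis=1)


def permutation_test(W, groups, B: int = 1000, seed=None,
                     alternative: str = "absolute",
                     rank_mode: str | None = None,
                     small_sample_correction: bool = False) -> BiomarkerResult:
    """Permutation p-values and ranking for the group-difference statistic.

    Parameters
    ----------
    W : OutlyingnessMatrix or (n, d) array of aggregated outlyingness values.
    groups : n labels, exactly 2 distinct.
    B : number of permutation replicates (1000 in the reference experiments).
    alternative : {"absolute", "signed_as_printed"}
        "signed_as_printed" estimates p_j = (1/B) #{b : m_j <= m_j(b)}
        (one-sided in the signed statistic); "absolute" uses
        |m_j| <= |m_j(b)|, symmetric in the group labels, and is the default
        for discovery.
    small_sample_correction : bool
        If True, use (1 + #) / (1 + B) instead of the plain proportion
        (which can be exactly 0).

    Returns
    -------
    BiomarkerResult with m, ranks, p_values (multiples of 1/B by default).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if alternative not in ("absolute", "signed_as_printed"):
        raise ValueError(f"unknown alternative {alternative!r}")
    Wv = _as_w(W)
    groups = np.asarray(groups)
    mask1, mask2 = _two_group_masks(groups)
    m_obs = np.median(Wv[mask1], axis=0) - np.median(Wv[mask2], axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Wv.shape[1], dtype=int)
    for _ in range(B):
        Wb = permute_rows(Wv, rng)
        m_b = np.median(Wb[mask1], axis=0) - np.median(Wb[mask2], axis=0)
        if alternative == "absolute":
            exceed += np.abs(m_obs) <= np.abs(m_b)
        else:
            exceed += m_obs <= m_b
    if small_sample_correction:
        p = (1 + exceed) / (1 + B)
    else:
        p = exceed / B
    if rank_mode is None:
        rank_mode = ("descending_absolute" if alternative == "absolute"
                     else "descending_signed")
    ranks = rank_variables(m_obs, mode=rank_mode)
    feature_ids = W.feature_ids if isinstance(W, OutlyingnessMatrix) else None
    return BiomarkerResult(m=m_obs, ranks=ranks, p_values=p, B=B, seed=seed,
                           alternative=alternative, feature_ids=feature_ids)


class RPLRBiomarker(SelectorMixin, BaseEstimator):
    """Two-group biomarker selection via cell-rPLR and a permutation test.

    Runs :class:`CellRPLR` on the training table, computes the group median
    difference m_j of the outlyingness values, ranks features, and assigns
    permutation p-values. As a scikit-learn selector, ``transform`` keeps
    the features with p-value <= ``alpha``.

    Parameters
    ----------
    function, c, k, c1, c2, c3, reference, include_diagonal :
        passed through to :class:`CellRPLR`.
    B : int, default=1000
        Permutation replicates.
    alternative : {"absolute", "signed_as_printed"}, default="absolute"
    alpha : float, default=0.05
        Selection level on the permutation p-values.
    adjust : {None, "fdr_bh"}, default=None
        Optional Benjamini-Hochberg adjustment applied before selection.
    random_state : int or None
        Seed for the permutation replicates.

    Attributes
    ----------
    m_ : ndarray of shape (d,) — group median differences.
    ranks_ : ndarray of shape (d,) — 1 = most important.
    p_values_ : ndarray of shape (d,) — permutation p-values (adjusted if
        ``adjust`` is set; raw values stay in ``raw_p_values_``).
    scorer_ : the fitted CellRPLR estimator.
    """

    def __init__(self, function="tukey", c=TUKEY_C, k=HUBER_K,
                 c1=HAMPEL_C1, c2=HAMPEL_C2, c3=HAMPEL_C3,
                 reference="auto", include_diagonal=True, B=1000,
                 alternative="absolute", alpha=0.05, adjust=None,
                 random_state=None):
        self.function = function
        self.c = c
        self.k = k
        self.c1 = c1
        self.c2 = c2
        self.c3 = c3
        self.reference = reference
        self.include_diagonal = include_diagonal
        self.B = B
        self.alternative = alternative
        self.alpha = alpha
        self.adjust = adjust
        self.random_state = random_state

    def fit(self, X, y):
        scorer = CellRPLR(function=self.function, c=self.c, k=self.k,
                          c1=self.c1, c2=self.c2, c3=self.c3,
                          reference=self.reference,
                          include_diagonal=self.include_diagonal,
                          random_state=self.random_state)
        W = scorer.fit(X, y).transform(X)
        res = permutation_test(W, y, B=self.B, seed=self.random_state,
                               alternative=self.alternative)
        self.scorer_ = scorer
        self.outlyingness_ = W
        self.m_ = res.m
        self.ranks_ = res.ranks
        self.raw_p_values_ = res.p_values
        if self.adjust is None:
            self.p_values_ = res.p_values
        elif self.adjust == "fdr_bh":
            from statsmodels.stats.multitest import multipletests

            self.p_values_ = multipletests(res.p_values, method="fdr_bh")[1]
        else:
            raise ValueError(f"unknown adjustment {self.adjust!r}")
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "p_values_")
        return self.p_values_ <= self.alpha
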