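"""Synthetic metabolomics tables, cellwise contamination, and evaluation metrics.

The generator emulates the data structure the log-ratio machinery is built
for: log-normal feature abundances, a per-sample multiplicative size effect
(think urine dilution — every measurement of a sample scales by an unknown
s_i > 0), two sample groups, and a few planted biomarkers whose log
abundance is shifted in the second group. Noise is homoscedastic on the log
scale, i.e. multiplicative — and therefore heteroscedastic — on the raw
abundance scale.

Cellwise contamination replaces a randomly chosen fraction of cells by

    x~ = x * M + A,   M ~ U(0.2, 0.5) or U(2, 10) (fair coin),  A ~ U(2, 5),

the scheme used in the reference simulation studies; contaminated cells
stay positive. Evaluation helpers cover both tasks: ROC/AUC of |w_ij| for
recovering the contamination mask, and TPR/TNR/average-rank of the
permutation test for recovering planted biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .biomarker import BiomarkerResult
from .data_model import GroupedDataMatrix

__all__ = [
    "SyntheticSpec",
    "ContaminationRecord",
    "generate_dataset",
    "contaminate",
    "roc_points",
    "column_zscore_scores",
    "biomarker_metrics",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic two-group abundance table.

    n1, n2 : group sizes (group "g1" is listed first and is the reference
        when n1 >= n2).
    d : number of features.
    n_biomarkers : number of planted discriminating features.
    log_fold_change : shift (natural-log scale) added to the planted
        features in group 2; 1.5 with log_sd 0.5 is a strong but not
        trivial three-sigma effect.
    base_log_mean_range : per-feature baseline log abundances are drawn
        uniformly from this interval; (2, 5) spans abundances ~7-150 so the
        additive part of the contamination scheme is non-negligible for
        low-abundance features.
    log_sd : standard deviation of the log-scale noise.
    size_effect_range : per-sample multiplicative factors s_i are drawn
        log-uniformly from this interval; (0.2, 5) is a strong,
        dilution-like size effect.
    """

    n1: int = 10
    n2: int = 10
    d: int = 100
    n_biomarkers: int = 5
    log_fold_change: float = 1.5
    base_log_mean_range: tuple = (2.0, 5.0)
    log_sd: float = 0.5
    size_effect_range: tuple = (0.2, 5.0)

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("both groups need at least 2 samples")
        if not 0 <= self.n_biomarkers < self.d:
            raise ValueError("require 0 <= n_biomarkers < d")
        lo, hi = self.base_log_mean_range
        if not lo <= hi:
            raise ValueError("invalid base_log_mean_range")
        slo, shi = self.size_effect_range
        if not (0 < slo <= shi):
            raise ValueError("size effects must be positive")
        if self.log_sd < 0:
            raise ValueError("log_sd must be nonnegative")


@dataclass
class ContaminationRecord:
    """Ground truth of one contamination draw."""

    mask: np.ndarray          # n x d bool, True = contaminated cell
    fraction: float           # realized fraction of contaminated cells
    M_values: np.ndarray      # multiplicative effects, one per contaminated cell
    A_values: np.ndarray      # additive effects, one per contaminated cell
    seed: object = None


def generate_dataset(spec: SyntheticSpec = SyntheticSpec(), seed=None):
    """Draw a synthetic grouped table and the planted-biomarker ground truth.

    x_ij = s_i * exp(mu_j + delta_j * 1[i in group 2] + eps_ij) with
    eps ~ N(0, log_sd^2) and delta_j = log_fold_change on the planted set.

    Returns
    -------
    (GroupedDataMatrix, truth) where truth is the sorted array of planted
    biomarker column indices (empty when n_biomarkers == 0).
    """
    rng = np.random.default_rng(seed)
    n = spec.n1 + spec.n2
    mu = rng.uniform(*spec.base_log_mean_range, size=spec.d)
    truth = np.sort(rng.choice(spec.d, size=spec.n_biomarkers, replace=False))
    delta = np.zeros(spec.d)
    delta[truth] = spec.log_fold_change
    in_group2 = np.zeros((n, 1))
    in_group2[spec.n1:] = 1.0
    eps = rng.normal(0.0, spec.log_sd, size=(n, spec.d))
    log_s = rng.uniform(np.log(spec.size_effect_range[0]),
                        np.log(spec.size_effect_range[1]), size=(n, 1))
    X = np.exp(log_s + mu + in_group2 * delta + eps)
    groups = np.array(["g1"] * spec.n1 + ["g2"] * spec.n2)
    gdm = GroupedDataMatrix(values=X, groups=groups)
    return gdm, truth


def contaminate(X: GroupedDataMatrix, fraction_range=(0.05, 0.15), seed=None):
    """Contaminate a random fraction of cells with x*M + A.

    A fraction f ~ U(fraction_range) of the n*d cells is picked uniformly
    without replacement; each picked cell is replaced by x*M + A with
    M drawn from U(0.2, 0.5) or U(2, 10) (equal probability) and
    A ~ U(2, 5). All contaminated values remain positive.

    Returns
    -------
    (contaminated GroupedDataMatrix, ContaminationRecord)
    """
    lo, hi = fraction_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("fraction_range must lie in (0, 1]")
    n, d = X.values.shape
    if n * d == 0:
        raise ValueError("empty matrix")
    rng = np.random.default_rng(seed)
    frac = rng.uniform(lo, hi)
    n_cells = int(round(frac * n * d))
    flat = rng.choice(n * d, size=n_cells, replace=False)
    mask = np.zeros(n * d, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(n, d)
    low_range = rng.random(n_cells) < 0.5
    M = np.where(low_range, rng.uniform(0.2, 0.5, size=n_cells),
                 rng.uniform(2.0, 10.0, size=n_cells))
    A = rng.uniform(2.0, 5.0, size=n_cells)
    values = X.values.copy()
    values[mask] = values[mask] * M + A
    out = GroupedDataMatrix(values=values, groups=X.groups.copy(),
                            sample_ids=X.sample_ids.copy(),
                            feature_ids=X.feature_ids.copy())
    record = ContaminationRecord(mask=mask, fraction=n_cells / (n * d),
                                 M_values=M, A_values=A, seed=seed)
    return out, record


def roc_points(scores, mask):
    """ROC curve of cellwise outlier scores against a truth mask.

    Parameters
    ----------
    scores : n x d array of outlier scores (typically |w_ij|); higher means
        more outlying.
    mask : n x d boolean truth (True = contaminated cell).

    Returns
    -------
    (fpr, tpr, auc_value) — the curve points (TPR nondecreasing) and the
    trapezoidal area under the curve.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(mask).astype(bool).ravel()
    if scores.shape != truth.shape:
        raise ValueError("scores and mask must have identical shapes")
    if truth.all() or not truth.any():
        raise ValueError("mask needs at least one positive and one negative cell")
    fpr, tpr, _ = _sk_roc_curve(truth, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))


def column_zscore_scores(X) -> np.ndarray:
    """Naive baseline: |column z-score| of the raw, unnormalized abundances.

    Ignores the size effect entirely, which is exactly why it fails on
    dilution-affected data; used as the reference point the log-ratio
    scores are compared against.
    """
    V = X.values if isinstance(X, GroupedDataMatrix) else np.asarray(X, float)
    sd = V.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return np.abs((V - V.mean(axis=0)) / sd)


def biomarker_metrics(result: BiomarkerResult, truth, alpha: float = 0.05):
    """TPR, TNR and average rank of the planted biomarkers.

    TPR = fraction of true biomarkers with p <= alpha; TNR = fraction of
    non-biomarkers with p > alpha; the average rank is over the truth set
    (1 = ranked most important).
    """
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("truth set must be nonempty")
    d = len(result.p_values)
    is_true = np.zeros(d, dtype=bool)
    is_true[truth] = True
    rejected = result.p_values <= alpha
    tpr = float(np.mean(rejected[is_true]))
    tnr = float(np.mean(~rejected[~is_true])) if (~is_true).any() else 1.0
    avg_rank = float(np.mean(result.ranks[is_true]))
    return tpr, tnr, avg_rank
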