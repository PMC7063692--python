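"""Grouped abundance tables: container, I/O, validation, reference-group selection.

The central object is :class:`GroupedDataMatrix`, an n-samples x d-features
table of strictly positive abundances with one group label per sample.
Positivity is a hard requirement because every downstream quantity is a
pairwise log ratio ln(x_ij / x_ik).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroupedDataMatrix",
    "read_table",
    "write_table",
    "majority_group",
]


@dataclass
class GroupedDataMatrix:
    """An n x d matrix of strictly positive abundances with sample group labels.

    Parameters
    ----------
    values : ndarray of shape (n, d)
        Strictly positive abundances, samples in rows.
    groups : ndarray of shape (n,)
        One group label per sample; at least two distinct labels are
        required for the methods in this package.
    sample_ids, feature_ids : sequences of str, optional
        Unique row / column labels; defaults are generated.
    """

    values: np.ndarray
    groups: np.ndarray
    sample_ids: np.ndarray = field(default=None)
    feature_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples-by-features matrix")
        n, d = self.values.shape
        self.groups = np.asarray(self.groups)
        if self.groups.shape != (n,):
            raise ValueError(
                f"groups has length {self.groups.shape}, expected ({n},)"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array([f"sample_{i}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids)
        if self.feature_ids is None:
            self.feature_ids = np.array([f"feature_{j}" for j in range(d)])
        else:
            self.feature_ids = np.asarray(self.feature_ids)
        if len(self.sample_ids) != n or len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique and of length n")
        if len(self.feature_ids) != d or len(set(self.feature_ids)) != d:
            raise ValueError("feature_ids must be unique and of length d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no NaN/inf); missing values are rejected")
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValueError(
                f"all abundances must be strictly positive (log ratios are "
                f"undefined otherwise); offending cell: sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def group_labels(self) -> np.ndarray:
        """Distinct group labels in order of first appearance."""
        _, idx = np.unique(self.groups, return_index=True)
        return self.groups[np.sort(idx)]

    @property
    def group_sizes(self) -> dict:
        labels = self.group_labels
        return {g: int(np.sum(self.groups == g)) for g in labels}

    def group_mask(self, label) -> np.ndarray:
        mask = self.groups == label
        if not mask.any():
            raise ValueError(f"group label {label!r} not present")
        return mask

    def to_dataframe(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)
        df.insert(0, group_column, self.groups)
        return df


def majority_group(groups, tie_break: str = "first_label", seed=None):
    """Return the label of the largest group (the reference for standardization).

    Robust centers and scales are computed on the biggest group so that group
    differences survive standardization. Ties between equally large groups are
    resolved either deterministically by order of first appearance
    (``first_label``) or by a seeded random draw (``seeded_random``).
    """
    groups = np.asarray(groups)
    if groups.size == 0:
        raise ValueError("empty group label vector")
    _, first_idx = np.unique(groups, return_index=True)
    labels = groups[np.sort(first_idx)]  # order of first appearance
    if len(labels) < 2:
        raise ValueError("at least 2 distinct group labels are required")
    counts = np.array([np.sum(groups == g) for g in labels])
    winners = labels[counts == counts.max()]
    if len(winners) == 1 or tie_break == "first_label":
        return winners[0]
    if tie_break == "seeded_random":
        rng = np.random.default_rng(seed)
        return winners[rng.integers(len(winners))]
    raise ValueError(f"unknown tie_break {tie_break!r}")


def _apply_positivity_policy(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    if policy == "error":
        return df  # GroupedDataMatrix raises with the offending cell named
    if policy == "replace_half_min":
        # standard metabolomics imputation: half the smallest positive value
        # of the feature column
        out = df.copy()
        for col in out.columns:
            vals = out[col].to_numpy(dtype=float)
            bad = vals <= 0
            if bad.any():
                pos = vals[vals > 0]
                if pos.size == 0:
                    raise ValueError(
                        f"feature {col!r} has no positive value to impute from"
                    )
                vals[bad] = pos.min() / 2.0
                out[col] = vals
        return out
    raise ValueError(f"unknown positivity policy {policy!r}")


def read_table(
    path,
    group_column: str = "group",
    delimiter: str = ",",
    sample_id_column=None,
    positivity_policy: str = "error",
) -> GroupedDataMatrix:
    """Read a delimited abundance table (samples in rows) into a GroupedDataMatrix.

    The file must have a header row of feature names plus one column holding
    the group label of each sample. Row order is preserved.

    Parameters
    ----------
    positivity_policy : {"error", "replace_half_min"}
        How to treat values <= 0: raise (default), or replace by half the
        smallest positive value of that feature column.
    """
    df = pd.read_csv(path, sep=delimiter)
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path}")
    if sample_id_column is not None:
        if sample_id_column not in df.columns:
            raise ValueError(f"sample id column {sample_id_column!r} not found")
        sample_ids = df[sample_id_column].astype(str).to_numpy()
        df = df.drop(columns=[sample_id_column])
    else:
        sample_ids = None
    groups = df[group_column].to_numpy()
    data = df.drop(columns=[group_column])
    coerced = data.apply(pd.to_numeric, errors="coerce")
    if coerced.isna().to_numpy().any() and not data.isna().to_numpy().any():
        bad = coerced.columns[coerced.isna().any()].tolist()
        raise ValueError(f"non-numeric cells in feature columns: {bad}")
    if len(set(groups)) < 2:
        raise ValueError("fewer than 2 distinct groups in the table")
    coerced = _apply_positivity_policy(coerced, positivity_policy)
    return GroupedDataMatrix(
        values=coerced.to_numpy(dtype=float),
        groups=groups,
        sample_ids=sample_ids,
        feature_ids=np.asarray(data.columns.astype(str)),
    )


def write_table(X: GroupedDataMatrix, path, group_column: str = "group",
                delimiter: str = ",") -> None:
    """Write a GroupedDataMatrix back to a delimited file (inverse of read_table)."""
    X.to_dataframe(group_column).to_csv(path, sep=delimiter, index_label="sample_id")
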