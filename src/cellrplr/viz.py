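"""Heatmap diagnostics of the outlyingness matrix.

Red encodes positive outlyingness (nominator dominance, value higher than
expected), blue negative, white zero; color saturation scales with
magnitude. The color scale is fixed symmetrically at [-1, 1] so that panels
from different outlyingness functions or data sets are directly comparable.
Samples are drawn in input order, grouped, with black horizontal separators
between groups.
"""

from __future__ import annotations

import numpy as np

from .cell_rplr import OutlyingnessMatrix

__all__ = ["heatmap", "CMAP_NAME"]

CMAP_NAME = "RdBu_r"  # -1 blue, 0 (near-)white, +1 red


def heatmap(W, group_separators: bool = True, output=None, ax=None,
            max_labels: int = 60):
    """Render the outlyingness matrix as a diverging heatmap.

    Parameters
    ----------
    W : OutlyingnessMatrix or (n, d) array in [-1, 1].
    group_separators : draw black horizontal lines between sample groups
        (requires group information, i.e. an OutlyingnessMatrix).
    output : optional path; written as PNG/SVG/PDF by extension.
    ax : optional matplotlib Axes to draw into.
    max_labels : suppress tick labels beyond this many rows/columns.

    Returns
    -------
    matplotlib Figure (deterministic given inputs).
    """
    import matplotlib

    if output is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(W, OutlyingnessMatrix):
        values = W.values
        row_labels = W.sample_ids
        col_labels = W.feature_ids
        groups = W.groups
    else:
        values = np.asarray(W, dtype=float)
        row_labels = col_labels = groups = None
    n, d = values.shape
    if ax is None:
        fig, ax = plt.subplots(
            figsize=(min(14, 2 + 0.12 * d), min(10, 2 + 0.22 * n)))
    else:
        fig = ax.figure
    mesh = ax.pcolormesh(values, cmap=CMAP_NAME, vmin=-1.0, vmax=1.0)
    ax.invert_yaxis()  # first sample on top
    if groups is not None and group_separators:
        # boundary after each block of equal consecutive labels
        change = np.nonzero(groups[1:] != groups[:-1])[0] + 1
        for b in change:
            ax.axhline(b, color="black", linewidth=1.5)
    if row_labels is not None and n <= max_labels:
        ax.set_yticks(np.arange(n) + 0.5, labels=row_labels, fontsize=6)
    else:
        ax.set_yticks([])
    if col_labels is not None and d <= max_labels:
        ax.set_xticks(np.arange(d) + 0.5, labels=col_labels, fontsize=6,
                      rotation=90)
    else:
        ax.set_xticks([])
    fig.colorbar(mesh, ax=ax, label="outlyingness")
    if output is not None:
        fig.savefig(output, dpi=150)
    return fig
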