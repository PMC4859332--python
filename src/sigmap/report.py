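"""Replicate collapsing and global-scale heatmaps.

Heatmaps here deliberately use one color scale for the entire matrix and no
per-gene centering or variance scaling: rescaling each gene to its own range
misrepresents the relative importance of genes, and hides the case where a
gene varies strongly in one species but not the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import Compendium

GROUP_MODES = ("cell_type", "dataset_cell_type")


@dataclass
class CollapsedMatrix:
    """Genes x groups, each entry the median over the group's replicates (log2)."""

    values: pd.DataFrame
    group_by: str

    @property
    def groups(self) -> list:
        return list(self.values.columns)


def collapse_replicates_median(
    compendium: Compendium, group_by: str = "cell_type"
) -> CollapsedMatrix:
    """Per gene, per group: median across the group's samples.

    Groups are cell types (pooling datasets) or (dataset, cell type) pairs.
    Even replicate counts use the midpoint of the two central values.
    """
    if group_by not in GROUP_MODES:
        raise ValueError(f"group_by must be one of {GROUP_MODES}")
    if group_by == "cell_type":
        keys = compendium.samples["cell_type"]
    else:
        keys = compendium.samples["dataset_id"] + ":" + compendium.samples["cell_type"]
    collapsed = compendium.values.T.groupby(keys.to_numpy()).median().T
    collapsed = collapsed[sorted(collapsed.columns)]
    return CollapsedMatrix(values=collapsed, group_by=group_by)


def heatmap(
    matrix: CollapsedMatrix,
    genes,
    emphasis: dict | None = None,
    cmap: str = "RdBu_r",
    ax=None,
):
    """Global-scale heatmap of the requested genes in the requested order.

    One color scale spans the whole displayed matrix — color is the same
    monotone function of value for every cell, with no per-row stretch.
    Requested genes absent from the matrix are reported in a warning and
    omitted, never silently dropped. ``emphasis`` maps gene -> color for bold
    row labels.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    present = [g for g in genes if g in matrix.values.index]
    missing = [g for g in genes if g not in matrix.values.index]
    if missing:
        warnings.warn(f"genes absent from matrix (omitted): {missing}", stacklevel=2)
    if not present:
        raise ValueError("none of the requested genes are present")
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    data = matrix.values.loc[present]
    if ax is None:
        fig, ax = plt.subplots(
            figsize=(1.5 + 0.4 * data.shape[1], 1.0 + 0.22 * data.shape[0])
        )
    else:
        fig = ax.figure
    vmin = float(data.to_numpy().min())
    vmax = float(data.to_numpy().max())
    if vmin == vmax:  # constant matrix: single-color image
        vmin, vmax = vmin - 0.5, vmax + 0.5
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels(data.index, fontsize=7)
    emphasis = emphasis or {}
    for label in ax.get_yticklabels():
        if label.get_text() in emphasis:
            label.set_fontweight("bold")
            label.set_color(emphasis[label.get_text()])
    fig.colorbar(im, ax=ax, label=f"expression (log2, global scale)")
    fig.tight_layout()
    return fig
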