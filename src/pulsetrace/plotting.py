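"""Basic result plots: enrichment heat maps and ordination scatter."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["enrichment_heatmap", "ordination_plot"]


def enrichment_heatmap(
    budget: pd.DataFrame,
    element: str = "13C",
    value_col: str = "atom_percent_excess",
    ax=None,
):
    """Pools x sampling days heat map of mean enrichment.

    Rows are pools, columns sampling days; cell colour is the mean of
    *value_col* across plots.
    """
    import matplotlib.pyplot as plt

    sub = budget[budget["element"] == element]
    grid = sub.pivot_table(index="pool", columns="day", values=value_col, aggfunc="mean")
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * grid.shape[1] + 2, 0.4 * grid.shape[0] + 1.5))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(grid.shape[1]), [str(d) for d in grid.columns])
    ax.set_yticks(range(grid.shape[0]), list(grid.index))
    ax.set_xlabel("day after labelling")
    ax.figure.colorbar(im, ax=ax, label=value_col)
    return ax


def ordination_plot(coordinates: pd.DataFrame, vectors: pd.DataFrame | None = None, ax=None):
    """PCoA scatter coloured by management, with optional fitted vectors."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for mgmt, sub in coordinates.groupby("management"):
        ax.scatter(sub["axis1"], sub["axis2"], label=mgmt, alpha=0.8)
    if vectors is not None:
        scale = np.nanmax(np.abs(coordinates[["axis1", "axis2"]].to_numpy())) * 0.9
        for row in vectors.itertuples():
            if getattr(row, "retained", True):
                ax.annotate(
                    row.variable,
                    xy=(row.axis1 * scale, row.axis2 * scale),
                    xytext=(0, 0),
                    textcoords="data",
                    arrowprops={"arrowstyle": "<-", "color": "grey"},
                )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("PCoA axis 1")
    ax.set_ylabel("PCoA axis 2")
    ax.legend()
    return ax
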