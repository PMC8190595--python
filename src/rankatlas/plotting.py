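"""Static scatter export of atlas coordinates."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def scatter_coords(
    coords: pd.DataFrame,
    path: str | Path,
    x: str = "PC1",
    y: str = "PC2",
    color_by: str | None = None,
) -> Path:
    """Write a 2D scatter of atlas/projection coordinates to an image file.

    ``coords`` is a table as returned by :func:`rankatlas.atlas.coords_table`
    (PC columns plus optional annotation columns).
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 5))
    if color_by is not None and color_by in coords.columns:
        for label, grp in coords.groupby(coords[color_by].astype(str)):
            ax.scatter(grp[x], grp[y], s=14, label=label, alpha=0.8)
        ax.legend(fontsize=7, frameon=False)
    else:
        ax.scatter(coords[x], coords[y], s=14, alpha=0.8)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
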