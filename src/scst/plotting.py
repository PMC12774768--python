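"""Optional rendering helpers (matplotlib required).

Corn plots are 3D scatters of positional expression values on the
address lattice; single-cell maps scatter placed cells inside their
regions.  Imports are lazy so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["render_corn_plot"]


def render_corn_plot(
    table: pd.DataFrame,
    path: str | Path,
    title: str = "",
    cmap: str = "viridis",
    point_size: float = 60.0,
) -> None:
    """Render a long-format (address, value) corn-plot table (as produced
    by :func:`scst.io.corn_plot_table`) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(
        table["x"], table["y"], table["z"],
        c=table["value"], cmap=cmap, s=point_size, depthshade=False,
    )
    fig.colorbar(sc, ax=ax, shrink=0.6, label="value")
    ax.set_xlabel("x (A − / P +)")
    ax.set_ylabel("y (L − / R +)")
    ax.set_zlabel("z (section)")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
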