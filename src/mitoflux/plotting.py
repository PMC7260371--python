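"""Plate-level visualisation helpers (Agg backend; file output only)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .xf_io import COLUMNS, ROWS, parse_well_id


def plate_heatmap(
    values: dict[str, float],
    path: str | Path,
    title: str = "",
    cmap: str = "viridis",
) -> Path:
    """Render a 96-well heatmap of per-well values to a PNG file."""
    grid = np.full((len(ROWS), len(COLUMNS)), np.nan)
    for well, v in values.items():
        row, col = parse_well_id(well)
        grid[ROWS.index(row), col - 1] = v
    fig, ax = plt.subplots(figsize=(7.5, 5))
    masked = np.ma.masked_invalid(grid)
    im = ax.imshow(masked, cmap=cmap, aspect="auto")
    ax.set_xticks(range(len(COLUMNS)), [str(c) for c in COLUMNS])
    ax.set_yticks(range(len(ROWS)), list(ROWS))
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
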