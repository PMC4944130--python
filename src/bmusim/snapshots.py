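"""Snapshot exports: grid occupancy and fields as CSV, optionally PNG.

CSV formats are plain text for regression testing; PNG rendering needs
matplotlib (the ``plot`` extra) and is imported lazily.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fields import FieldSet
from .lattice import GridState, Phenotype

__all__ = ["grid_to_frame", "save_grid_csv", "save_field_csv",
           "save_grid_png", "save_field_png"]

_COLORS = {
    0: "#f5f5f0", "bone": "#c8b89a",
    int(Phenotype.MSC): "#9467bd", int(Phenotype.POB): "#aec7e8",
    int(Phenotype.AOB): "#1f77b4", int(Phenotype.POC): "#ffbb78",
    int(Phenotype.AOC): "#d62728", int(Phenotype.TRP): "#2ca02c",
    int(Phenotype.TR): "#98df8a", int(Phenotype.TP): "#bcbd22",
    int(Phenotype.TN): "#7f7f7f",
}


def grid_to_frame(grid: GridState) -> pd.DataFrame:
    """Long-form (x, y, phenotype) table of all occupied and bone sites."""
    rows = []
    for x, y in np.argwhere(grid.bone):
        rows.append({"x": int(x), "y": int(y), "phenotype": "BONE"})
    for x, y in np.argwhere(grid.phen > 0):
        rows.append({"x": int(x), "y": int(y),
                     "phenotype": Phenotype(int(grid.phen[x, y])).name})
    return pd.DataFrame(rows, columns=["x", "y", "phenotype"])


def save_grid_csv(grid: GridState, path: str | Path) -> None:
    grid_to_frame(grid).to_csv(path, index=False)


def save_field_csv(fields: FieldSet, name: str, path: str | Path) -> None:
    """One field as a dense CSV matrix (rows = x, columns = y)."""
    np.savetxt(path, getattr(fields, name), delimiter=",")


def save_grid_png(grid: GridState, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    codes = grid.phen.astype(int).copy()
    codes[grid.bone] = 10
    order = [0, *(int(p) for p in Phenotype), 10]
    lut = {c: i for i, c in enumerate(order)}
    img = np.vectorize(lut.get)(codes)
    cmap = ListedColormap(
        [_COLORS[0]] + [_COLORS[int(p)] for p in Phenotype]
        + [_COLORS["bone"]])
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(img.T, origin="lower", cmap=cmap, interpolation="nearest")
    ax.set_xlabel("x (sites)")
    ax.set_ylabel("y (sites)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def save_field_png(fields: FieldSet, name: str, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(getattr(fields, name).T, origin="lower", cmap="viridis",
                   interpolation="nearest")
    fig.colorbar(im, ax=ax, label=name)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
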