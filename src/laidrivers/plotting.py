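"""Rendering of dominance maps and importance curves to image files."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .interpret import CrossingResult, DominanceMap


def plot_dominance_map(dm: DominanceMap, grid_shape: tuple, path) -> None:
    """Render a dominance map as a grid image.

    Blue end = moisture-dominant (mean importance > 0.5), red end =
    temperature-dominant, matching the field's usual convention.
    """
    n_rows, n_cols = grid_shape
    values = np.asarray(dm.mean_sm_importance).reshape(n_rows, n_cols)
    fig, ax = plt.subplots(figsize=(4, 3.2))
    im = ax.imshow(values, cmap="RdBu", vmin=0.0, vmax=1.0)
    for (r, c), v in np.ndenumerate(values):
        ax.text(c, r, f"{v:.2f}", ha="center", va="center", fontsize=7)
    ax.set_title(f"soil-moisture importance ({dm.period})")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance_curves(table: pd.DataFrame, x_col: str, path,
                           crossing: float | None = None) -> None:
    """Render binned soil-moisture/temperature importance curves."""
    fig, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(table[x_col], table["sm_importance"], "x-", label="soil moisture")
    ax.plot(table[x_col], table["temp_importance"], "o--", mfc="none",
            label="temperature")
    ax.axhline(0.5, color="grey", lw=0.8)
    if crossing is not None:
        ax.axvline(crossing, color="grey", lw=0.8, ls=":")
    ax.set_xlabel(x_col)
    ax.set_ylabel("importance")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
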