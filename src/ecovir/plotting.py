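"""Figure rendering: PIP rasters and sweep panels.

Headless-safe (Agg backend is selected if no display is configured); every
function returns the matplotlib objects so callers can restyle or save.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .adaptive import PipGrid

__all__ = ["plot_pip", "plot_sweep"]


def plot_pip(pip: PipGrid, ax: Optional[plt.Axes] = None, title: str = ""):
    """Black/white PIP raster: black where the mutant invades the resident."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    # rows of sign_matrix are residents; plot resident on x, mutant on y
    invadable = (pip.sign_matrix.T > 0).astype(float)
    extent = (
        pip.trait_axis[0],
        pip.trait_axis[-1],
        pip.trait_axis[0],
        pip.trait_axis[-1],
    )
    ax.imshow(
        invadable,
        origin="lower",
        extent=extent,
        cmap="gray_r",
        aspect="auto",
        interpolation="nearest",
    )
    for star in pip.singular_points:
        ax.plot(star, star, "o", mfc="white", mec="red", ms=6)
    ax.set_xlabel("resident trait")
    ax.set_ylabel("mutant trait")
    if title:
        ax.set_title(title)
    return ax


def plot_sweep(
    df: pd.DataFrame,
    value: str = "relative_es_virulence",
    x: str = "r12",
    title: str = "",
):
    """One panel per specialism case, one curve per strength, ``value`` vs ``x``."""
    cases = sorted(df["case_id"].unique())
    fig, axes = plt.subplots(1, len(cases), figsize=(3.2 * len(cases), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, case in zip(axes, cases):
        sub = df[df["case_id"] == case]
        for strength, grp in sub.groupby("strength"):
            grp = grp.sort_values(x)
            ax.plot(grp[x], grp[value], marker="o", ms=3, label=f"s={strength:g}")
        ax.set_title(case)
        ax.set_xlabel(x)
    axes[0].set_ylabel(value)
    axes[-1].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig, axes
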