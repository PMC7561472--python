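"""Figures: joint scatter of N/C YAP vs exposed proportion with marginal
densities, per group (e.g. control vs confined cohorts)."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


def joint_marginal_plot(
    records: pd.DataFrame,
    x: str = "prop_exposed",
    y: str = "nc_yap",
    hue: Optional[str] = None,
    path: Optional[str] = None,
    threshold: Optional[float] = None,
):
    """Scatter of y vs x with marginal kernel-density estimates.

    When ``hue`` names a column, each group gets its own colour and marginal
    density. ``threshold`` draws a dashed horizontal cut on y (the high/low
    N/C YAP threshold). Returns the matplotlib figure; saves to ``path``
    (SVG/PNG by suffix) when given.
    """
    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          wspace=0.05, hspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)
    for a in (ax_top, ax_right):
        a.axis("off")

    groups = [(None, records)] if hue is None else list(records.groupby(hue))
    colors = plt.cm.tab10.colors
    for i, (name, df) in enumerate(groups):
        xs = df[x].to_numpy(dtype=float)
        ys = df[y].to_numpy(dtype=float)
        ok = np.isfinite(xs) & np.isfinite(ys)
        xs, ys = xs[ok], ys[ok]
        c = colors[i % len(colors)]
        ax.scatter(xs, ys, s=14, alpha=0.7, color=c, label=str(name) if name else None)
        for vals, axis, vertical in ((xs, ax_top, False), (ys, ax_right, True)):
            if len(vals) > 2 and np.ptp(vals) > 0:
                kde = stats.gaussian_kde(vals)
                grid = np.linspace(vals.min(), vals.max(), 200)
                dens = kde(grid)
                if vertical:
                    axis.plot(dens, grid, color=c)
                else:
                    axis.plot(grid, dens, color=c)
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="k", lw=1)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    if hue is not None:
        ax.legend(frameon=False, fontsize=8)
    if path is not None:
        fig.savefig(Path(path), bbox_inches="tight", dpi=150)
        plt.close(fig)
    return fig
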