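"""Plot helpers for accuracy results (requires matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_group_lines(group_lines: pd.DataFrame, distance_range=(-20.0, 120.0), ax=None):
    """Regression lines of sqrt(TRE) against centered target distance per group.

    ``group_lines`` is the DataFrame from
    :meth:`~splintnav.analysis.SqrtTreResults.group_lines` or
    :func:`~splintnav.analysis.derive_group_lines`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    d = np.linspace(*distance_range, 100)
    for _, row in group_lines.iterrows():
        ax.plot(d, row["intercept"] + row["slope"] * d,
                label=f"{row['technique']} / {row['method']}")
    ax.set_xlabel("centered target distance (mm)")
    ax.set_ylabel(r"$\sqrt{TRE}$ ($\sqrt{mm}$)")
    ax.legend(fontsize=8)
    return ax


def plot_distributions(summary: dict, ax_grid=None):
    """Histogram + KDE panels per group from :func:`distribution_summary`."""
    import matplotlib.pyplot as plt

    groups = list(summary)
    if ax_grid is None:
        _, ax_grid = plt.subplots(1, len(groups), figsize=(4 * len(groups), 3),
                                  squeeze=False)
        ax_grid = ax_grid[0]
    for ax, key in zip(ax_grid, groups):
        entry = summary[key]
        widths = np.diff(entry["bin_edges"])
        density = entry["counts"] / max(entry["counts"].sum(), 1) / widths
        ax.bar(entry["bin_edges"][:-1], density, width=widths, align="edge", alpha=0.5)
        if "kde_grid" in entry and np.all(np.isfinite(entry["kde_density"])):
            ax.plot(entry["kde_grid"], entry["kde_density"])
        ax.set_title(f"{key[0]} / {key[1]}", fontsize=9)
    return ax_grid
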