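"""Optional matplotlib output: genotype tile grids and variant kymographs."""

from __future__ import annotations

from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")  # file output only; no interactive backend needed
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import ListedColormap

from .core import Trajectory
from .variant import PHASE_ORDER, PHASE_RANK, CellRow, phase_of_cell


def plot_trajectory_grid(trajectories: Mapping[str, Trajectory], path) -> None:
    """One panel per genotype: factor rows x region columns, shaded by level
    over the four timepoints (light = weak, dark = strong)."""
    names = list(trajectories)
    ncols = 3
    nrows = int(np.ceil(len(names) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False
    )
    for ax in axes.flat:
        ax.set_visible(False)
    for k, name in enumerate(names):
        traj = trajectories[name]
        ax = axes[k // ncols][k % ncols]
        ax.set_visible(True)
        factors = traj.factors
        # rows: factor x timepoint stacked; columns: regions
        img = np.zeros((len(factors) * traj.n_timepoints, traj.n_regions))
        for i, f in enumerate(factors):
            mx = traj.factor_defs[i].max_level
            for t in range(traj.n_timepoints):
                for r in range(traj.n_regions):
                    img[i * traj.n_timepoints + t, r] = traj.levels[r, t, i] / mx
        ax.imshow(img, cmap="Blues", vmin=0, vmax=1, aspect="auto")
        ax.set_title(traj.genotype.label)
        ax.set_yticks(
            [i * traj.n_timepoints + traj.n_timepoints / 2 - 0.5 for i in range(len(factors))],
            factors,
            fontsize=7,
        )
        ax.set_xticks(range(traj.n_regions), [f"r{r+1}" for r in range(traj.n_regions)])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_kymograph(rows: Iterable[CellRow], path) -> None:
    """Cell (x) by step (y) image coloured by phase."""
    rows = list(rows)
    n_cells = max(r.n_cells for r in rows)
    img = np.full((len(rows), n_cells), np.nan)
    for t, row in enumerate(rows):
        for i in range(row.n_cells):
            img[t, i] = PHASE_RANK[phase_of_cell(row, i)]
    cmap = ListedColormap(
        ["#f0f0f0", "#1b9e77", "#66a61e", "#7570b3", "#d95f02", "#e7298a"]
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(img, cmap=cmap, vmin=-0.5, vmax=len(PHASE_ORDER) - 0.5, aspect="auto")
    cbar = fig.colorbar(im, ax=ax, ticks=range(len(PHASE_ORDER)))
    cbar.ax.set_yticklabels(PHASE_ORDER)
    ax.set_xlabel("cell (anterior -> posterior)")
    ax.set_ylabel("step")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
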