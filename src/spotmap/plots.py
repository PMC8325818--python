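"""Figure rendering for the toolbox outputs.

All functions return a matplotlib Figure and never call ``show``; the CLI
saves them to files.  Density maps use a grayscale colormap, colocalization
heat maps a diverging palette (red = enriched, blue = depleted), and
spatial cluster / class maps share color keys with their companion heat
maps and bar charts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .coloc import ColocResult  # noqa: E402
from .density import DensityMap  # noqa: E402
from .gradients import AxisProjection, GradientField  # noqa: E402


def plot_counts(counts: pd.DataFrame, frequencies: pd.DataFrame):
    fig, axes = plt.subplots(1, 2, figsize=(12, 4))
    counts.T.plot.bar(ax=axes[0], legend=len(counts) <= 10)
    axes[0].set_ylabel("reads")
    im = axes[1].imshow(frequencies.to_numpy(), aspect="auto", cmap="viridis")
    axes[1].set_xticks(range(frequencies.shape[1]))
    axes[1].set_xticklabels(frequencies.columns, rotation=90, fontsize=6)
    axes[1].set_yticks(range(frequencies.shape[0]))
    axes[1].set_yticklabels(frequencies.index, fontsize=6)
    fig.colorbar(im, ax=axes[1], label="frequency")
    fig.tight_layout()
    return fig


def plot_density(dm: DensityMap):
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(
        dm.values, cmap="gray", origin="upper",
        extent=[dm.x_grid[0], dm.x_grid[-1], dm.y_grid[-1], dm.y_grid[0]],
    )
    ax.set_title(f"{dm.gene} (bw={dm.bandwidth:.1f} px)")
    fig.colorbar(im, ax=ax, label="density / px²")
    return fig


def plot_overlay(rgb2: np.ndarray, genes: tuple[str, str]):
    img = np.zeros(rgb2.shape[:2] + (3,))
    img[..., 0] = rgb2[..., 0]
    img[..., 1] = rgb2[..., 1]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img, origin="upper")
    ax.set_title(f"red={genes[0]}, green={genes[1]}")
    return fig


def plot_coloc(result: ColocResult):
    z = result.z.to_numpy()
    lim = np.nanmax(np.abs(z)) or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(z, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(result.genes)))
    ax.set_xticklabels(result.genes, rotation=90, fontsize=6)
    ax.set_yticks(range(len(result.genes)))
    ax.set_yticklabels(result.genes, fontsize=6)
    fig.colorbar(im, ax=ax, label="Z")
    fig.tight_layout()
    return fig


def plot_gradient_field(gf: GradientField):
    fig, ax = plt.subplots(figsize=(6, 6))
    xx, yy = np.meshgrid(gf.lattice_x, gf.lattice_y)
    ax.quiver(xx, yy, gf.g_x, gf.g_y, np.hypot(gf.g_x, gf.g_y), cmap="viridis")
    ax.invert_yaxis()
    ax.set_title("gradient field" + (" (signed)" if gf.signed else " (magnitudes)"))
    return fig


def plot_projection(proj: AxisProjection):
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(proj.spots.x, proj.spots.y, c=proj.distances, s=2, cmap="viridis")
    ax.plot(proj.origin[:, 0], proj.origin[:, 1], "r.", ms=2)
    ax.invert_yaxis()
    fig.colorbar(sc, ax=ax, label="distance to origin (px)")
    return fig


def plot_profiles(profiles: dict[str, tuple[np.ndarray, np.ndarray]], per_panel: int = 9):
    genes = list(profiles)
    n_panels = max(1, int(np.ceil(len(genes) / per_panel)))
    fig, axes = plt.subplots(n_panels, 1, figsize=(7, 3 * n_panels), squeeze=False)
    for p in range(n_panels):
        ax = axes[p, 0]
        for g in genes[p * per_panel:(p + 1) * per_panel]:
            grid, dens = profiles[g]
            ax.plot(grid, dens, label=g)
        ax.legend(fontsize=6)
        ax.set_xlabel("distance along gradient (px)")
        ax.set_ylabel("density")
    fig.tight_layout()
    return fig


def plot_rgb_map(centroids: np.ndarray, rgb: np.ndarray, size: float = 8.0):
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(centroids[:, 0], centroids[:, 1], c=np.clip(rgb, 0, 1), s=size)
    ax.invert_yaxis()
    ax.set_title("RGB embedding map")
    return fig


def plot_cluster_map(centroids: np.ndarray, labels: np.ndarray, size: float = 8.0):
    fig, ax = plt.subplots(figsize=(6, 6))
    uniq = np.unique(labels)
    cmap = plt.get_cmap("tab20")
    for i, lab in enumerate(uniq):
        m = labels == lab
        ax.scatter(centroids[m, 0], centroids[m, 1], s=size,
                   color=cmap(i % 20), label=str(lab))
    ax.invert_yaxis()
    if len(uniq) <= 20:
        ax.legend(fontsize=6, markerscale=2)
    return fig


def plot_cluster_means(means: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(means.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(means.shape[1]))
    ax.set_xticklabels(means.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(means.shape[0]))
    ax.set_yticklabels(means.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="mean expression")
    fig.tight_layout()
    return fig


def plot_composition(freq: pd.DataFrame):
    fig, ax = plt.subplots(figsize=(8, 4))
    freq.plot.bar(stacked=True, ax=ax, colormap="tab20", legend=True)
    ax.legend(fontsize=6, bbox_to_anchor=(1.02, 1))
    ax.set_ylabel("class frequency")
    fig.tight_layout()
    return fig
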