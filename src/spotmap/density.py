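"""2D kernel-density expression maps per gene and two-gene overlays.

Each map is a true probability density (integrates to 1 over the plane);
any per-map rescaling for display happens only at render time, so maps of
different genes remain directly comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SpotTable

__all__ = ["DensityMap", "gene_density", "overlay_densities", "silverman_bandwidth",
           "evaluate_kde"]


def silverman_bandwidth(xy: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth (pixels) for a 2D point set.

    Uses the mean of the per-axis standard deviations and h = sigma * n^(-1/6)
    (the d=2 case of the multivariate rule).
    """
    n = len(xy)
    if n < 2:
        return 1.0
    sigma = float(np.mean(np.std(xy, axis=0, ddof=1)))
    return max(sigma * n ** (-1.0 / 6.0), 1e-6)


def evaluate_kde(points: np.ndarray, at: np.ndarray, bandwidth: float) -> np.ndarray:
    """Isotropic Gaussian KDE of ``points`` evaluated at ``at`` (both (m, 2)).

    Defined everywhere in the plane (never clipped to a grid).
    """
    from sklearn.neighbors import KernelDensity

    kde = KernelDensity(kernel="gaussian", bandwidth=float(bandwidth))
    kde.fit(np.asarray(points, float))
    return np.exp(kde.score_samples(np.asarray(at, float)))


@dataclass
class DensityMap:
    """Per-gene KDE on a regular grid.

    ``values[i, j]`` is the density (per pixel²) at ``(x_grid[j], y_grid[i])``;
    the grid covers the reads' bounding box plus three bandwidths of margin.
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    values: np.ndarray  # shape (len(y_grid), len(x_grid))
    gene: str
    bandwidth: float
    grid_step: float

    def integrate(self) -> float:
        """Grid-rule integral of the map (≈ 1 for a well-resolved map)."""
        return float(self.values.sum() * self.grid_step**2)


def gene_density(
    spots: SpotTable,
    gene: str,
    *,
    bandwidth: float | None = None,
    grid_step: float | None = None,
) -> DensityMap:
    """Gaussian KDE of a gene's read positions on a regular grid.

    bandwidth defaults to Silverman's rule on that gene's reads and is
    always recorded in the output; grid_step defaults to bandwidth / 2.
    """
    sub = spots.subset_gene(gene)
    pts = sub.xy
    if len(pts) == 1:
        warnings.warn(f"gene {gene!r} has a single read: map is one Gaussian bump")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(pts)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid_step is None:
        grid_step = bandwidth / 2.0
    margin = 3.0 * bandwidth
    x0, x1 = pts[:, 0].min() - margin, pts[:, 0].max() + margin
    y0, y1 = pts[:, 1].min() - margin, pts[:, 1].max() + margin
    xg = np.arange(x0, x1 + grid_step, grid_step)
    yg = np.arange(y0, y1 + grid_step, grid_step)
    xx, yy = np.meshgrid(xg, yg)
    at = np.column_stack([xx.ravel(), yy.ravel()])
    vals = evaluate_kde(pts, at, bandwidth).reshape(len(yg), len(xg))
    return DensityMap(
        x_grid=xg, y_grid=yg, values=vals, gene=gene,
        bandwidth=float(bandwidth), grid_step=float(grid_step),
    )


def _resample(src: DensityMap, xg: np.ndarray, yg: np.ndarray,
              spots_xy: np.ndarray | None = None) -> np.ndarray:
    """Bilinear resample of a map onto another grid (KDE re-evaluation is
    exact but this keeps overlays cheap; out-of-grid points get 0)."""
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (src.y_grid, src.x_grid), src.values, bounds_error=False, fill_value=0.0
    )
    xx, yy = np.meshgrid(xg, yg)
    return interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(len(yg), len(xg))


def overlay_densities(a: DensityMap, b: DensityMap) -> np.ndarray:
    """Two-channel composite of two density maps.

    Each channel is independently rescaled to [0, 1] by its own maximum;
    returns an array of shape (ny, nx, 2) on ``a``'s grid (``b`` is
    resampled when the grids differ; a warning is emitted when the
    bounding boxes are disjoint and the union grid is used).
    """
    same_grid = (
        len(a.x_grid) == len(b.x_grid)
        and len(a.y_grid) == len(b.y_grid)
        and np.allclose(a.x_grid, b.x_grid)
        and np.allclose(a.y_grid, b.y_grid)
    )
    if same_grid:
        xg, yg = a.x_grid, a.y_grid
        va, vb = a.values, b.values
    else:
        disjoint = (
            a.x_grid[-1] < b.x_grid[0] or b.x_grid[-1] < a.x_grid[0]
            or a.y_grid[-1] < b.y_grid[0] or b.y_grid[-1] < a.y_grid[0]
        )
        if disjoint:
            warnings.warn("density maps have disjoint bounding boxes; using union grid")
        step = min(a.grid_step, b.grid_step)
        x0 = min(a.x_grid[0], b.x_grid[0])
        x1 = max(a.x_grid[-1], b.x_grid[-1])
        y0 = min(a.y_grid[0], b.y_grid[0])
        y1 = max(a.y_grid[-1], b.y_grid[-1])
        xg = np.arange(x0, x1 + step, step)
        yg = np.arange(y0, y1 + step, step)
        va = _resample(a, xg, yg)
        vb = _resample(b, xg, yg)
    out = np.zeros(va.shape + (2,))
    for i, v in enumerate((va, vb)):
        m = v.max()
        out[..., i] = v / m if m > 0 else v
    return out
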