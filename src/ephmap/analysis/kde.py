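"""Kernel-density contour analysis.

An isotropic Gaussian KDE is evaluated on a 100 x 100 grid over the
structure; the bandwidth maximises the leave-one-out cross-validated
log-likelihood.  The P% contour encloses the top P% of the total
labelling mass; the readout is the enclosed area as a percentage of the
structure's area.  The same machinery measures what fraction of the SC
is covered by a given share of total synaptic weight.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist, pdist

BANDWIDTH_FLOOR = 1e-3
BANDWIDTH_CEIL = 0.5
GRID_N = 100


def cv_bandwidth(points: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Bandwidth maximising the leave-one-out log-likelihood.

    Coincident (or near-coincident) point sets have no interior optimum;
    the bandwidth floor is applied and a warning issued.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < 3:
        raise ValueError("at least 3 points are required")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()

    d2 = cdist(points, points, "sqeuclidean")
    if np.max(pdist(points)) < 10 * BANDWIDTH_FLOOR:
        warnings.warn("degenerate (near-coincident) points: bandwidth floor applied")
        return BANDWIDTH_FLOOR
    np.fill_diagonal(d2, np.inf)  # exclude each point from its own estimate

    def neg_loglik(log_k: float) -> float:
        k = 10.0**log_k
        kern = np.exp(-d2 / (2.0 * k * k))
        dens = (kern @ weights) / ((wsum - weights) * 2.0 * np.pi * k * k)
        dens = np.maximum(dens, 1e-300)
        return -float(np.sum(weights * np.log(dens)))

    res = minimize_scalar(
        neg_loglik,
        bounds=(np.log10(BANDWIDTH_FLOOR), np.log10(BANDWIDTH_CEIL)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(10.0**res.x)


def _grid_density(points, weights, k, outline, n_grid=GRID_N):
    """KDE evaluated at cell centres of a grid over the outline's bbox."""
    x0, y0, x1, y1 = outline.bbox
    xs = np.linspace(x0, x1, n_grid + 1)
    ys = np.linspace(y0, y1, n_grid + 1)
    cx = 0.5 * (xs[:-1] + xs[1:])
    cy = 0.5 * (ys[:-1] + ys[1:])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    inside = outline.contains(grid)
    d2 = cdist(grid, points, "sqeuclidean")
    dens = (np.exp(-d2 / (2.0 * k * k)) @ weights) / (
        weights.sum() * 2.0 * np.pi * k * k
    )
    cell_area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return dens, inside, cell_area


def _contour_area_pct(points, weights, k, percentile, outline, n_grid=GRID_N) -> float:
    dens, inside, cell_area = _grid_density(points, weights, k, outline, n_grid)
    dens = dens[inside]
    mass = dens * cell_area
    total = mass.sum()
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(mass[order])
    n_cells = int(np.searchsorted(cum, (percentile / 100.0) * total) + 1)
    n_cells = min(n_cells, dens.size)
    return 100.0 * n_cells / dens.size


def kde_contour(
    points: np.ndarray,
    percentile: float,
    outline=None,
    weights: np.ndarray | None = None,
    n_grid: int = GRID_N,
) -> tuple[float, float]:
    """CV bandwidth and % of retinal area inside the top-``percentile`` contour."""
    from ephmap.substrate import Circle

    if outline is None:
        outline = Circle()
    points = np.asarray(points, dtype=float)
    if weights is None:
        weights = np.ones(points.shape[0])
    k = cv_bandwidth(points, weights)
    area = _contour_area_pct(points, weights, k, percentile, outline, n_grid)
    return k, area


def sc_coverage(W: np.ndarray, substrate, mass: float = 0.99, n_grid: int = GRID_N) -> float:
    """% of SC area inside the contour holding ``mass`` of synaptic weight.

    Synapse locations are the SC neuron positions, weighted by the total
    afferent weight each neuron receives.
    """
    W = np.asarray(W, dtype=float)
    if not np.any(W > 0):
        raise ValueError("weight matrix has no positive entries")
    w_sc = W.sum(axis=0)
    keep = w_sc > 0
    pts = substrate.sc[keep]
    wts = w_sc[keep]
    if pts.shape[0] < 3:  # degenerate: all weight on 1-2 neurons
        k = BANDWIDTH_FLOOR
    else:
        k = cv_bandwidth(pts, wts)
    return _contour_area_pct(pts, wts, k, 100.0 * mass, substrate.sc_outline, n_grid)
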