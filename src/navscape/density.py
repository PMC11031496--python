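"""Trajectory density maps, hexagonal tessellation, and local Getis-Ord Gi*.

Heat maps are built by binning path crossings over the arena bounding box,
smoothing with a Gaussian kernel, normalizing and (optionally) log
transforming.  Because rectangular heat maps are subject to binning
artefacts, group differences are additionally quantified on a hexagonal
tessellation of the disc via the local Getis-Ord Gi* statistic — a z-score
of the concentration of path crossings among each tile's k nearest
neighboring centroids, the tile itself included.  Positive Gi* marks local
clustering of high values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .records import Trajectory

__all__ = ["DensityMap", "HexGrid", "GiStarMap", "build_density",
           "difference_map", "hex_tessellate", "gi_star", "hex_crossings",
           "DegenerateFieldError"]


class DegenerateFieldError(ValueError):
    """Raised when Gi* is requested on a spatially constant field."""


@dataclass(frozen=True)
class DensityMap:
    """Smoothed, normalized path-crossing intensity on a rectangular grid."""

    intensity: np.ndarray        # (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    smoothing_sd: float          # kernel SD in bins
    transform: str               # 'raw' | 'log' | 'difference'
    normalize: str               # 'max' | 'sum' | 'none'

    def same_grid(self, other: "DensityMap") -> bool:
        return (self.intensity.shape == other.intensity.shape
                and np.allclose(self.x_edges, other.x_edges)
                and np.allclose(self.y_edges, other.y_edges))


def build_density(trajs, *, radius: float, bins: int = 101,
                  smoothing_sd: float = 5.0, transform: str = "log",
                  normalize: str = "max") -> DensityMap:
    """Heat map of path crossings for one or more trajectories.

    Pipeline: per-bin sample counts → Gaussian smoothing (``smoothing_sd``
    in bin units) → normalization (peak to 1 by default) → optional log1p
    intensity transform.  Deterministic in its inputs.
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    if transform not in ("raw", "log"):
        raise ValueError(f"unknown transform {transform!r}")
    if normalize not in ("max", "sum", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    edges = np.linspace(-radius, radius, bins + 1)
    counts = np.zeros((bins, bins))
    for tr in trajs:
        h, _, _ = np.histogram2d(tr.y, tr.x, bins=(edges, edges))
        counts += h
    sm = gaussian_filter(counts, sigma=smoothing_sd) if smoothing_sd > 0 else counts
    if normalize == "max" and sm.max() > 0:
        sm = sm / sm.max()
    elif normalize == "sum" and sm.sum() > 0:
        sm = sm / sm.sum()
    if transform == "log":
        sm = np.log1p(sm)
    return DensityMap(sm, edges.copy(), edges.copy(), smoothing_sd, transform, normalize)


def difference_map(a: DensityMap, b: DensityMap) -> DensityMap:
    """Signed elementwise difference a − b of two maps on the same grid."""
    if not a.same_grid(b):
        raise ValueError("density maps are on different grids")
    if a.transform != b.transform:
        raise ValueError("density maps use different intensity transforms")
    return DensityMap(a.intensity - b.intensity, a.x_edges, a.y_edges,
                      a.smoothing_sd, "difference", a.normalize)


# ------------------------------------------------------------ hex layer

@dataclass(frozen=True)
class HexGrid:
    """Hexagonal tessellation of the arena disc with KNN neighbor weights.

    ``cell_size`` is the hexagon circumradius; centroids form a flat-top
    axial lattice (neighbor spacing ``sqrt(3) * cell_size``) clipped to
    centroids inside the disc.  Each tile's neighborhood is its own centroid
    plus its ``k_neighbors`` nearest centroids.
    """

    centroids: np.ndarray          # (n, 2)
    cell_size: float
    k_neighbors: int
    radius: float
    neighbor_idx: np.ndarray = field(repr=False, default=None)  # (n, k+1), col 0 = self

    @property
    def n(self) -> int:
        return len(self.centroids)

    def weights(self, row_standardize: bool = False) -> np.ndarray:
        """Dense spatial weight matrix W with self-inclusion (w_ii = 1)."""
        w = np.zeros((self.n, self.n))
        rows = np.repeat(np.arange(self.n), self.neighbor_idx.shape[1])
        w[rows, self.neighbor_idx.ravel()] = 1.0
        if row_standardize:
            w /= w.sum(axis=1, keepdims=True)
        return w

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Index of the nearest tile centroid for each 2-D point."""
        tree = cKDTree(self.centroids)
        return tree.query(np.asarray(points, dtype=float))[1]


def hex_tessellate(radius: float, cell_size: float, k_neighbors: int = 6) -> HexGrid:
    """Flat-top hexagonal lattice clipped to the disc, with KNN weights.

    Hexagons tessellate a circular arena with minimal edge distortion; the
    default ``k_neighbors = 6`` is the hexagonal coordination number, so
    interior tiles are weighted by exactly their touching neighbors.
    """
    if not 0 < cell_size <= radius:
        raise ValueError("cell_size must be in (0, radius]")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    s = cell_size
    qmax = int(radius / (1.5 * s)) + 2
    rmax = int(radius / (math.sqrt(3) * s)) + 2
    pts = []
    for q in range(-qmax, qmax + 1):
        for r in range(-rmax, rmax + 1):
            x = 1.5 * s * q
            y = math.sqrt(3) * s * (r + q / 2.0)
            if x * x + y * y <= radius * radius:
                pts.append((x, y))
    centroids = np.array(sorted(pts))
    n = len(centroids)
    if n < k_neighbors + 2:
        raise ValueError(
            f"grid of {n} tiles too small for k={k_neighbors} neighbors; "
            "decrease cell_size or k")
    tree = cKDTree(centroids)
    _, idx = tree.query(centroids, k=k_neighbors + 1)
    return HexGrid(centroids, cell_size, k_neighbors, radius, idx)


def hex_crossings(grid: HexGrid, trajs, *, normalize: bool = True) -> np.ndarray:
    """Per-tile path-crossing counts for one or more trajectories.

    With ``normalize=True`` counts are scaled to fractions of all samples,
    making cohorts of different sizes comparable before differencing.
    """
    trajs = [trajs] if isinstance(trajs, Trajectory) else list(trajs)
    x = np.zeros(grid.n)
    for tr in trajs:
        np.add.at(x, grid.assign(tr.xy), 1.0)
    if normalize and x.sum() > 0:
        x = x / x.sum()
    return x


# -------------------------------------------------------------- Gi* map

@dataclass(frozen=True)
class GiStarMap:
    """Per-tile local Getis-Ord Gi* z-scores over a hex grid."""

    grid: HexGrid
    x: np.ndarray            # per-tile value the statistic was computed on
    z: np.ndarray
    p: np.ndarray            # two-sided normal p per tile
    p_threshold: float

    @property
    def mask(self) -> np.ndarray:
        """Tiles flagged at the configured threshold (descriptive, uncorrected)."""
        return self.p < self.p_threshold


def gi_star(values: np.ndarray, grid: HexGrid, *, row_standardize: bool = False,
            p_threshold: float = 0.10) -> GiStarMap:
    """Local Getis-Ord Gi* z-score per tile, self-inclusive.

    For tile i with weights w_ij (its own centroid plus k nearest
    neighbors)::

        z_i = (Σ_j w_ij x_j − X̄ Σ_j w_ij)
              / (S sqrt[(n Σ_j w_ij² − (Σ_j w_ij)²) / (n − 1)])

    with X̄ and S the global mean and (population) SD of x.  Positive z
    marks local clustering of high values.  A spatially constant field has
    both numerator and denominator zero and raises ``DegenerateFieldError``.
    """
    x = np.asarray(values, dtype=float)
    n = grid.n
    if len(x) != n:
        raise ValueError("one value per tile required")
    if n < 3:
        raise ValueError("need at least 3 tiles")
    xbar = x.mean()
    s_sd = x.std(ddof=0)
    if s_sd == 0.0:
        raise DegenerateFieldError("constant field: Gi* is 0/0 on every tile")
    w = grid.weights(row_standardize=row_standardize)
    wi = w.sum(axis=1)
    s1 = (w ** 2).sum(axis=1)
    denom_inner = (n * s1 - wi ** 2) / (n - 1)
    if np.any(denom_inner <= 0):
        raise ValueError("degenerate weights: a neighborhood spans the whole grid")
    z = (w @ x - xbar * wi) / (s_sd * np.sqrt(denom_inner))
    p = 2.0 * sps.norm.sf(np.abs(z))
    return GiStarMap(grid, x, z, p, p_threshold)
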