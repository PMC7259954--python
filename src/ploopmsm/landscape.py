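"""PCA conformational space and the weighted free-energy surface.

The 36-dimensional loop-distance vectors of the MSM microstates are reduced
by plain PCA (mean-centered, full SVD, no whitening); the conformational
free-energy surface is a weighted 2-D histogram in the PC1/PC3 plane (50
bins per axis spanning the data range, weights = microstate equilibrium
probabilities) converted to free energies F = -ln p in kT, smoothed with a
Gaussian of variance 0.3 grid cells, and summarized by six evenly spaced
level-set boundaries.  External (e.g. crystal) conformations are projected
into the same PCA space so simulation and experiment share one map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.decomposition import PCA


@dataclass
class PcaModel:
    """Mean vector, orthonormal component rows, explained-variance fractions."""

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(vectors: np.ndarray) -> PcaModel:
    """Full-SVD PCA without whitening or variance scaling.

    Component signs are fixed deterministically (the largest-magnitude
    loading of each component is made positive) so projections are
    reproducible across runs and platforms.
    """
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 vectors")
    pca = PCA(whiten=False, svd_solver="full")
    pca.fit(X)
    components = pca.components_.copy()
    for i, row in enumerate(components):
        if row[np.argmax(np.abs(row))] < 0:
            components[i] = -row
    return PcaModel(mean=pca.mean_, components=components,
                    explained_variance_ratio=pca.explained_variance_ratio_)


def project(vectors: np.ndarray, model: PcaModel, dims: tuple = (1, 3)) -> np.ndarray:
    """Project vectors onto selected principal components (1-based indices;
    the default (1, 3) is the PC1/PC3 plane used for the P-loop map)."""
    X = np.atleast_2d(np.asarray(vectors, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"vectors have dimension {X.shape[1]}, model expects {model.mean.shape[0]}")
    sel = [d - 1 for d in dims]
    if max(sel) >= model.n_components:
        raise ValueError(f"requested PC {max(dims)} but model has {model.n_components}")
    return (X - model.mean) @ model.components[sel].T


@dataclass
class FreeEnergySurface:
    """2-D free-energy grid in kT with bin edges and level-set boundaries."""

    grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    smoothing_variance: float
    levels: np.ndarray
    smooth_space: str

    def minima_count(self, connectivity_threshold: float = 0.0) -> int:
        """Number of local minima (4-neighborhood, strictly lower than all
        finite neighbors by more than ``connectivity_threshold``)."""
        F = self.grid
        count = 0
        for i in range(F.shape[0]):
            for j in range(F.shape[1]):
                if not np.isfinite(F[i, j]):
                    continue
                neigh = []
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    a, b = i + di, j + dj
                    if 0 <= a < F.shape[0] and 0 <= b < F.shape[1] and np.isfinite(F[a, b]):
                        neigh.append(F[a, b])
                if neigh and all(F[i, j] < v - connectivity_threshold for v in neigh):
                    count += 1
        return count


def bin_of(surface: "FreeEnergySurface", point: np.ndarray) -> tuple[int, int]:
    """Grid cell containing a 2-D point (clipped to the edge bins)."""
    i = int(np.clip(np.searchsorted(surface.x_edges, point[0], side="right") - 1,
                    0, surface.grid.shape[0] - 1))
    j = int(np.clip(np.searchsorted(surface.y_edges, point[1], side="right") - 1,
                    0, surface.grid.shape[1] - 1))
    return i, j


def connection_level(surface: "FreeEnergySurface", cell_a: tuple[int, int],
                     cell_b: tuple[int, int]) -> float:
    """Lowest free-energy level at which two grid cells become connected.

    Cells with F <= level are passable (4-connectivity).  The barrier
    separating two basins is this level minus the higher of the two basin
    minima.
    """
    from scipy.ndimage import label

    F = surface.grid
    candidates = np.unique(F[np.isfinite(F)])
    lo, hi = 0, len(candidates) - 1
    if _connected(F, candidates[hi], cell_a, cell_b) is False:
        return float("inf")
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected(F, candidates[mid], cell_a, cell_b):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def _connected(F, level, cell_a, cell_b) -> bool:
    from scipy.ndimage import label

    passable = np.isfinite(F) & (F <= level)
    if not (passable[cell_a] and passable[cell_b]):
        return False
    lab, _ = label(passable)
    return lab[cell_a] == lab[cell_b]


def smooth_probability_grid(H: np.ndarray, variance: float) -> np.ndarray:
    """Normalized-kernel Gaussian smoothing of a probability grid with
    reflective boundaries; total mass is conserved."""
    return gaussian_filter(H, sigma=np.sqrt(variance), mode="reflect")


def free_energy_surface(points2d: np.ndarray, weights: np.ndarray, bins: int = 50,
                        variance: float = 0.3, n_levels: int = 6,
                        smooth_space: str = "free_energy",
                        smooth: bool = True) -> FreeEnergySurface:
    """Weighted free-energy surface over a 2-D projection.

    Parameters
    ----------
    points2d : (n, 2) array
        Projected conformations (one point per MSM microstate).
    weights : (n,) array
        Equilibrium probabilities (non-negative, positive sum).
    variance : float
        Gaussian kernel variance in grid-cell units (sigma = sqrt(variance)).
        Set ``smooth=False`` to skip smoothing entirely.
    smooth_space : "free_energy" | "probability"
        Where the convolution is applied.  The default follows the literal
        construction order — histogram, -ln, then convolve — with empty-cell
        infinities capped at (max finite F + 1) before convolving.
        "probability" smooths the histogram before taking the logarithm,
        which conserves probability mass exactly.
    """
    P = np.atleast_2d(np.asarray(points2d, dtype=float))
    w = np.asarray(weights, dtype=float)
    if P.shape[1] != 2:
        raise ValueError("points2d must be (n, 2)")
    if len(w) != len(P):
        raise ValueError("weights must match points")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    if smooth_space not in ("free_energy", "probability"):
        raise ValueError(f"unknown smooth_space {smooth_space!r}")

    H, x_edges, y_edges = np.histogram2d(P[:, 0], P[:, 1], bins=bins, weights=w)
    p = H / H.sum()

    if smooth and smooth_space == "probability":
        p = smooth_probability_grid(p, variance)
    with np.errstate(divide="ignore"):
        F = -np.log(p)
    if smooth and smooth_space == "free_energy":
        cap = np.nanmax(np.where(np.isfinite(F), F, np.nan)) + 1.0
        F = gaussian_filter(np.where(np.isfinite(F), F, cap),
                            sigma=np.sqrt(variance), mode="reflect")
    finite = F[np.isfinite(F)]
    fmin, fmax = float(finite.min()), float(finite.max())
    levels = np.linspace(fmin, fmax, n_levels)
    return FreeEnergySurface(grid=F, x_edges=x_edges, y_edges=y_edges,
                             smoothing_variance=float(variance) if smooth else 0.0,
                             levels=levels, smooth_space=smooth_space)
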