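"""Canopy marking: parameterised filter chain + Delaunay-regularity search.

The probability image is pushed through five stages parameterised by the
triple (p, k, s):

1. clip/normalise — probabilities below ``p`` are zeroed, the rest rescaled
   linearly onto the full 8-bit range;
2. 3x3 median filter — removes isolated noise pixels;
3. density — mean filter with a circular kernel of diameter ``k``,
   homogenising clusters of high-probability pixels;
4. segmentation — binarise at threshold ``s``;
5. centroid extraction — one centroid per 8-connected component.

For every (p, k, s) on a regular grid the Delaunay triangulation of the
centroids is computed and the coefficient of variation (Cv) of its side
lengths measured, after recursively pruning elongated boundary triangles
(inradius/circumradius < 0.1). A regular planting lattice gives nearly equal
side lengths, hence a small Cv; because Cv is dimensionless it is comparable
across captures with different ground sample distances. Among iterations
whose canopy count lies within +/-40% of the median count, the (p, k, s)
minimising Cv wins and its centroids are the detected canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "MarkingParams",
    "ParameterGrid",
    "OptimizationResult",
    "NoSolutionError",
    "clip_normalize",
    "median3",
    "density",
    "segment",
    "extract_centroids",
    "pruned_delaunay_sides",
    "coefficient_of_variation",
    "median_count",
    "run_stages",
    "evaluate_grid",
    "select_optimum",
    "mark_canopies",
]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class NoSolutionError(RuntimeError):
    """No grid iteration survived the canopy-count feasibility band.

    Carries the full diagnostic surface so callers can inspect why.
    """

    def __init__(self, message: str, surface: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.surface = surface


class MarkingParams(NamedTuple):
    """The optimised triple: probability threshold, kernel diameter (px),
    8-bit segmentation threshold."""

    p: float
    k: int
    s: int


@dataclass(frozen=True)
class ParameterGrid:
    """Regular discretisation of the (p, k, s) search space.

    Defaults: p in 0.05..0.95 step 0.05 (19 values), k in 5..30 step 5
    (6 values), s in 5..250 step 5 (50 values) — 5700 iterations.
    """

    P: tuple[float, ...] = tuple(np.round(np.arange(1, 20) * 0.05, 2))
    K: tuple[int, ...] = tuple(range(5, 31, 5))
    S: tuple[int, ...] = tuple(range(5, 251, 5))

    def __post_init__(self) -> None:
        if not (self.P and self.K and self.S):
            raise ValueError("parameter grid must be non-empty")
        if any(not 0 < p < 1 for p in self.P):
            raise ValueError("probability thresholds must lie in (0, 1)")
        if any(k < 1 for k in self.K):
            raise ValueError("kernel diameters must be >= 1")
        if any(not 0 <= s <= 255 for s in self.S):
            raise ValueError("segmentation thresholds must lie in [0, 255]")

    @property
    def size(self) -> int:
        return len(self.P) * len(self.K) * len(self.S)


@dataclass
class OptimizationResult:
    """The full brute-force surface plus the selected optimum."""

    surface: pd.DataFrame  # columns p, k, s, cv, count, feasible
    median_count: float
    band: tuple[float, float]
    best: MarkingParams
    canopies: np.ndarray  # (n, 2) float, columns (x, y)


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def clip_normalize(prob: np.ndarray, p: float) -> np.ndarray:
    """Zero probabilities below ``p``; rescale [p, 1] linearly onto [0, 255].

    Rounding is half-away-from-zero, matching 8-bit image semantics.
    """
    if not 0 < p < 1:
        raise ValueError("probability threshold must lie in (0, 1)")
    prob = np.asarray(prob, dtype=np.float64)
    scaled = (prob - p) / (1.0 - p) * 255.0
    out = np.floor(scaled + 0.5)
    out[prob < p] = 0.0
    return np.clip(out, 0, 255).astype(np.uint8)


def median3(img: np.ndarray) -> np.ndarray:
    """3x3 median filter with replicated borders."""
    return ndimage.median_filter(np.asarray(img), size=3, mode="nearest")


def disc_kernel(diameter: float) -> np.ndarray:
    """Binary circular kernel: offsets whose centre lies within diameter/2."""
    if diameter < 1:
        raise ValueError("kernel diameter must be >= 1")
    radius = int(np.floor(diameter / 2.0))
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (np.hypot(xx, yy) <= diameter / 2.0).astype(np.float64)


def density(img: np.ndarray, k: float) -> np.ndarray:
    """Mean filter with a circular kernel of diameter ``k`` (replicate edges).

    Each pixel becomes the mean of itself and the neighbours whose centres
    lie within ``k/2``; ``k = 1`` is the identity.
    """
    kernel = disc_kernel(k)
    kernel /= kernel.sum()
    radius = kernel.shape[0] // 2
    padded = np.pad(np.asarray(img, dtype=np.float64), radius, mode="edge")
    return signal.fftconvolve(padded, kernel, mode="valid")


def segment(img: np.ndarray, s: float) -> np.ndarray:
    """Binarise: pixel >= s -> 1, else 0."""
    return (np.asarray(img) >= s).astype(np.uint8)


def extract_centroids(binary: np.ndarray) -> np.ndarray:
    """One centroid per 8-connected foreground component.

    Returns an (n, 2) float array with columns (x, y) — x is the column
    index — where each centroid is the arithmetic mean of the component's
    pixel coordinates. An empty image yields an empty array.
    """
    labels, n = ndimage.label(np.asarray(binary) > 0, structure=_EIGHT_CONNECTED)
    if n == 0:
        return np.empty((0, 2), dtype=np.float64)
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    counts = np.bincount(lab, minlength=n + 1)[1:]
    cx = np.bincount(lab, weights=xs, minlength=n + 1)[1:] / counts
    cy = np.bincount(lab, weights=ys, minlength=n + 1)[1:] / counts
    return np.column_stack([cx, cy])


# ---------------------------------------------------------------------------
# triangulation statistics
# ---------------------------------------------------------------------------

def _triangle_quality(points: np.ndarray, simplex: np.ndarray) -> float:
    """Inradius/circumradius ratio: 0.5 for equilateral, -> 0 for slivers."""
    a, b, c = points[simplex]
    la = np.hypot(*(b - c))
    lb = np.hypot(*(a - c))
    lc = np.hypot(*(a - b))
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0 or la * lb * lc == 0:
        return 0.0
    # r/R = (2*Area/perim) / (abc/(4*Area)) = 8*Area^2/(abc*perim); area2 = 2*Area
    return float(2.0 * area2**2 / (la * lb * lc * (la + lb + lc)))


def pruned_delaunay_sides(
    canopies: np.ndarray, ratio_threshold: float = 0.1
) -> Optional[np.ndarray]:
    """Unique side lengths of the Delaunay triangulation after sliver pruning.

    Boundary triangles — those owning at least one side that belongs to a
    single triangle — whose inradius/circumradius ratio falls below
    ``ratio_threshold`` are removed, and the criterion is re-applied to the
    newly exposed boundary until it stabilises, so no interior holes are
    created. Returns ``None`` (an infeasibility signal, not an error) when a
    triangulation cannot be built: fewer than 3 points, collinear input, or
    every triangle pruned away.
    """
    pts = np.asarray(canopies, dtype=np.float64)
    if len(pts) < 3:
        return None
    try:
        tri = Delaunay(pts)
    except QhullError:
        return None
    simplices = tri.simplices
    if len(simplices) == 0:
        return None
    alive = np.ones(len(simplices), dtype=bool)
    tri_edges = [
        [tuple(sorted((s[i], s[j]))) for i, j in ((0, 1), (1, 2), (0, 2))]
        for s in simplices
    ]
    quality = np.array([_triangle_quality(pts, s) for s in simplices])
    while True:
        edge_count: dict[tuple[int, int], int] = {}
        for t in np.nonzero(alive)[0]:
            for e in tri_edges[t]:
                edge_count[e] = edge_count.get(e, 0) + 1
        removed = False
        for t in np.nonzero(alive)[0]:
            on_boundary = any(edge_count[e] == 1 for e in tri_edges[t])
            if on_boundary and quality[t] < ratio_threshold:
                alive[t] = False
                removed = True
        if not removed:
            break
    if not alive.any():
        return None
    edges = {e for t in np.nonzero(alive)[0] for e in tri_edges[t]}
    idx = np.array(sorted(edges))
    return np.hypot(*(pts[idx[:, 0]] - pts[idx[:, 1]]).T)


def coefficient_of_variation(lengths: Sequence[float] | np.ndarray) -> float:
    """Cv = sqrt(N * sum((l - mean)^2)) / sum(l) — population sigma over mean.

    Dimensionless, so point patterns at different ground sample distances
    are directly comparable; 0 iff all lengths are equal.
    """
    lengths = np.asarray(lengths, dtype=np.float64)
    if lengths.size == 0:
        raise ValueError("empty side-length multiset")
    if np.any(lengths <= 0):
        raise ValueError("side lengths must be positive")
    n = lengths.size
    mean = lengths.mean()
    return float(np.sqrt(n * np.sum((lengths - mean) ** 2)) / lengths.sum())


def median_count(counts: Sequence[float]) -> float:
    """Median of the per-iteration canopy counts (mean of middles for even n)."""
    counts = np.sort(np.asarray(counts, dtype=np.float64))
    if counts.size == 0:
        raise ValueError("no counts")
    c = counts.size
    if c % 2:
        return float(counts[(c - 1) // 2])
    return float((counts[c // 2 - 1] + counts[c // 2]) / 2.0)


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def run_stages(prob: np.ndarray, p: float, k: int, s: int) -> np.ndarray:
    """The full stage chain for one (p, k, s); returns the centroids."""
    clipped = clip_normalize(prob, p)
    filtered = median3(clipped)
    dens = density(filtered, k)
    binary = segment(dens, s)
    return extract_centroids(binary)


def evaluate_grid(
    prob: np.ndarray, grid: ParameterGrid = ParameterGrid(), ratio_threshold: float = 0.1
) -> pd.DataFrame:
    """Evaluate Cv and canopy count for every (p, k, s) of the grid.

    Iteration order is lexicographic in (P, K, S). The first two stages
    depend only on ``p`` and the density stage only on (p, k), so their
    results are shared across the inner loops; the outcome is identical to
    running the five stages independently per iteration. Iterations where
    the triangulation is infeasible get ``cv = NaN`` and ``feasible=False``.
    """
    records = []
    for p in grid.P:
        filtered = median3(clip_normalize(prob, p))
        for k in grid.K:
            dens = density(filtered, k)
            for s in grid.S:
                centroids = extract_centroids(segment(dens, s))
                lengths = pruned_delaunay_sides(centroids, ratio_threshold)
                cv = (
                    coefficient_of_variation(lengths)
                    if lengths is not None and lengths.size
                    else np.nan
                )
                records.append(
                    (p, k, s, cv, len(centroids), bool(np.isfinite(cv)))
                )
    return pd.DataFrame(records, columns=["p", "k", "s", "cv", "count", "feasible"])


def select_optimum(
    surface: pd.DataFrame, band: float = 0.4
) -> tuple[MarkingParams, float, tuple[float, float]]:
    """Pick the (p, k, s) minimising Cv inside the canopy-count band.

    The median count M is taken over all iterations that produced a
    triangulation; only iterations with count strictly inside
    ``((1 - band) * M, (1 + band) * M)`` compete. Ties on Cv go to the
    lexicographically smallest (p, k, s); the surface is already in that
    order, so the first minimum wins.
    """
    feasible = surface[surface["feasible"]]
    if feasible.empty:
        raise NoSolutionError("no grid iteration produced a triangulation", surface)
    m = median_count(feasible["count"].to_numpy())
    lo, hi = (1.0 - band) * m, (1.0 + band) * m
    in_band = feasible[(feasible["count"] > lo) & (feasible["count"] < hi)]
    if in_band.empty:
        raise NoSolutionError(
            f"no iteration with canopy count strictly inside ({lo}, {hi})", surface
        )
    row = in_band.loc[in_band["cv"].idxmin()]
    best = MarkingParams(float(row["p"]), int(row["k"]), int(row["s"]))
    return best, m, (lo, hi)


def mark_canopies(
    prob: np.ndarray,
    grid: ParameterGrid = ParameterGrid(),
    ratio_threshold: float = 0.1,
    band: float = 0.4,
) -> tuple[np.ndarray, OptimizationResult]:
    """Full brute-force canopy marking on one probability image.

    Returns the winning centroids ((n, 2), columns x, y) and the diagnostic
    :class:`OptimizationResult` with the full (p, k, s) surface.
    """
    surface = evaluate_grid(prob, grid, ratio_threshold)
    best, m, band_limits = select_optimum(surface, band)
    canopies = run_stages(prob, best.p, best.k, best.s)
    result = OptimizationResult(
        surface=surface,
        median_count=m,
        band=band_limits,
        best=best,
        canopies=canopies,
    )
    return canopies, result


def write_centroids(canopies: np.ndarray, capture_id: str, path) -> None:
    """Write detected centroids as CSV ``capture_id,x,y`` (0-based pixels)."""
    df = pd.DataFrame(
        {
            "capture_id": capture_id,
            "x": np.asarray(canopies)[:, 0] if len(canopies) else [],
            "y": np.asarray(canopies)[:, 1] if len(canopies) else [],
        }
    )
    df.to_csv(path, index=False)


def read_centroids(path) -> pd.DataFrame:
    return pd.read_csv(path)
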