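"""Independent brute-force oracles used to check the image-processing and
triangulation stages. Deliberately slow and literal: per-pixel loops, BFS
component labelling, per-round triangle scans — no shared code with the
implementations they validate beyond scipy's Delaunay vertex list.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import Delaunay


def median3_bruteforce(img: np.ndarray) -> np.ndarray:
    """Per-pixel sorted-window 3x3 median with replicated borders."""
    img = np.asarray(img)
    h, w = img.shape
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            window = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    window.append(img[yy, xx])
            out[y, x] = sorted(window)[4]
    return out


def density_bruteforce(img: np.ndarray, k: float) -> np.ndarray:
    """Per-pixel mean over the disc of neighbours within k/2 (replicate edges)."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    radius = int(np.floor(k / 2.0))
    offsets = [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if np.hypot(dx, dy) <= k / 2.0
    ]
    out = np.empty_like(img)
    for y in range(h):
        for x in range(w):
            vals = [
                img[min(max(y + dy, 0), h - 1), min(max(x + dx, 0), w - 1)]
                for dy, dx in offsets
            ]
            out[y, x] = sum(vals) / len(vals)
    return out


def centroids_bruteforce(binary: np.ndarray) -> list[tuple[float, float]]:
    """BFS 8-connected component labelling; centroids as (x, y) pixel means."""
    binary = np.asarray(binary) > 0
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    centroids = []
    for y0 in range(h):
        for x0 in range(w):
            if not binary[y0, x0] or seen[y0, x0]:
                continue
            queue = deque([(y0, x0)])
            seen[y0, x0] = True
            members = []
            while queue:
                y, x = queue.popleft()
                members.append((y, x))
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w and binary[yy, xx] and not seen[yy, xx]:
                            seen[yy, xx] = True
                            queue.append((yy, xx))
            ys = [m[0] for m in members]
            xs = [m[1] for m in members]
            centroids.append((sum(xs) / len(xs), sum(ys) / len(ys)))
    return centroids


def _side_lengths(pts, tri):
    a, b, c = (np.asarray(pts[i], dtype=float) for i in tri)
    return (
        float(np.hypot(*(b - c))),
        float(np.hypot(*(a - c))),
        float(np.hypot(*(a - b))),
    )


def _inradius_circumradius_ratio(pts, tri) -> float:
    la, lb, lc = _side_lengths(pts, tri)
    a, b, c = (np.asarray(pts[i], dtype=float) for i in tri)
    u, v = b - a, c - a
    area = abs(u[0] * v[1] - u[1] * v[0]) / 2.0
    if area == 0:
        return 0.0
    inradius = 2.0 * area / (la + lb + lc)
    circumradius = la * lb * lc / (4.0 * area)
    return inradius / circumradius


def pruned_sides_bruteforce(points: np.ndarray, threshold: float = 0.1):
    """Recursive boundary-sliver pruning, recomputing everything per round."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 3:
        return None
    try:
        tri = Delaunay(points)
    except Exception:
        return None
    triangles = [tuple(s) for s in tri.simplices]
    if not triangles:
        return None
    while True:
        edge_owner: dict[tuple[int, int], int] = {}
        for t in triangles:
            for i in range(3):
                for j in range(i + 1, 3):
                    e = tuple(sorted((t[i], t[j])))
                    edge_owner[e] = edge_owner.get(e, 0) + 1
        doomed = []
        for t in triangles:
            edges = [
                tuple(sorted((t[i], t[j])))
                for i in range(3)
                for j in range(i + 1, 3)
            ]
            if any(edge_owner[e] == 1 for e in edges):
                if _inradius_circumradius_ratio(points, t) < threshold:
                    doomed.append(t)
        if not doomed:
            break
        triangles = [t for t in triangles if t not in doomed]
    if not triangles:
        return None
    edges = set()
    for t in triangles:
        for i in range(3):
            for j in range(i + 1, 3):
                edges.add(tuple(sorted((t[i], t[j]))))
    return sorted(
        float(np.hypot(*(points[i] - points[j]))) for i, j in edges
    )


def cv_bruteforce(lengths) -> float:
    """Population standard deviation over the mean, from first principles."""
    lengths = list(map(float, lengths))
    n = len(lengths)
    mean = sum(lengths) / n
    var = sum((l - mean) ** 2 for l in lengths) / n
    return (var**0.5) / mean
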