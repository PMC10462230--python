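"""Independent brute-force oracles, kept deliberately naive.

These re-derive quantities by enumeration or pixel-by-pixel loops and never
call the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

# ---------------------------------------------------------------------------
# GLCM: explicit pair counting


def brute_glcm(levels_img: np.ndarray, offset: tuple[int, int], n_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix by explicit pair counting."""
    h, w = levels_img.shape
    dr, dc = offset
    counts = np.zeros((n_levels, n_levels))
    for r in range(h):
        for c in range(w):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                a, b = levels_img[r, c], levels_img[rr, cc]
                counts[a, b] += 1
                counts[b, a] += 1
    return counts / counts.sum()


def brute_glcm_props(p: np.ndarray) -> dict[str, float]:
    """Haralick-style properties via explicit double loops."""
    n = p.shape[0]
    contrast = homogeneity = energy = entropy = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            contrast += (i - j) ** 2 * p[i, j]
            homogeneity += p[i, j] / (1 + (i - j) ** 2)
            energy += p[i, j] ** 2
            if p[i, j] > 0:
                entropy -= p[i, j] * np.log2(p[i, j])
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    correlation = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


# angle -> (row, col) displacement at distance 1 (rows grow downward, so the
# 45-degree offset is down-right; symmetric counting makes direction sign
# irrelevant)
GLCM_OFFSETS = {
    "0": (0, 1),
    "45": (1, 1),
    "90": (1, 0),
    "135": (1, -1),
}


# ---------------------------------------------------------------------------
# LBP: per-pixel neighbor thresholding with bilinear interpolation


def _bilinear(img: np.ndarray, r: float, c: float) -> float:
    # two-stage interpolation (columns within each row, then across rows)
    # with floor/ceil corner selection, so integer coordinates are exact
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    r1, c1 = int(np.ceil(r)), int(np.ceil(c))
    dr, dc = r - r0, c - c0
    top = (1 - dc) * img[r0, c0] + dc * img[r0, c1]
    bottom = (1 - dc) * img[r1, c0] + dc * img[r1, c1]
    return (1 - dr) * top + dr * bottom


def brute_lbp_uniform_hist(img: np.ndarray, p: int = 8, radius: float = 1.0) -> np.ndarray:
    """Normalized histogram of rotation-invariant uniform LBP codes.

    Codes 0..p count set bits of uniform patterns (<= 2 circular
    transitions); code p+1 pools non-uniform patterns. Only interior pixels
    (full radius-R neighborhood inside the image) contribute; sampling uses
    bilinear interpolation on the circle with comparison >= center.
    """
    h, w = img.shape
    hist = np.zeros(p + 2)
    # circle sample offsets, rounded to 8 decimals so axis-aligned samples
    # land exactly on grid points
    offsets = [
        (round(-radius * np.sin(2 * np.pi * k / p), 8),
         round(radius * np.cos(2 * np.pi * k / p), 8))
        for k in range(p)
    ]
    b = int(np.ceil(radius))
    for r in range(b, h - b):
        for c in range(b, w - b):
            bits = []
            for dr, dc in offsets:
                bits.append(1 if _bilinear(img, r + dr, c + dc) >= img[r, c] else 0)
            transitions = sum(bits[i] != bits[(i + 1) % p] for i in range(p))
            code = sum(bits) if transitions <= 2 else p + 1
            hist[code] += 1
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Connected components: recursive flood fill


def flood_fill_count(grid: np.ndarray, class_id: int) -> int:
    """Number of 8-connected components of ``class_id`` cells."""
    visited = np.zeros(grid.shape, dtype=bool)
    count = 0
    h, w = grid.shape
    for r0 in range(h):
        for c0 in range(w):
            if grid[r0, c0] != class_id or visited[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            visited[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < h and 0 <= cc < w and not visited[rr, cc]
                                and grid[rr, cc] == class_id):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
    return count


# ---------------------------------------------------------------------------
# Spanning trees: exhaustive enumeration (feasible to |V| ~ 7)


def exhaustive_mst_length(points: np.ndarray) -> float:
    """Minimum total Euclidean length over all spanning trees of the
    complete graph, by enumerating every (n-1)-edge subset."""
    n = len(points)
    edges = [(i, j, float(np.linalg.norm(points[i] - points[j])))
             for i, j in combinations(range(n), 2)]
    best = np.inf
    for subset in combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for i, j, _ in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                acyclic = False
                break
            parent[ri] = rj
        if acyclic:
            best = min(best, sum(w for _, _, w in subset))
    return best


def all_pairs_edges(points: np.ndarray, radius: float) -> set[tuple[int, int]]:
    """O(n^2) distance thresholding."""
    out = set()
    for i, j in combinations(range(len(points)), 2):
        if np.linalg.norm(points[i] - points[j]) <= radius:
            out.add((i, j))
    return out
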