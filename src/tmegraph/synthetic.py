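"""Synthetic fixtures with full planted ground truth.

Three generators cover the pipeline stages:

* :func:`make_tile` — 224x224 H&E-like tiles with class-distinguishable
  textures, stained through the Beer-Lambert forward model so hematoxylin
  deconvolution can recover the planted concentrations;
* :func:`make_slide` — an annotated slide image assembled from rectangular
  labeled regions, with the analytically derived retained-tile grid;
* :func:`make_cohort` — patient cohorts whose spatial co-arrangement of
  selected class pairs differs by treatment outcome, at a controllable
  effect size, alongside per-cell texture summaries.

Everything is byte-reproducible from (spec, seed). Planted truth is
recorded so each stage can be scored without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotation_io import AnnotatedRegion, OutcomeTable
from .classes import CLASSES, EMPTY_CELL, TISSUE_CLASSES, HistologyClass, class_by_id
from .histology_map import HistologyMap
from .tile_prep import TILE_SIZE, Tile, stains_to_rgb
from .tme_graph import TEXTURE_SUMMARY_NAMES

# ---------------------------------------------------------------------------
# Tiles


@dataclass
class TextureSpec:
    """Recipe for one class's texture: generator family, spatial scale,
    orientation (radians), contrast in [0,1], and base H/E optical-density
    concentrations."""

    class_id: int
    family: str  # noise | stripes | blobs | checker | mixture
    scale: float = 8.0
    orientation: float = 0.0
    contrast: float = 0.6
    base_h: float = 0.5
    base_e: float = 0.3


def _texture_field(spec: TextureSpec, shape: tuple[int, int], rng: np.random.Generator,
                   origin: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Scalar texture in [0, 1]; stripes/checker are functions of global
    coordinates, noise/blobs are seeded random fields."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    xs = xs + origin[0]
    ys = ys + origin[1]
    if spec.family == "stripes":
        u = xs * np.cos(spec.orientation) + ys * np.sin(spec.orientation)
        return 0.5 + 0.5 * np.sin(2 * np.pi * u / max(spec.scale, 1.0))
    if spec.family == "checker":
        s = max(int(spec.scale), 1)
        return (((xs // s) + (ys // s)) % 2).astype(float)
    if spec.family in ("noise", "blobs"):
        sigma = spec.scale if spec.family == "blobs" else max(spec.scale / 4.0, 0.5)
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        lo, hi = f.min(), f.max()
        return (f - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)
    if spec.family == "mixture":
        stripes = _texture_field(
            TextureSpec(spec.class_id, "stripes", spec.scale, spec.orientation), shape, rng, origin
        )
        noise = _texture_field(TextureSpec(spec.class_id, "noise", 2.0), shape, rng, origin)
        return 0.5 * stripes + 0.5 * noise
    raise ValueError(f"unknown texture family {spec.family!r}")


def make_tile(spec: TextureSpec, seed: int = 0, origin: tuple[int, int] = (0, 0)) -> Tile:
    """Synthesize one 224x224 tile via Beer-Lambert forward staining."""
    rng = np.random.default_rng(seed)
    t = _texture_field(spec, (TILE_SIZE, TILE_SIZE), rng, origin)
    c_h = spec.base_h + spec.contrast * (t - 0.5)
    c_e = spec.base_e + 0.5 * spec.contrast * (0.5 - t)
    conc = np.stack([np.maximum(c_h, 0.0), np.maximum(c_e, 0.0)], axis=-1)
    rgb = stains_to_rgb(conc)
    return Tile(
        tile_id=f"synth_{spec.class_id}_{seed}",
        slide_id="synthetic",
        origin=origin,
        rgb=rgb,
        true_label=class_by_id(spec.class_id),
    )


def default_texture_specs() -> dict[int, TextureSpec]:
    """One distinguishable recipe per class (16 tissue + background)."""
    specs = {
        0: TextureSpec(0, "stripes", scale=24, orientation=0.0, contrast=0.5, base_h=0.35, base_e=0.45),
        1: TextureSpec(1, "blobs", scale=6, contrast=0.8, base_h=0.85, base_e=0.25),
        2: TextureSpec(2, "noise", scale=2, contrast=0.9, base_h=0.95, base_e=0.15),
        3: TextureSpec(3, "mixture", scale=20, orientation=np.pi / 2, contrast=0.7, base_h=0.6, base_e=0.4),
        4: TextureSpec(4, "blobs", scale=16, contrast=0.3, base_h=0.4, base_e=0.4),
        5: TextureSpec(5, "blobs", scale=24, contrast=0.9, base_h=0.75, base_e=0.3),
        6: TextureSpec(6, "stripes", scale=12, orientation=np.pi / 4, contrast=0.8, base_h=0.45, base_e=0.7),
        7: TextureSpec(7, "noise", scale=10, contrast=0.35, base_h=0.25, base_e=0.5),
        8: TextureSpec(8, "checker", scale=8, contrast=0.7, base_h=0.55, base_e=0.6),
        9: TextureSpec(9, "blobs", scale=10, contrast=0.5, base_h=0.6, base_e=0.35),
        10: TextureSpec(10, "noise", scale=4, contrast=0.85, base_h=0.9, base_e=0.2),
        11: TextureSpec(11, "checker", scale=20, contrast=0.6, base_h=0.7, base_e=0.35),
        12: TextureSpec(12, "noise", scale=8, contrast=0.6, base_h=0.3, base_e=0.9),
        13: TextureSpec(13, "blobs", scale=32, contrast=0.25, base_h=0.12, base_e=0.12),
        14: TextureSpec(14, "stripes", scale=40, orientation=3 * np.pi / 4, contrast=0.55, base_h=0.5, base_e=0.55),
        15: TextureSpec(15, "blobs", scale=5, contrast=0.3, base_h=0.2, base_e=0.25),
        16: TextureSpec(16, "noise", scale=1, contrast=0.03, base_h=0.02, base_e=0.02),
    }
    assert set(specs) == {c.id for c in CLASSES}
    return specs


def make_tile_dataset(
    tiles_per_class: int = 12,
    classes: tuple = CLASSES,
    seed: int = 0,
) -> tuple[list[Tile], np.ndarray]:
    """Balanced labeled tile set over all classes (distinct seeds per tile)."""
    specs = default_texture_specs()
    rng = np.random.default_rng(seed)
    tiles, labels = [], []
    for c in classes:
        cid = c.id if isinstance(c, HistologyClass) else int(c)
        for _ in range(tiles_per_class):
            tiles.append(make_tile(specs[cid], seed=int(rng.integers(2**31))))
            labels.append(cid)
    return tiles, np.array(labels)


# ---------------------------------------------------------------------------
# Slides


@dataclass
class SlideFixture:
    image: np.ndarray
    regions: list[AnnotatedRegion]
    planted_grid: np.ndarray  # class id per grid cell, EMPTY_CELL elsewhere


def _rect_cover_fraction(rect: tuple[int, int, int, int], cell: tuple[int, int]) -> float:
    """Fraction of grid cell (row, col) covered by rect (x0, y0, x1, y1) —
    1-D overlap arithmetic, independent of any geometry library."""
    x0, y0, x1, y1 = rect
    r, c = cell
    cx0, cy0 = c * TILE_SIZE, r * TILE_SIZE
    ox = max(0.0, min(x1, cx0 + TILE_SIZE) - max(x0, cx0))
    oy = max(0.0, min(y1, cy0 + TILE_SIZE) - max(y0, cy0))
    return ox * oy / TILE_SIZE**2


def make_slide(
    layout: list[tuple[tuple[int, int, int, int], int]],
    canvas: tuple[int, int] = (2048, 2048),
    min_fraction: float = 0.9,
    seed: int = 0,
) -> SlideFixture:
    """Render axis-aligned rectangular regions ``((x0, y0, x1, y1), class)``
    onto a white canvas and derive the retained-tile grid analytically.

    Regions of different classes must not overlap.
    """
    h, w = canvas[1], canvas[0]
    specs = default_texture_specs()
    rng = np.random.default_rng(seed)
    image = np.full((h, w, 3), 255, dtype=np.uint8)
    occupancy = np.full((h, w), -1, dtype=int)
    regions: list[AnnotatedRegion] = []
    for i, ((x0, y0, x1, y1), cid) in enumerate(layout):
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"region {i}: rect {(x0, y0, x1, y1)} outside canvas {canvas}")
        patch_occ = occupancy[y0:y1, x0:x1]
        clash = patch_occ[(patch_occ >= 0) & (patch_occ != cid)]
        if clash.size:
            raise ValueError(f"region {i}: overlaps a region of class {clash[0]}")
        patch_occ[:] = cid
        t = _texture_field(specs[cid], (y1 - y0, x1 - x0), rng, origin=(x0, y0))
        c_h = np.maximum(specs[cid].base_h + specs[cid].contrast * (t - 0.5), 0.0)
        c_e = np.maximum(specs[cid].base_e + 0.5 * specs[cid].contrast * (0.5 - t), 0.0)
        image[y0:y1, x0:x1] = stains_to_rgb(np.stack([c_h, c_e], axis=-1))
        contour = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
        regions.append(AnnotatedRegion(f"synth_region_{i}", "synthetic", contour, class_by_id(cid)))

    grid = np.full((h // TILE_SIZE, w // TILE_SIZE), EMPTY_CELL, dtype=int)
    for (x0, y0, x1, y1), cid in layout:
        for r in range(y0 // TILE_SIZE, min(-(-y1 // TILE_SIZE), grid.shape[0])):
            for c in range(x0 // TILE_SIZE, min(-(-x1 // TILE_SIZE), grid.shape[1])):
                if _rect_cover_fraction((x0, y0, x1, y1), (r, c)) >= min_fraction - 1e-12:
                    grid[r, c] = cid
    return SlideFixture(image, regions, grid)


# ---------------------------------------------------------------------------
# Cohorts

#: Planted informative pairs: (class A id, class B id, P(close | pCR), P(close | RD)).
#: Tumor (1) adjacent to tumorTIL (10) marks responders; microvessel (8)
#: adjacent to PGCC (5) marks residual disease.
DEFAULT_INFORMATIVE = (
    (1, 10, 0.9, 0.1),
    (8, 5, 0.1, 0.9),
)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``effect`` in [0, 1] scales the outcome dependence of the informative
    pairs' close-placement probabilities toward 0.5 (0 = no signal,
    1 = the probabilities above). Inter-cluster distances follow shifted
    Gamma laws: close ~ 0.8 + Gamma(2, 0.35) tiles, far ~ 5 + Gamma(2, 1.0).
    """

    n_pcr: int = 51
    n_rd: int = 34
    grid_size: int = 32
    effect: float = 1.0
    informative: tuple = DEFAULT_INFORMATIVE
    anchors_per_pair: int = 3
    background_clusters_per_class: int = 2
    seed: int = 0


@dataclass
class PatientFixture:
    patient_id: str
    outcome: str
    hmap: HistologyMap
    cell_textures: dict[tuple[int, int], np.ndarray]


@dataclass
class CohortFixture:
    patients: list[PatientFixture]
    outcomes: OutcomeTable
    spec: CohortSpec

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.outcome for p in self.patients])


def _class_texture_means() -> dict[int, np.ndarray]:
    """Deterministic per-class mean texture-summary vectors (6 dims)."""
    means = {}
    for c in TISSUE_CLASSES:
        rng = np.random.default_rng(1000 + c.id)
        means[c.id] = rng.uniform(0.1, 0.9, size=len(TEXTURE_SUMMARY_NAMES))
    return means


def _place_cluster(grid: np.ndarray, rng: np.random.Generator, cid: int,
                   center: tuple[float, float], n_cells: int) -> None:
    """Place an n-cell 8-connected cluster near ``center`` on free cells."""
    g = grid.shape[0]
    r0 = int(np.clip(round(center[0]), 0, g - 1))
    c0 = int(np.clip(round(center[1]), 0, g - 1))
    if grid[r0, c0] != EMPTY_CELL:  # nearest free cell, deterministic scan
        free = np.argwhere(grid == EMPTY_CELL)
        if free.size == 0:
            return
        d = np.abs(free[:, 0] - r0) + np.abs(free[:, 1] - c0)
        r0, c0 = free[np.argmin(d)]
    grid[r0, c0] = cid
    placed = [(r0, c0)]
    while len(placed) < n_cells:
        r, c = placed[rng.integers(len(placed))]
        dr, dc = rng.integers(-1, 2, size=2)
        rr, cc = r + dr, c + dc
        if 0 <= rr < g and 0 <= cc < g and grid[rr, cc] == EMPTY_CELL:
            grid[rr, cc] = cid
            placed.append((rr, cc))
        elif rng.random() < 0.1:  # crowded neighborhood: give up growing
            break


def _sample_patient_grid(spec: CohortSpec, outcome: str, rng: np.random.Generator) -> np.ndarray:
    g = spec.grid_size
    grid = np.full((g, g), EMPTY_CELL, dtype=int)
    informative_ids = {a for a, _, _, _ in spec.informative} | {b for _, b, _, _ in spec.informative}
    for a, b, p_pcr, p_rd in spec.informative:
        p_base = p_pcr if outcome == "pCR" else p_rd
        p_close = 0.5 + spec.effect * (p_base - 0.5)
        for _ in range(spec.anchors_per_pair):
            anchor = rng.uniform(2, g - 3, size=2)
            _place_cluster(grid, rng, a, tuple(anchor), int(rng.integers(1, 4)))
            if rng.random() < p_close:
                dist = 0.8 + rng.gamma(2.0, 0.35)
            else:
                dist = 5.0 + rng.gamma(2.0, 1.0)
            theta = rng.uniform(0, 2 * np.pi)
            partner = anchor + dist * np.array([np.sin(theta), np.cos(theta)])
            partner = np.clip(partner, 0, g - 1)
            _place_cluster(grid, rng, b, tuple(partner), int(rng.integers(1, 4)))
    # Non-informative classes: identical placement law for both outcomes.
    for c in TISSUE_CLASSES:
        if c.id in informative_ids:
            continue
        for _ in range(spec.background_clusters_per_class):
            center = rng.uniform(0, g - 1, size=2)
            _place_cluster(grid, rng, c.id, tuple(center), int(rng.integers(1, 4)))
    return grid


def make_cohort(spec: CohortSpec) -> CohortFixture:
    """Generate a map-level patient cohort with planted spatial signal.

    Each patient gets a histology label grid plus per-cell texture summary
    vectors (class mean + N(0, 0.02) noise). Cluster positions for the
    informative pairs are drawn with outcome-dependent proximity; all other
    classes are placed identically in distribution across outcomes.
    """
    rng = np.random.default_rng(spec.seed)
    tex_means = _class_texture_means()
    patients: list[PatientFixture] = []
    rows = []
    outcomes = ["pCR"] * spec.n_pcr + ["RD"] * spec.n_rd
    for i, outcome in enumerate(outcomes):
        pid = f"P{i:03d}"
        grid = _sample_patient_grid(spec, outcome, rng)
        hmap = HistologyMap(pid, grid)
        textures = {}
        for r, c in zip(*np.nonzero(grid != EMPTY_CELL)):
            cid = int(grid[r, c])
            textures[(int(r), int(c))] = tex_means[cid] + rng.normal(0, 0.02, len(TEXTURE_SUMMARY_NAMES))
        patients.append(PatientFixture(pid, outcome, hmap, textures))
        rows.append({"patient_id": pid, "outcome": outcome})
    table = OutcomeTable(pd.DataFrame(rows), cohort="synthetic")
    return CohortFixture(patients, table, spec)


# ---------------------------------------------------------------------------
# Direct feature-matrix generator (for feature-selection studies)


def make_feature_matrix(
    n_per_class: tuple[int, int] = (24, 16),
    n_columns: int = 200,
    n_informative: int = 8,
    effect: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian feature matrix with ``n_informative`` planted signal columns.

    Informative columns have class means separated by ``effect`` standard
    deviations; the rest are pure noise. Returns (matrix, labels,
    informative column indices). Informative columns are spread across the
    matrix rather than packed at the front.
    """
    rng = np.random.default_rng(seed)
    n = sum(n_per_class)
    labels = np.array(["pCR"] * n_per_class[0] + ["RD"] * n_per_class[1])
    X = rng.standard_normal((n, n_columns))
    informative = np.linspace(0, n_columns - 1, n_informative, dtype=int)
    shift = np.where(labels == "pCR", effect / 2.0, -effect / 2.0)
    for j in informative:
        X[:, j] += shift
    return X, labels, informative
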