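"""Tile extraction, stain color normalization and hematoxylin separation.

Annotated regions are partitioned on a global stride-224 grid; a tile is
retained when the annotation polygon covers at least ``min_fraction`` of it
(the classical >=90% rule). Color handling works in optical density (OD)
space under the Beer-Lambert model:

    OD = -log10(I / I0),   OD = C @ M

with ``M`` the row-wise stain OD matrix and ``C`` per-pixel stain
concentrations. Deconvolution uses the standard Ruifrok-Johnston H&E
vectors; normalization re-estimates the stain basis per image with the
Macenko SVD procedure and maps concentrations onto a reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation_io import AnnotatedRegion, containment_fraction
from .classes import HistologyClass

log = logging.getLogger(__name__)

TILE_SIZE = 224

# Ruifrok-Johnston H&E optical-density vectors (rows: hematoxylin, eosin,
# residual), each normalized to unit length.
_H = np.array([0.65, 0.70, 0.29])
_E = np.array([0.07, 0.99, 0.11])
_R = np.cross(_H, _E)
STAIN_MATRIX = np.stack([_H / np.linalg.norm(_H), _E / np.linalg.norm(_E), _R / np.linalg.norm(_R)])

#: OD concentration mapped to hema value 1.0 (values above are clipped).
HEMA_MAX_CONCENTRATION = 2.0

_OD_EPS = 1.0 / 255.0


@dataclass
class StainReference:
    """Target stain basis and 99th-percentile concentrations for Macenko
    normalization."""

    stain_matrix: np.ndarray  # 2x3, rows = (hematoxylin, eosin) unit OD vectors
    max_concentrations: np.ndarray  # length-2, 99th percentile target


#: Default reference: Ruifrok-Johnston basis at unit concentration scale.
DEFAULT_REFERENCE = StainReference(STAIN_MATRIX[:2].copy(), np.array([1.0, 1.0]))


@dataclass
class Tile:
    """A 224x224 patch with slide coordinates and derived channels."""

    tile_id: str
    slide_id: str
    origin: tuple[int, int]  # (x, y) level-0 pixels
    rgb: np.ndarray  # uint8 (224, 224, 3)
    hema: np.ndarray | None = None  # float in [0, 1]
    true_label: HistologyClass | None = None

    @property
    def grid_pos(self) -> tuple[int, int]:
        """(row, col) on the stride-224 grid."""
        return self.origin[1] // TILE_SIZE, self.origin[0] // TILE_SIZE

    def __post_init__(self) -> None:
        if self.rgb.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise ValueError(f"tile {self.tile_id}: shape {self.rgb.shape}, expected (224, 224, 3)")


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """8-bit RGB -> optical density (base-10), white -> ~0."""
    intensity = np.maximum(rgb.astype(float), 1.0) / 255.0
    return -np.log10(intensity)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Optical density -> 8-bit RGB with clamping."""
    rgb = 255.0 * np.power(10.0, -np.maximum(od, 0.0))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def stains_to_rgb(concentrations: np.ndarray, stain_matrix: np.ndarray = STAIN_MATRIX) -> np.ndarray:
    """Beer-Lambert forward model: per-pixel stain concentrations -> RGB."""
    od = concentrations @ stain_matrix[: concentrations.shape[-1]]
    return od_to_rgb(od)


def stain_concentrations(rgb: np.ndarray, stain_matrix: np.ndarray = STAIN_MATRIX) -> np.ndarray:
    """Invert the forward model: least-squares concentrations per pixel."""
    od = rgb_to_od(rgb).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(stain_matrix.T, od.T, rcond=None)
    return conc.T.reshape(rgb.shape[:-1] + (stain_matrix.shape[0],))


def hematoxylin_channel(rgb: np.ndarray) -> np.ndarray:
    """Hematoxylin OD concentration rescaled to [0, 1].

    Concentrations are clipped at :data:`HEMA_MAX_CONCENTRATION` then divided
    by it, so a pure-white tile maps to 0 and saturated nuclear staining to 1.
    """
    conc = stain_concentrations(rgb, STAIN_MATRIX)
    hema = np.clip(conc[..., 0], 0.0, HEMA_MAX_CONCENTRATION)
    return hema / HEMA_MAX_CONCENTRATION


def estimate_stain_basis(
    rgb: np.ndarray, beta: float = 0.15, alpha: float = 1.0
) -> tuple[np.ndarray, np.ndarray] | None:
    """Macenko estimation of the 2-stain OD basis of an H&E image.

    Returns ``(stain_matrix 2x3, concentrations Nx2 over tissue pixels)`` or
    ``None`` when too few pixels exceed the ``beta`` OD threshold (e.g. an
    all-white tile).
    """
    od = rgb_to_od(rgb).reshape(-1, 3)
    tissue = od[(od > beta).any(axis=1)]
    if len(tissue) < 10:
        return None
    # Plane of the two dominant stain directions.
    _, _, vt = np.linalg.svd(tissue - 0.0, full_matrices=False)
    plane = vt[:2]
    # Orient so projections fall on a consistent side.
    if plane[0].sum() < 0:
        plane[0] *= -1
    if plane[1].sum() < 0:
        plane[1] *= -1
    proj = tissue @ plane.T
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [alpha, 100 - alpha])
    v1 = plane.T @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane.T @ np.array([np.cos(hi), np.sin(hi)])
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    # Hematoxylin absorbs red light most strongly: larger red-OD component.
    he = np.stack([v1, v2] if v1[0] >= v2[0] else [v2, v1])
    conc, *_ = np.linalg.lstsq(he.T, tissue.T, rcond=None)
    return he, conc.T


def normalize_stain(
    rgb: np.ndarray, reference: StainReference = DEFAULT_REFERENCE
) -> tuple[np.ndarray, bool]:
    """Macenko stain color normalization onto a reference basis.

    Returns ``(normalized uint8 RGB, no_tissue_flag)``. Tiles without
    measurable stain (all white) are returned unchanged with the flag set.
    """
    est = estimate_stain_basis(rgb)
    if est is None:
        log.warning("normalize_stain: no tissue detected; tile returned unchanged")
        return rgb.copy(), True
    he, _ = est
    od = rgb_to_od(rgb).reshape(-1, 3)
    conc, *_ = np.linalg.lstsq(he.T, od.T, rcond=None)
    conc = conc.T  # N x 2
    max_c = np.percentile(np.maximum(conc, 0.0), 99, axis=0)
    scale = np.where(max_c > 1e-6, reference.max_concentrations / np.maximum(max_c, 1e-6), 1.0)
    norm_od = (conc * scale) @ reference.stain_matrix
    return od_to_rgb(norm_od).reshape(rgb.shape), False


class TilingError(ValueError):
    pass


class AmbiguousTileError(TilingError):
    """One tile satisfies the containment rule under two different labels."""


def tile_slide(
    image: np.ndarray,
    regions: list[AnnotatedRegion],
    min_fraction: float = 0.9,
    compute_hema: bool = True,
) -> list[Tile]:
    """Partition annotated regions into retained 224x224 tiles.

    Candidate tiles lie on the global stride-224 grid restricted to each
    region's bounding box; a tile is kept when the region covers at least
    ``min_fraction`` of its area and carries that region's label. A tile
    claimed by two regions with different labels raises
    :class:`AmbiguousTileError`.
    """
    h, w = image.shape[:2]
    if h < TILE_SIZE or w < TILE_SIZE:
        raise TilingError(f"image {w}x{h} smaller than one {TILE_SIZE}px tile")

    claimed: dict[tuple[int, int], tuple[str, HistologyClass]] = {}
    for region in regions:
        minx, miny, maxx, maxy = region.polygon().bounds
        col0 = max(int(minx // TILE_SIZE), 0)
        row0 = max(int(miny // TILE_SIZE), 0)
        col1 = min(int(np.ceil(maxx / TILE_SIZE)), w // TILE_SIZE)
        row1 = min(int(np.ceil(maxy / TILE_SIZE)), h // TILE_SIZE)
        n_region = 0
        for row in range(row0, row1):
            for col in range(col0, col1):
                x, y = col * TILE_SIZE, row * TILE_SIZE
                tile_box = (x, y, x + TILE_SIZE, y + TILE_SIZE)
                if containment_fraction(region, tile_box) >= min_fraction - 1e-12:
                    key = (row, col)
                    if key in claimed and claimed[key][1].id != region.label.id:
                        other_id, other_label = claimed[key]
                        raise AmbiguousTileError(
                            f"tile (row={row}, col={col}) claimed by region "
                            f"{other_id!r} ({other_label.name}) and region "
                            f"{region.region_id!r} ({region.label.name})"
                        )
                    claimed[key] = (region.region_id, region.label)
                    n_region += 1
        if n_region == 0:
            log.warning("region %r yielded no tiles at min_fraction=%.2f", region.region_id, min_fraction)

    tiles: list[Tile] = []
    slide_id = regions[0].slide_id if regions else "slide"
    for (row, col), (_, label) in sorted(claimed.items()):
        x, y = col * TILE_SIZE, row * TILE_SIZE
        rgb = np.ascontiguousarray(image[y : y + TILE_SIZE, x : x + TILE_SIZE])
        tile = Tile(
            tile_id=f"{slide_id}_r{row}_c{col}",
            slide_id=slide_id,
            origin=(x, y),
            rgb=rgb,
            true_label=label,
        )
        if compute_hema:
            tile.hema = hematoxylin_channel(rgb)
        tiles.append(tile)

    by_class: dict[str, int] = {}
    for t in tiles:
        by_class[t.true_label.name] = by_class.get(t.true_label.name, 0) + 1
    log.info("tile_slide: %d tiles retained; per-class counts %s", len(tiles), by_class)
    return tiles
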