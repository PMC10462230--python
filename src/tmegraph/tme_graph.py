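"""Spatial tumor-microenvironment graphs over histology-map tile clusters.

For every unordered pair of tissue classes, same-class tile clusters
(8-connected components of the histology map) become graph nodes at their
centroids; edges connect nodes within a Euclidean radius (a random
geometric construct). Twenty features per (patient, class pair) summarize
the graph: texture averages over interacting nodes, local node
configuration (including the algebraic connectivity of a spectral
construct) and global connectivity of the Euclidean minimum spanning
forest. With 16 tissue classes this yields C(16,2) = 120 pairs x 20
features = 2400 columns per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .classes import TISSUE_CLASSES, HistologyClass
from .histology_map import HistologyMap

TILE_SIZE = 224

#: Default edge radius: three tile widths.
DEFAULT_RADIUS = 3 * TILE_SIZE

#: The six per-tile texture summaries averaged over graph nodes.
TEXTURE_SUMMARY_NAMES = (
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "lbp_entropy",
    "intensity_mean",
)

GRAPH_FEATURE_NAMES: tuple[str, ...] = (
    # texture averages (random geometric construct, degree >= 1 nodes)
    *(f"tex_{n}_avg" for n in TEXTURE_SUMMARY_NAMES),
    # local node configuration (spectral construct)
    "node_count",
    "edge_count",
    "degree_mean",
    "degree_variance",
    "clustering_coefficient",
    "cross_class_edge_fraction",
    "algebraic_connectivity",
    # global connectivity (minimum spanning tree construct)
    "n_components",
    "largest_component_fraction",
    "mst_total_length",
    "mst_mean_edge_length",
    "mst_edge_length_variance",
    "mst_diameter",
    "mean_nn_distance",
)
assert len(GRAPH_FEATURE_NAMES) == 20


def texture_summary(features: np.ndarray, registry) -> np.ndarray:
    """Reduce one 80-feature tile vector to the six node-level summaries.

    LBP entropy is the Shannon entropy of the tile's 10-bin LBP histogram;
    intensity mean is the lower-order histogram mean.
    """
    lbp_names = [f"lbp_u{b}" for b in range(9)] + ["lbp_nonuniform"]
    p = np.array([features[registry.index(n)] for n in lbp_names])
    nz = p[p > 0]
    lbp_entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    return np.array(
        [
            features[registry.index("glcm_contrast")],
            features[registry.index("glcm_correlation")],
            features[registry.index("glcm_energy")],
            features[registry.index("glcm_homogeneity")],
            lbp_entropy,
            features[registry.index("hist_mean")],
        ]
    )


@dataclass
class TileCluster:
    """A connected same-class component of the histology map."""

    cluster_id: str
    class_id: int
    member_cells: list[tuple[int, int]]  # (row, col)
    centroid: tuple[float, float]  # (x, y) pixels
    mean_texture: np.ndarray = field(default_factory=lambda: np.zeros(len(TEXTURE_SUMMARY_NAMES)))


_EIGHT_CONN = np.ones((3, 3), dtype=int)


def find_clusters(
    hmap: HistologyMap,
    cls: HistologyClass | int,
    cell_textures: dict[tuple[int, int], np.ndarray] | None = None,
) -> list[TileCluster]:
    """8-connected components of ``cls`` cells; centroids are the mean of
    member tile centers in level-0 pixels."""
    class_id = cls.id if isinstance(cls, HistologyClass) else int(cls)
    mask = hmap.grid == class_id
    if not mask.any():
        return []
    labeled, n = ndimage.label(mask, structure=_EIGHT_CONN)
    clusters = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labeled == lab)
        cx = float((cols + 0.5).mean() * TILE_SIZE)
        cy = float((rows + 0.5).mean() * TILE_SIZE)
        cells = list(zip(rows.tolist(), cols.tolist()))
        if cell_textures:
            texs = [cell_textures[rc] for rc in cells if rc in cell_textures]
            mean_tex = (np.mean(texs, axis=0) if texs
                        else np.zeros(len(TEXTURE_SUMMARY_NAMES)))
        else:
            mean_tex = np.zeros(len(TEXTURE_SUMMARY_NAMES))
        clusters.append(
            TileCluster(f"{hmap.slide_id}_c{class_id}_k{lab}", class_id, cells, (cx, cy), mean_tex)
        )
    return clusters


@dataclass
class TMEGraph:
    """Simple undirected graph over the clusters of one class pair."""

    patient_id: str
    class_pair: tuple[int, int]  # sorted class ids
    graph: nx.Graph


def build_pair_graph(
    clusters_a: list[TileCluster],
    clusters_b: list[TileCluster],
    radius: float = DEFAULT_RADIUS,
    patient_id: str = "patient",
) -> TMEGraph:
    """Random geometric graph: nodes = clusters of both classes, edges where
    centroid distance <= radius. Self-pairs (A == B) use the single cluster set."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    nodes = list(clusters_a)
    if clusters_b is not clusters_a:
        nodes += list(clusters_b)
    g = nx.Graph()
    for i, c in enumerate(nodes):
        g.add_node(i, pos=c.centroid, class_id=c.class_id, texture=c.mean_texture,
                   cells=c.member_cells)
    pos = np.array([c.centroid for c in nodes]) if nodes else np.zeros((0, 2))
    if len(nodes) > 1:
        d = cdist(pos, pos)
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if d[i, j] <= radius:
                    g.add_edge(i, j, weight=float(d[i, j]))
    ids = sorted({c.class_id for c in nodes}) or [0, 0]
    pair = (ids[0], ids[-1])
    return TMEGraph(patient_id, pair, g)


def _mst_stats(g: nx.Graph) -> tuple[float, float, float, float]:
    """(total length, mean edge length, edge-length variance, diameter in
    edges) of the Euclidean minimum spanning forest."""
    forest = nx.minimum_spanning_tree(g, weight="weight")
    lengths = np.array([d["weight"] for _, _, d in forest.edges(data=True)])
    if lengths.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    diameter = 0
    for comp in nx.connected_components(forest):
        if len(comp) > 1:
            sub = forest.subgraph(comp)
            ecc = nx.eccentricity(sub)  # hop counts
            diameter = max(diameter, max(ecc.values()))
    return float(lengths.sum()), float(lengths.mean()), float(lengths.var()), float(diameter)


def graph_features(tme: TMEGraph) -> np.ndarray:
    """The 20-feature vector of one pair graph (order:
    :data:`GRAPH_FEATURE_NAMES`). Empty graph -> zeros; single node -> zeros
    except node count."""
    g = tme.graph
    n = g.number_of_nodes()
    out = np.zeros(len(GRAPH_FEATURE_NAMES))
    names = GRAPH_FEATURE_NAMES
    if n == 0:
        return out
    out[names.index("node_count")] = n
    if n == 1:
        return out

    # texture averages over interacting (degree >= 1) nodes
    connected = [v for v in g if g.degree(v) >= 1]
    if connected:
        tex = np.mean([g.nodes[v]["texture"] for v in connected], axis=0)
        out[: len(TEXTURE_SUMMARY_NAMES)] = tex

    degrees = np.array([d for _, d in g.degree()])
    m = g.number_of_edges()
    out[names.index("edge_count")] = m
    out[names.index("degree_mean")] = degrees.mean()
    out[names.index("degree_variance")] = degrees.var()
    out[names.index("clustering_coefficient")] = nx.average_clustering(g) if m else 0.0
    if m:
        cross = sum(1 for u, v in g.edges()
                    if g.nodes[u]["class_id"] != g.nodes[v]["class_id"])
        out[names.index("cross_class_edge_fraction")] = cross / m

    comps = list(nx.connected_components(g))
    largest = max(comps, key=len)
    if len(largest) > 1:
        lap = nx.laplacian_matrix(g.subgraph(largest), weight=None).toarray()
        eig = np.linalg.eigvalsh(lap)
        out[names.index("algebraic_connectivity")] = float(eig[1])

    out[names.index("n_components")] = len(comps)
    out[names.index("largest_component_fraction")] = len(largest) / n
    total, mean_len, var_len, diam = _mst_stats(g)
    out[names.index("mst_total_length")] = total
    out[names.index("mst_mean_edge_length")] = mean_len
    out[names.index("mst_edge_length_variance")] = var_len
    out[names.index("mst_diameter")] = diam

    pos = np.array([g.nodes[v]["pos"] for v in g])
    d = cdist(pos, pos)
    np.fill_diagonal(d, np.inf)
    out[names.index("mean_nn_distance")] = float(d.min(axis=1).mean())
    return out


def class_pairs(classes: tuple = TISSUE_CLASSES) -> list[tuple[int, int]]:
    """All unordered pairs of tissue-class ids (120 for 16 classes)."""
    ids = sorted(c.id if isinstance(c, HistologyClass) else int(c) for c in classes)
    return list(combinations(ids, 2))


def pair_feature_columns(classes: tuple = TISSUE_CLASSES) -> list[str]:
    """Fixed column order for the patient x (pair, feature) matrix."""
    return [
        f"p{a}-{b}|{feat}"
        for a, b in class_pairs(classes)
        for feat in GRAPH_FEATURE_NAMES
    ]


def all_pair_features(
    hmap: HistologyMap,
    cell_textures: dict[tuple[int, int], np.ndarray] | None = None,
    radius: float = DEFAULT_RADIUS,
    classes: tuple = TISSUE_CLASSES,
    patient_id: str = "patient",
) -> np.ndarray:
    """Concatenated 20-feature vectors over all unordered class pairs."""
    by_class = {
        (c.id if isinstance(c, HistologyClass) else int(c)): find_clusters(hmap, c, cell_textures)
        for c in classes
    }
    blocks = []
    for a, b in class_pairs(classes):
        tme = build_pair_graph(by_class[a], by_class[b], radius=radius, patient_id=patient_id)
        blocks.append(graph_features(tme))
    return np.concatenate(blocks)
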