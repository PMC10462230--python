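import numpy as np
import pytest

from tmegraph.texture_features import FeatureRegistry, extract_features, filter_features
from tmegraph.tile_prep import hematoxylin_channel
from tmegraph.tme_graph import all_pair_features
from tmegraph.synthetic import CohortSpec, make_cohort, make_tile_dataset


@pytest.fixture(scope="session")
def tile_dataset():
    """Balanced 17-class synthetic tile set with its 80-feature matrix and
    the training-fit retained mask (shared: feature extraction dominates
    runtime)."""
    tiles, labels = make_tile_dataset(tiles_per_class=12, seed=42)
    registry = FeatureRegistry.default()
    X = np.stack([extract_features(hematoxylin_channel(t.rgb), registry) for t in tiles])
    retained = filter_features(X, registry)
    return tiles, labels, X, retained, registry


@pytest.fixture(scope="session")
def strong_cohort():
    """Map-level synthetic cohort at the default (strong) spatial effect,
    with its patient x (pair, feature) matrix."""
    cohort = make_cohort(CohortSpec(seed=7))
    X = np.stack([
        all_pair_features(p.hmap, p.cell_textures, patient_id=p.patient_id)
        for p in cohort.patients
    ])
    return cohort, X
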