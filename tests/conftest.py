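import numpy as np
import pytest

import rhopocket as rp


@pytest.fixture(scope="session")
def toy_pocket():
    """A deterministic 24-residue toy pocket with its sequence."""
    return rp.make_toy_pocket(seed=42, n_residues=24)


@pytest.fixture(scope="session")
def featurized_pockets():
    """Ten featurized toy pockets (identity indices, full-structure SASA)."""
    items = []
    for s in range(10):
        st, _ = rp.make_toy_pocket(seed=100 + s, n_residues=24)
        items.append(rp.featurize_structure(st, pocket_indices=st.residue_indices()))
    return items


@pytest.fixture(scope="session")
def normalized_graphs(featurized_pockets):
    stats = rp.fit_normalizer([fp.features for fp in featurized_pockets])
    return rp.graphs_from_featurized(featurized_pockets, stats), stats


@pytest.fixture(scope="session")
def planted_labels(normalized_graphs):
    graphs, _ = normalized_graphs
    means = np.vstack([g.node_features.mean(axis=0) for g in graphs])
    coeffs = rp.random_planted_coeffs(means, seed=3)
    labels = rp.plant_labels(graphs, coeffs, noise_sigma=0.0, seed=4)
    return labels, coeffs


def random_graph(rng, n_nodes, n_features, p_edge=0.5):
    """A random symmetric MolecularGraph for layer-oracle tests."""
    x = rng.normal(size=(n_nodes, n_features))
    pairs = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    if pairs:
        w = rng.uniform(0.5, 2.0, size=len(pairs))
        edges = np.array(pairs + [(j, i) for i, j in pairs])
        weights = np.concatenate([w, w])
    else:
        edges = np.empty((0, 2), dtype=int)
        weights = np.empty(0)
    return rp.MolecularGraph(x, edges, weights, graph_id="rand")
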