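"""Self-contained synthetic experiments exercised by tests and reporting.

Each experiment builds its own fixtures, runs the full pipeline and
returns a plain dict of numbers.  The problem sizes are chosen for a
single CPU (small pockets, a few hundred graphs); the methods note
documents them as the package's study conditions.
"""

from __future__ import annotations

import numpy as np

from . import fixtures
from .features import fit_normalizer
from .pipeline import featurize_structure, graphs_from_featurized
from .training import TrainConfig, evaluate, train


def _featurized_set(n: int, n_residues: int, seed0: int):
    items = []
    for s in range(n):
        st, _ = fixtures.make_toy_pocket(seed=seed0 + s, n_residues=n_residues)
        items.append(featurize_structure(st, pocket_indices=st.residue_indices()))
    return items


def parameter_recovery(
    seed: int = 0,
    n_train: int = 200,
    n_test: int = 50,
    n_residues: int = 8,
    noise_sigma: float = 2.0,
    epochs: int = 600,
) -> dict:
    """Planted affine labels + Gaussian noise; how close does the trained
    model's test MAE come to the L1-optimal floor σ·√(2/π)?

    Labels are an affine function of the per-graph mean node feature
    vector (σ = 2 nm noise).  Training is full-batch for determinism.
    """
    base = (seed * 100_003) % 2**31
    items = _featurized_set(n_train + n_test, n_residues, base + 1000)
    train_items, test_items = items[:n_train], items[n_train:]
    stats = fit_normalizer([fp.features for fp in train_items])
    tg = graphs_from_featurized(train_items, stats)
    eg = graphs_from_featurized(test_items, stats)
    means = np.vstack([g.node_features.mean(axis=0) for g in tg])
    coeffs = fixtures.random_planted_coeffs(means, seed=base + 11)
    y_tr = fixtures.plant_labels(tg, coeffs, noise_sigma, seed=base + 12)
    y_te = fixtures.plant_labels(eg, coeffs, noise_sigma, seed=base + 13)
    cfg = TrainConfig(seed=seed, epochs=epochs, batch_size=n_train)
    params, history = train(tg, y_tr, cfg)
    m_test = evaluate(params, eg, y_te)
    m_train = evaluate(params, tg, y_tr)
    floor = noise_sigma * np.sqrt(2.0 / np.pi)
    return {
        "test_mae_nm": m_test.mean_nm,
        "test_median_nm": m_test.median_nm,
        "train_mae_nm": m_train.mean_nm,
        "l1_optimal_floor_nm": float(floor),
        "mae_over_floor": m_test.mean_nm / floor,
        "final_train_loss_nm": history[-1],
        "n_train": n_train,
        "n_test": n_test,
    }


def neighbor_heterogeneity_labels(
    graphs, column: int, beta: float = 6.0,
    center_nm: float = 550.0, spread_nm: float = 40.0,
) -> np.ndarray:
    """Labels that reward attention: per node, the gap between a softmax-
    weighted (temperature β) and the plain mean of its neighbours' values
    of one atom-level feature; averaged over nodes, standardized to a
    spectral range.  A convolution computes plain neighbour means; the
    softmax gap is exactly the kind of neighbour re-weighting an
    attention layer can express."""
    vals = []
    for g in graphs:
        f = g.node_features[:, column]
        acc = []
        for i in range(g.n_nodes):
            nb = g.edges[g.edges[:, 1] == i, 0]
            if len(nb) == 0:
                continue
            fn = f[nb]
            w = np.exp(beta * (fn - fn.max()))
            w /= w.sum()
            acc.append(float((w * fn).sum() - fn.mean()))
        vals.append(np.mean(acc))
    vals = np.asarray(vals)
    std = vals.std()
    if std == 0:
        raise ValueError("heterogeneity statistic is constant; pick an atom-level column")
    return center_nm + spread_nm * (vals - vals.mean()) / std


def attention_advantage(
    seed: int = 0,
    n_seeds: int = 5,
    n_train: int = 40,
    n_test: int = 20,
    n_residues: int = 6,
    epochs: int = 250,
) -> dict:
    """Paired attention-on vs attention-off runs on neighbour-heterogeneity
    labels, seed-averaged.  Returns mean test MAE per architecture."""
    base = (seed * 99_991) % 2**31
    err_gat, err_gcn = [], []
    for rep in range(n_seeds):
        items = _featurized_set(n_train + n_test, n_residues,
                                base + 20_000 + rep * 1_000)
        ti, ei = items[:n_train], items[n_train:]
        stats = fit_normalizer([fp.features for fp in ti])
        tg = graphs_from_featurized(ti, stats)
        eg = graphs_from_featurized(ei, stats)
        retained = np.array(ti[0].features.schema.column_names)[stats.retained_mask]
        col = list(retained).index("partial_charge")
        y = neighbor_heterogeneity_labels(tg + eg, col)
        y_tr, y_te = y[:n_train], y[n_train:]
        cfg = TrainConfig(seed=rep, epochs=epochs, batch_size=n_train)
        p_gat, _ = train(tg, y_tr, cfg, attention=True)
        p_gcn, _ = train(tg, y_tr, cfg, attention=False)
        err_gat.append(evaluate(p_gat, eg, y_te).mean_nm)
        err_gcn.append(evaluate(p_gcn, eg, y_te).mean_nm)
    return {
        "attention_on_mae_nm": float(np.mean(err_gat)),
        "attention_off_mae_nm": float(np.mean(err_gcn)),
        "per_seed_on": [float(x) for x in err_gat],
        "per_seed_off": [float(x) for x in err_gcn],
        "n_seeds": n_seeds,
    }


def synthetic_benchmark(
    seed: int = 0,
    n_wt_groups: int = 20,
    mutants_per_wt: int = 3,
    n_test_wt: int = 5,
    n_residues: int = 8,
    noise_sigma: float = 2.0,
    epochs: int = 400,
) -> dict:
    """End-to-end protocol on a synthetic mutant-family dataset: wild-type-
    grouped split, train-only normalization, training, evaluation in both
    units, and the train/test label-distribution KS similarity."""
    from .fixtures import FixtureConfig, make_dataset
    from .training import DatasetRecord, ks_similarity, split_by_wildtype

    base = (seed * 104_729) % 2**31
    cfg_fix = FixtureConfig(
        n_wt_groups=n_wt_groups, mutants_per_wt=mutants_per_wt,
        n_residues=n_residues, noise_sigma=noise_sigma, seed=base,
    )
    rec_dicts, structures = make_dataset(cfg_fix)
    items = {
        rid: featurize_structure(st, pocket_indices=st.residue_indices())
        for rid, st in structures.items()
    }
    from .graphs import build_graph

    raw_graphs = {
        rid: build_graph(fp.pocket, fp.features.values, graph_id=rid)
        for rid, fp in items.items()
    }
    order = [r["seq_id"] for r in rec_dicts]
    means = np.vstack([raw_graphs[rid].node_features.mean(axis=0) for rid in order])
    coeffs = fixtures.random_planted_coeffs(means, seed=base + 21)
    labels = fixtures.plant_labels(
        [raw_graphs[rid] for rid in order], coeffs, noise_sigma, seed=base + 22
    )
    records = [
        DatasetRecord(r["seq_id"], r["wt_group"], r["sequence"], float(y),
                      method="synthetic")
        for r, y in zip(rec_dicts, labels)
    ]
    train_recs, test_recs = split_by_wildtype(records, n_test_wt=n_test_wt,
                                              seed=seed)
    stats = fit_normalizer([items[r.seq_id].features for r in train_recs])
    tg = graphs_from_featurized([items[r.seq_id] for r in train_recs], stats)
    eg = graphs_from_featurized([items[r.seq_id] for r in test_recs], stats)
    y_tr = np.array([r.lambda_max for r in train_recs])
    y_te = np.array([r.lambda_max for r in test_recs])
    cfg = TrainConfig(seed=seed, epochs=epochs, batch_size=len(tg))
    params, history = train(tg, y_tr, cfg)
    m = evaluate(params, eg, y_te)
    return {
        "test_median_nm": m.median_nm,
        "test_mean_nm": m.mean_nm,
        "test_median_ev": m.median_ev,
        "test_mean_ev": m.mean_ev,
        "ks_train_test": ks_similarity(y_tr, y_te),
        "final_train_loss_nm": history[-1],
        "n_train": len(tg),
        "n_test": len(eg),
    }


def overfit_sanity(seed: int = 0, n_graphs: int = 10, epochs: int = 1000) -> dict:
    """Capacity check: memorize a handful of noiseless planted labels."""
    base = (seed * 7_919) % 2**31
    items = _featurized_set(n_graphs, 24, base + 100)
    stats = fit_normalizer([fp.features for fp in items])
    graphs = graphs_from_featurized(items, stats)
    means = np.vstack([g.node_features.mean(axis=0) for g in graphs])
    coeffs = fixtures.random_planted_coeffs(means, seed=base + 3)
    labels = fixtures.plant_labels(graphs, coeffs, noise_sigma=0.0, seed=base + 4)
    cfg = TrainConfig(seed=seed, epochs=epochs)
    params, history = train(graphs, labels, cfg)
    m = evaluate(params, graphs, labels)
    return {
        "train_median_nm": m.median_nm,
        "train_mean_nm": m.mean_nm,
        "first_epoch_loss_nm": history[0],
        "final_epoch_loss_nm": history[-1],
        "n_graphs": n_graphs,
        "epochs": epochs,
    }
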