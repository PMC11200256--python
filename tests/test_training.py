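"""Units, loss, wild-type splitting, KS statistic, training behaviour,
evaluation metrics and ablation plumbing."""

import numpy as np
import pytest
import scipy.stats

import rhopocket as rp
from rhopocket.training import (
    HC_EV_NM,
    DatasetRecord,
    TrainConfig,
    TrainingDiverged,
    l1_loss,
)


class TestUnits:
    def test_hc_definitional_point(self):
        assert rp.nm_to_ev(HC_EV_NM) == pytest.approx(1.0)

    @pytest.mark.parametrize("x", [400.0, 550.0, 700.0])
    def test_round_trip(self, x):
        assert rp.ev_to_nm(rp.nm_to_ev(x)) == pytest.approx(x, rel=1e-9)

    def test_500nm_energy(self):
        assert rp.nm_to_ev(500.0) == pytest.approx(2.4796840, rel=1e-6)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rp.nm_to_ev(0.0)
        with pytest.raises(ValueError):
            rp.ev_to_nm(-1.0)


class TestL1Loss:
    def test_zero_and_simple(self):
        assert l1_loss(530.0, 530.0) == 0.0
        assert l1_loss(540.0, 530.0) == 10.0

    def test_symmetric_and_batch_mean(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert l1_loss(a, b) == pytest.approx(l1_loss(b, a))
        assert l1_loss(a, b) == pytest.approx(np.abs(a - b).mean())


def make_records(n_groups, per_group, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for g in range(n_groups):
        lam = float(rng.uniform(450, 650))
        recs.append(DatasetRecord(f"wt{g}", f"wt{g}", "ACDK", lam))
        for m in range(per_group):
            recs.append(
                DatasetRecord(f"wt{g}m{m}", f"wt{g}", "ACDK",
                              float(np.clip(lam + rng.normal(0, 5), 300, 800)))
            )
    return recs


class TestSplit:
    def test_75_groups_give_10_test_groups(self):
        recs = make_records(75, 3)
        train, test = rp.split_by_wildtype(recs, n_test_wt=10, seed=1)
        assert len({r.wt_group for r in test}) == 10
        assert len({r.wt_group for r in train}) == 65

    @pytest.mark.parametrize("seed", range(100))
    def test_no_group_straddles_the_split(self, seed):
        recs = make_records(20, 2, seed=seed)
        train, test = rp.split_by_wildtype(recs, n_test_wt=5, seed=seed)
        assert {r.wt_group for r in train}.isdisjoint({r.wt_group for r in test})
        assert {r.seq_id for r in train}.isdisjoint({r.seq_id for r in test})

    def test_same_seed_identical_split(self):
        recs = make_records(30, 2)
        s1 = rp.split_by_wildtype(recs, seed=7)
        s2 = rp.split_by_wildtype(recs, seed=7)
        assert [r.seq_id for r in s1[0]] == [r.seq_id for r in s2[0]]
        assert [r.seq_id for r in s1[1]] == [r.seq_id for r in s2[1]]

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="wild-type groups"):
            rp.split_by_wildtype(make_records(5, 1), n_test_wt=10)


class TestDatasetRecords:
    def test_out_of_window_lambda_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            DatasetRecord("x", "x", "ACDK", 250.0)

    def test_csv_roundtrip(self, tmp_path):
        recs = make_records(3, 1)
        import csv

        p = tmp_path / "d.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["seq_id", "wt_group", "sequence", "lambda_max_nm", "method"])
            for r in recs:
                w.writerow([r.seq_id, r.wt_group, r.sequence, r.lambda_max, "synthetic"])
        back = rp.load_dataset(p)
        assert [r.seq_id for r in back] == [r.seq_id for r in recs]
        assert back[0].lambda_max == pytest.approx(recs[0].lambda_max)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("seq_id,sequence\na,ACDK\n")
        with pytest.raises(ValueError, match="wt_group"):
            rp.load_dataset(p)


class TestKsSimilarity:
    def test_identical_samples_zero(self):
        assert rp.ks_similarity([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert rp.ks_similarity([1, 2], [10, 11, 12]) == 1.0

    def test_matches_brute_force_cdf_scan(self):
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 4.0]

        def brute(a, b):
            grid = sorted(set(a) | set(b))
            return max(
                abs(sum(x <= g for x in a) / len(a) - sum(x <= g for x in b) / len(b))
                for g in grid
            )

        assert rp.ks_similarity(a, b) == pytest.approx(brute(a, b))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=23)
        b = rng.normal(0.4, 1.3, size=31)
        assert rp.ks_similarity(a, b) == pytest.approx(
            scipy.stats.ks_2samp(a, b).statistic
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rp.ks_similarity([], [1.0])


class TestTrainingBehaviour:
    def test_determinism_same_seed_identical_history(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        cfg = TrainConfig(seed=3, epochs=5)
        _, h1 = rp.train(graphs, labels, cfg)
        _, h2 = rp.train(graphs, labels, cfg)
        assert h1 == h2

    def test_unregularized_descends_at_least_as_fast(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        reg = TrainConfig(seed=0, epochs=40)
        noreg = TrainConfig(seed=0, epochs=40, weight_decay_l2=0.0, l1_alpha=0.0)
        _, h_reg = rp.train(graphs, labels, reg)
        _, h_none = rp.train(graphs, labels, noreg)
        assert h_none[-1] <= h_reg[-1] + 1e-9

    def test_history_finite_and_decreasing_overall(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        _, hist = rp.train(graphs, labels, TrainConfig(seed=1, epochs=60))
        assert np.all(np.isfinite(hist))
        assert hist[-1] < hist[0]
        assert len(hist) == 60

    def test_ev_training_unit(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        cfg = TrainConfig(seed=0, epochs=3, target_units="eV")
        params, _ = rp.train(graphs, labels, cfg)
        assert params.meta["target_units"] == "eV"
        preds = rp.forward(graphs, params)
        assert np.all(preds < 10)  # eV scale, not hundreds of nm

    def test_too_few_graphs_rejected(self, normalized_graphs):
        graphs, _ = normalized_graphs
        with pytest.raises(ValueError):
            rp.train(graphs[:1], np.array([550.0]), TrainConfig(epochs=1))

    def test_divergence_reported_with_epoch(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels = np.full(len(graphs), np.nan)
        with pytest.raises((TrainingDiverged, ValueError)):
            rp.train(graphs, labels, TrainConfig(seed=0, epochs=2))


class TestEvaluate:
    def _trained(self, normalized_graphs, planted_labels, epochs=3):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        params, _ = rp.train(graphs, labels, TrainConfig(seed=0, epochs=epochs))
        return params, graphs, labels

    def test_metrics_consistent_with_errors(self, normalized_graphs, planted_labels):
        params, graphs, labels = self._trained(normalized_graphs, planted_labels)
        m = rp.evaluate(params, graphs, labels)
        assert m.median_nm == pytest.approx(np.median(m.errors_nm))
        assert m.mean_nm == pytest.approx(np.mean(m.errors_nm))
        assert m.std_nm == pytest.approx(np.std(m.errors_nm))

    def test_hand_built_errors_aggregate(self):
        m = rp.Metrics(errors_nm=np.array([2.0, 4.0, 9.0]),
                       errors_ev=np.array([0.01, 0.02, 0.04]))
        assert m.median_nm == 4.0
        assert m.mean_nm == 5.0

    def test_single_record_median_equals_mean(self, normalized_graphs, planted_labels):
        params, graphs, labels = self._trained(normalized_graphs, planted_labels)
        m = rp.evaluate(params, graphs[:1], labels[:1])
        assert m.median_nm == m.mean_nm
        assert m.std_nm == 0.0

    def test_unit_consistency_nm_vs_ev(self, normalized_graphs, planted_labels):
        """eV errors must equal |hc/pred_nm − hc/label_nm| record-wise."""
        params, graphs, labels = self._trained(normalized_graphs, planted_labels)
        m = rp.evaluate(params, graphs, labels)
        preds_nm = rp.forward(graphs, params)
        expected_ev = np.abs(rp.nm_to_ev(preds_nm) - rp.nm_to_ev(labels))
        np.testing.assert_allclose(m.errors_ev, expected_ev, rtol=1e-9)


@pytest.fixture(scope="module")
def sets(featurized_pockets, planted_labels):
    labels, _ = planted_labels
    triples = [
        (fp.pocket, fp.features, float(labels[i]))
        for i, fp in enumerate(featurized_pockets)
    ]
    return triples[:7], triples[7:]


class TestAblation:
    def test_drop_one_runs_per_group(self, sets, featurized_pockets):
        train_set, test_set = sets
        schema = featurized_pockets[0].features.schema
        cfg = TrainConfig(seed=0, epochs=2)
        m = rp.ablate(train_set, test_set, schema, "drop_one", cfg,
                      group="hydropathy")
        assert np.isfinite(m.mean_nm)

    def test_keep_one_single_group(self, sets, featurized_pockets):
        train_set, test_set = sets
        schema = featurized_pockets[0].features.schema
        cfg = TrainConfig(seed=0, epochs=2)
        m = rp.ablate(train_set, test_set, schema, "keep_one", cfg,
                      group="partial atom charge")
        assert np.isfinite(m.mean_nm)

    def test_no_features_mode_finishes_with_finite_metrics(self, sets, featurized_pockets):
        train_set, test_set = sets
        schema = featurized_pockets[0].features.schema
        cfg = TrainConfig(seed=0, epochs=2)
        m = rp.ablate(train_set, test_set, schema, "no_features", cfg)
        assert np.isfinite(m.mean_nm) and np.isfinite(m.mean_ev)

    def test_unknown_group_rejected(self, sets, featurized_pockets):
        train_set, test_set = sets
        schema = featurized_pockets[0].features.schema
        with pytest.raises(KeyError, match="unknown feature group"):
            rp.ablate(train_set, test_set, schema, "drop_one",
                      TrainConfig(epochs=1), group="nope")

    def test_keep_one_with_all_constant_columns_rejected(self, sets, featurized_pockets):
        train_set, test_set = sets
        schema = featurized_pockets[0].features.schema
        # zero out the radius column so the group is constant on train
        import copy

        t2 = []
        for p, fm, y in train_set:
            fm2 = copy.deepcopy(fm)
            col = schema.column_names.index("atomic_radius")
            fm2.values[:, col] = 1.7
            t2.append((p, fm2, y))
        with pytest.raises(ValueError, match="constant"):
            rp.ablate(t2, test_set, schema, "keep_one",
                      TrainConfig(epochs=1), group="atomic radius")

    def test_attention_off_variant_architecture(self, normalized_graphs, planted_labels):
        graphs, _ = normalized_graphs
        labels, _ = planted_labels
        params, _ = rp.attention_off_variant(graphs, labels, TrainConfig(seed=0, epochs=2))
        assert params.architecture_report() == ["GCN", "GCN", "GCN", "GCN"]
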