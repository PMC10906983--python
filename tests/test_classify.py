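import numpy as np
import pandas as pd
import pytest

from netconstraint import classify


def metrics_table(n=100, seed=3):
    """Distinct-valued metric table for seeding tests."""
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"n{i:03d}" for i in range(n)], name="node")
    return pd.DataFrame(
        {
            "degree": rng.integers(1, 30, n),
            "aspl": rng.permutation(np.linspace(2, 8, n)),
            "bc": rng.permutation(np.linspace(0, 0.5, n)),
            "nc": rng.permutation(np.linspace(1, 25, n)),
        },
        index=idx,
    )


class TestSeedLabels:
    def test_seed_counts_on_100_nodes(self):
        seeds = classify.seed_labels(metrics_table())
        counts = seeds.value_counts()
        assert counts["H"] == 1
        assert 1 <= counts["I"] <= 10
        assert 1 <= counts["P"] <= 10

    def test_conflict_priority_h_over_i(self):
        m = metrics_table()
        # force one node to top both the BC and NC rankings
        m.loc["n000", "bc"] = m["bc"].max() + 1
        m.loc["n000", "nc"] = m["nc"].max() + 1
        seeds = classify.seed_labels(m)
        assert seeds["n000"] == "H"

    def test_constant_metric_rejected(self):
        m = metrics_table()
        m["bc"] = 0.5
        with pytest.raises(ValueError, match="constant"):
            classify.seed_labels(m)

    def test_disjoint_single_labels(self):
        seeds = classify.seed_labels(metrics_table())
        assert not seeds.index.duplicated().any()
        assert set(seeds.unique()) <= {"H", "I", "P"}


class TestOversampleMinority:
    def test_balances_to_majority(self, separable_training):
        metrics, seeds = separable_training
        small = pd.concat([seeds[seeds == "H"].iloc[:2],
                           seeds[seeds == "I"], seeds[seeds == "P"]])
        training = classify.oversample_minority(small, metrics, k_neighbors=1,
                                                seed=0)
        counts = training.labels.value_counts()
        assert counts.to_dict() == {"H": 20, "I": 20, "P": 20}
        assert int(training.synthetic.sum()) == 18
        assert (training.labels[training.synthetic] == "H").all()

    def test_balanced_input_unchanged(self, separable_training):
        metrics, seeds = separable_training
        training = classify.oversample_minority(seeds, metrics, seed=0)
        assert not training.synthetic.any()
        assert len(training.features) == len(seeds)

    def test_synthetic_points_are_convex_combinations(self, separable_training):
        metrics, seeds = separable_training
        small = pd.concat([seeds[seeds == "H"].iloc[:6],
                           seeds[seeds == "I"], seeds[seeds == "P"]])
        training = classify.oversample_minority(small, metrics, seed=1)
        real = training.features[~training.synthetic]
        real_h = real.loc[training.labels[~training.synthetic] == "H"].to_numpy()
        for _, row in training.features[training.synthetic].iterrows():
            x = row.to_numpy()
            ok = False
            for i in range(len(real_h)):
                for j in range(len(real_h)):
                    if i == j:
                        continue
                    a, b = real_h[i], real_h[j]
                    seg = b - a
                    denom = seg @ seg
                    if denom == 0:
                        continue
                    u = (x - a) @ seg / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(a + u * seg, x,
                                                              atol=1e-9):
                        ok = True
                        break
                if ok:
                    break
            assert ok, "synthetic row not on a segment between real H rows"

    def test_class_smaller_than_k_rejected(self, separable_training):
        metrics, seeds = separable_training
        small = pd.concat([seeds[seeds == "H"].iloc[:3],
                           seeds[seeds == "I"], seeds[seeds == "P"]])
        with pytest.raises(ValueError, match="smaller k"):
            classify.oversample_minority(small, metrics, k_neighbors=5, seed=0)

    def test_reproducible_under_seed(self, separable_training):
        metrics, seeds = separable_training
        small = pd.concat([seeds[seeds == "H"].iloc[:6],
                           seeds[seeds == "I"], seeds[seeds == "P"]])
        t1 = classify.oversample_minority(small, metrics, seed=7)
        t2 = classify.oversample_minority(small, metrics, seed=7)
        pd.testing.assert_frame_equal(t1.features, t2.features)


class TestCrossValidate:
    def test_separable_seeds_near_perfect(self, separable_training):
        metrics, seeds = separable_training
        training = classify.oversample_minority(seeds, metrics, seed=0)
        reports = classify.cross_validate(training, folds=9, replicates=5, seed=0)
        assert classify.summarize_cv(reports)["mean_accuracy"] >= 0.95

    def test_permuted_labels_at_chance(self, separable_training):
        metrics, seeds = separable_training
        rng = np.random.default_rng(5)
        shuffled = pd.Series(rng.permutation(seeds.to_numpy()),
                             index=seeds.index)
        training = classify.oversample_minority(shuffled, metrics, seed=0)
        reports = classify.cross_validate(training, folds=9, replicates=10,
                                          seed=0)
        acc = classify.summarize_cv(reports)["mean_accuracy"]
        assert abs(acc - 1 / 3) < 0.2  # chance level within Monte-Carlo error

    def test_deterministic_under_seed(self, separable_training):
        metrics, seeds = separable_training
        training = classify.oversample_minority(seeds, metrics, seed=0)
        r1 = classify.cross_validate(training, replicates=2, seed=3)
        r2 = classify.cross_validate(training, replicates=2, seed=3)
        assert [r.fold_accuracies for r in r1] == [r.fold_accuracies for r in r2]

    def test_stratified_requires_large_enough_classes(self, separable_training):
        metrics, seeds = separable_training
        small = pd.concat([seeds[seeds == "H"].iloc[:6],
                           seeds[seeds == "I"], seeds[seeds == "P"]])
        training = classify.TrainingSet(
            features=(metrics.loc[small.index, ["aspl", "bc", "nc"]]),
            labels=small, synthetic=pd.Series(False, index=small.index),
            center=pd.Series(0.0, index=["aspl", "bc", "nc"]),
            scale=pd.Series(1.0, index=["aspl", "bc", "nc"]),
            seed_nodes=small)
        with pytest.raises(ValueError, match="stratif"):
            classify.cross_validate(training, folds=9, replicates=1,
                                    stratified=True, seed=0)


class TestClassifyNodes:
    @pytest.fixture
    def trained(self, separable_training):
        metrics, seeds = separable_training
        training = classify.oversample_minority(seeds, metrics, seed=0)
        return metrics, seeds, training

    def test_centroid_probe_gets_confident_hub_label(self, trained):
        metrics, seeds, training = trained
        probe = metrics.loc[seeds[seeds == "H"].index].mean()
        extended = pd.concat([metrics, probe.to_frame("probe_H").T])
        out = classify.classify_nodes(training, extended, seed=0)
        assert out.loc["probe_H", "label"] == "H"
        assert out.loc["probe_H", "support"] > 0.7

    @pytest.mark.parametrize("threshold,expect_uncertain_all", [(1.0, True), (0.0, False)])
    def test_threshold_bounds(self, trained, threshold, expect_uncertain_all):
        metrics, seeds, training = trained
        rng = np.random.default_rng(0)
        extra = metrics.sample(10, random_state=1) + rng.normal(0, 0.2, (10, 4))
        extra.index = [f"x{i}" for i in range(10)]
        table = pd.concat([metrics, extra])
        out = classify.classify_nodes(training, table,
                                      support_threshold=threshold, seed=0)
        predicted = out[out["source"] == "predicted"]
        if expect_uncertain_all:
            assert (predicted["label"] == "uncertain").all()
            assert predicted["raw_label"].isin(["H", "I", "P"]).all()
        else:
            assert not (predicted["label"] == "uncertain").any()

    def test_uncertain_count_monotone_in_threshold(self, trained, synthetic_metrics):
        metrics, seeds, training = trained
        counts = []
        for t in (0.0, 0.4, 0.6, 0.9, 1.0):
            out = classify.classify_nodes(training, metrics,
                                          support_threshold=t, seed=0)
            counts.append(int((out["label"] == "uncertain").sum()))
        assert counts == sorted(counts)

    def test_seed_nodes_keep_seed_labels(self, trained):
        metrics, seeds, training = trained
        out = classify.classify_nodes(training, metrics, seed=0)
        assert (out.loc[seeds.index, "source"] == "seed").all()
        assert (out.loc[seeds.index, "label"] == seeds).all()


class TestClassifyNetwork:
    def test_pipeline_deterministic(self, synthetic_metrics):
        out1, _ = classify.classify_network(synthetic_metrics, seed=11)
        out2, _ = classify.classify_network(synthetic_metrics, seed=11)
        pd.testing.assert_frame_equal(out1, out2)

    def test_class_bc_ordering(self, synthetic_metrics):
        """Predicted hubs out-rank intermediates out-rank peripherals on BC."""
        out, _ = classify.classify_network(synthetic_metrics, seed=2)
        merged = synthetic_metrics.join(out)
        means = merged.groupby("label")["bc"].mean()
        assert means["H"] > means["I"] > means["P"]
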