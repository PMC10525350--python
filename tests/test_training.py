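import numpy as np
import pytest

from epimci.genome_io import GenomeBins, ValidationError
from epimci.hypergraph import Hyperedge, HyperedgeSet
from epimci.model import ModelConfig
from epimci.sampling import LabeledSample, build_dataset
from epimci.training import (
    PAPER_GRIDS,
    TrainConfig,
    compute_metrics,
    cross_validate,
    enumerate_grid,
    evaluate,
    graph_from_samples,
    grid_search,
    kfold_split,
    mean_metric,
    pairwise_auc,
    train,
)


def toy_dataset(rng, n_bins=30, n_pos=60, seed=0):
    """Small labeled dataset with a planted signal in the embeddings."""
    bins = GenomeBins(("chr1",), (n_bins * 1_000_000,), 1_000_000)
    tuples = set()
    while len(tuples) < n_pos:
        order = int(rng.integers(3, 7))
        # positives live in the first half of the genome
        tuples.add(tuple(sorted(rng.choice(n_bins // 2, size=order, replace=False).tolist())))
    positives = HyperedgeSet(tuple(Hyperedge(t, 1) for t in sorted(tuples)), n_bins)
    samples = build_dataset(positives, bins, seed=seed)
    embeddings = rng.normal(size=(n_bins, 8))
    embeddings[: n_bins // 2, 0] += 3.0  # planted marker dimension
    return samples, embeddings, n_bins


class TestKFold:
    def make_samples(self, n, rng):
        samples = []
        seen = set()
        while len(samples) < n:
            order = int(rng.integers(3, 7))
            t = tuple(sorted(rng.choice(200, size=order, replace=False).tolist()))
            if t in seen:
                continue
            seen.add(t)
            samples.append(LabeledSample(t, int(rng.integers(2))))
        return samples

    def test_fold_sizes(self, rng):
        samples = self.make_samples(10, rng)
        folds = kfold_split(samples, 5, seed=0)
        assert all(len(test) == 2 for _, test in folds)

    def test_partition_property(self, rng):
        samples = self.make_samples(53, rng)
        folds = kfold_split(samples, 5, seed=1)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test.tolist()) == list(range(53))
        for train_idx, test_idx in folds:
            assert set(train_idx).isdisjoint(test_idx)
            assert len(train_idx) + len(test_idx) == 53

    def test_stratification(self, rng):
        # per-fold positive fraction within 5% of global at n = 1500
        samples = []
        seen = set()
        while len(samples) < 1500:
            order = int(rng.integers(3, 7))
            t = tuple(sorted(rng.choice(300, size=order, replace=False).tolist()))
            if t in seen:
                continue
            seen.add(t)
            samples.append(LabeledSample(t, 1 if len(samples) % 3 == 0 else 0))
        global_frac = np.mean([s.label for s in samples])
        for _, test_idx in kfold_split(samples, 5, seed=2):
            fold_frac = np.mean([samples[i].label for i in test_idx])
            assert abs(fold_frac - global_frac) < 0.05

    def test_too_few_samples(self, rng):
        with pytest.raises(ValidationError):
            kfold_split(self.make_samples(3, rng), 5)


class TestMetrics:
    def test_perfect_separation(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(labels, scores)
        assert m["auc"] == 1.0 and m["aupr"] == 1.0

    def test_random_scores_null_auc(self, rng):
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.uniform(size=10_000)
        m = compute_metrics(labels, scores)
        assert abs(m["auc"] - 0.5) < 0.02

    def test_all_predicted_positive(self):
        labels = np.array([1, 0, 0, 1, 0])
        scores = np.full(5, 0.9)
        m = compute_metrics(labels, scores)
        assert m["recall"] == 1.0
        assert m["precision"] == pytest.approx(0.4)

    def test_single_class_auc_is_none(self):
        m = compute_metrics(np.ones(4), np.array([0.1, 0.6, 0.7, 0.9]))
        assert m["auc"] is None and m["aupr"] is None
        assert m["accuracy"] == pytest.approx(0.75)

    def test_auc_matches_pairwise_oracle(self, rng):
        labels = rng.integers(0, 2, size=500)
        labels[:5] = 1
        labels[5:10] = 0
        scores = rng.uniform(size=500).round(2)  # force some ties
        m = compute_metrics(labels, scores)
        assert m["auc"] == pytest.approx(pairwise_auc(labels, scores), abs=1e-12)


class TestTrain:
    def test_loss_decreases_and_deterministic(self, rng):
        samples, embeddings, n_bins = toy_dataset(rng)
        config = TrainConfig(epochs=15, batch_size=32, dropout=0.1, seed=3)
        graph = graph_from_samples(samples, n_bins)
        model_config = ModelConfig(feature_dim=8, embed_dim=8, n_heads=2, dropout=0.1)
        r1 = train(samples, embeddings, graph, config, model_config)
        r2 = train(samples, embeddings, graph, config, model_config)
        assert r1.report.loss_curve[-1] < r1.report.loss_curve[0]
        np.testing.assert_array_equal(
            r1.params["head_w"].data, r2.params["head_w"].data
        )
        e1 = evaluate(r1.params, samples, embeddings, graph)
        e2 = evaluate(r2.params, samples, embeddings, graph)
        assert e1.overall == e2.overall

    def test_noshe_ignores_lambda_kl(self, rng):
        # noSHE has no KL path: runs with different lambda are identical
        samples, embeddings, n_bins = toy_dataset(rng)
        graph = graph_from_samples(samples, n_bins)
        model_config = ModelConfig(feature_dim=8, embed_dim=8, n_heads=2, variant="noSHE", dropout=0.0)
        out = []
        for lam in (0.0, 5.0):
            config = TrainConfig(epochs=4, batch_size=32, dropout=0.0, lambda_kl=lam, seed=4, variant="noSHE")
            out.append(train(samples, embeddings, graph, config, model_config))
        np.testing.assert_array_equal(out[0].params["head_w"].data, out[1].params["head_w"].data)
        assert out[0].report.loss_curve == out[1].report.loss_curve

    def test_embedding_coverage_checked(self, rng):
        samples, _, n_bins = toy_dataset(rng)
        graph = graph_from_samples(samples, n_bins)
        with pytest.raises(ValidationError):
            train(samples, np.zeros((3, 8)), graph, TrainConfig(epochs=1))

    def test_evaluate_per_order_slices(self, rng):
        samples, embeddings, n_bins = toy_dataset(rng)
        graph = graph_from_samples(samples, n_bins)
        config = TrainConfig(epochs=2, batch_size=32, seed=5)
        model_config = ModelConfig(feature_dim=8, embed_dim=8, n_heads=2, dropout=0.0)
        result = train(samples, embeddings, graph, config, model_config)
        report = evaluate(result.params, samples, embeddings, graph)
        orders = {s.order for s in samples}
        assert set(report.per_order) == orders
        for metrics in report.per_order.values():
            for name in ("accuracy", "precision", "recall", "f1"):
                assert 0.0 <= metrics[name] <= 1.0


class TestCrossValidate:
    def test_reports_per_fold(self, rng):
        samples, embeddings, n_bins = toy_dataset(rng, n_pos=40)
        config = TrainConfig(epochs=2, batch_size=32, folds=3, seed=6)
        model_config = ModelConfig(feature_dim=8, embed_dim=8, n_heads=2, dropout=0.0)
        reports = cross_validate(samples, embeddings, n_bins, config, model_config)
        assert len(reports) == 3
        assert 0.0 <= mean_metric(reports, "auc") <= 1.0


class TestGridSearch:
    def test_paper_grid_enumerates_75(self):
        combos = enumerate_grid(PAPER_GRIDS)
        assert len(combos) == 3 * 5 * 5

    def test_singleton_grid(self):
        assert len(enumerate_grid({"dropout": (0.1,)})) == 1

    def test_best_is_argmax(self, rng):
        samples, embeddings, n_bins = toy_dataset(rng, n_pos=30)
        base = TrainConfig(epochs=2, batch_size=32, folds=3, seed=7)
        grids = {"learning_rate": (0.001, 0.01)}
        table, best = grid_search(samples, embeddings, n_bins, base, grids)
        assert len(table) == 2
        assert best["mean_auc"] == max(row["mean_auc"] for row in table)

    def test_empty_grid_rejected(self, rng):
        samples, embeddings, n_bins = toy_dataset(rng, n_pos=30)
        with pytest.raises(ValidationError):
            grid_search(samples, embeddings, n_bins, TrainConfig(), {})


class TestTrainConfigValidation:
    def test_bad_batch_size(self):
        with pytest.raises(ValidationError):
            TrainConfig(batch_size=0)

    def test_bad_learning_rate(self):
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=-1.0)
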