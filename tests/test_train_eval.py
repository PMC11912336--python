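import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from toxgat import gat_net, train_eval
from toxgat.mol_graph import featurize
from toxgat.synthetic_bench import SyntheticConfig, make_pretrain_set


class TestMetrics:
    def test_rmse_zero_on_equal(self):
        assert train_eval.metric_rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_rmse_hand_value(self):
        assert train_eval.metric_rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_roc_auc_perfect(self):
        assert train_eval.metric_roc_auc([0.9, 0.1], [1, 0]) == 1.0

    def test_roc_auc_all_tied(self):
        assert train_eval.metric_roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5

    def test_roc_auc_matches_sklearn(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, size=200)
        assert train_eval.metric_roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_roc_auc_with_ties_matches_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 4, size=100).astype(float)  # many ties
        labels = rng.integers(0, 2, size=100)
        assert train_eval.metric_roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            train_eval.metric_rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            train_eval.metric_roc_auc([1.0], [1, 0])

    def test_single_class_fails(self):
        with pytest.raises(ValueError):
            train_eval.metric_roc_auc([0.1, 0.9], [1, 1])


class TestStratifiedKFold:
    def test_imbalanced_172_116_fold_balance(self):
        labels = np.array([1] * 172 + [0] * 116)
        folds = train_eval.stratified_kfold(labels, k=10, seed=0)
        assert sorted(np.unique(folds)) == list(range(10))
        for f in range(10):
            in_fold = labels[folds == f]
            assert int((in_fold == 1).sum()) in (17, 18)
            assert int((in_fold == 0).sum()) in (11, 12)

    def test_folds_partition_index_set(self):
        labels = np.array([0, 1] * 20)
        folds = train_eval.stratified_kfold(labels, k=5, seed=1)
        assert folds.shape == (40,)
        assert np.bincount(folds).sum() == 40

    def test_single_class_fails(self):
        with pytest.raises(ValueError):
            train_eval.stratified_kfold(np.ones(20), k=2)

    def test_k_exceeding_class_count_fails(self):
        labels = np.array([1, 1, 0, 0])
        with pytest.raises(ValueError):
            train_eval.stratified_kfold(labels, k=4)

    def test_reproducible(self):
        labels = np.array([0, 1] * 30)
        a = train_eval.stratified_kfold(labels, k=3, seed=9)
        b = train_eval.stratified_kfold(labels, k=3, seed=9)
        np.testing.assert_array_equal(a, b)


class _OraclePredictor:
    """Scores equal to the true labels."""

    def predict_records(self, records):
        return np.array([t for _, t in records], dtype=float)


class _RandomPredictor:
    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def predict_records(self, records):
        return self.rng.random(len(records))


def _fake_dataset(n, seed=0, pos_fraction=0.5):
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < pos_fraction).astype(float)
    return [(f"mol{i}", float(labels[i])) for i in range(n)]


class TestRepeatedSplitEval:
    def test_perfect_oracle(self):
        dataset = _fake_dataset(100)
        report = train_eval.repeated_split_eval(
            lambda recs, s: _OraclePredictor(), dataset, n_splits=5, seed=0
        )
        assert report.mean == 1.0
        assert report.sd == 0.0

    def test_random_predictor_near_half(self):
        dataset = _fake_dataset(1000, seed=1)
        report = train_eval.repeated_split_eval(
            lambda recs, s: _RandomPredictor(s), dataset, n_splits=10, seed=2
        )
        assert abs(report.mean - 0.5) < 0.1

    def test_single_split_sd_zero_with_warning(self):
        dataset = _fake_dataset(50, seed=3)
        with pytest.warns(UserWarning, match="single split"):
            report = train_eval.repeated_split_eval(
                lambda recs, s: _OraclePredictor(), dataset, n_splits=1, seed=0
            )
        assert report.sd == 0.0

    def test_single_class_dataset_fails(self):
        dataset = [(f"m{i}", 1.0) for i in range(20)]
        with pytest.raises(ValueError):
            train_eval.repeated_split_eval(
                lambda recs, s: _OraclePredictor(), dataset, n_splits=1
            )

    def test_report_mean_sd_recomputable(self):
        report = train_eval.EvalReport(metric="roc_auc", per_split=[0.8, 0.9, 1.0])
        assert report.mean == pytest.approx(np.mean([0.8, 0.9, 1.0]))
        assert report.sd == pytest.approx(np.std([0.8, 0.9, 1.0], ddof=1))


SMALL = dict(embed_dim=16, n_conv_layers=2, n_global_heads=4)


def _tiny_regression_records():
    smiles = ["CCO", "CCC", "CCN", "CCCC", "c1ccccc1", "CCS", "CCCl", "CC=O",
              "CCCO", "CCCN", "CC(C)C", "c1ccncc1"]
    return [(s, float(i % 5) / 2 - 1) for i, s in enumerate(smiles)]


def _tiny_classification_records():
    smiles = ["CCO", "CCC", "CCN", "CCCC", "c1ccccc1", "CCS", "CCCl", "CC=O",
              "CCCO", "CCCN", "CC(C)C", "c1ccncc1"]
    return [(s, float(i % 2)) for i, s in enumerate(smiles)]


class TestPretrain:
    def test_max_epochs_one(self):
        config = train_eval.TrainConfig(seed=0, max_epochs=1, batch_size=4)
        _, history = train_eval.pretrain(
            config, _tiny_regression_records(),
            gat_net.ModelConfig(**SMALL), return_history=True,
        )
        assert len(history) == 1

    def test_patience_honored_on_plateau(self):
        # learning rate ~0 with frozen normalization statistics plateaus
        # validation loss immediately
        config = train_eval.TrainConfig(
            seed=0, max_epochs=50, patience=3, batch_size=4, learning_rate=1e-30,
            freeze_bn_stats=True,
        )
        _, history = train_eval.pretrain(
            config, _tiny_regression_records(),
            gat_net.ModelConfig(**SMALL), return_history=True,
        )
        assert len(history) == 1 + 3  # first epoch improves from +inf, then stop

    def test_identical_targets_warn(self):
        records = [(s, 1.0) for s, _ in _tiny_regression_records()]
        config = train_eval.TrainConfig(seed=0, max_epochs=1, batch_size=4)
        with pytest.warns(UserWarning, match="identical"):
            train_eval.pretrain(config, records, gat_net.ModelConfig(**SMALL))

    def test_too_few_records(self):
        config = train_eval.TrainConfig()
        with pytest.raises(ValueError):
            train_eval.pretrain(config, [("CCO", 1.0)])

    def test_learning_reduces_validation_loss(self):
        config = train_eval.TrainConfig(
            seed=0, max_epochs=10, batch_size=16, learning_rate=1e-3,
            validation_fraction=0.2,
        )
        data = make_pretrain_set(60, SyntheticConfig(seed=3))
        _, history = train_eval.pretrain(
            config, data.records, gat_net.ModelConfig(**SMALL), return_history=True
        )
        assert history[-1]["val_loss"] < history[0]["val_loss"]

    def test_predict_values_units(self):
        config = train_eval.TrainConfig(seed=0, max_epochs=2, batch_size=8)
        data = make_pretrain_set(30, SyntheticConfig(seed=4))
        state = train_eval.pretrain(config, data.records, gat_net.ModelConfig(**SMALL))
        graphs = [featurize(s) for s, _ in data.records[:5]]
        raw = gat_net.predict_batch(state, graphs)
        vals = train_eval.predict_values(state, graphs)
        np.testing.assert_allclose(
            vals, state.target_mean + state.target_sd * raw
        )


@pytest.fixture(scope="module")
def pretrained():
    config = train_eval.TrainConfig(seed=1, max_epochs=2, batch_size=4)
    return train_eval.pretrain(
        config, _tiny_regression_records(), gat_net.ModelConfig(**SMALL)
    )


class TestFinetune:

    def test_head_replaced_and_backbone_moves(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=1, batch_size=4)
        tuned = train_eval.finetune(
            pretrained, _tiny_classification_records(), config
        )
        assert tuned.config.head_kind == "binary-classification"
        # head differs from the pretrained head
        assert not np.array_equal(
            tuned.params["head.W1"].data, pretrained.params["head.W1"].data
        )
        # conv weights moved but only slightly at the small learning rate
        delta = np.linalg.norm(
            tuned.params["conv0.h0.W"].data - pretrained.params["conv0.h0.W"].data
        )
        assert 0 < delta < 1.0

    def test_parameter_count_preserved(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=1, batch_size=4)
        tuned = train_eval.finetune(
            pretrained, _tiny_classification_records(), config
        )
        assert tuned.n_parameters() == pretrained.n_parameters()
        assert set(tuned.params) == set(pretrained.params)

    def test_regression_head_kind_rejected(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=1)
        with pytest.raises(ValueError, match="classifier|classification"):
            train_eval.finetune(
                pretrained, _tiny_classification_records(), config,
                head_kind="regression",
            )

    def test_classification_checkpoint_rejected(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=1, batch_size=4)
        tuned = train_eval.finetune(
            pretrained, _tiny_classification_records(), config
        )
        with pytest.raises(ValueError, match="regression"):
            train_eval.finetune(tuned, _tiny_classification_records(), config)

    def test_zero_learning_rate_freezes_backbone(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=3, batch_size=4)
        tuned = train_eval.finetune(
            pretrained, _tiny_classification_records(), config, learning_rate=0.0
        )
        np.testing.assert_array_equal(
            tuned.params["conv0.h0.W"].data, pretrained.params["conv0.h0.W"].data
        )

    def test_nonbinary_labels_rejected(self, pretrained):
        config = train_eval.TrainConfig(seed=2, max_epochs=1)
        records = [(s, t * 2) for s, t in _tiny_classification_records()]
        with pytest.raises(ValueError, match="binary"):
            train_eval.finetune(pretrained, records, config)


def test_train_config_validation():
    with pytest.raises(ValueError):
        train_eval.TrainConfig(learning_rate=-1.0).validate()
    with pytest.raises(ValueError):
        train_eval.TrainConfig(patience=0).validate()
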