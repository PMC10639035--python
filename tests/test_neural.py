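import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from conftest import fast_train, small_arch
from oracles import naive_attention

from oriseq import SyntheticConfig, generate_synthetic_dataset
from oriseq.neural import (
    ArchConfig,
    NeuralSequenceExtractor,
    TrainConfig,
    attention_pool,
    one_hot_encode,
)
from oriseq.seq_data import train_test_split_set


class TestOneHot:
    def test_single_base(self):
        assert one_hot_encode("A").tolist() == [[1, 0, 0, 0]]

    def test_acgt_is_identity(self):
        assert np.array_equal(one_hot_encode("ACGT"), np.eye(4))

    def test_rows_sum_to_one(self):
        m = one_hot_encode("GGATTACA")
        assert np.array_equal(m.sum(axis=1), np.ones(8))


class TestAttentionPool:
    def test_single_key_value(self):
        pooled, w = attention_pool([1.0, 0.0], [[3.0, 1.0]], [[5.0, 6.0]])
        assert np.allclose(w, [1.0])
        assert np.allclose(pooled, [5.0, 6.0])

    def test_identical_keys_give_uniform_weights(self):
        keys = np.ones((4, 3))
        values = np.arange(8.0).reshape(4, 2)
        pooled, w = attention_pool(np.array([0.3, -1.0, 2.0]), keys, values)
        assert np.allclose(w, 0.25)
        assert np.allclose(pooled, values.mean(axis=0))

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        q = rng.standard_normal(4)
        K = rng.standard_normal((5, 4))
        V = rng.standard_normal((5, 3))
        pooled, w = attention_pool(q, K, V)
        exp_pooled, exp_w = naive_attention(q, K, V)
        assert np.allclose(pooled, exp_pooled, atol=1e-6)
        assert np.allclose(w, exp_w, atol=1e-6)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()

    def test_empty_keys_rejected(self):
        with pytest.raises(ValueError):
            attention_pool([1.0], np.empty((0, 1)), np.empty((0, 1)))


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_synthetic_dataset(
        SyntheticConfig(n_per_class=40, gc_skew_shift=0.1, motif_rate=0.8, seed=5)
    )


class TestBuildAndShapes:
    def test_forward_shapes_and_probability_range(self, tiny_dataset):
        ext = NeuralSequenceExtractor(arch=small_arch(), train=fast_train(epochs=1))
        ext.fit(tiny_dataset.sequences(), tiny_dataset.labels())
        seqs = tiny_dataset.sequences()[:8]
        proba = ext.predict_proba(seqs)
        assert proba.shape == (8, 2)
        assert ((proba >= 0) & (proba <= 1)).all()
        feats = ext.transform(seqs)
        assert feats.shape == (8, ext.feature_dim_)
        # attention output = concat of both bidirectional stacks
        assert ext.feature_dim_ == 2 * 6 + 2 * 8

    def test_same_seed_same_initial_weights(self):
        a = NeuralSequenceExtractor(arch=small_arch(), train=fast_train())
        b = NeuralSequenceExtractor(arch=small_arch(), train=fast_train())
        a.arch_, b.arch_ = a.arch, b.arch
        a._build(300, seed=13)
        b._build(300, seed=13)
        for pa, pb in zip(a.params_, b.params_):
            assert np.array_equal(pa.data, pb.data)

    def test_kernel_larger_than_window_rejected(self, tiny_dataset):
        arch = small_arch(conv_branches=((4, 400),))
        ext = NeuralSequenceExtractor(arch=arch, train=fast_train(epochs=1))
        with pytest.raises(ValueError, match="kernel"):
            ext.fit(tiny_dataset.sequences(), tiny_dataset.labels())

    def test_single_class_rejected(self, tiny_dataset):
        pos = [r.seq for r in tiny_dataset if r.label == 1]
        ext = NeuralSequenceExtractor(arch=small_arch(), train=fast_train(epochs=1))
        with pytest.raises(ValueError):
            ext.fit(pos, np.ones(len(pos)))

    @pytest.mark.parametrize(
        "ablation", [{"use_attention": False}, {"use_gru": False}]
    )
    def test_ablated_architectures_train(self, tiny_dataset, ablation):
        arch = small_arch(**ablation)
        ext = NeuralSequenceExtractor(arch=arch, train=fast_train(epochs=2))
        ext.fit(tiny_dataset.sequences(), tiny_dataset.labels())
        assert ext.predict_proba(tiny_dataset.sequences()[:4]).shape == (4, 2)


class TestTraining:
    def test_learnable_signal_reaches_high_auc(self):
        """Median held-out AUC over 3 seeds on a strong two-signal set."""
        aucs = []
        for seed in (0, 1, 2):
            ds = generate_synthetic_dataset(
                SyntheticConfig(
                    n_per_class=500, gc_skew_shift=0.1, motif_rate=0.8, seed=100 + seed
                )
            )
            train, test = train_test_split_set(ds, 0.2, seed=seed)
            ext = NeuralSequenceExtractor(
                arch=small_arch(), train=fast_train(epochs=12, seed=seed)
            )
            ext.fit(train.sequences(), train.labels())
            p = ext.predict_proba(test.sequences())[:, 1]
            aucs.append(roc_auc_score(test.labels(), p))
        assert np.median(aucs) > 0.85

    def test_label_permutation_gives_chance_auc(self):
        aucs = []
        for seed in (0, 1, 2):
            ds = generate_synthetic_dataset(
                SyntheticConfig(
                    n_per_class=500, gc_skew_shift=0.1, motif_rate=0.8, seed=200 + seed
                )
            )
            rng = np.random.default_rng(seed)
            y = rng.permutation(ds.labels())
            train_idx = rng.permutation(len(y))[:700]
            test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
            seqs = ds.sequences()
            ext = NeuralSequenceExtractor(
                arch=small_arch(), train=fast_train(epochs=6, seed=seed)
            )
            ext.fit([seqs[i] for i in train_idx], y[train_idx])
            p = ext.predict_proba([seqs[i] for i in test_idx])[:, 1]
            aucs.append(roc_auc_score(y[test_idx], p))
        assert abs(np.median(aucs) - 0.5) < 0.07

    def test_loss_decreases_on_learnable_set(self, trained_extractor):
        hist = trained_extractor.history_
        assert hist[0]["train_loss"] > min(h["train_loss"] for h in hist[1:])

    def test_training_history_is_seed_deterministic(self, tiny_dataset):
        runs = []
        for _ in range(2):
            ext = NeuralSequenceExtractor(
                arch=small_arch(), train=fast_train(epochs=2, seed=3)
            )
            ext.fit(tiny_dataset.sequences(), tiny_dataset.labels())
            runs.append(ext.history_)
        assert runs[0] == runs[1]


class TestExtraction:
    def test_extraction_is_deterministic(self, trained_extractor, learnable_dataset):
        seqs = learnable_dataset.sequences()[:10]
        assert np.array_equal(
            trained_extractor.transform(seqs), trained_extractor.transform(seqs)
        )

    def test_wrong_window_length_rejected(self, trained_extractor):
        with pytest.raises(ValueError, match="length"):
            trained_extractor.transform(["ACGT" * 10])

    def test_save_load_roundtrip(self, trained_extractor, learnable_dataset, tmp_path):
        seqs = learnable_dataset.sequences()[:10]
        before = trained_extractor.transform(seqs)
        trained_extractor.save(tmp_path / "bundle")
        loaded = NeuralSequenceExtractor.load(tmp_path / "bundle")
        after = loaded.transform(seqs)
        assert np.abs(before - after).max() < 1e-6

    def test_linear_probe_on_dl_features(self, trained_extractor):
        ds = generate_synthetic_dataset(
            SyntheticConfig(n_per_class=200, gc_skew_shift=0.1, motif_rate=0.8, seed=77)
        )
        train, test = train_test_split_set(ds, 0.25, seed=0)
        F_tr = trained_extractor.transform(train.sequences())
        F_te = trained_extractor.transform(test.sequences())
        probe = LogisticRegression(max_iter=2000).fit(F_tr, train.labels())
        auc = roc_auc_score(test.labels(), probe.predict_proba(F_te)[:, 1])
        assert auc > 0.8
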