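import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from conftest import encoder_only_config

from oriseq import SyntheticConfig, generate_synthetic_dataset
from oriseq.encoders import CKSNAPEncoder, DCCEncoder, FeatureBlock, PCPseDNCEncoder
from oriseq.fusion import fuse
from oriseq.model import OrderedBoostedClassifier
from oriseq.selection import (
    AttributionReport,
    ShapleyFeatureSelector,
    rank_and_select,
    shapley_attributions,
)


def _block(name, width, n=5, seed=0):
    rng = np.random.default_rng(seed)
    return FeatureBlock(name, [f"{name}:{i}" for i in range(width)], rng.random((n, width)))


class TestFuse:
    def test_registry_ranges_tile_without_gaps(self):
        blocks = [_block(n, w) for n, w in zip(("DL", "CKSNAP", "PCPseDNC", "DCC"), (128, 96, 18, 4))]
        fused = fuse(blocks)
        assert fused.n_features == 246
        spans = [(e.start, e.stop) for e in fused.registry]
        assert spans == [(0, 128), (128, 224), (224, 242), (242, 246)]
        assert fused.block_names == ["DL", "CKSNAP", "PCPseDNC", "DCC"]

    def test_canonical_order_imposed_on_shuffled_input(self):
        blocks = [_block("DCC", 4), _block("DL", 8), _block("CKSNAP", 6)]
        fused = fuse(blocks)
        assert fused.block_names == ["DL", "CKSNAP", "DCC"]

    def test_single_block_identity(self):
        b = _block("CKSNAP", 7)
        fused = fuse([b])
        assert np.array_equal(fused.matrix, b.matrix)
        assert fused.feature_names == b.feature_names

    def test_slice_recovers_block(self):
        blocks = [_block("DL", 5, seed=1), _block("DCC", 3, seed=2)]
        fused = fuse(blocks)
        assert np.array_equal(fused.block("DCC"), blocks[1].matrix)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse([_block("DL", 3, n=5), _block("DCC", 3, n=6)])

    def test_duplicate_and_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fuse([_block("DL", 3), _block("DL", 4)])
        with pytest.raises(ValueError, match="unrecognized"):
            fuse([_block("WAT", 3)])


@pytest.fixture(scope="module")
def fitted_model_and_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 12))
    y = (X[:, 0] + 0.5 * X[:, 3] + 0.2 * rng.standard_normal(200) > 0).astype(int)
    model = OrderedBoostedClassifier(n_trees=80, depth=4, seed=0).fit(X, y)
    return model, X, y


class TestShapley:
    def test_local_accuracy_against_margin(self, fitted_model_and_data):
        model, X, _ = fitted_model_and_data
        report = shapley_attributions(model, X)
        recon = report.base_value + report.attributions.sum(axis=1)
        margins = model.raw_margin(X)
        assert np.abs(recon - margins).max() < 1e-4

    def test_stump_attributes_only_its_feature(self):
        # depth-1, single-tree model: closed-form Shapley puts all
        # non-base attribution on the split feature
        rng = np.random.default_rng(1)
        X = rng.standard_normal((300, 5))
        y = (X[:, 2] > 0).astype(int)
        stump = OrderedBoostedClassifier(n_trees=1, depth=1, learning_rate=1.0, seed=0).fit(X, y)
        report = shapley_attributions(stump, X)
        others = np.delete(report.attributions, 2, axis=1)
        assert np.abs(others).max() < 1e-9
        assert np.abs(report.attributions[:, 2]).max() > 0

    def test_constant_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((150, 6))
        X[:, 4] = 3.14
        y = (X[:, 0] > 0).astype(int)
        model = OrderedBoostedClassifier(n_trees=50, depth=3, seed=0).fit(X, y)
        report = shapley_attributions(model, X)
        assert np.abs(report.attributions[:, 4]).max() == 0.0

    def test_feature_count_mismatch_rejected(self, fitted_model_and_data):
        model, X, _ = fitted_model_and_data
        with pytest.raises(ValueError, match="features"):
            shapley_attributions(model, X[:, :5])

    def test_sampling_estimator_for_non_tree_model(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        y = (X[:, 1] > 0).astype(int)
        lr = LogisticRegression().fit(X, y)
        report = shapley_attributions(lr, X[:10], background=X, n_samples=32, seed=0)
        # additivity holds in expectation; the top feature must be the true one
        assert np.argmax(report.mean_abs) == 1

    def test_permuted_labels_shrink_attributions(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 8))
        y = (X[:, 0] > 0).astype(int)
        maxima = {"real": [], "null": []}
        for seed in (0, 1, 2):
            m = OrderedBoostedClassifier(n_trees=60, depth=3, seed=seed).fit(X, y)
            maxima["real"].append(shapley_attributions(m, X).mean_abs.max())
            y_perm = np.random.default_rng(seed).permutation(y)
            m0 = OrderedBoostedClassifier(n_trees=60, depth=3, seed=seed).fit(X, y_perm)
            maxima["null"].append(shapley_attributions(m0, X).mean_abs.max())
        assert np.median(maxima["null"]) < np.median(maxima["real"])


class TestRankAndSelect:
    def test_tiebreak_by_column_index(self):
        report = AttributionReport(0.0, np.zeros((1, 3)), np.array([0.3, 0.1, 0.3]))
        out = rank_and_select(report, top_k=2)
        assert out.ranking.tolist() == [0, 2, 1]
        assert out.selected_mask.tolist() == [True, False, True]

    def test_top_k_all_is_identity_selection(self, fitted_model_and_data):
        model, X, y = fitted_model_and_data
        sel = ShapleyFeatureSelector(top_k=X.shape[1], seed=0).fit(X, y)
        assert sel.transform(X).shape == X.shape
        assert np.array_equal(sel.transform(X), X)

    def test_invalid_top_k(self):
        report = AttributionReport(0.0, np.zeros((1, 2)), np.array([0.1, 0.2]))
        with pytest.raises(ValueError):
            rank_and_select(report, 0)

    def test_mask_has_exactly_top_k(self, fitted_model_and_data):
        model, X, y = fitted_model_and_data
        sel = ShapleyFeatureSelector(top_k=5, seed=0).fit(X, y)
        assert sel.report_.selected_mask.sum() == 5
        assert sel.transform(X).shape == (len(X), 5)

    def test_report_rendering_lists_top_20(self, fitted_model_and_data):
        model, X, y = fitted_model_and_data
        sel = ShapleyFeatureSelector(top_k=8, seed=0).fit(X, y)
        assert len(sel.report_.top_features(20)) == min(20, X.shape[1])
        assert len(sel.report_.top_features(5)) == 5


class TestSelectionConsistency:
    """Keeping the top-attributed features preserves signal; keeping the
    bottom-attributed features destroys it."""

    def test_top_vs_bottom_selection(self):
        deltas_top, deltas_bottom = [], []
        for seed in (0, 1, 2, 3, 4):
            ds = generate_synthetic_dataset(
                SyntheticConfig(
                    n_per_class=500, gc_skew_shift=0.1, motif_rate=0.9, seed=300 + seed
                )
            )
            seqs, y = ds.sequences(), ds.labels()
            blocks = [
                CKSNAPEncoder().encode_block(seqs),
                PCPseDNCEncoder(lam=2).encode_block(seqs),
                DCCEncoder().encode_block(seqs),
            ]
            fused = fuse(blocks)
            n = len(y)
            rng = np.random.default_rng(seed)
            perm = rng.permutation(n)
            tr, te = perm[: int(0.75 * n)], perm[int(0.75 * n) :]

            def auc_with(cols):
                m = OrderedBoostedClassifier(n_trees=150, seed=seed).fit(
                    fused.matrix[np.ix_(tr, cols)], y[tr]
                )
                p = m.predict_proba(fused.matrix[np.ix_(te, cols)])[:, 1]
                return roc_auc_score(y[te], p)

            base = auc_with(np.arange(fused.n_features))
            sel = ShapleyFeatureSelector(top_k=10, seed=seed).fit(fused.matrix[tr], y[tr])
            top_cols = np.flatnonzero(sel.report_.selected_mask)
            bottom_cols = sel.report_.ranking[-10:]
            deltas_top.append(base - auc_with(top_cols))
            deltas_bottom.append(base - auc_with(bottom_cols))
        assert np.median(deltas_top) < 0.03
        assert np.median(deltas_bottom) >= 0.10

    def test_block_importance_summary(self, fitted_model_and_data):
        blocks = [_block("DL", 6, n=80, seed=1), _block("CKSNAP", 4, n=80, seed=2)]
        fused = fuse(blocks)
        y = (fused.matrix[:, 0] > 0.5).astype(int)
        sel = ShapleyFeatureSelector(top_k=5, seed=0).fit(fused, y)
        imp = sel.block_importance(fused)
        assert list(imp["block"]) == ["DL", "CKSNAP"]
        assert (imp["n_selected"].sum()) == 5
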