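"""Fusion: spans, descriptors, SMOTE, XGBoost head, soft voting."""

import numpy as np
import pytest
import xgboost as xgb

from parkfuse.errors import ConfigError
from parkfuse.fusion import (
    build_fused_dataset,
    fused_matrix,
    pca_speech,
    smote_balance,
    soft_vote,
    split_standardize_balance,
    staged_margin,
    train_xgboost,
    tree_regularization,
)
from parkfuse.types import Embedding, FusedVector


def _pools(rng, dims=(32, 64, 64), n=10):
    out = {}
    for m, d in zip(("speech", "handwriting", "gait"), dims):
        embs = []
        for label, shift in (("hc", 0.0), ("pd", 3.0)):
            for i in range(n):
                embs.append(Embedding(rng.normal(shift, 1, d), m,
                                      f"{m}-{label}-{i}", label))
        out[m] = embs
    return out


class TestPCASpeech:
    def test_full_rank_reconstruction(self, rng):
        x = rng.normal(size=(20, 6))
        z, basis = pca_speech(x, n_components=6)
        recon = basis.pca.inverse_transform(z)
        assert np.abs(recon - x).max() < 1e-9

    def test_line_data_one_component(self, rng):
        t = rng.normal(size=50)
        x = np.column_stack([t, 2 * t + 1e-6 * rng.normal(size=50)])
        _, basis = pca_speech(x, n_components=2)
        assert basis.pca.explained_variance_ratio_[0] > 0.999

    def test_same_basis_applied_to_train_and_test(self, rng):
        train = rng.normal(size=(30, 8))
        test = rng.normal(size=(10, 8))
        _, basis = pca_speech(train, n_components=4)
        h = basis.fit_hash
        basis.transform(test)
        assert basis.fit_hash == h  # transform never refits

    def test_too_many_components_raise(self, rng):
        with pytest.raises(ConfigError):
            pca_speech(rng.normal(size=(10, 4)), n_components=8)


class TestFusedDataset:
    def test_span_arithmetic(self, rng):
        fused, _ = build_fused_dataset(_pools(rng), seed=0)
        f = fused[0]
        assert len(f.values) == 160
        assert f.spans == {"speech": (0, 32), "handwriting": (32, 96),
                           "gait": (96, 160)}

    def test_degenerate_single_sample_pools(self, rng):
        pools = _pools(rng, n=1)
        fused, desc = build_fused_dataset(pools, seed=0)
        by_label = {f.label: f for f in fused}
        for label in ("hc", "pd"):
            expect = np.concatenate([
                [e.vector for e in pools[m] if e.label == label][0]
                for m in ("speech", "handwriting", "gait")])
            np.testing.assert_array_equal(by_label[label].values, expect)
        np.testing.assert_array_equal(
            desc.means[("speech", "hc")],
            [e.vector for e in pools["speech"] if e.label == "hc"][0])
        assert np.all(desc.sds[("speech", "hc")] == 0)

    def test_class_conditional_descriptor_hand_arithmetic(self):
        pools = {m: [Embedding(np.array(v), m, f"{m}{i}", "hc")
                     for i, v in enumerate([[0.0, 2.0], [2.0, 4.0]])]
                 + [Embedding(np.array(v), m, f"{m}p{i}", "pd")
                    for i, v in enumerate([[5.0, 5.0], [7.0, 7.0]])]
                 for m in ("speech", "handwriting", "gait")}
        _, desc = build_fused_dataset(pools, seed=0)
        np.testing.assert_allclose(desc.means[("gait", "hc")], [1.0, 3.0])
        np.testing.assert_allclose(desc.sds[("gait", "hc")], [1.0, 1.0])

    def test_missing_class_raises(self, rng):
        pools = _pools(rng)
        pools["gait"] = [e for e in pools["gait"] if e.label == "hc"]
        with pytest.raises(ConfigError):
            build_fused_dataset(pools, seed=0)

    def test_span_invariant_enforced(self):
        with pytest.raises(ValueError):
            FusedVector(values=np.zeros(10), spans={"speech": (0, 4)}, label="hc")


class TestSplitStandardizeBalance:
    def test_smote_balances_counts(self, rng):
        x = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(5, 1, (30, 4))])
        y = np.array([1] * 10 + [0] * 30)
        xb, yb = smote_balance(x, y, k=5, seed=0)
        assert (np.bincount(yb) == [30, 30]).all()

    def test_smote_points_lie_on_minority_segments(self, rng):
        minority = rng.normal(0, 1, (8, 3))
        x = np.vstack([minority, rng.normal(6, 1, (20, 3))])
        y = np.array([1] * 8 + [0] * 20)
        xb, yb = smote_balance(x, y, k=5, seed=0)
        synth = xb[len(x):]
        for s in synth:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    lam = (s - minority[i]) @ d / (d @ d)
                    if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(
                            minority[i] + lam * d, s, atol=1e-8):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_tiny_minority_suggests_smaller_k(self, rng):
        x = rng.normal(size=(12, 3))
        y = np.array([1] * 4 + [0] * 8)
        with pytest.raises(ConfigError, match="smaller"):
            smote_balance(x, y, k=5, seed=0)

    def test_test_partition_untouched_and_scaled_with_train_stats(self, rng):
        fused, _ = build_fused_dataset(_pools(rng, dims=(4, 4, 4), n=20), seed=0)
        split = split_standardize_balance(fused, split_ratio=0.7, seed=0)
        x, y = fused_matrix(fused)
        # reconstruct: every test row must equal scaler.transform of an
        # original fused row (SMOTE never touches the test partition)
        raw = split.scaler.inverse_transform(split.x_test)
        for row in raw:
            assert np.any(np.all(np.isclose(x, row, atol=1e-8), axis=1))
        # post-SMOTE training classes are balanced
        assert np.bincount(split.y_train)[0] == np.bincount(split.y_train)[1]


class TestXGBoost:
    def test_regularizer_hand_arithmetic(self):
        # gamma*M + (lambda/2)*||w||^2 with M=3, gamma=1, lambda=2
        assert tree_regularization(3, [1.0, -2.0, 0.5], gamma=1.0, lam=2.0) \
            == pytest.approx(8.25)

    def test_single_stump_on_separable_data(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 40), rng.uniform(2, 3, 40)])[:, None]
        y = np.array([0] * 40 + [1] * 40)
        model = train_xgboost(x, y, seed=0, n_estimators=1, max_depth=1)
        assert (model.predict(x) == y).all()

    def test_staged_additive_identity(self, rng):
        x = rng.normal(size=(60, 5))
        y = (x[:, 0] + 0.2 * rng.normal(size=60) > 0).astype(int)
        model = train_xgboost(x, y, seed=0, n_estimators=20)
        booster = model.get_booster()
        full = booster.predict(xgb.DMatrix(x[:7]), output_margin=True)
        # cumulative margins are sums of per-tree contributions
        prev = None
        for f in (1, 5, 20):
            margin = staged_margin(model, x[:7], f)
            if prev is not None:
                assert not np.allclose(margin, prev)
            prev = margin
        np.testing.assert_allclose(staged_margin(model, x[:7], 20), full, atol=1e-6)

    def test_single_class_raises(self, rng):
        with pytest.raises(ConfigError):
            train_xgboost(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))

    def test_deterministic_per_seed(self, rng):
        x = rng.normal(size=(50, 4))
        y = (x[:, 0] > 0).astype(int)
        a = train_xgboost(x, y, seed=3, n_estimators=10).predict_proba(x)
        b = train_xgboost(x, y, seed=3, n_estimators=10).predict_proba(x)
        np.testing.assert_array_equal(a, b)


class TestSoftVote:
    def test_mean_of_three(self):
        p = [np.array([[0.1, 0.9]]), np.array([[0.4, 0.6]]), np.array([[0.7, 0.3]])]
        mean, arg = soft_vote(p)
        np.testing.assert_allclose(mean, [[0.4, 0.6]])
        assert arg[0] == 1

    def test_identical_inputs_identity(self):
        p = np.array([[0.3, 0.7], [0.8, 0.2]])
        mean, _ = soft_vote([p, p, p])
        np.testing.assert_allclose(mean, p)

    def test_output_sums_to_one(self, rng):
        ps = []
        for _ in range(3):
            raw = rng.uniform(size=(5, 2))
            ps.append(raw / raw.sum(axis=1, keepdims=True))
        mean, _ = soft_vote(ps)
        np.testing.assert_allclose(mean.sum(axis=1), 1.0, atol=1e-12)

    def test_mismatched_class_sets_raise(self):
        with pytest.raises(ConfigError):
            soft_vote([np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2))])
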