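"""Blocked LOO boosting, stacking, importance, embedding."""

import numpy as np
import pandas as pd
import pytest

from phenomarker.ensemble import (BlockPredictionMatrix, FeatureBlock,
                                  ModelOptions, loo_block_predict,
                                  make_blocks, stack, tsne_embed)


def _block(X, name="b", ids=None):
    ids = ids or [f"p{i:03d}" for i in range(len(X))]
    return FeatureBlock(name, pd.DataFrame(np.asarray(X, float), index=ids))


class TestMakeBlocks:
    def _tables(self, n_spec, n=6):
        ids = [f"p{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        return {
            "dist": pd.DataFrame(rng.normal(size=(n, 109)), index=ids),
            "spectral": pd.DataFrame(rng.normal(size=(n, n_spec)), index=ids),
        }

    def test_spectral_chunking_4200(self):
        blocks = make_blocks(self._tables(4200))
        sizes = [b.matrix.shape[1] for b in blocks if b.name.startswith("spec")]
        assert sizes == [1000, 1000, 1000, 1000, 200]

    def test_spectral_single_chunk_boundary(self):
        blocks = make_blocks(self._tables(1000))
        names = [b.name for b in blocks]
        assert names == ["dist", "spectral_1"]

    def test_misaligned_participants_rejected(self):
        t = self._tables(50)
        t["spectral"] = t["spectral"].iloc[::-1]
        with pytest.raises(ValueError, match="participant mismatch"):
            make_blocks(t)

    def test_period_annotation_carried(self):
        t = self._tables(10)
        t["spectral"].columns = [f"spec_f{k:04d}" for k in range(10)]
        periods = {c: float(k + 1) for k, c in enumerate(t["spectral"].columns)}
        blocks = make_blocks(t, spectral_periods=periods)
        spec = [b for b in blocks if b.name == "spectral_1"][0]
        assert spec.period_s["spec_f0003"] == 4.0


class TestLooBlockPredict:
    def test_constant_target_predicted_exactly(self, rng, fast_model_opts):
        blk = _block(rng.normal(size=(12, 5)))
        y = pd.Series(np.full(12, 31.0), index=blk.matrix.index)
        pred, _ = loo_block_predict(blk, y, fast_model_opts)
        np.testing.assert_allclose(pred.to_numpy(), 31.0, atol=1e-3)

    def test_deterministic_and_leakage_free(self, rng, fast_model_opts):
        X = rng.normal(size=(15, 8))
        blk = _block(X)
        y = pd.Series(X[:, 0] + rng.normal(0, 0.5, 15), index=blk.matrix.index)
        pred1, _ = loo_block_predict(blk, y, fast_model_opts)
        # removing participant i from the training data must leave the stored
        # out-of-sample prediction for i unchanged (it never saw i)
        i = 7
        model = fast_model_opts.regressor()
        mask = np.ones(15, bool)
        mask[i] = False
        model.fit(X[mask], y.to_numpy()[mask])
        assert model.predict(X[i:i + 1])[0] == pytest.approx(pred1.iloc[i],
                                                             abs=1e-9)

    def test_planted_linear_signal_tracks_oracle(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        noise_sd = np.std(x1) / 3.0  # SNR 3:1
        y = x1 + rng.normal(0, noise_sd, n)
        X = np.column_stack([x1, rng.normal(size=(n, 4))])
        blk = _block(X)
        ys = pd.Series(y, index=blk.matrix.index)
        pred, gain = loo_block_predict(blk, ys, ModelOptions(seed=1))
        r = np.corrcoef(pred, y)[0, 1]
        # oracle: leave-one-out linear regression on the informative column
        oracle_pred = np.empty(n)
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            b = np.polyfit(x1[m], y[m], 1)
            oracle_pred[i] = np.polyval(b, x1[i])
        r_oracle = np.corrcoef(oracle_pred, y)[0, 1]
        assert r >= 0.7
        assert r >= 0.9 * r_oracle
        assert gain.idxmax() == 0  # informative column dominates gain

    def test_missing_features_routed_natively(self, rng, fast_model_opts):
        X = rng.normal(size=(12, 4))
        X[::3, 1] = np.nan
        blk = _block(X)
        y = pd.Series(X[:, 0], index=blk.matrix.index)
        pred, _ = loo_block_predict(blk, y, fast_model_opts)
        assert np.all(np.isfinite(pred))

    def test_all_missing_block_rejected(self, fast_model_opts):
        blk = _block(np.full((8, 3), np.nan))
        y = pd.Series(np.arange(8.0), index=blk.matrix.index)
        with pytest.raises(ValueError, match="MISSING"):
            loo_block_predict(blk, y, fast_model_opts)

    def test_too_few_participants_rejected(self, fast_model_opts):
        blk = _block(np.zeros((4, 3)))
        with pytest.raises(ValueError):
            loo_block_predict(blk, pd.Series(np.arange(4.0),
                                             index=blk.matrix.index),
                              fast_model_opts)


def _bpm(cols: dict, ids):
    return BlockPredictionMatrix(pd.DataFrame(cols, index=ids))


class TestStack:
    def test_informative_block_carries_through(self, rng):
        n = 80
        rho = 0.8
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = r.normal(29, 9, n)
            good = rho * (y - y.mean()) / y.std() + np.sqrt(1 - rho ** 2) * r.normal(size=n)
            ids = [f"p{i}" for i in range(n)]
            bpm = _bpm({"good": good, "n1": r.normal(size=n),
                        "n2": r.normal(size=n)}, ids)
            res = stack(bpm, pd.Series(y, index=ids), ModelOptions(seed=seed))
            diffs.append(np.corrcoef(res.predictions, y)[0, 1] - rho)
        assert abs(np.mean(diffs)) < 0.15

    def test_duplicate_block_changes_little(self, rng):
        n = 80
        r = np.random.default_rng(3)
        y = r.normal(29, 9, n)
        good = 0.8 * (y - y.mean()) / y.std() + 0.6 * r.normal(size=n)
        ids = [f"p{i}" for i in range(n)]
        noise = r.normal(size=n)
        r1 = []
        for cols in ({"good": good, "n1": noise},
                     {"good": good, "good2": good.copy(), "n1": noise}):
            res = stack(_bpm(cols, ids), pd.Series(y, index=ids),
                        ModelOptions(seed=0))
            r1.append(np.corrcoef(res.predictions, y)[0, 1])
        assert abs(r1[0] - r1[1]) < 0.08

    def test_pure_noise_blocks_near_zero(self):
        rs = []
        for seed in range(10):
            r = np.random.default_rng(100 + seed)
            n = 40
            ids = [f"p{i}" for i in range(n)]
            y = pd.Series(r.normal(29, 9, n), index=ids)
            bpm = _bpm({f"b{k}": r.normal(size=n) for k in range(4)}, ids)
            res = stack(bpm, y, ModelOptions(seed=seed))
            rs.append(np.corrcoef(res.predictions, y)[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_missing_predictions_rejected(self):
        ids = [f"p{i}" for i in range(8)]
        m = pd.DataFrame({"a": np.arange(8.0)}, index=ids)
        m.iloc[2, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            stack(BlockPredictionMatrix(m),
                  pd.Series(np.arange(8.0), index=ids))

    def test_importance_table_sorted_and_nonnegative(self, rng, fast_model_opts):
        n = 20
        ids = [f"p{i}" for i in range(n)]
        y = pd.Series(rng.normal(size=n), index=ids)
        bpm = _bpm({"a": y.to_numpy() + rng.normal(0, 0.5, n),
                    "b": rng.normal(size=n)}, ids)
        gains = {"a": pd.Series({"f1": 3.0, "f2": 1.0}),
                 "b": pd.Series({"g1": 2.0})}
        res = stack(bpm, y, fast_model_opts, block_importances=gains,
                    period_maps={"a": {"f1": 6.35}})
        imp = res.importance
        assert np.all(imp["score"].to_numpy() >= 0)
        assert np.all(np.diff(imp["score"].to_numpy()) <= 1e-12)
        assert imp.set_index("feature").loc["f1", "period_s"] == 6.35


class TestTsne:
    def _bpm(self, n=30, seed=0):
        r = np.random.default_rng(seed)
        ids = [f"p{i}" for i in range(n)]
        return _bpm if False else BlockPredictionMatrix(
            pd.DataFrame(r.normal(size=(n, 4)), index=ids))

    def test_shape_and_determinism(self):
        bpm = self._bpm()
        c1 = tsne_embed(bpm, seed=5)
        c2 = tsne_embed(bpm, seed=5)
        assert c1.shape == (30, 3)
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tsne_embed(self._bpm(n=5))

    def test_separated_groups_stay_separated(self):
        from sklearn.metrics import silhouette_score
        r = np.random.default_rng(2)
        n = 60
        labels = np.repeat([0, 1], n // 2)
        M = r.normal(size=(n, 4)) + labels[:, None] * 6.0
        bpm = BlockPredictionMatrix(
            pd.DataFrame(M, index=[f"p{i}" for i in range(n)]))
        coords = tsne_embed(bpm, seed=0)
        assert silhouette_score(coords, labels) > 0.2
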