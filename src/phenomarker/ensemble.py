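"""Blocked leave-one-out stacked gradient boosting.

Lower level: one boosted-tree regressor per feature block (accelerometer
distribution, dynamics, spectral chunks of 1000 frequency bins, text,
call), each producing strictly out-of-sample severity predictions by
leave-one-out cross-validation.  Upper level: a boosted-tree meta-learner
over the matrix of block predictions, itself evaluated by leave-one-out.
The meta level reuses the lower-level out-of-sample predictions as its
feature matrix rather than running a fully nested double-LOO; the slight
optimism of that shortcut is documented in the methods note.

Variable importance follows the two-level structure of the ensemble: the
meta-learner's gain ranks the blocks, the lower-level refit-averaged gain
ranks features within a block, and the final table orders features by the
product (block share of meta gain x feature share of block gain), so the
single most influential biomarker is the top feature of the most
influential lower-order model.  Spectral features are annotated with
their oscillation period in seconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

__all__ = [
    "ModelOptions",
    "FeatureBlock",
    "BlockPredictionMatrix",
    "EnsembleResult",
    "make_blocks",
    "loo_block_predict",
    "stack",
    "tsne_embed",
]

SPECTRAL_CHUNK = 1000


@dataclass(frozen=True)
class ModelOptions:
    """Fixed boosted-tree hyperparameters (no search is performed)."""

    max_depth: int = 3
    learning_rate: float = 0.1
    n_estimators: int = 200
    subsample: float = 0.8
    colsample_bytree: float = 0.25
    seed: int = 0

    def regressor(self) -> xgb.XGBRegressor:
        return xgb.XGBRegressor(
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            random_state=self.seed,
            n_jobs=1,
            tree_method="exact",
            importance_type="gain",
        )


@dataclass
class FeatureBlock:
    """Named participant x feature matrix; NaN marks MISSING."""

    name: str
    matrix: pd.DataFrame  # index = participant ids, columns = feature names
    period_s: dict[str, float] = field(default_factory=dict)  # spectral only

    @property
    def column_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class BlockPredictionMatrix:
    """Per-participant out-of-sample predictions from each block learner."""

    matrix: pd.DataFrame  # index = participants, columns = block names
    out_of_sample: bool = True

    @property
    def block_names(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass
class EnsembleResult:
    predictions: pd.Series            # out-of-sample predicted severity
    importance: pd.DataFrame          # feature, block, gain, period_s
    block_loo_r: dict[str, float]     # per-block LOO correlation with y
    out_of_sample: bool = True


def make_blocks(feature_tables: dict[str, pd.DataFrame],
                spectral_periods: dict[str, float] | None = None) -> list[FeatureBlock]:
    """Assemble aligned feature blocks from per-family feature tables.

    *feature_tables* maps family name ('dist', 'dtvem', 'spectral', 'text',
    'call') to a participant-indexed DataFrame.  The spectral family is
    split into consecutive chunks of 1000 columns in frequency order,
    named 'spectral_1', 'spectral_2', ...  All tables must share the same
    participant index in the same order.
    """
    ref_index = None
    for name, df in feature_tables.items():
        if ref_index is None:
            ref_index = df.index
        elif not df.index.equals(ref_index):
            extra = sorted(set(df.index).symmetric_difference(ref_index))
            raise ValueError(
                f"participant mismatch in block '{name}': {extra[:10]}")
    blocks: list[FeatureBlock] = []
    for name, df in feature_tables.items():
        if name == "spectral":
            ncol = df.shape[1]
            nchunks = math.ceil(ncol / SPECTRAL_CHUNK)
            for k in range(nchunks):
                sub = df.iloc[:, k * SPECTRAL_CHUNK:(k + 1) * SPECTRAL_CHUNK]
                periods = {c: spectral_periods[c] for c in sub.columns
                           if spectral_periods and c in spectral_periods}
                blocks.append(FeatureBlock(f"spectral_{k + 1}", sub, periods))
        else:
            blocks.append(FeatureBlock(name, df))
    return blocks


def _loo_fit_predict(X: np.ndarray, y: np.ndarray, opts: ModelOptions,
                     collect_importance: bool = False):
    """Leave-one-out predictions (and mean per-feature gain) for one matrix."""
    n = len(y)
    preds = np.empty(n)
    gain_sum = np.zeros(X.shape[1]) if collect_importance else None
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = opts.regressor()
        model.fit(X[mask], y[mask])
        preds[i] = float(model.predict(X[i:i + 1])[0])
        if collect_importance:
            # raw total gain (summed over splits) is on the squared-error
            # scale of y, hence comparable across blocks of any width
            score = model.get_booster().get_score(importance_type="total_gain")
            for fname, g in score.items():
                gain_sum[int(fname[1:])] += g
        mask[i] = True
    if collect_importance:
        return preds, gain_sum / n
    return preds


def loo_block_predict(block: FeatureBlock, y: pd.Series | np.ndarray,
                      opts: ModelOptions | None = None,
                      collect_importance: bool = True):
    """Out-of-sample predictions of y from one feature block.

    For each participant i, a boosted-tree regressor is trained on the
    other n-1 rows and predicts row i.  NaN features are routed natively by
    the trees.  Returns (predictions: pd.Series, mean_gain: pd.Series).
    Deterministic given opts.seed.
    """
    opts = opts or ModelOptions()
    X = block.matrix.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(X):
        raise ValueError("y length does not match block rows")
    if len(yv) < 5:
        raise ValueError("need at least 5 participants for LOO")
    if not np.all(np.isfinite(yv)):
        raise ValueError("y must be finite")
    if np.all(np.isnan(X)):
        raise ValueError(f"block '{block.name}' is entirely MISSING")
    preds, gain = _loo_fit_predict(X, yv, opts, collect_importance=True)
    pred_s = pd.Series(preds, index=block.matrix.index, name=block.name)
    gain_s = pd.Series(gain, index=block.matrix.columns, name=block.name)
    if collect_importance:
        return pred_s, gain_s
    return pred_s


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def stack(block_preds: BlockPredictionMatrix, y: pd.Series | np.ndarray,
          opts: ModelOptions | None = None,
          block_importances: dict[str, pd.Series] | None = None,
          period_maps: dict[str, dict[str, float]] | None = None) -> EnsembleResult:
    """Meta-level boosted-tree stacking over block predictions, LOO-scored.

    *block_importances* (block name -> per-feature mean gain from the
    lower-level LOO refits) are pooled into one descending-gain table;
    *period_maps* annotates spectral feature names with their period.
    """
    opts = opts or ModelOptions()
    M = block_preds.matrix.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(yv) != len(M):
        raise ValueError("y length does not match block-prediction rows")
    if np.any(np.isnan(M)):
        raise ValueError("block predictions must be complete (no MISSING)")
    # column subsampling is a p >> n device for the wide lower-level blocks;
    # the meta matrix has one column per block, and every tree should see
    # all of them so the gain allocation reflects block quality
    meta_opts = dataclasses.replace(opts, colsample_bytree=1.0)
    meta_preds, meta_gain = _loo_fit_predict(M, yv, meta_opts,
                                             collect_importance=True)
    predictions = pd.Series(meta_preds, index=block_preds.matrix.index,
                            name="y_pred")

    block_r = {b: _safe_corr(M[:, j], yv)
               for j, b in enumerate(block_preds.block_names)}
    meta_gain_by_block = dict(zip(block_preds.block_names, meta_gain))
    meta_total = sum(meta_gain_by_block.values()) or 1.0

    rows = []
    if block_importances:
        for bname, gains in block_importances.items():
            pmap = (period_maps or {}).get(bname, {})
            block_share = meta_gain_by_block.get(bname, 0.0) / meta_total
            block_total = float(np.sum(np.maximum(gains.to_numpy(), 0.0))) or 1.0
            for feat, g in gains.items():
                g = max(float(g), 0.0)
                rows.append((feat, bname, g,
                             block_share * g / block_total,
                             pmap.get(feat, math.nan)))
    importance = pd.DataFrame(
        rows, columns=["feature", "block", "gain", "score", "period_s"])
    importance = importance.sort_values("score", ascending=False,
                                        kind="mergesort").reset_index(drop=True)
    return EnsembleResult(predictions=predictions, importance=importance,
                          block_loo_r=block_r, out_of_sample=True)


def tsne_embed(block_preds: BlockPredictionMatrix, seed: int = 0) -> np.ndarray:
    """3-D t-SNE embedding of the block-prediction rows (seeded, exact)."""
    from sklearn.manifold import TSNE

    M = block_preds.matrix.to_numpy(dtype=float)
    n = len(M)
    if n < 10:
        raise ValueError("need at least 10 participants for a stable embedding")
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=3, perplexity=perplexity, init="pca",
                random_state=seed, method="exact")
    return tsne.fit_transform(M)


def plot_embedding(coords: np.ndarray, severity: np.ndarray, path=None):
    """Scatter the 3-D embedding colored by observed severity (first two
    embedding axes shown; the axes themselves carry no meaning)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=severity, cmap="coolwarm")
    fig.colorbar(sc, ax=ax, label="observed SIAS")
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
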