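"""Regression models for ddG: support vector regression, random forest and a
feed-forward neural network, plus tuning, the restart-averaged DNN ensemble
and the one-at-a-time feature ablation study.

SVR and RF are scikit-learn estimators configured with this pipeline's
defaults (SVR: RBF kernel, gamma 0.015, epsilon 0.1, behind a standardizer;
RF: 500 trees, 22 candidate variables per split).  The DNN is implemented
here so that its initialization (weights uniform on [-eps, eps]) and
minibatch SGD/Adam training on mean squared error are fully specified and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

MODEL_BUNDLE_VERSION = 1


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SVRConfig:
    kernel: str = "rbf"           # rbf | poly | sigmoid | linear
    gamma: float = 0.015
    epsilon: float = 0.1
    cost: float = 1.0

    kind = "svr"


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    vars_per_split: int = 22
    seed: int = 0

    kind = "rf"


@dataclass(frozen=True)
class DNNConfig:
    n_hidden_layers: int = 2      # 1..4
    width: int = 50               # hidden units per layer, 10..100
    activation: str = "relu"      # tanh | relu
    learning_rate: float = 0.01   # 0.001..0.1
    init_range: float = 0.01      # eps of U(-eps, eps), 0.001..0.1
    minibatch: int = 32           # {8,...,512}
    optimizer: str = "adam"       # sgd | adam
    seed: int = 0
    max_epochs: int = 200
    patience: int = 20

    kind = "dnn"

    def __post_init__(self):
        if not 1 <= self.n_hidden_layers <= 4:
            raise ValueError("n_hidden_layers must be in [1, 4]")
        if self.activation not in ("tanh", "relu"):
            raise ValueError("activation must be tanh or relu")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be sgd or adam")


ModelConfig = SVRConfig | RFConfig | DNNConfig


@dataclass(frozen=True)
class Metrics:
    rmse: float
    pearson_r: float

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


# ---------------------------------------------------------------------------
# DNN
# ---------------------------------------------------------------------------

class DNNRegressor(BaseEstimator, RegressorMixin):
    """Feed-forward network y = W_L^T h_L + b_L trained with minibatch
    gradient descent on mean squared error.

    Weights and biases are initialized from U(-init_range, init_range);
    features are standardized with training statistics.  When a validation
    set is passed to :meth:`fit`, training stops early after `patience`
    epochs without improvement in validation RMSE and the best weights are
    restored.
    """

    def __init__(self, n_hidden_layers: int = 2, width: int = 50,
                 activation: str = "relu", learning_rate: float = 0.01,
                 init_range: float = 0.01, minibatch: int = 32,
                 optimizer: str = "adam", seed: int = 0,
                 max_epochs: int = 200, patience: int = 20,
                 standardize: bool = True):
        self.n_hidden_layers = n_hidden_layers
        self.width = width
        self.activation = activation
        self.learning_rate = learning_rate
        self.init_range = init_range
        self.minibatch = minibatch
        self.optimizer = optimizer
        self.seed = seed
        self.max_epochs = max_epochs
        self.patience = patience
        self.standardize = standardize

    # -- internals ---------------------------------------------------------

    def _act(self, z):
        return np.tanh(z) if self.activation == "tanh" else np.maximum(z, 0.0)

    def _act_grad(self, z, a):
        return 1.0 - a * a if self.activation == "tanh" else (z > 0).astype(float)

    def _forward(self, X):
        h = X
        zs, hs = [], [h]
        for W, b in zip(self.coefs_[:-1], self.intercepts_[:-1]):
            z = h @ W + b
            h = self._act(z)
            zs.append(z)
            hs.append(h)
        y = h @ self.coefs_[-1] + self.intercepts_[-1]
        return y.ravel(), zs, hs

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in training data")
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self._mu = X.mean(axis=0)
            sd = X.std(axis=0)
            self._sd = np.where(sd > 0, sd, 1.0)
        else:
            self._mu = np.zeros(X.shape[1])
            self._sd = np.ones(X.shape[1])
        Xs = (X - self._mu) / self._sd
        Xv = yv = None
        if X_val is not None:
            Xv = (np.asarray(X_val, dtype=float) - self._mu) / self._sd
            yv = np.asarray(y_val, dtype=float).ravel()

        rng = np.random.default_rng(self.seed)
        sizes = ([X.shape[1]] + [self.width] * self.n_hidden_layers + [1])
        eps = self.init_range
        self.coefs_ = [rng.uniform(-eps, eps, (a, b))
                       for a, b in zip(sizes, sizes[1:])]
        self.intercepts_ = [rng.uniform(-eps, eps, b) for b in sizes[1:]]

        if self.optimizer == "adam":
            mW = [np.zeros_like(W) for W in self.coefs_]
            vW = [np.zeros_like(W) for W in self.coefs_]
            mb = [np.zeros_like(b) for b in self.intercepts_]
            vb = [np.zeros_like(b) for b in self.intercepts_]
            b1, b2, adam_eps, t = 0.9, 0.999, 1e-8, 0

        best_rmse, best_weights, stale = np.inf, None, 0
        self.loss_curve_, self.val_rmse_curve_ = [], []
        n = len(Xs)
        batch = max(1, min(self.minibatch, n))
        for _epoch in range(self.max_epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = perm[start:start + batch]
                xb, yb = Xs[idx], y[idx]
                pred, zs, hs = self._forward(xb)
                err = pred - yb
                epoch_loss += float(np.sum(err ** 2))
                # backprop of MSE = mean(err^2): d/dpred = 2 err / m
                delta = (2.0 * err / len(xb))[:, None]
                gW = [None] * len(self.coefs_)
                gb = [None] * len(self.intercepts_)
                gW[-1] = hs[-1].T @ delta
                gb[-1] = delta.sum(axis=0)
                d = delta @ self.coefs_[-1].T
                for layer in range(len(self.coefs_) - 2, -1, -1):
                    d = d * self._act_grad(zs[layer], hs[layer + 1])
                    gW[layer] = hs[layer].T @ d
                    gb[layer] = d.sum(axis=0)
                    if layer > 0:
                        d = d @ self.coefs_[layer].T
                if self.optimizer == "sgd":
                    for k in range(len(self.coefs_)):
                        self.coefs_[k] -= self.learning_rate * gW[k]
                        self.intercepts_[k] -= self.learning_rate * gb[k]
                else:
                    t += 1
                    for k in range(len(self.coefs_)):
                        mW[k] = b1 * mW[k] + (1 - b1) * gW[k]
                        vW[k] = b2 * vW[k] + (1 - b2) * gW[k] ** 2
                        mb[k] = b1 * mb[k] + (1 - b1) * gb[k]
                        vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
                        mhW = mW[k] / (1 - b1 ** t)
                        vhW = vW[k] / (1 - b2 ** t)
                        mhb = mb[k] / (1 - b1 ** t)
                        vhb = vb[k] / (1 - b2 ** t)
                        self.coefs_[k] -= self.learning_rate * mhW / (np.sqrt(vhW) + adam_eps)
                        self.intercepts_[k] -= self.learning_rate * mhb / (np.sqrt(vhb) + adam_eps)
            self.loss_curve_.append(epoch_loss / n)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError("DNN training diverged (non-finite loss)")
            if Xv is not None:
                val_pred, _, _ = self._forward(Xv)
                vr = float(np.sqrt(np.mean((val_pred - yv) ** 2)))
                self.val_rmse_curve_.append(vr)
                if vr < best_rmse - 1e-12:
                    best_rmse = vr
                    best_weights = ([W.copy() for W in self.coefs_],
                                    [b.copy() for b in self.intercepts_])
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_weights is not None:
            self.coefs_, self.intercepts_ = best_weights
        return self

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}")
        if len(X) == 0:
            return np.zeros(0)
        Xs = (X - self._mu) / self._sd
        pred, _, _ = self._forward(Xs)
        return pred


class DNNEnsemble(BaseEstimator, RegressorMixin):
    """Average of `n_restarts` DNNs differing only in weight initialization
    (seeds seed, seed+1, ...).  Restarts that diverge are excluded and
    counted in `n_failed_`."""

    def __init__(self, config: DNNConfig | None = None, n_restarts: int = 5):
        self.config = config
        self.n_restarts = n_restarts

    def fit(self, X, y, X_val=None, y_val=None):
        if self.n_restarts < 2:
            raise ValueError("n_restarts must be >= 2")
        cfg = self.config or DNNConfig()
        self.models_ = []
        self.n_failed_ = 0
        for i in range(self.n_restarts):
            m = _dnn_from_config(dataclasses.replace(cfg, seed=cfg.seed + i))
            try:
                m.fit(X, y, X_val=X_val, y_val=y_val)
            except FloatingPointError:
                self.n_failed_ += 1
                continue
            self.models_.append(m)
        if not self.models_:
            raise RuntimeError("all DNN restarts diverged")
        return self

    def predict(self, X):
        check_is_fitted(self, "models_")
        return np.mean([m.predict(X) for m in self.models_], axis=0)

    def restart_metrics(self, X, y) -> list[Metrics]:
        """Per-restart evaluation (for reporting restart averages)."""
        return [evaluate(m.predict(X), y) for m in self.models_]


def dnn_ensemble(X, y, cfg: DNNConfig, n_restarts: int = 5,
                 X_val=None, y_val=None) -> DNNEnsemble:
    return DNNEnsemble(config=cfg, n_restarts=n_restarts).fit(
        X, y, X_val=X_val, y_val=y_val)


# ---------------------------------------------------------------------------
# Model factory / train / predict / evaluate
# ---------------------------------------------------------------------------

def _dnn_from_config(cfg: DNNConfig) -> DNNRegressor:
    return DNNRegressor(n_hidden_layers=cfg.n_hidden_layers, width=cfg.width,
                        activation=cfg.activation,
                        learning_rate=cfg.learning_rate,
                        init_range=cfg.init_range, minibatch=cfg.minibatch,
                        optimizer=cfg.optimizer, seed=cfg.seed,
                        max_epochs=cfg.max_epochs, patience=cfg.patience)


def make_model(cfg: ModelConfig, n_features: int | None = None):
    """Instantiate an unfitted estimator from a config."""
    if isinstance(cfg, SVRConfig):
        return Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel=cfg.kernel, gamma=cfg.gamma,
                        epsilon=cfg.epsilon, C=cfg.cost)),
        ])
    if isinstance(cfg, RFConfig):
        max_features = cfg.vars_per_split
        if n_features is not None:
            max_features = min(max_features, n_features)
        return RandomForestRegressor(n_estimators=cfg.n_trees,
                                     max_features=max_features,
                                     bootstrap=True, random_state=cfg.seed)
    if isinstance(cfg, DNNConfig):
        return _dnn_from_config(cfg)
    raise TypeError(f"unknown model config {type(cfg).__name__}")


def _as_array(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def train_model(X, y, cfg: ModelConfig, X_val=None, y_val=None):
    """Fit a model; validation data is used only by the DNN (early stopping)."""
    Xa, ya = _as_array(X), np.asarray(y, dtype=float).ravel()
    if len(Xa) != len(ya):
        raise ValueError("X and y lengths differ")
    if len(Xa) < 10:
        raise ValueError("need at least 10 training records")
    if not (np.all(np.isfinite(Xa)) and np.all(np.isfinite(ya))):
        raise ValueError("non-finite values in training data")
    model = make_model(cfg, n_features=Xa.shape[1])
    if isinstance(model, DNNRegressor) and X_val is not None:
        model.fit(Xa, ya, X_val=_as_array(X_val),
                  y_val=np.asarray(y_val, dtype=float).ravel())
    else:
        model.fit(Xa, ya)
    return model


def predict(model, X) -> np.ndarray:
    Xa = _as_array(X)
    if len(Xa) == 0:
        return np.zeros(0)
    return np.asarray(model.predict(Xa), dtype=float)


def evaluate(p, y) -> Metrics:
    """RMSE and Pearson correlation between predictions and labels."""
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(p) != len(y):
        raise ValueError("prediction/label length mismatch")
    if len(p) < 2:
        raise ValueError("need at least 2 records to evaluate")
    if np.ptp(y) == 0:
        raise ValueError("labels are constant; Pearson R is undefined")
    rmse = float(np.sqrt(np.mean((p - y) ** 2)))
    if np.ptp(p) == 0:
        r = 0.0  # degenerate constant predictor: no linear association
    else:
        r = float(pearsonr(p, y)[0])
    return Metrics(rmse=rmse, pearson_r=r)


# ---------------------------------------------------------------------------
# Hyperparameter tuning
# ---------------------------------------------------------------------------

@dataclass
class TuneResult:
    best: ModelConfig
    trace: pd.DataFrame = field(repr=False, default=None)


def tune(X, y, cfg_grid, n_folds: int = 10, search: str = "grid",
         n_iter: int = 20, seed: int = 0, groups=None,
         X_dev=None, y_dev=None) -> TuneResult:
    """Select the config minimizing mean cross-validated RMSE (or dev-set
    RMSE when a dev set is given, as used for the DNN).

    Folds respect `groups` (the grouped-split keys) when provided.  `search`
    is 'grid' (all configs) or 'random' (n_iter configs sampled with `seed`).
    Ties go to the first-listed config.
    """
    cfg_grid = list(cfg_grid)
    if not cfg_grid:
        raise ValueError("empty config grid")
    if search == "random" and len(cfg_grid) > n_iter:
        rng = np.random.default_rng(seed)
        pick = sorted(rng.choice(len(cfg_grid), size=n_iter, replace=False))
        cfg_grid = [cfg_grid[i] for i in pick]
    elif search not in ("grid", "random"):
        raise ValueError("search must be grid or random")

    Xa, ya = _as_array(X), np.asarray(y, dtype=float).ravel()
    rows = []
    for cfg in cfg_grid:
        if X_dev is not None:
            model = train_model(Xa, ya, cfg, X_val=X_dev, y_val=y_dev)
            scores = [float(np.sqrt(np.mean(
                (predict(model, X_dev) - np.asarray(y_dev, float).ravel()) ** 2)))]
        else:
            scores = _cv_rmse(Xa, ya, cfg, n_folds, groups)
        rows.append({"config": cfg, "mean_rmse": float(np.mean(scores)),
                     "fold_rmse": scores})
    trace = pd.DataFrame(rows)
    best_idx = int(trace["mean_rmse"].idxmin())  # stable: first minimum
    return TuneResult(best=trace.loc[best_idx, "config"], trace=trace)


def _cv_rmse(X, y, cfg, n_folds, groups):
    if groups is not None:
        uniq = len(set(groups))
        if uniq < n_folds:
            raise ValueError(f"{uniq} groups < {n_folds} folds")
        splitter = GroupKFold(n_splits=n_folds)
        folds = splitter.split(X, y, groups=groups)
    else:
        splitter = KFold(n_splits=n_folds)
        folds = splitter.split(X, y)
    scores = []
    for tr, te in folds:
        model = train_model(X[tr], y[tr], cfg)
        err = predict(model, X[te]) - y[te]
        scores.append(float(np.sqrt(np.mean(err ** 2))))
    return scores


# ---------------------------------------------------------------------------
# Ablation study
# ---------------------------------------------------------------------------

def default_feature_groups(names) -> dict[str, list[str]]:
    """Group one-hot blocks (secondary structure, residue categories) and the
    SASA pair into named units; every other column ablates alone."""
    groups: dict[str, list[str]] = {}
    block_prefixes = []
    for site in ("mut1", "mut2"):
        block_prefixes += [(f"{site}_sasa", f"{site}_sasa_"),
                           (f"{site}_ss", f"{site}_ss_"),
                           (f"{site}_wt_type", f"{site}_wt_"),
                           (f"{site}_target_type", f"{site}_target_")]
    for name in names:
        for label, prefix in block_prefixes:
            if name.startswith(prefix):
                groups.setdefault(label, []).append(name)
                break
        else:
            groups[name] = [name]
    return groups


def ablate(X: pd.DataFrame, y, cfg: ModelConfig, split,
           feature_groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """One-at-a-time feature ablation.

    For each named feature group, retrain on the training rows without those
    columns and evaluate on the test rows; rows are ranked by drop in
    Pearson R relative to the full-feature baseline (largest drop first).
    `split` is a (train_indices, test_indices) pair or a DatasetSplit.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("ablation requires named feature columns (DataFrame)")
    if hasattr(split, "train"):
        train_idx, test_idx = list(split.train), list(split.test)
    else:
        train_idx, test_idx = (list(s) for s in split)
    y = np.asarray(y, dtype=float).ravel()
    groups = feature_groups or default_feature_groups(X.columns)
    if any(len(cols) >= X.shape[1] for cols in groups.values()):
        raise ValueError("removing a group would empty the feature set")

    def fit_eval(frame: pd.DataFrame) -> Metrics:
        model = train_model(frame.iloc[train_idx], y[train_idx], cfg)
        return evaluate(predict(model, frame.iloc[test_idx]), y[test_idx])

    baseline = fit_eval(X)
    rows = []
    for label, cols in groups.items():
        m = fit_eval(X.drop(columns=cols))
        rows.append({"feature": label, "rmse": m.rmse,
                     "pearson_r": m.pearson_r,
                     "delta_r": baseline.pearson_r - m.pearson_r})
    out = pd.DataFrame(rows).sort_values("delta_r", ascending=False,
                                         kind="stable")
    out.attrs["baseline"] = baseline
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model, path, config: ModelConfig | None = None) -> None:
    joblib.dump({"format_version": MODEL_BUNDLE_VERSION,
                 "model": model, "config": config}, path)


def load_model(path):
    bundle = joblib.load(path)
    if bundle.get("format_version") != MODEL_BUNDLE_VERSION:
        raise ValueError(f"unsupported model bundle version in {path}")
    return bundle["model"]
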