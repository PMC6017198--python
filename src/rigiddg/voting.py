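"""Voting schemes that synthesize one ddG prediction from several models.

Given m models with predictions h_i(x) and reference-set quality metrics
c_i (Pearson R) and r_i (RMSE), each scheme pulls every model's prediction
toward the best model h*(x) in proportion to how much worse it is:

    uwa          mean_i h_i(x)
    c-wa         mean_i [ h_i + (h* - h_i)(1 - c_i/c*) ],  c* = max c_i
    rmse-wa      mean_i [ h_i + (h* - h_i)(1 - r*/r_i) ],  r* = min r_i
    combined-wa  mean_i [ h_i + (h* - h_i)(1 - g_i/g*) ],  g_i = c_i/r_i

Reference metrics may first be recomputed under an outlier policy: a record
is an outlier when its loss-to-RMSE ratio exceeds a threshold; outliers are
either excluded or their residuals scaled by a constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import Metrics, evaluate

SCHEMES = ("uwa", "c-wa", "rmse-wa", "combined-wa")
OUTLIER_MODES = ("none", "exclude", "scale")


@dataclass(frozen=True)
class VotingConfig:
    scheme: str = "combined-wa"
    outlier_threshold: float = np.inf   # tau > 0
    outlier_mode: str = "none"
    scale_factor: float = 1.0           # alpha in (0, 1]
    loss: str = "absolute"              # absolute | squared

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.outlier_mode not in OUTLIER_MODES:
            raise ValueError(f"unknown outlier mode {self.outlier_mode!r}")
        if not self.outlier_threshold > 0:
            raise ValueError("outlier threshold must be > 0")
        if not 0 < self.scale_factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        if self.loss not in ("absolute", "squared"):
            raise ValueError("loss must be absolute or squared")


@dataclass
class ModelOutputs:
    """Aligned per-model predictions plus reference-set metrics."""
    predictions: np.ndarray              # shape (n_records, m)
    c: np.ndarray                        # Pearson R per model
    r: np.ndarray                        # RMSE per model
    names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.predictions = np.atleast_2d(np.asarray(self.predictions, float))
        self.c = np.asarray(self.c, dtype=float).ravel()
        self.r = np.asarray(self.r, dtype=float).ravel()
        m = self.predictions.shape[1]
        if m < 2:
            raise ValueError("voting needs at least 2 models")
        if len(self.c) != m or len(self.r) != m:
            raise ValueError("metrics length must match model count")
        if np.any(self.r <= 0):
            raise ValueError("all model RMSEs must be > 0")
        if not self.names:
            self.names = tuple(f"model_{i}" for i in range(m))

    @property
    def m(self) -> int:
        return self.predictions.shape[1]

    @property
    def gamma(self) -> np.ndarray:
        return self.c / self.r

    @classmethod
    def from_reference(cls, predictions, y_ref, names=(),
                       cfg: VotingConfig | None = None) -> "ModelOutputs":
        """Compute c_i, r_i on a reference (dev) set, applying the config's
        outlier policy to the metric computation when given."""
        predictions = np.atleast_2d(np.asarray(predictions, float))
        cfg = cfg or VotingConfig()
        c, r = [], []
        for j in range(predictions.shape[1]):
            m = metrics_with_outlier_policy(predictions[:, j], y_ref, cfg)
            c.append(m.pearson_r)
            r.append(m.rmse)
        return cls(predictions=predictions, c=np.array(c), r=np.array(r),
                   names=tuple(names))


def metrics_with_outlier_policy(p, y, cfg: VotingConfig) -> Metrics:
    """RMSE and R after the outlier policy.

    A record is an outlier when loss(p - y) / RMSE(p, y) exceeds the
    threshold; mode 'exclude' drops it, mode 'scale' shrinks its residual by
    the scale factor (p' = y + alpha * (p - y)) before re-evaluating.
    """
    p = np.asarray(p, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(p) != len(y):
        raise ValueError("prediction/label length mismatch")
    if cfg.outlier_mode == "none" or np.isinf(cfg.outlier_threshold):
        return evaluate(p, y)
    residual = p - y
    base_rmse = float(np.sqrt(np.mean(residual ** 2)))
    loss = np.abs(residual) if cfg.loss == "absolute" else residual ** 2
    outlier = loss / base_rmse > cfg.outlier_threshold
    if cfg.outlier_mode == "exclude":
        keep = ~outlier
        if keep.sum() < 2:
            raise ValueError("outlier exclusion removed (almost) all records")
        return evaluate(p[keep], y[keep])
    adjusted = np.where(outlier, y + cfg.scale_factor * residual, p)
    return evaluate(adjusted, y)


def vote(outputs: ModelOutputs, cfg: VotingConfig) -> np.ndarray:
    """Voted per-record predictions under the chosen scheme."""
    h = outputs.predictions
    if cfg.scheme == "uwa":
        return h.mean(axis=1)
    if cfg.scheme == "c-wa":
        if np.any(outputs.c < 0) or outputs.c.max() <= 0:
            raise ValueError("c-wa requires positive Pearson correlations")
        best = int(np.argmax(outputs.c))
        factor = 1.0 - outputs.c / outputs.c[best]
    elif cfg.scheme == "rmse-wa":
        best = int(np.argmin(outputs.r))
        factor = 1.0 - outputs.r[best] / outputs.r
    else:  # combined-wa
        if np.any(outputs.c < 0) or outputs.c.max() <= 0:
            raise ValueError("combined-wa requires positive Pearson correlations")
        gamma = outputs.gamma
        best = int(np.argmax(gamma))
        factor = 1.0 - gamma / gamma[best]
    h_star = h[:, best][:, None]
    adjusted = h + (h_star - h) * factor[None, :]
    return adjusted.mean(axis=1)


@dataclass
class VotingTuneResult:
    best: dict[str, VotingConfig]
    trace: list = field(default_factory=list, repr=False)


def tune_voting(dev_predictions, y_dev, grid, names=()) -> VotingTuneResult:
    """Per scheme, pick the config maximizing dev-set R (ties: lower RMSE,
    then first-listed).  The chosen configs are applied unchanged to test."""
    grid = list(grid)
    if not grid:
        raise ValueError("empty voting grid")
    y_dev = np.asarray(y_dev, dtype=float).ravel()
    best: dict[str, tuple] = {}
    trace = []
    for order, cfg in enumerate(grid):
        outputs = ModelOutputs.from_reference(dev_predictions, y_dev,
                                              names=names, cfg=cfg)
        voted = vote(outputs, cfg)
        m = evaluate(voted, y_dev)
        trace.append({"config": cfg, "dev_r": m.pearson_r, "dev_rmse": m.rmse})
        key = (-m.pearson_r, m.rmse, order)
        if cfg.scheme not in best or key < best[cfg.scheme][0]:
            best[cfg.scheme] = (key, cfg)
    return VotingTuneResult(best={s: v[1] for s, v in best.items()},
                            trace=trace)


def default_voting_grid(schemes=SCHEMES) -> list[VotingConfig]:
    """tau in {1.5, 2, 2.5, 3, inf} x modes, alpha in {0.25, 0.5, 1}."""
    grid = []
    for scheme in schemes:
        grid.append(VotingConfig(scheme=scheme))
        for tau in (1.5, 2.0, 2.5, 3.0):
            grid.append(VotingConfig(scheme=scheme, outlier_threshold=tau,
                                     outlier_mode="exclude"))
            for alpha in (0.25, 0.5):
                grid.append(VotingConfig(scheme=scheme, outlier_threshold=tau,
                                         outlier_mode="scale",
                                         scale_factor=alpha))
    return grid


class WeightedVotingRegressor:
    """Estimator-shaped wrapper: fit() learns the per-model reference
    metrics from dev-set predictions, predict() votes on new prediction
    matrices (rows = records, columns = models)."""

    def __init__(self, scheme: str = "combined-wa",
                 outlier_threshold: float = np.inf,
                 outlier_mode: str = "none", scale_factor: float = 1.0,
                 loss: str = "absolute"):
        self.scheme = scheme
        self.outlier_threshold = outlier_threshold
        self.outlier_mode = outlier_mode
        self.scale_factor = scale_factor
        self.loss = loss

    def _config(self) -> VotingConfig:
        return VotingConfig(scheme=self.scheme,
                            outlier_threshold=self.outlier_threshold,
                            outlier_mode=self.outlier_mode,
                            scale_factor=self.scale_factor, loss=self.loss)

    def get_params(self, deep=True):
        return {"scheme": self.scheme,
                "outlier_threshold": self.outlier_threshold,
                "outlier_mode": self.outlier_mode,
                "scale_factor": self.scale_factor, "loss": self.loss}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, H_dev, y_dev):
        cfg = self._config()
        ref = ModelOutputs.from_reference(H_dev, y_dev, cfg=cfg)
        self.c_ = ref.c
        self.r_ = ref.r
        self.n_models_ = ref.m
        return self

    def predict(self, H):
        if not hasattr(self, "c_"):
            raise RuntimeError("fit before predict")
        outputs = ModelOutputs(predictions=H, c=self.c_, r=self.r_)
        return vote(outputs, self._config())
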