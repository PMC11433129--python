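"""Gradient-boosted tree classifier with Bayesian hyperparameter search.

The classifier is XGBoost (binary logistic objective, histogram tree
method, single-threaded for bit-reproducibility).  The search is a small
Gaussian-process Bayesian optimization loop: a Matern-5/2 surrogate over
the unit-cube-normalized hyperparameter space, expected-improvement
acquisition maximized over random candidates, and the trial with the
highest validation AUC wins.  No canonical search space exists for this
problem; the bounds here are conventional wide defaults, fully configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_auc_score

from .errors import ContractError, TuningError
from .preprocess import EncodedMatrix


@dataclass(frozen=True)
class HyperParams:
    """One hyperparameter combination for the boosted-tree learner."""

    max_depth: int = 6
    num_boost_round: int = 200
    learning_rate: float = 0.1
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    min_child_weight: float = 1.0
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0

    def to_xgb(self, seed: int) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "auc",
            "tree_method": "hist",
            "nthread": 1,
            "seed": int(seed),
            "max_depth": int(self.max_depth),
            "eta": float(self.learning_rate),
            "subsample": float(self.subsample),
            "colsample_bytree": float(self.colsample_bytree),
            "min_child_weight": float(self.min_child_weight),
            "lambda": float(self.reg_lambda),
            "alpha": float(self.reg_alpha),
        }


#: (low, high, scale) per tunable dimension; scale in {"int", "linear", "log"}
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float, str]] = {
    "max_depth": (2, 10, "int"),
    "num_boost_round": (50, 2000, "int"),
    "learning_rate": (1e-3, 0.3, "log"),
    "subsample": (0.5, 1.0, "linear"),
    "colsample_bytree": (0.5, 1.0, "linear"),
    "min_child_weight": (0.0, 10.0, "linear"),
    "reg_lambda": (1e-3, 10.0, "log"),
    "reg_alpha": (1e-4, 1.0, "log"),
}


def desk_search_space() -> dict[str, tuple[float, float, str]]:
    """A trimmed space for quick desk-scale runs (fewer, shallower trees)."""
    space = dict(DEFAULT_SEARCH_SPACE)
    space["num_boost_round"] = (30, 300, "int")
    space["max_depth"] = (2, 8, "int")
    return space


@dataclass
class ModelHandle:
    """A fitted booster plus the feature order it was trained with."""

    booster: xgb.Booster
    feature_names: list[str]
    params: HyperParams
    seed: int

    def _dmatrix(self, X: EncodedMatrix | np.ndarray) -> xgb.DMatrix:
        values = X.values if isinstance(X, EncodedMatrix) else np.asarray(X)
        if values.shape[1] != len(self.feature_names):
            raise ContractError(
                f"feature count mismatch: model has {len(self.feature_names)}, "
                f"data has {values.shape[1]}"
            )
        if isinstance(X, EncodedMatrix) and X.feature_names != self.feature_names:
            raise ContractError("feature order differs from training order")
        return xgb.DMatrix(values, feature_names=self.feature_names, nthread=1)

    def predict_proba(self, X: EncodedMatrix | np.ndarray) -> np.ndarray:
        return self.booster.predict(self._dmatrix(X))

    def predict_margin(self, X: EncodedMatrix | np.ndarray) -> np.ndarray:
        return self.booster.predict(self._dmatrix(X), output_margin=True)

    def save(self, path) -> None:
        self.booster.save_model(str(path))  # native JSON text format


@dataclass(frozen=True)
class Metrics:
    """Held-out discrimination metrics; accuracy is at threshold 0.5."""

    auc: float
    accuracy_at_half: float
    n_evaluated: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def fit(
    X: EncodedMatrix,
    y: np.ndarray,
    params: HyperParams | None = None,
    seed: int = 0,
) -> ModelHandle:
    """Train a boosted-tree model; deterministic for a fixed seed."""
    params = params or HyperParams()
    y = np.asarray(y)
    if X.n_rows != len(y):
        raise ContractError("row count mismatch between matrix and labels")
    dtrain = xgb.DMatrix(
        X.values, label=y, feature_names=X.feature_names, nthread=1
    )
    booster = xgb.train(
        params.to_xgb(seed), dtrain, num_boost_round=int(params.num_boost_round)
    )
    return ModelHandle(booster, list(X.feature_names), params, seed)


def evaluate(model: ModelHandle, X: EncodedMatrix, y: np.ndarray) -> Metrics:
    """AUC and accuracy-at-0.5 on a held-out set (both classes required)."""
    y = np.asarray(y)
    if len(y) == 0:
        raise ContractError("empty evaluation set")
    if len(np.unique(y)) < 2:
        raise ContractError("AUC undefined: evaluation set has one class")
    proba = model.predict_proba(X)
    auc = float(roc_auc_score(y, proba))
    acc = float(np.mean((proba >= 0.5).astype(np.int64) == y))
    return Metrics(auc=auc, accuracy_at_half=acc, n_evaluated=int(len(y)))


# ---------------------------------------------------------------------------
# Bayesian search


def _decode(z: np.ndarray, space: dict) -> HyperParams:
    kw = {}
    for zi, (name, (lo, hi, scale)) in zip(z, space.items()):
        if scale == "log":
            val = float(np.exp(np.log(lo) + zi * (np.log(hi) - np.log(lo))))
        else:
            val = float(lo + zi * (hi - lo))
        if scale == "int":
            val = int(round(val))
        kw[name] = val
    return HyperParams(**kw)


def _expected_improvement(
    gp: GaussianProcessRegressor, cand: np.ndarray, best: float, xi: float = 1e-3
) -> np.ndarray:
    mu, sd = gp.predict(cand, return_std=True)
    sd = np.maximum(sd, 1e-12)
    imp = mu - best - xi
    zz = imp / sd
    return imp * norm.cdf(zz) + sd * norm.pdf(zz)


@dataclass
class TuneResult:
    """Winner of the search plus the full trial log."""

    best_params: HyperParams
    best_auc: float
    trials: pd.DataFrame = field(repr=False)


def tune(
    X_train: EncodedMatrix,
    y_train: np.ndarray,
    X_val: EncodedMatrix,
    y_val: np.ndarray,
    budget: int = 50,
    seed: int = 0,
    space: dict[str, tuple[float, float, str]] | None = None,
) -> TuneResult:
    """Bayesian search over ``space``, selecting by validation AUC.

    The first ``max(4, budget//4)`` trials are random; afterwards each trial
    maximizes expected improvement under a Gaussian-process surrogate fit to
    the observed (combination, AUC) pairs.
    """
    if budget < 1:
        raise TuningError("budget must be >= 1")
    for lab, arr in (("training", y_train), ("validation", y_val)):
        if len(np.unique(np.asarray(arr))) < 2:
            raise TuningError(f"degenerate {lab} labels: one class only")
    space = space or DEFAULT_SEARCH_SPACE
    d = len(space)
    rng = np.random.default_rng(seed)
    n_init = min(budget, max(4, budget // 4))
    Z: list[np.ndarray] = []
    records: list[dict] = []
    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(d, 0.3), nu=2.5) + WhiteKernel(1e-4)
    for t in range(budget):
        if t < n_init or len(records) < 2:
            z = rng.random(d)
        else:
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, alpha=1e-8, random_state=0
            )
            gp.fit(np.vstack(Z), np.array([r["auc"] for r in records]))
            cand = rng.random((256, d))
            ei = _expected_improvement(gp, cand, max(r["auc"] for r in records))
            z = cand[int(np.argmax(ei))]
        params = _decode(z, space)
        model = fit(X_train, y_train, params, seed=seed)
        auc = evaluate(model, X_val, y_val).auc
        Z.append(z)
        records.append({"trial": t, "auc": auc, **asdict(params)})
    trials = pd.DataFrame.from_records(records)
    best = trials["auc"].idxmax()
    best_params = HyperParams(
        **{k: trials.loc[best, k] for k in HyperParams.__dataclass_fields__}
    )
    return TuneResult(best_params=best_params, best_auc=float(trials.loc[best, "auc"]), trials=trials)
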