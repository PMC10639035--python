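"""Gradient-boosted tree classifier and Bayesian hyperparameter search.

The final classifier is a gradient-boosted decision-tree ensemble.  The
method family this package implements was designed around an
ordered-boosting engine (residuals computed on examples unseen by
earlier trees, avoiding prediction shift); the engine used here is
XGBoost, a standard gradient-boosting fallback, and the engine name is
recorded in the fitted model's metadata so downstream reports are
explicit about it.

Hyperparameter search follows the classic Bayesian-optimization loop:
declare a search space, define a cross-validated objective, fit a
probabilistic surrogate (Gaussian process) to the observed trials,
acquire the next candidate by expected improvement, iterate to a budget,
and deliver the best trial.  Everything is seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

ENGINE = "xgboost"


@dataclass
class BoostParams:
    """Core boosted-ensemble hyperparameters (engine-agnostic names)."""

    n_trees: int = 300
    depth: int = 6
    learning_rate: float = 0.1
    l2_reg: float = 1.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_trees < 1 or self.depth < 1 or self.learning_rate <= 0:
            raise ValueError("invalid boosting parameters")


class OrderedBoostedClassifier(ClassifierMixin, BaseEstimator):
    """Seeded gradient-boosted tree binary classifier (XGBoost engine)."""

    def __init__(self, n_trees=300, depth=6, learning_rate=0.1, l2_reg=1.0, seed=0, extra=None):
        self.n_trees = n_trees
        self.depth = depth
        self.learning_rate = learning_rate
        self.l2_reg = l2_reg
        self.seed = seed
        self.extra = extra

    def _check_X(self, X) -> np.ndarray:
        Xm = np.asarray(getattr(X, "matrix", X), dtype=float)
        if not np.isfinite(Xm).all():
            bad = sorted(set(np.argwhere(~np.isfinite(Xm))[:, 1].tolist()))
            raise ValueError(f"non-finite values in feature columns {bad[:10]}")
        return Xm

    def fit(self, X, y):
        BoostParams(self.n_trees, self.depth, self.learning_rate, self.l2_reg, self.seed).validate()
        Xm = self._check_X(X)
        y = np.asarray(y).ravel()
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("single-class training labels")
        self.classes_ = classes
        self.model_ = xgb.XGBClassifier(
            n_estimators=int(self.n_trees),
            max_depth=int(self.depth),
            learning_rate=float(self.learning_rate),
            reg_lambda=float(self.l2_reg),
            random_state=int(self.seed),
            n_jobs=1,
            tree_method="exact",
            eval_metric="logloss",
            **(self.extra or {}),
        )
        self.model_.fit(Xm, y)
        self.n_features_in_ = Xm.shape[1]
        self.metadata_ = {
            "engine": ENGINE,
            "ordered_boosting": False,  # XGBoost uses conventional boosting
            "params": {
                "n_trees": self.n_trees,
                "depth": self.depth,
                "learning_rate": self.learning_rate,
                "l2_reg": self.l2_reg,
                "seed": self.seed,
            },
        }
        return self

    def _check_fitted(self, X) -> np.ndarray:
        Xm = self._check_X(X)
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {Xm.shape[1]}")
        return Xm

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(self._check_fitted(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def raw_margin(self, X) -> np.ndarray:
        return self.model_.get_booster().predict(
            xgb.DMatrix(self._check_fitted(X)), output_margin=True
        )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.model_.get_booster().save_model(str(d / "engine.json"))
        (d / "params.json").write_text(json.dumps(self.metadata_, indent=2))

    @classmethod
    def load(cls, directory) -> "OrderedBoostedClassifier":
        d = Path(directory)
        meta = json.loads((d / "params.json").read_text())
        est = cls(**meta["params"])
        est.model_ = xgb.XGBClassifier()
        est.model_.load_model(str(d / "engine.json"))
        est.n_features_in_ = est.model_.get_booster().num_features()
        est.classes_ = np.array([0, 1])
        est.metadata_ = meta
        return est


def train_classifier(X, y, params: BoostParams | None = None) -> OrderedBoostedClassifier:
    p = params or BoostParams()
    return OrderedBoostedClassifier(
        n_trees=p.n_trees, depth=p.depth, learning_rate=p.learning_rate,
        l2_reg=p.l2_reg, seed=p.seed, extra=p.extra or None,
    ).fit(X, y)


def predict_proba(model: OrderedBoostedClassifier, X) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# Bayesian hyperparameter search


@dataclass(frozen=True)
class ParamRange:
    """One search-space dimension."""

    name: str
    kind: str  # int | float | logfloat | categorical
    low: float | None = None
    high: float | None = None
    choices: tuple | None = None

    def sample(self, rng: np.random.Generator):
        return self.decode(rng.random())

    def decode(self, u: float):
        """Map the unit interval to a parameter value."""
        if self.kind == "categorical":
            i = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[i]
        if self.kind == "int":
            return int(round(self.low + u * (self.high - self.low)))
        if self.kind == "float":
            return self.low + u * (self.high - self.low)
        if self.kind == "logfloat":
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        raise ValueError(self.kind)

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.choices
        return self.low <= value <= self.high


DEFAULT_SEARCH_SPACE = (
    ParamRange("n_trees", "int", 100, 1000),
    ParamRange("depth", "int", 4, 10),
    ParamRange("learning_rate", "logfloat", 1e-3, 0.3),
    ParamRange("l2_reg", "float", 1.0, 10.0),
)


@dataclass
class TrialRecord:
    trial_id: int
    params: dict
    objective: float
    fold_scores: list = field(default_factory=list)


def tune_hyperparameters(
    objective,
    space=DEFAULT_SEARCH_SPACE,
    budget: int = 25,
    seed: int = 0,
    n_init: int = 8,
    maximize: bool = True,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Sequential Gaussian-process search over ``space``.

    ``objective(params_dict) -> float`` (or ``(float, fold_scores)``); the
    first ``n_init`` trials are random, later candidates maximize expected
    improvement of a GP surrogate fitted to the unit-cube encodings of all
    finished trials.  Returns (best trial, all trials).
    """
    space = tuple(space)
    if not space:
        raise ValueError("empty search space")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    encoded: list[np.ndarray] = []
    values: list[float] = []

    def run_trial(u: np.ndarray, tid: int):
        params = {dim.name: dim.decode(ui) for dim, ui in zip(space, u)}
        res = objective(params)
        obj, folds = res if isinstance(res, tuple) else (res, [])
        trials.append(TrialRecord(tid, params, float(obj), list(folds)))
        encoded.append(u)
        values.append(float(obj) if maximize else -float(obj))

    for t in range(min(n_init, budget)):
        run_trial(rng.random(len(space)), t)
    for t in range(len(trials), budget):
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * RBF(0.3) + WhiteKernel(1e-4),
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(np.vstack(encoded), np.asarray(values))
        cand = rng.random((256, len(space)))
        mu, sd = gp.predict(cand, return_std=True)
        best = max(values)
        sd = np.maximum(sd, 1e-12)
        z = (mu - best) / sd
        ei = (mu - best) * norm.cdf(z) + sd * norm.pdf(z)
        run_trial(cand[int(np.argmax(ei))], t)
    best_trial = max(trials, key=lambda tr: tr.objective if maximize else -tr.objective)
    return best_trial, trials


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    rows = [{"trial_id": t.trial_id, "objective": t.objective, **t.params} for t in trials]
    return pd.DataFrame(rows)
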