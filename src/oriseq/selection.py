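"""Shapley-value feature attribution, ranking and selection.

For a fitted gradient-boosted tree ensemble the per-sample attributions
are exact TreeSHAP values computed on the raw margin (log-odds), so the
additive decomposition  base value + Σ_t attribution_t  reproduces the
model output for every sample (local accuracy).  For arbitrary models a
seeded permutation-sampling estimator over a background sample is used
instead.  Features are ranked by mean |attribution| (descending, ties
broken by ascending column index) and the top_k highest-ranked features
form the selection mask.

The selector is leakage-safe by construction: it is fitted on training
rows only and the frozen mask is then applied to any later split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .fusion import FusedMatrix


@dataclass
class AttributionReport:
    """Per-sample additive attributions plus the derived ranking/mask."""

    base_value: float
    attributions: np.ndarray  # n x D
    mean_abs: np.ndarray  # D
    ranking: np.ndarray | None = None  # permutation of 0..D-1
    selected_mask: np.ndarray | None = None  # D booleans
    top_k: int | None = None
    feature_names: list[str] | None = None

    def to_frame(self, blocks: list[str] | None = None) -> pd.DataFrame:
        d = len(self.mean_abs)
        rank_of = np.empty(d, dtype=int)
        rank_of[self.ranking] = np.arange(d)
        return pd.DataFrame(
            {
                "feature": self.feature_names if self.feature_names else [str(i) for i in range(d)],
                "block": blocks if blocks else [""] * d,
                "mean_abs": self.mean_abs,
                "rank": rank_of,
                "selected": self.selected_mask,
            }
        )

    def top_features(self, k: int = 20) -> pd.DataFrame:
        df = self.to_frame().sort_values("rank").head(k)
        return df.reset_index(drop=True)


def _find_booster(model) -> xgb.Booster | None:
    """Unwrap to an xgboost Booster if the model is tree-based."""
    for candidate in (model, getattr(model, "model_", None)):
        if isinstance(candidate, xgb.Booster):
            return candidate
        if hasattr(candidate, "get_booster"):
            return candidate.get_booster()
    return None


def shapley_attributions(
    model,
    X,
    background: np.ndarray | None = None,
    n_samples: int = 64,
    seed: int = 0,
) -> AttributionReport:
    """Additive per-feature attributions of a fitted model on X.

    Tree ensembles (XGBoost) use the exact path-dependent TreeSHAP on the
    margin; anything else falls back to a seeded permutation-sampling
    estimator over ``background`` rows.
    """
    Xm = X.matrix if isinstance(X, FusedMatrix) else np.asarray(X, dtype=float)
    names = X.feature_names if isinstance(X, FusedMatrix) else None
    booster = _find_booster(model)
    if booster is not None:
        if booster.num_features() != Xm.shape[1]:
            raise ValueError(
                f"model expects {booster.num_features()} features, got {Xm.shape[1]}"
            )
        contribs = booster.predict(xgb.DMatrix(Xm), pred_contribs=True)
        base = float(contribs[0, -1])
        attr = contribs[:, :-1]
    else:
        if background is None or len(background) == 0:
            raise ValueError("background sample required for non-tree models")
        attr, base = _sampling_shap(model, Xm, np.asarray(background), n_samples, seed)
    mean_abs = np.abs(attr).mean(axis=0)
    return AttributionReport(
        base_value=base, attributions=attr, mean_abs=mean_abs, feature_names=names
    )


def _predict_raw(model, X):
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X), dtype=float)[:, 1]
    return np.asarray(model.predict(X), dtype=float)


def _sampling_shap(model, X, background, n_samples, seed):
    """Permutation-sampling Shapley estimate (Štrumbelj-Kononenko style)."""
    rng = np.random.default_rng(seed)
    n, d = X.shape
    base = float(_predict_raw(model, background).mean())
    attr = np.zeros((n, d))
    for _ in range(n_samples):
        perm = rng.permutation(d)
        bg = background[rng.integers(len(background), size=n)]
        cur = bg.copy()
        prev = _predict_raw(model, cur)
        for j in perm:
            cur[:, j] = X[:, j]
            nxt = _predict_raw(model, cur)
            attr[:, j] += nxt - prev
            prev = nxt
    return attr / n_samples, base


def rank_and_select(report: AttributionReport, top_k: int) -> AttributionReport:
    """Rank by descending mean |attribution| (index tiebreak); keep top_k."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    d = len(report.mean_abs)
    # lexsort: primary descending mean_abs, secondary ascending index
    ranking = np.lexsort((np.arange(d), -report.mean_abs))
    mask = np.zeros(d, dtype=bool)
    mask[ranking[: min(top_k, d)]] = True
    report.ranking = ranking
    report.selected_mask = mask
    report.top_k = min(top_k, d)
    return report


class ShapleyFeatureSelector(SelectorMixin, BaseEstimator):
    """Fit an auxiliary boosted model, attribute, and keep the top_k columns.

    Parameters
    ----------
    top_k : int or None
        Number of columns kept; None keeps min(500, D).
    model_params : dict
        Passed to the auxiliary XGBClassifier.
    seed : int
        Seeds the auxiliary model and any sampling estimator.
    """

    def __init__(self, top_k=None, model_params=None, seed=0):
        self.top_k = top_k
        self.model_params = model_params
        self.seed = seed

    def fit(self, X, y):
        from .model import OrderedBoostedClassifier

        Xm = X.matrix if isinstance(X, FusedMatrix) else np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        params = dict(self.model_params or {})
        params.setdefault("seed", self.seed)
        aux = OrderedBoostedClassifier(**params).fit(Xm, y)
        report = shapley_attributions(aux.model_, Xm)
        k = self.top_k if self.top_k is not None else min(500, Xm.shape[1])
        self.report_ = rank_and_select(report, k)
        self.n_features_in_ = Xm.shape[1]
        return self

    def _get_support_mask(self):
        return self.report_.selected_mask

    def transform(self, X):
        Xm = X.matrix if isinstance(X, FusedMatrix) else np.asarray(X, dtype=float)
        if Xm.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {Xm.shape[1]}"
            )
        return Xm[:, self._get_support_mask()]

    def block_importance(self, fused: FusedMatrix) -> pd.DataFrame:
        """Mean |attribution| summed per block (plot-ready summary)."""
        rows = []
        for e in fused.registry:
            rows.append(
                {
                    "block": e.block,
                    "total_mean_abs": float(self.report_.mean_abs[e.start : e.stop].sum()),
                    "n_features": e.stop - e.start,
                    "n_selected": int(self.report_.selected_mask[e.start : e.stop].sum()),
                }
            )
        return pd.DataFrame(rows)
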