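"""Boosted-tree classification of interferome expression classes.

A drop-out regularised (DART) gradient-boosted tree ensemble is trained to
distinguish two gene classes (e.g. ISG vs IRG) from the 185 compositional
features. Model quality is assessed by 50 replicates of stratified 5-fold
cross-validation; per-class accuracy is the proportion of genes of that
class correctly identified among out-of-fold predictions. Hyperparameters
are chosen by cross-validated accuracy over randomly sampled combinations
from a documented grid, then the final model is refit on all data.

Feature importance uses TreeSHAP: per-gene per-feature Shapley values of
the final model, summarised as the mean absolute value per feature across
genes, summed over the features making up each broad feature class (all six
measures of one dinucleotide pool into that dinucleotide's class), and
rescaled so the largest class aggregate is exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import ParameterSampler, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .composition import FEATURE_NAMES, feature_classes

#: hyperparameter grid for the random search; configuration, not science
DEFAULT_PARAM_GRID: dict[str, list] = {
    "max_depth": [2, 3, 4, 5, 6],
    "learning_rate": [0.03, 0.05, 0.1, 0.2, 0.3],
    "n_estimators": [30, 60, 100, 150],
    "rate_drop": [0.0, 0.05, 0.1, 0.2],
    "subsample": [0.6, 0.8, 1.0],
    "colsample_bytree": [0.6, 0.8, 1.0],
    "min_child_weight": [1, 3, 5],
}


class InterferomeClassifier(ClassifierMixin, BaseEstimator):
    """Two-class DART boosted-regression-tree classifier over gene features.

    Thin sklearn-compatible wrapper around XGBoost's DART booster that
    records the training feature names and exposes per-gene Shapley values.

    Parameters mirror the XGBoost names; ``rate_drop`` is the DART tree
    drop-out rate (0 recovers plain gradient boosting).
    """

    def __init__(
        self,
        max_depth: int = 4,
        learning_rate: float = 0.1,
        n_estimators: int = 60,
        rate_drop: float = 0.1,
        subsample: float = 0.8,
        colsample_bytree: float = 0.8,
        min_child_weight: int = 1,
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.n_estimators = n_estimators
        self.rate_drop = rate_drop
        self.subsample = subsample
        self.colsample_bytree = colsample_bytree
        self.min_child_weight = min_child_weight
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            if not all(isinstance(c, str) for c in X.columns):
                X = X.rename(columns=str)
            return X
        X = np.asarray(X, float)
        if hasattr(self, "feature_names_") and X.shape[1] == len(self.feature_names_):
            return pd.DataFrame(X, columns=self.feature_names_)
        return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])

    def _check_features(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [n for n in self.feature_names_ if n not in X.columns]
        extra = [n for n in X.columns if n not in self.feature_names_]
        if missing or extra:
            raise ValueError(
                f"feature names do not match training: missing={missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}, extra={extra[:5]}"
                f"{'...' if len(extra) > 5 else ''}"
            )
        return X[list(self.feature_names_)]

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y) -> "InterferomeClassifier":
        X = self._as_frame(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of genes")
        if not np.all(np.isfinite(X.to_numpy(float))):
            raise ValueError("features must be finite")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need two classes to train a classifier")
        if len(self.classes_) > 2:
            raise ValueError("only two-class problems are supported")
        self.feature_names_ = list(X.columns)
        y_enc = (y == self.classes_[1]).astype(int)
        self._booster_args = dict(
            booster="dart",
            tree_method="hist",
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            n_estimators=self.n_estimators,
            rate_drop=self.rate_drop,
            subsample=self.subsample,
            colsample_bytree=self.colsample_bytree,
            min_child_weight=self.min_child_weight,
            random_state=self.random_state,
            n_jobs=1,
            eval_metric="logloss",
        )
        self.model_ = xgboost.XGBClassifier(**self._booster_args)
        self.model_.fit(X, y_enc)
        self.booster_ = self.model_.get_booster()
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        X = self._check_features(self._as_frame(X))
        dmat = xgboost.DMatrix(X, feature_names=list(X.columns))
        p1 = self.booster_.predict(dmat)
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] >= 0.5).astype(int)]

    # -- Shapley attributions ---------------------------------------------

    def shap_values(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene per-feature TreeSHAP values and per-gene base values.

        The attributions are on the margin (log-odds) scale of the positive
        class (``classes_[1]``); each row sums with its base value to the
        model's margin output.
        """
        check_is_fitted(self, "booster_")
        X = self._check_features(self._as_frame(X))
        dmat = xgboost.DMatrix(X, feature_names=list(X.columns))
        contrib = self.booster_.predict(dmat, pred_contribs=True)
        return contrib[:, :-1], contrib[:, -1]

    def margin(self, X) -> np.ndarray:
        check_is_fitted(self, "booster_")
        X = self._check_features(self._as_frame(X))
        dmat = xgboost.DMatrix(X, feature_names=list(X.columns))
        return self.booster_.predict(dmat, output_margin=True)

    # -- serialisation -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise to a single JSON file with an embedded feature manifest."""
        check_is_fitted(self, "booster_")
        raw = self.booster_.save_raw(raw_format="json").decode()
        payload = {
            "format": "ifncomp-classifier",
            "version": 1,
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "feature_names": self.feature_names_,
            "booster": json.loads(raw),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "InterferomeClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "ifncomp-classifier":
            raise ValueError(f"{path}: not a serialised classifier")
        est = cls(**payload["params"])
        est.classes_ = np.asarray(payload["classes"])
        est.feature_names_ = list(payload["feature_names"])
        est.n_features_in_ = len(est.feature_names_)
        booster = xgboost.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        booster.feature_names = est.feature_names_
        est.booster_ = booster
        return est


# --------------------------------------------------------------------------
# Cross-validation and tuning


@dataclass(frozen=True)
class CvReport:
    """Accuracy summary over repeated stratified k-fold cross-validation."""

    per_class_accuracy: Mapping[str, float]  # mean over replicates
    interval_95: Mapping[str, tuple[float, float]]  # central 95% of observed
    replicate_accuracies: pd.DataFrame  # replicate x class
    folds: int
    replicates: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(list(self.per_class_accuracy.values())))

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "replicates": self.replicates,
            "per_class_accuracy": dict(self.per_class_accuracy),
            "interval_95": {k: list(v) for k, v in self.interval_95.items()},
            "mean_accuracy": self.mean_accuracy,
        }


def repeated_cv(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 5,
    replicates: int = 50,
    seed: int = 0,
    estimator: InterferomeClassifier | None = None,
) -> CvReport:
    """Repeated stratified k-fold CV; per-class accuracy per replicate.

    Each replicate reshuffles the stratified fold assignment; within a
    replicate every fold serves once as the test set and the per-class
    accuracy is the proportion of genes of that class correctly identified
    among the pooled out-of-fold predictions.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} genes, fewer than {folds} folds"
        )
    base = estimator if estimator is not None else InterferomeClassifier()
    seeds = np.random.SeedSequence(seed).generate_state(replicates)
    rows = []
    X = features
    for rep, rep_seed in enumerate(seeds):
        rep_seed = int(rep_seed % (2 ** 31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        pred = np.empty(len(labels), dtype=labels.dtype)
        for train_idx, test_idx in skf.split(X, labels):
            est = base.__class__(**base.get_params())
            est.set_params(random_state=rep_seed)
            est.fit(X.iloc[train_idx], labels[train_idx])
            pred[test_idx] = est.predict(X.iloc[test_idx])
        rows.append({c: float(np.mean(pred[labels == c] == c)) for c in classes})
    rep_df = pd.DataFrame(rows)
    per_class = {str(c): float(rep_df[c].mean()) for c in classes}
    interval = {
        str(c): (
            float(np.percentile(rep_df[c], 2.5)),
            float(np.percentile(rep_df[c], 97.5)),
        )
        for c in classes
    }
    return CvReport(
        per_class_accuracy=per_class,
        interval_95=interval,
        replicate_accuracies=rep_df,
        folds=folds,
        replicates=replicates,
    )


def tune_and_train(
    features: pd.DataFrame,
    labels: Sequence[str],
    n_combos: int = 100,
    seed: int = 0,
    folds: int = 5,
    param_grid: Mapping[str, list] | None = None,
) -> tuple[InterferomeClassifier, dict]:
    """Random hyperparameter search, then refit the best model on all data.

    ``n_combos`` random combinations are drawn from the grid; each is scored
    by stratified ``folds``-fold cross-validated mean per-class accuracy and
    the best (ties: first drawn) is refit on the full data set.

    Returns the fitted classifier and the chosen hyperparameters.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need two classes to train a classifier")
    grid = dict(param_grid if param_grid is not None else DEFAULT_PARAM_GRID)
    sampler = ParameterSampler(grid, n_iter=n_combos, random_state=seed)
    best_score, best_params = -np.inf, None
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(features, labels))
    for params in sampler:
        correct = 0
        for train_idx, test_idx in splits:
            est = InterferomeClassifier(random_state=seed, **params)
            est.fit(features.iloc[train_idx], labels[train_idx])
            correct += int(
                (est.predict(features.iloc[test_idx]) == labels[test_idx]).sum()
            )
        score = correct / len(labels)
        if score > best_score:
            best_score, best_params = score, params
    final = InterferomeClassifier(random_state=seed, **best_params)
    final.fit(features, labels)
    return final, {"params": best_params, "cv_accuracy": best_score}


# --------------------------------------------------------------------------
# Prediction helpers


def predict_probability(
    model: InterferomeClassifier, features: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene class probabilities (columns named by class label)."""
    proba = model.predict_proba(features)
    return pd.DataFrame(proba, index=features.index,
                        columns=[str(c) for c in model.classes_])


def classify_external(
    model: InterferomeClassifier,
    features: pd.DataFrame,
    labels: Sequence[str],
) -> dict[str, tuple[int, int]]:
    """Counts of correctly argmax-classified genes per true class.

    Returns {class: (n_correct, n_total)} for each class present in the
    model; classes absent from ``labels`` report (0, 0).
    """
    labels = np.asarray(labels)
    pred = model.predict(features)
    out = {}
    for c in model.classes_:
        mask = labels == c
        out[str(c)] = (int((pred[mask] == c).sum()), int(mask.sum()))
    return out


# --------------------------------------------------------------------------
# Feature importance


@dataclass(frozen=True)
class ImportanceReport:
    """Aggregated Shapley-value feature importance of a trained model."""

    per_feature_mean_abs: pd.Series  # mean |SHAP| per feature across genes
    class_aggregate: pd.Series  # per feature class, before rescaling
    class_rescaled: pd.Series  # aggregate / max, so max == 1
    shap_matrix: pd.DataFrame  # per-gene per-feature Shapley values (audit)
    aggregation: str  # "mean" or "sum"

    def top(self, n: int = 15) -> pd.Series:
        return self.class_rescaled.sort_values(ascending=False).head(n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aggregate": self.class_aggregate, "rescaled": self.class_rescaled}
        ).sort_values("rescaled", ascending=False)


def feature_importance(
    model: InterferomeClassifier,
    features: pd.DataFrame,
    aggregation: Literal["mean", "sum"] = "mean",
) -> ImportanceReport:
    """Aggregate per-gene Shapley values into per-feature-class importances.

    Per feature: the mean (or, optionally, sum) of absolute Shapley values
    across genes. Per feature class: the sum over its member features —
    e.g. the CpG class pools the whole-transcript CG bias and proportion,
    ORF CG bias and proportion, and bridge/non-bridge CG biases. Aggregates
    are rescaled by their maximum so the top class is exactly 1.
    """
    if not isinstance(model, InterferomeClassifier):
        raise TypeError("feature_importance supports tree-based InterferomeClassifier only")
    shap_vals, _ = model.shap_values(features)
    shap_df = pd.DataFrame(shap_vals, index=features.index,
                           columns=model.feature_names_)
    abs_vals = shap_df.abs()
    per_feature = abs_vals.mean(axis=0) if aggregation == "mean" else abs_vals.sum(axis=0)

    classes = dict(feature_classes())
    scheme_members = {m for members in classes.values() for m in members}
    # features outside the canonical scheme each form their own class
    for name in per_feature.index:
        if name not in scheme_members:
            classes[name] = (name,)
    agg = {}
    for cls_name, members in classes.items():
        present = [m for m in members if m in per_feature.index]
        if not present:
            continue
        agg[cls_name] = float(per_feature[present].sum())
    agg = pd.Series(agg)
    max_val = agg.max()
    rescaled = agg / max_val if max_val > 0 else agg
    return ImportanceReport(
        per_feature_mean_abs=per_feature,
        class_aggregate=agg,
        class_rescaled=rescaled,
        shap_matrix=shap_df,
        aggregation=aggregation,
    )
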