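"""CNV presence/subtype classification under the study's resampling protocols.

Two protocols are provided. Plain stratified five-fold cross-validation,
where every eye is scored exactly once out-of-fold, is used for high-signal
outcomes (CNV vs no CNV). For harder subtype outcomes, a stratified 15%
holdout is put aside first and two-stage non-nested tuning runs on the
remaining 85%: stage one eliminates features recursively by the model's
internal importances under cross-validation, stage two grid-searches
hyperparameters on the reduced feature set reusing the same folds; the
refit model is then scored once on the untouched holdout.

The learner is configurable (tree ensembles with internal feature
importances by default; penalized logistic regression as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .evaluate import ROCResult, auroc, bootstrap_ci, roc_curve, youden_cutoff

__all__ = [
    "ModelConfig",
    "LabeledDataset",
    "TrainedModel",
    "RFECurve",
    "CVReport",
    "cross_validate",
    "tune_with_holdout",
    "recursive_feature_elimination",
    "predict",
]

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [None, 4],
    "min_samples_leaf": [1, 5],
}


@dataclass(frozen=True)
class ModelConfig:
    """Learner family and fixed + grid-searched hyperparameters."""

    family: str = "random_forest"  # random_forest | gradient_boosting | logistic
    fixed_params: dict = field(default_factory=dict)
    grid: dict[str, list] = field(default_factory=lambda: dict(DEFAULT_GRID))

    def build(self, seed: int, **overrides):
        params = {**self.fixed_params, **overrides}
        if self.family == "random_forest":
            return RandomForestClassifier(
                n_estimators=params.pop("n_estimators", 100),
                random_state=seed,
                **params,
            )
        if self.family == "gradient_boosting":
            params.pop("min_samples_leaf", None)
            return GradientBoostingClassifier(random_state=seed, **params)
        if self.family == "logistic":
            params.pop("max_depth", None)
            params.pop("min_samples_leaf", None)
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(max_iter=2000, random_state=seed, **params),
            )
        raise ValueError(f"unknown model family {self.family!r}")


def _importances(fitted, n_features: int) -> np.ndarray:
    """Internal feature importances of a fitted learner (|coef| for linear)."""
    if hasattr(fitted, "feature_importances_"):
        return np.asarray(fitted.feature_importances_)
    if hasattr(fitted, "named_steps"):  # scaled logistic pipeline
        lr = fitted.named_steps["logisticregression"]
        return np.abs(lr.coef_).ravel()
    raise TypeError(f"cannot extract importances from {type(fitted).__name__}")


@dataclass
class LabeledDataset:
    """Feature matrix plus a binary outcome derived from FA classes."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = positive class, 0 = negative
    positive_classes: tuple[str, ...]
    negative_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if set(self.positive_classes) & set(self.negative_classes):
            raise ValueError("positive and negative class sets overlap")
        for side, need in ((1, "positive"), (0, "negative")):
            if np.sum(self.y == side) < 2:
                raise ValueError(f"need at least 2 {need} eyes")

    @classmethod
    def from_labels(
        cls,
        X: pd.DataFrame,
        labels: pd.Series,
        positive: Sequence[str],
        negative: Sequence[str],
    ) -> "LabeledDataset":
        keep = labels.isin(list(positive) + list(negative))
        Xk, lk = X.loc[keep], labels.loc[keep]
        y = lk.isin(list(positive)).to_numpy().astype(int)
        return cls(Xk, y, tuple(positive), tuple(negative))

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class TrainedModel:
    """A fitted scorer restricted to its selected features."""

    estimator: object
    feature_names: list[str]
    family: str
    hyperparameters: dict
    seed: int
    n_folds: int

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing[:5]}")
        p = self.estimator.predict_proba(X[self.feature_names].to_numpy())[:, 1]
        return p


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Probability of the positive class for each row of ``X``."""
    return model.predict_proba(X)


@dataclass
class CVReport:
    """Out-of-fold predictions and per-fold / pooled ROC results."""

    oof_scores: np.ndarray
    y: np.ndarray
    fold_assignment: np.ndarray
    fold_results: list[ROCResult]
    pooled: ROCResult

    def per_fold_table(self) -> pd.DataFrame:
        """Per-fold AUROC with sensitivity/specificity at Youden's cutoff."""
        rows = []
        for i, r in enumerate(self.fold_results, start=1):
            c, se, sp = youden_cutoff(r)
            rows.append(
                {"ROC": r.auroc, "Sens": se, "Spec": sp, "Resample": f"Fold {i}"}
            )
        return pd.DataFrame(rows)


def _check_folds(y: np.ndarray, k: int) -> None:
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n_pos, n_neg) < k:
        raise ValueError(
            f"cannot stratify {k} folds with {n_pos} positives / {n_neg} negatives"
        )


def cross_validate(
    dataset: LabeledDataset,
    config: ModelConfig | None = None,
    k: int = 5,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> CVReport:
    """Stratified k-fold CV: each eye is scored exactly once out-of-fold."""
    config = config or ModelConfig()
    names = list(feature_names) if feature_names is not None else list(dataset.X.columns)
    X = dataset.X[names].to_numpy()
    y = dataset.y
    _check_folds(y, k)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    fold_results: list[ROCResult] = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        est = config.build(seed)
        est.fit(X[tr], y[tr])
        p = est.predict_proba(X[te])[:, 1]
        oof[te] = p
        fold_of[te] = fold
        fold_results.append(roc_curve(p, y[te]))
    assert not np.isnan(oof).any()
    pooled = roc_curve(oof, y)
    return CVReport(oof, y.copy(), fold_of, fold_results, pooled)


@dataclass
class RFECurve:
    """AUROC as a function of retained feature count during elimination."""

    stages: list[dict]  # each: n_features, auroc, features (list[str])
    elimination_order: list[str]  # first eliminated first
    final_ranking: list[str]  # most important first

    @property
    def n_features(self) -> list[int]:
        return [s["n_features"] for s in self.stages]

    @property
    def aurocs(self) -> list[float]:
        return [s["auroc"] for s in self.stages]

    def top_features(self, n: int) -> list[str]:
        return self.final_ranking[:n]

    def best_stage(self, within: float = 0.0) -> dict:
        """Smallest feature set whose AUROC is within ``within`` of the max."""
        best = max(self.aurocs)
        ok = [s for s in self.stages if s["auroc"] >= best - within]
        return min(ok, key=lambda s: s["n_features"])


def _step_schedule(n: int, step: int | None) -> int:
    if step is not None:
        return step
    return 5 if n > 30 else 1


def recursive_feature_elimination(
    dataset: LabeledDataset,
    config: ModelConfig | None = None,
    step: int | None = None,
    k: int = 5,
    seed: int = 0,
) -> RFECurve:
    """Recursively drop the least important features, re-cross-validating.

    At each stage the model is cross-validated on the retained set (recording
    AUROC) and refit on all rows to rank features by internal importance;
    the ``step`` lowest-ranked features are dropped. By default the step is
    5 while more than 30 features remain, then 1 — finer resolution near the
    elbow of the curve. Retained sets are nested along the elimination.
    """
    config = config or ModelConfig()
    features = list(dataset.X.columns)
    y = dataset.y
    stages: list[dict] = []
    eliminated: list[str] = []
    final_importance: np.ndarray | None = None
    while features:
        report = cross_validate(dataset, config, k=k, seed=seed, feature_names=features)
        stages.append(
            {
                "n_features": len(features),
                "auroc": report.pooled.auroc,
                "features": list(features),
            }
        )
        est = config.build(seed)
        est.fit(dataset.X[features].to_numpy(), y)
        imp = _importances(est, len(features))
        final_importance = imp
        if len(features) == 1:
            break
        s = min(_step_schedule(len(features), step), len(features) - 1)
        drop_idx = np.argsort(imp, kind="stable")[:s]
        dropped = [features[i] for i in sorted(drop_idx, key=lambda i: imp[i])]
        eliminated.extend(dropped)
        features = [f for i, f in enumerate(features) if i not in set(drop_idx)]
    # Final ranking: survivors by last importance (desc), then reverse elimination.
    survivors = stages[-1]["features"]
    order = np.argsort(-final_importance, kind="stable")
    ranking = [survivors[i] for i in order] + list(reversed(eliminated))
    return RFECurve(stages, eliminated, ranking)


def tune_with_holdout(
    dataset: LabeledDataset,
    config: ModelConfig | None = None,
    holdout_fraction: float = 0.15,
    k: int = 5,
    seed: int = 0,
    rfe_step: int | None = None,
    selection_slack: float = 0.01,
    ci_boot: int = 1000,
) -> tuple[TrainedModel, ROCResult]:
    """Two-stage non-nested tuning on 85% of the data, scored on a 15% holdout.

    The holdout is split off first (stratified) and never touched during
    feature elimination or grid search. Stage 1 runs recursive feature
    elimination on the development split and keeps the smallest feature set
    within ``selection_slack`` AUROC of the best stage; stage 2 grid-searches
    hyperparameters with the same CV folds on the reduced set. The winning
    configuration is refit on the full development split and evaluated once
    on the holdout (AUROC, bootstrap CI, Youden operating point).
    """
    config = config or ModelConfig()
    idx = np.arange(dataset.n)
    dev_idx, hold_idx = train_test_split(
        idx,
        test_size=holdout_fraction,
        stratify=dataset.y,
        random_state=seed,
    )
    y_hold = dataset.y[hold_idx]
    if len(np.unique(y_hold)) < 2:
        raise ValueError(
            "holdout contains a single class; use a different seed or a "
            "larger dataset"
        )
    dev = LabeledDataset(
        dataset.X.iloc[dev_idx],
        dataset.y[dev_idx],
        dataset.positive_classes,
        dataset.negative_classes,
    )

    # Stage 1: supervised feature elimination on the development split.
    curve = recursive_feature_elimination(dev, config, step=rfe_step, k=k, seed=seed)
    selected = curve.best_stage(within=selection_slack)["features"]

    # Stage 2: hyperparameter grid on the reduced set, same folds.
    grid_names = sorted(config.grid)
    best_params, best_auc = {}, -np.inf
    for combo in product(*(config.grid[g] for g in grid_names)):
        params = dict(zip(grid_names, combo))
        cfg = ModelConfig(config.family, {**config.fixed_params, **params}, {})
        rep = cross_validate(dev, cfg, k=k, seed=seed, feature_names=selected)
        if rep.pooled.auroc > best_auc:
            best_auc, best_params = rep.pooled.auroc, params

    est = config.build(seed, **best_params)
    est.fit(dev.X[selected].to_numpy(), dev.y)
    model = TrainedModel(est, list(selected), config.family, best_params, seed, k)

    p_hold = model.predict_proba(dataset.X.iloc[hold_idx])
    roc = roc_curve(p_hold, y_hold)
    roc.ci = bootstrap_ci(p_hold, y_hold, n_boot=ci_boot, seed=seed)
    roc.ci_level = 0.95
    roc.operating_point = youden_cutoff(roc)
    return model, roc
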